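"""Survey record schema, CSV I/O and outcome harmonization.

One row = one girl aged 0–14 with her mother's individual and household
covariates, sampling-cluster and region identifiers, survey year and design
weight.  Different survey waves report daughters differently (eldest only,
most-recently-cut only, or all daughters); :func:`harmonize_outcome` maps any
of them onto the single binary cut/uncut outcome.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical column order of the on-disk CSV
CANONICAL_COLUMNS = [
    "girl_id", "mother_id", "cluster_id", "region_id", "survey_year", "y",
    "age_girl", "age_mother", "mother_cut", "mother_supports_continuation",
    "mother_believes_religious_obligation", "ethnicity", "religion",
    "education", "wealth_quintile", "urban", "weight",
]

EDUCATION_LEVELS = ["none", "primary", "secondary", "higher"]
WEALTH_LEVELS = ["poorest", "poorer", "middle", "richer", "richest"]

#: survey years whose questionnaire lacked the given attitude item
DEFAULT_MISSING_ATTITUDES = {
    2003: ("mother_supports_continuation", "mother_believes_religious_obligation"),
    1998: ("mother_believes_religious_obligation",),
}


class OutcomeRule(enum.Enum):
    ELDEST_DAUGHTER = "eldest_daughter"
    MOST_RECENTLY_CUT_DAUGHTER = "most_recently_cut_daughter"
    ALL_DAUGHTERS = "all_daughters"


#: wave-specific daughter-reporting rules of the Kenya DHS series
DEFAULT_OUTCOME_RULES = {
    1998: OutcomeRule.ELDEST_DAUGHTER,
    2003: OutcomeRule.ELDEST_DAUGHTER,
    2008: OutcomeRule.MOST_RECENTLY_CUT_DAUGHTER,
    2014: OutcomeRule.ALL_DAUGHTERS,
}


@dataclass
class OutcomeDefinition:
    survey_year: int
    rule: OutcomeRule


@dataclass
class SurveyDataset:
    """Validated girl-level survey table.

    ``records`` is a DataFrame in canonical column order; ``(girl_id,
    survey_year)`` is unique.
    """

    records: pd.DataFrame
    schema_version: str = "1"

    @property
    def years(self) -> set[int]:
        return set(int(y) for y in self.records["survey_year"].unique())

    def __len__(self) -> int:
        return len(self.records)

    def write_csv(self, path) -> None:
        self.records[CANONICAL_COLUMNS].to_csv(path, index=False)


def _check_rows(df: pd.DataFrame, missing_attitude_years=None):
    """Row-level invariant checks; returns (ok_mask, diagnostics)."""
    if missing_attitude_years is None:
        missing_attitude_years = DEFAULT_MISSING_ATTITUDES
    diags = []
    ok = np.ones(len(df), dtype=bool)

    def flag(mask, rule):
        nonlocal ok
        bad = np.asarray(mask) & ok
        for idx in df.index[bad]:
            diags.append(f"row {idx}: {rule}")
        ok &= ~np.asarray(mask)

    flag(~df["y"].isin([0, 1]), "y must be 0 or 1")
    flag((df["age_girl"] < 0) | (df["age_girl"] > 14), "age_girl must be in 0..14")
    flag((df["age_mother"] < 15) | (df["age_mother"] > 49), "age_mother must be in 15..49")
    flag(~(df["weight"] > 0), "weight must be positive")
    flag(~df["mother_cut"].isin([0, 1]), "mother_cut must be 0 or 1")
    for col in ("mother_supports_continuation", "mother_believes_religious_obligation"):
        vals = df[col]
        year = df["survey_year"].astype(int)
        allowed_missing = year.map(
            lambda yr: col in missing_attitude_years.get(yr, ())
        ).to_numpy()
        bad = (~vals.isin([0, 1]) & ~vals.isna()) | (vals.isna() & ~allowed_missing)
        flag(bad.to_numpy(), f"{col} must be 0/1 (missing allowed only in flagged years)")
    return ok, diags


def make_dataset(df: pd.DataFrame, strict: bool = True,
                 missing_attitude_years=None) -> tuple[SurveyDataset, list[str]]:
    """Validate a raw girl-level frame into a :class:`SurveyDataset`.

    Non-integer ages are floored (DHS reports completed years).  Rows failing
    invariants are dropped and reported in the returned diagnostics; with
    ``strict`` an empty result raises.
    """
    df = df.copy()
    for col in ("age_girl", "age_mother"):
        frac = df[col] % 1
        if (frac != 0).any():
            import warnings

            warnings.warn(f"non-integer {col} floored to completed years")
        df[col] = np.floor(df[col]).astype(int)
    ok, diags = _check_rows(df, missing_attitude_years)
    df = df.loc[ok].reset_index(drop=True)
    if df.duplicated(["girl_id", "survey_year"]).any():
        raise ValueError("(girl_id, survey_year) must be unique")
    if strict and len(df) == 0:
        raise ValueError("no valid records after filtering")
    return SurveyDataset(df[CANONICAL_COLUMNS]), diags


def read_records(path, schema: dict[str, str] | None = None,
                 strict: bool = True) -> tuple[SurveyDataset, list[str]]:
    """Read a delimited survey file.

    ``schema`` maps canonical field names to the file's column names (DHS
    recode exports vary by wave); omitted entries default to the canonical
    name itself.
    """
    df = pd.read_csv(path)
    if len(df) == 0:
        raise ValueError(f"{path}: empty file")
    schema = schema or {}
    rename = {schema.get(c, c): c for c in CANONICAL_COLUMNS}
    missing = [src for src in rename if src not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mapped columns {missing}")
    df = df.rename(columns=rename)
    return make_dataset(df, strict=strict)


def harmonize_outcome(daughter_rows: pd.DataFrame,
                      defn: OutcomeDefinition) -> pd.DataFrame:
    """Apply a wave's daughter-reporting rule to per-daughter rows.

    Input rows are one per daughter (columns include mother_id, age_girl and
    the cut indicator ``y``), all from ``defn.survey_year``.  Output is the
    girl-level table the wave would have produced:

    - ELDEST_DAUGHTER: at most one row per mother — her eldest daughter aged
      0–14, with that daughter's status;
    - MOST_RECENTLY_CUT_DAUGHTER: the mother's most recently cut daughter if
      any was cut (youngest cut daughter as the proxy for the latest event),
      else her eldest daughter with y = 0;
    - ALL_DAUGHTERS: every daughter aged 0–14.
    """
    if len(daughter_rows) == 0:
        return daughter_rows.copy()
    if not (daughter_rows["survey_year"].astype(int) == defn.survey_year).all():
        raise ValueError("rows' survey_year does not match the outcome definition")
    rows = daughter_rows[(daughter_rows["age_girl"] >= 0)
                         & (daughter_rows["age_girl"] <= 14)]
    if defn.rule is OutcomeRule.ALL_DAUGHTERS:
        return rows.reset_index(drop=True)
    out = []
    for _, grp in rows.groupby("mother_id", sort=False):
        if defn.rule is OutcomeRule.ELDEST_DAUGHTER:
            out.append(grp.loc[[grp["age_girl"].idxmax()]])
        else:  # MOST_RECENTLY_CUT_DAUGHTER
            cut = grp[grp["y"] == 1]
            if len(cut):
                out.append(cut.loc[[cut["age_girl"].idxmin()]])
            else:
                out.append(grp.loc[[grp["age_girl"].idxmax()]])
    return pd.concat(out, ignore_index=True)


@dataclass
class ValidationReport:
    counts_by_year_region: pd.DataFrame
    missingness: pd.Series
    unknown_regions: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.unknown_regions


def validate_dataset(ds: SurveyDataset, graph=None) -> ValidationReport:
    """Report-only consistency summary; never mutates the dataset."""
    df = ds.records
    counts = df.groupby(["survey_year", "region_id"]).size().rename("n").reset_index()
    missing = df.isna().sum()
    unknown = []
    if graph is not None:
        known = set(graph.region_ids)
        unknown = sorted(set(df["region_id"]) - known)
    return ValidationReport(counts, missing, unknown)
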