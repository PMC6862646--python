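"""Community-level normative-influence covariates.

"Community" is the sampling cluster (the DHS primary sampling unit, which
approximates a village or urban neighbourhood).  For every cluster we compute
the share of mothers who are themselves cut, who support continuation of the
practice, and who believe it is a religious requirement, plus the ethnic
fractionalization index

    EFI = 1 - sum_k s_k**2,

a decreasing transform of the Herfindahl concentration of the cluster's
ethnic-group shares s_k: 0 for a monoethnic community, approaching 1 when
many groups are present in equal proportion.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .data_model import SurveyDataset

_ATTR_MAP = {
    "prop_cut": "mother_cut",
    "prop_support": "mother_supports_continuation",
    "prop_religious_req": "mother_believes_religious_obligation",
}


def compute_efi(group_proportions) -> float:
    """Ethnic fractionalization index 1 - Σ s_k² of group shares s_k.

    Shares must be non-negative and sum to 1; sums off by at most 1e-3 are
    renormalized with a warning, larger discrepancies raise.
    """
    s = np.asarray(group_proportions, dtype=float)
    if s.size == 0:
        raise ValueError("at least one group required")
    if (s < 0).any():
        raise ValueError("negative group proportion")
    total = s.sum()
    if abs(total - 1.0) > 1e-8:
        if abs(total - 1.0) <= 1e-3:
            warnings.warn(f"group proportions sum to {total:.6f}; renormalizing")
            s = s / total
        else:
            raise ValueError(f"group proportions sum to {total}, not 1")
    return float(1.0 - np.sum(s**2))


def community_proportions(records: pd.DataFrame, attribute: str,
                          weights=None) -> float:
    """(Weighted) share of non-missing ``attribute`` values equal to 1.

    Returns NaN when every value is missing — e.g. attitude items in survey
    waves whose questionnaire lacked them.
    """
    if len(records) == 0:
        raise ValueError("empty cluster")
    vals = records[attribute]
    obs = vals.notna()
    if not obs.any():
        return float("nan")
    v = vals[obs].astype(float)
    if not v.isin([0.0, 1.0]).all():
        raise ValueError(f"{attribute} is not binary")
    if weights is None:
        return float(v.mean())
    w = np.asarray(weights, dtype=float)[np.asarray(obs)]
    return float(np.sum(w * v) / np.sum(w))


def _mother_level(df: pd.DataFrame) -> pd.DataFrame:
    # one row per mother per cluster-year (a mother's daughters share her values)
    return df.drop_duplicates(["survey_year", "cluster_id", "mother_id"])


def cluster_profiles(ds: SurveyDataset, leave_self_out: bool = False,
                     weighted_efi: bool = False) -> pd.DataFrame:
    """Per-(survey_year, cluster) community profile table.

    Default convention is leave-self-in (a mother contributes to her own
    cluster's shares) with unit weights; ``leave_self_out`` is provided for
    sensitivity checks and returns per-mother rows instead of per-cluster.
    """
    mothers = _mother_level(ds.records)
    rows = []
    for (year, cl), grp in mothers.groupby(["survey_year", "cluster_id"], sort=False):
        eth_w = None
        if weighted_efi:
            eth_w = grp.groupby("ethnicity")["weight"].sum()
        else:
            eth_w = grp.groupby("ethnicity").size()
        efi = compute_efi((eth_w / eth_w.sum()).to_numpy())
        rows.append({
            "survey_year": year, "cluster_id": cl, "n_women": len(grp),
            "prop_cut": community_proportions(grp, "mother_cut"),
            "prop_support": community_proportions(grp, "mother_supports_continuation"),
            "prop_religious_req": community_proportions(
                grp, "mother_believes_religious_obligation"),
            "efi": efi,
        })
    prof = pd.DataFrame(rows)
    if not leave_self_out:
        return prof
    # leave-one-out variant: recompute each mother's covariates excluding her
    loo = []
    for (year, cl), grp in mothers.groupby(["survey_year", "cluster_id"], sort=False):
        for _, m in grp.iterrows():
            rest = grp[grp["mother_id"] != m["mother_id"]]
            if len(rest) == 0:
                rec = {k: float("nan") for k in
                       ("prop_cut", "prop_support", "prop_religious_req", "efi")}
            else:
                shares = rest.groupby("ethnicity").size()
                rec = {
                    "prop_cut": community_proportions(rest, "mother_cut"),
                    "prop_support": community_proportions(
                        rest, "mother_supports_continuation"),
                    "prop_religious_req": community_proportions(
                        rest, "mother_believes_religious_obligation"),
                    "efi": compute_efi((shares / shares.sum()).to_numpy()),
                }
            rec.update(survey_year=year, cluster_id=cl, mother_id=m["mother_id"])
            loo.append(rec)
    return pd.DataFrame(loo)


COMMUNITY_COLUMNS = ["prop_cut", "prop_support", "prop_religious_req", "efi"]


def attach_community_covariates(ds: SurveyDataset,
                                leave_self_out: bool = False) -> SurveyDataset:
    """Join each girl's cluster profile onto her record (idempotent)."""
    df = ds.records.drop(columns=[c for c in COMMUNITY_COLUMNS
                                  if c in ds.records.columns])
    if leave_self_out:
        prof = cluster_profiles(ds, leave_self_out=True)
        out = df.merge(prof, on=["survey_year", "cluster_id", "mother_id"],
                       how="left", validate="many_to_one")
    else:
        prof = cluster_profiles(ds)
        out = df.merge(prof.drop(columns="n_women"),
                       on=["survey_year", "cluster_id"],
                       how="left", validate="many_to_one")
    return SurveyDataset(out, schema_version=ds.schema_version)


def weighted_prevalence(ds: SurveyDataset, by) -> pd.DataFrame:
    """Survey-weighted outcome share Σwᵢyᵢ/Σwᵢ per stratum, with unweighted n.

    Point estimates only — no design-based variance.  Empty strata simply do
    not appear (noted by construction of the group-by).
    """
    if isinstance(by, str):
        by = [by]
    df = ds.records
    if not (df["weight"] > 0).all():
        raise ValueError("weights must be positive")
    g = df.groupby(by, dropna=False)
    out = g.apply(
        lambda s: pd.Series({
            "prevalence": np.sum(s["weight"] * s["y"]) / np.sum(s["weight"]),
            "n": len(s),
        }),
        include_groups=False,
    ).reset_index()
    out["n"] = out["n"].astype(int)
    return out
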