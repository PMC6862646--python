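"""Model suites and run orchestration.

Single-survey analyses fit a nested triple: the normative-influence-only
model (A), the space-adjusted model (B: + structured and unstructured
regional effects), and the fully adjusted model (C: + individual-level
socio-demographic covariates and nonlinear age/EFI effects).  Pooled
multi-survey analyses fit the analogous I/II/III triple, where III adds a
smooth time trend and the space–time interaction surface.  Fits are
compared by DIC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assessment import FitSummary, summarize_fit
from .model import (MCMCConfig, ModelSpec, SmoothConfig, build_design,
                    run_mcmc)
from .spatial import RegionGraph

NORMATIVE_SMOOTHS = ["prop_cut", "prop_support", "prop_religious_req"]
ADJUSTED_LINEAR = ["urban", "religion", "education", "wealth_quintile"]
ADJUSTED_SMOOTHS = ["age_girl", "age_mother", "efi"]

_COMMUNITY_SMOOTH = SmoothConfig(n_inner_knots=8, degree=3, penalty_order=2)
_AGE_SMOOTH = SmoothConfig(n_inner_knots=8, degree=3, penalty_order=2)
_TIME_SMOOTH = SmoothConfig(n_inner_knots=2, degree=2, penalty_order=2)


@dataclass
class SuiteDefinition:
    """One member of a nested model suite."""

    name: str
    spec: ModelSpec
    description: str = ""


def _normative_terms(available: set):
    smooths = {"prop_cut": _COMMUNITY_SMOOTH}
    for extra in ("prop_support", "prop_religious_req"):
        if extra in available:
            smooths[extra] = _COMMUNITY_SMOOTH
    return smooths


def _available_columns(ds) -> set:
    df = ds.records if hasattr(ds, "records") else ds
    return {c for c in df.columns if df[c].notna().any()}


def standard_suite(ds, pooled: bool = False,
                   reference_levels: dict | None = None) -> list:
    """The A/B/C (single survey) or I/II/III (pooled) nested suite.

    Normative covariates absent from the data (attitude items in flagged
    waves) are dropped from every member with the complete-case convention.
    """
    avail = _available_columns(ds)
    refs = reference_levels or {"religion": "christian", "education": "none",
                                "wealth_quintile": "middle"}
    norm = _normative_terms(avail)
    names = ("I", "II", "III") if pooled else ("A", "B", "C")
    # pooled fits keep waves lacking an attitude item in the likelihood and
    # exclude them from that item's smooth only (per-term complete case)
    policy = "zero" if pooled else "drop"
    suite = [
        SuiteDefinition(names[0], ModelSpec(
            linear_terms=["mother_cut"], smooth_terms=dict(norm),
            missing_smooth_policy=policy),
            "Normative influence variables only"),
        SuiteDefinition(names[1], ModelSpec(
            linear_terms=["mother_cut"], smooth_terms=dict(norm),
            spatial_structured=True, spatial_unstructured=True,
            missing_smooth_policy=policy),
            "Normative influence variables and total spatial effects"),
    ]
    full = ModelSpec(
        linear_terms=["mother_cut"] + ADJUSTED_LINEAR,
        reference_levels=refs,
        smooth_terms={**norm, **{t: _AGE_SMOOTH for t in ADJUSTED_SMOOTHS}},
        spatial_structured=True, spatial_unstructured=True,
        time_smooth=_TIME_SMOOTH if pooled else None,
        interaction=pooled, missing_smooth_policy=policy)
    desc = ("Normative variables, space and time, space-time interaction "
            "and other individual-level covariates" if pooled else
            "Normative variables, space and other individual-level covariates")
    suite.append(SuiteDefinition(names[2], full, desc))
    return suite


def run_suite(ds, graph: RegionGraph, suite: list, config: MCMCConfig,
              out_dir=None, level: float = 0.95,
              prevalence_profile: dict | None = None):
    """Fit every suite member with deterministically derived per-model seeds
    and return (summaries, comparison table sorted by DIC).

    A member whose covariates are entirely absent is reported as failed and
    the rest still run.  With ``out_dir`` all artifacts (resolved config,
    draws, tables, log) are persisted so the run is reproducible bit-for-bit
    from the directory contents.
    """
    if not suite:
        raise ValueError("empty suite")
    seed_rng = np.random.default_rng(config.seed)
    member_seeds = seed_rng.integers(0, 2**31 - 1, size=len(suite))
    summaries, rows, failures = {}, [], {}
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    for sd, seed in zip(suite, member_seeds):
        cfg = MCMCConfig(n_iter=config.n_iter, burn_in=config.burn_in,
                         thin=config.thin, seed=int(seed))
        try:
            frame = build_design(ds, graph, sd.spec)
            samples = run_mcmc(frame, cfg)
            summ = summarize_fit(sd.name, samples, frame, level,
                                 prevalence_profile)
        except ValueError as e:
            failures[sd.name] = str(e)
            continue
        summaries[sd.name] = (summ, samples, frame)
        rows.append({"model": sd.name, "description": sd.description,
                     "dic": summ.dic, "pd": summ.pd,
                     "n_obs": summ.n_obs, "n_dropped": summ.n_dropped})
        if out_dir is not None:
            mdir = out_dir / f"model_{sd.name}"
            mdir.mkdir(exist_ok=True)
            samples.to_frame().to_csv(mdir / "draws.csv", index=False)
            summ.por_table.to_csv(mdir / "por.csv", index=False)
            if summ.region_table is not None:
                summ.region_table.to_csv(mdir / "regions.csv", index=False)
            if summ.prevalence is not None:
                summ.prevalence.to_csv(mdir / "prevalence.csv", index=False)
    if not rows:
        raise ValueError(f"no suite member could be fitted: {failures}")
    comparison = pd.DataFrame(rows).sort_values("dic").reset_index(drop=True)
    if out_dir is not None:
        comparison.to_csv(out_dir / "comparison.csv", index=False)
        resolved = {"seed": config.seed, "n_iter": config.n_iter,
                    "burn_in": config.burn_in, "thin": config.thin,
                    "level": level, "failures": failures,
                    "members": [sd.name for sd in suite]}
        (out_dir / "run.json").write_text(json.dumps(resolved, indent=2))
    return summaries, comparison, failures


def export_maps(summary: FitSummary, out_prefix, geometry_path=None):
    """Write map-ready per-region tables; optionally join onto GeoJSON.

    The CSV carries posterior means, credible bounds, significance classes
    and (when fitted) per-year prevalence.  With a GeoJSON whose features
    carry a ``region_id`` property, the same values are attached as feature
    properties for choropleth rendering.
    """
    if summary.region_table is None:
        raise ValueError("fit has no spatial block to map")
    out_prefix = Path(out_prefix)
    table = summary.region_table.copy()
    if summary.prevalence is not None:
        wide = summary.prevalence.pivot_table(
            index="region_id", columns="year", values="prevalence")
        wide.columns = [f"prevalence_{c}" for c in wide.columns]
        table = table.merge(wide.reset_index(), on="region_id", how="left")
    csv_path = out_prefix.with_suffix(".csv")
    table.to_csv(csv_path, index=False)
    written = [csv_path]
    if geometry_path is not None:
        gj = json.loads(Path(geometry_path).read_text())
        have = {f["properties"].get("region_id") for f in gj["features"]}
        missing = set(table["region_id"]) - have
        if missing:
            raise ValueError(f"geometry lacks regions: {sorted(missing)}")
        by_region = table.set_index("region_id")
        for f in gj["features"]:
            rid = f["properties"]["region_id"]
            if rid in by_region.index:
                props = by_region.loc[rid].to_dict()
                f["properties"].update(
                    {k: (v if not isinstance(v, np.generic) else v.item())
                     for k, v in props.items()})
        gj_path = out_prefix.with_suffix(".geojson")
        gj_path.write_text(json.dumps(gj))
        written.append(gj_path)
    return written
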