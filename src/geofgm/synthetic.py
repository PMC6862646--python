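"""Synthetic clustered survey generator with known ground truth.

Emulates the sampling structure of the Kenya DHS series — stratified
two-stage sampling (region → cluster → mother → daughters), eight provinces
with known adjacency, wave-specific daughter-reporting rules, attitude items
absent from flagged questionnaires — and generates binary cut/uncut outcomes
from the exact structured additive predictor the model assumes, so every
stage of the pipeline is testable against known truth without any survey
download.

The default configuration IS the study design: 8 regions × 10 clusters ×
25 mothers per survey year, years 2003/2008/2014, ICAR-distributed
structured spatial effects, iid unstructured effects, nonlinear girl-age /
mother-age / EFI / community-prevalence effects, a declining time trend and
a region-specific space–time interaction.  Covariate distributions are
documented modelling constants, not claims about Kenya.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import attach_community_covariates, compute_efi
from .data_model import (DEFAULT_MISSING_ATTITUDES, DEFAULT_OUTCOME_RULES,
                         OutcomeDefinition, OutcomeRule, SurveyDataset,
                         harmonize_outcome, make_dataset)
from .spatial import RegionGraph, kenya_province_graph, mrf_precision

ETHNIC_GROUPS = ["group_a", "group_b", "group_c", "group_d", "group_e"]
RELIGIONS = ["christian", "muslim", "other"]
EDUCATION = ["none", "primary", "secondary", "higher"]
WEALTH = ["poorest", "poorer", "middle", "richer", "richest"]


def _default_mixtures(n_regions: int) -> np.ndarray:
    """Region-varying ethnic mixtures: each region has a different dominant
    group, with dominance strength varying so EFI spans low to high."""
    k = len(ETHNIC_GROUPS)
    mix = np.full((n_regions, k), 1.0)
    for s in range(n_regions):
        mix[s, s % k] += 3.0 + 2.0 * (s % 3)
    return mix / mix.sum(axis=1, keepdims=True)


# documented smooth-effect shapes (centered near 0 over their ranges)
def shape_age_girl(x):
    return 1.2 / (1.0 + np.exp(-(np.asarray(x, float) - 7.0))) - 0.6


def shape_age_mother(x):
    return -0.03 * (np.asarray(x, float) - 32.0)


def shape_efi(x):
    x = np.asarray(x, float)
    return 0.5 - 1.8 * np.maximum(x - 0.4, 0.0) - 0.5 * x


def shape_prop_cut(x):
    x = np.asarray(x, float)
    return 2.0 * np.maximum(x - 0.5, 0.0) + 0.5 * x - 0.5


@dataclass
class GeneratorConfig:
    graph: RegionGraph = field(default_factory=kenya_province_graph)
    n_clusters_per_region: int = 10
    n_mothers_per_cluster: int = 25
    years: tuple = (2003, 2008, 2014)
    true_beta0: float = -1.0
    true_beta: dict = field(default_factory=lambda: {"mother_cut": 1.5,
                                                     "urban": -0.4})
    smooth_shapes: dict = field(default_factory=lambda: {
        "age_girl": shape_age_girl,
        "age_mother": shape_age_mother,
        "efi": shape_efi,
        "prop_cut": shape_prop_cut,
    })
    time_trend: float = -0.6      # total drop in eta across the year span
    tau_s_true: float = 0.8
    tau_u_true: float = 0.3
    interaction_amplitude: float = 0.3
    mother_cut_rates: np.ndarray = None   # per region; default set below
    ethnicity_mixtures: np.ndarray = None
    mean_daughters: float = 1.3
    outcome_rules: dict = field(default_factory=lambda: dict(DEFAULT_OUTCOME_RULES))
    missing_attitude_years: dict = field(
        default_factory=lambda: dict(DEFAULT_MISSING_ATTITUDES))
    seed: int = 0

    def __post_init__(self):
        s = self.graph.n_regions
        if self.n_clusters_per_region < 1 or self.n_mothers_per_cluster < 1:
            raise ValueError("counts must be >= 1")
        if self.tau_s_true < 0 or self.tau_u_true < 0:
            raise ValueError("variance scales must be nonnegative")
        if self.mother_cut_rates is None:
            # region-varying, between 0.15 and 0.75
            self.mother_cut_rates = 0.15 + 0.6 * (np.arange(s) % 4) / 3.0
        if self.ethnicity_mixtures is None:
            self.ethnicity_mixtures = _default_mixtures(s)
        if not np.allclose(self.ethnicity_mixtures.sum(axis=1), 1.0):
            raise ValueError("ethnicity mixture weights must sum to 1 per region")


@dataclass
class GroundTruth:
    f_str: np.ndarray
    f_unstr: np.ndarray
    beta0: float
    beta: dict
    smooth_grids: dict            # name -> (grid, values)
    interaction_u: np.ndarray     # per-region interaction loading
    time_trend: float
    years: tuple
    reference_profile: dict
    prevalence: pd.DataFrame      # per (region, year) at the reference profile
    config: GeneratorConfig = None

    def eta_reference(self, region_idx: int, year: float) -> float:
        cfg = self.config
        eta = self.beta0
        for name, val in self.reference_profile.items():
            if name in cfg.smooth_shapes:
                eta += float(cfg.smooth_shapes[name](val))
            elif name in self.beta:
                eta += self.beta[name] * val
        eta += self._time_effect(year)
        eta += self.f_str[region_idx] + self.f_unstr[region_idx]
        eta += self._interaction(region_idx, year)
        return float(eta)

    def _time_effect(self, year):
        lo, hi = min(self.years), max(self.years)
        if hi == lo:
            return 0.0
        return self.time_trend * ((year - lo) / (hi - lo) - 0.5)

    def _interaction(self, region_idx, year):
        yrs = np.asarray(self.years, float)
        if len(yrs) < 2:
            return 0.0
        z = (year - yrs.mean()) / (yrs.max() - yrs.min())
        return float(self.config.interaction_amplitude
                     * self.interaction_u[region_idx] * z)


def simulate_spatial_effects(graph: RegionGraph, tau_s: float, tau_u: float,
                             seed: int = 0):
    """Draw (f_str, f_unstr): f_str from the intrinsic MRF restricted to the
    sum-to-zero subspace (covariance τ_s²·Q⁺), f_unstr iid N(0, τ_u²)
    centered."""
    if not graph.is_connected:
        raise ValueError("default policy requires a connected graph")
    rng = np.random.default_rng(seed)
    q = mrf_precision(graph)
    lam, vec = np.linalg.eigh(q)
    pos = lam > 1e-10
    z = rng.standard_normal(pos.sum())
    f_str = tau_s * (vec[:, pos] @ (z / np.sqrt(lam[pos])))
    f_unstr = tau_u * rng.standard_normal(graph.n_regions)
    f_unstr -= f_unstr.mean()
    return f_str, f_unstr


def _sample_mothers(cfg: GeneratorConfig, rng, region_idx, year, cluster_id):
    n = cfg.n_mothers_per_cluster
    eth = rng.choice(len(ETHNIC_GROUPS), size=n,
                     p=cfg.ethnicity_mixtures[region_idx])
    cut = (rng.random(n) < cfg.mother_cut_rates[region_idx]).astype(int)
    # attitudes correlate with the mother's own status
    support = np.where(rng.random(n) < np.where(cut == 1, 0.7, 0.2), 1, 0)
    relig_req = np.where(rng.random(n) < np.where(cut == 1, 0.5, 0.1), 1, 0)
    missing = cfg.missing_attitude_years.get(year, ())
    support = (np.full(n, np.nan)
               if "mother_supports_continuation" in missing else support.astype(float))
    relig_req = (np.full(n, np.nan)
                 if "mother_believes_religious_obligation" in missing
                 else relig_req.astype(float))
    return pd.DataFrame({
        "mother_id": [f"{cluster_id}-m{i}" for i in range(n)],
        "cluster_id": cluster_id,
        "age_mother": rng.integers(15, 50, size=n),
        "ethnicity": [ETHNIC_GROUPS[e] for e in eth],
        "mother_cut": cut,
        "mother_supports_continuation": support,
        "mother_believes_religious_obligation": relig_req,
        "religion": rng.choice(RELIGIONS, size=n, p=[0.7, 0.2, 0.1]),
        "education": rng.choice(EDUCATION, size=n, p=[0.2, 0.45, 0.25, 0.1]),
        "wealth_quintile": rng.choice(WEALTH, size=n, p=[0.2] * 5),
        "urban": int(rng.random() < 0.3),  # urbanicity is a cluster attribute
        "weight": np.exp(rng.normal(0.0, 0.3, size=n)),
    })


def simulate_survey(config: GeneratorConfig) -> tuple[SurveyDataset, GroundTruth]:
    """Generate the full survey with the configured ground truth.

    Hierarchy: per year, each region holds ``n_clusters_per_region``
    clusters of ``n_mothers_per_cluster`` mothers; daughter counts are
    truncated-Poisson; outcomes are Bernoulli at logit⁻¹ of the true
    predictor; finally each year's daughter-reporting rule is applied.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    graph = cfg.graph
    f_str, f_unstr = simulate_spatial_effects(
        graph, cfg.tau_s_true, cfg.tau_u_true, seed=int(rng.integers(2**31)))
    u = rng.standard_normal(graph.n_regions)
    u -= u.mean()
    yrs = np.asarray(cfg.years, float)

    def time_effect(year):
        lo, hi = yrs.min(), yrs.max()
        return 0.0 if hi == lo else cfg.time_trend * ((year - lo) / (hi - lo) - 0.5)

    def interaction(region_idx, year):
        if len(yrs) < 2:
            return 0.0
        z = (year - yrs.mean()) / (yrs.max() - yrs.min())
        return cfg.interaction_amplitude * u[region_idx] * z

    daughter_frames = []
    for year in cfg.years:
        for sidx, region in enumerate(graph.region_ids):
            for c in range(cfg.n_clusters_per_region):
                cluster_id = f"{year}-{region}-c{c}"
                mothers = _sample_mothers(cfg, rng, sidx, year, cluster_id)
                # realized community covariates (leave-self-in, unit weights)
                shares = mothers["ethnicity"].value_counts(normalize=True)
                efi = compute_efi(shares.to_numpy())
                prop_cut = mothers["mother_cut"].mean()
                # every sampled mother has >=1 daughter aged 0-14 (the girl
                # file covers daughters'-module respondents), so the attached
                # community covariates equal the ones that generated eta
                n_d = 1 + np.minimum(
                    rng.poisson(max(cfg.mean_daughters - 1.0, 0.0),
                                size=len(mothers)), 3)
                for m_row, nd in zip(mothers.itertuples(index=False), n_d):
                    ages = rng.integers(0, 15, size=nd)
                    eta = (cfg.true_beta0
                           + cfg.true_beta.get("mother_cut", 0.0) * m_row.mother_cut
                           + cfg.true_beta.get("urban", 0.0) * m_row.urban
                           + cfg.smooth_shapes["age_girl"](ages)
                           + cfg.smooth_shapes["age_mother"](m_row.age_mother)
                           + cfg.smooth_shapes["efi"](efi)
                           + cfg.smooth_shapes["prop_cut"](prop_cut)
                           + time_effect(year)
                           + f_str[sidx] + f_unstr[sidx]
                           + interaction(sidx, year))
                    yvals = (rng.random(nd) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
                    for j in range(nd):
                        daughter_frames.append({
                            "girl_id": f"{m_row.mother_id}-d{j}",
                            "mother_id": m_row.mother_id,
                            "cluster_id": cluster_id,
                            "region_id": region,
                            "survey_year": year,
                            "y": int(yvals[j]),
                            "age_girl": int(ages[j]),
                            "age_mother": int(m_row.age_mother),
                            "mother_cut": int(m_row.mother_cut),
                            "mother_supports_continuation":
                                m_row.mother_supports_continuation,
                            "mother_believes_religious_obligation":
                                m_row.mother_believes_religious_obligation,
                            "ethnicity": m_row.ethnicity,
                            "religion": m_row.religion,
                            "education": m_row.education,
                            "wealth_quintile": m_row.wealth_quintile,
                            "urban": int(m_row.urban),
                            "weight": float(m_row.weight),
                        })
    if not daughter_frames:
        raise ValueError("configuration yielded zero eligible girls")
    daughters = pd.DataFrame(daughter_frames)

    harmonized = []
    for year in cfg.years:
        rule = cfg.outcome_rules.get(year, OutcomeRule.ALL_DAUGHTERS)
        defn = OutcomeDefinition(survey_year=year, rule=rule)
        harmonized.append(
            harmonize_outcome(daughters[daughters["survey_year"] == year], defn))
    girls = pd.concat(harmonized, ignore_index=True)

    ds, diags = make_dataset(girls,
                             missing_attitude_years=cfg.missing_attitude_years)
    assert not diags, f"generator produced invalid rows: {diags[:3]}"
    ds = attach_community_covariates(ds)

    reference_profile = {"mother_cut": 0, "urban": 0, "age_girl": 7,
                         "age_mother": 32, "efi": 0.3, "prop_cut": 0.4}
    truth = GroundTruth(
        f_str=f_str, f_unstr=f_unstr, beta0=cfg.true_beta0,
        beta=dict(cfg.true_beta),
        smooth_grids={
            "age_girl": (np.linspace(0, 14, 29),
                         cfg.smooth_shapes["age_girl"](np.linspace(0, 14, 29))),
            "age_mother": (np.linspace(15, 49, 35),
                           cfg.smooth_shapes["age_mother"](np.linspace(15, 49, 35))),
            "efi": (np.linspace(0, 0.8, 33),
                    cfg.smooth_shapes["efi"](np.linspace(0, 0.8, 33))),
            "prop_cut": (np.linspace(0, 1, 41),
                         cfg.smooth_shapes["prop_cut"](np.linspace(0, 1, 41))),
        },
        interaction_u=u, time_trend=cfg.time_trend, years=tuple(cfg.years),
        reference_profile=reference_profile,
        prevalence=None, config=cfg)
    rows = []
    for sidx, region in enumerate(graph.region_ids):
        for year in cfg.years:
            p = 1.0 / (1.0 + np.exp(-truth.eta_reference(sidx, year)))
            rows.append({"region_id": region, "year": year, "prevalence": p})
    truth.prevalence = pd.DataFrame(rows)
    return ds, truth


def single_year_config(year: int = 2014, seed: int = 0,
                       **overrides) -> GeneratorConfig:
    """One-wave configuration (all-daughters reporting), the desk-scale
    single-survey study design: ~2000 mothers, ~2600 girls."""
    kw = dict(years=(year,), time_trend=0.0, interaction_amplitude=0.0,
              seed=seed)
    kw.update(overrides)
    return GeneratorConfig(**kw)


def recovery_report(truth: GroundTruth, samples, frame) -> pd.DataFrame:
    """Compare a fit with the generator's truth.

    Reports fixed-effect bias and 95% CI coverage, Pearson correlation of
    the posterior-mean total spatial field with the true field, and RMSE of
    the predicted reference-profile prevalence against truth.
    """
    from .assessment import predict_prevalence

    rows = []
    lin = samples.coef["linear"]
    names = samples.columns["linear"]
    for true_name, true_val in truth.beta.items():
        if true_name in names:
            j = names.index(true_name)
            d = lin[:, j]
            lo, hi = np.quantile(d, [0.025, 0.975])
            rows.append({"metric": f"beta[{true_name}]_bias",
                         "value": float(d.mean() - true_val)})
            rows.append({"metric": f"beta[{true_name}]_covered",
                         "value": float(lo <= true_val <= hi)})
    if "f_str" in samples.coef:
        est = samples.coef["f_str"].mean(axis=0)
        tru = truth.f_str.copy()
        if "f_unstr" in samples.coef:
            est = est + samples.coef["f_unstr"].mean(axis=0)
            tru = tru + truth.f_unstr
        r = np.corrcoef(est, tru)[0, 1]
        rows.append({"metric": "spatial_field_pearson_r", "value": float(r)})
        errs = []
        for _, row in truth.prevalence.iterrows():
            yr = row["year"] if len(truth.years) > 1 else None
            pred = predict_prevalence(samples, frame, row["region_id"], yr,
                                      profile=truth.reference_profile)
            errs.append(pred["mean"] - row["prevalence"])
        rows.append({"metric": "prevalence_rmse",
                     "value": float(np.sqrt(np.mean(np.square(errs))))})
    return pd.DataFrame(rows)
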