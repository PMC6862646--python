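"""Structured additive logistic regression with spatial and spline effects.

The linear predictor for girl i in region s at survey time t is

    η_i = β0 + z_i'β + Σ_j f_j(x_ij) + f_y(t_i)
          + f_str(s_i) + f_unstr(s_i) + f_st(s_i, t_i),

with y_i ~ Bernoulli(logit⁻¹(η_i)).  Fixed effects get diffuse Gaussian
priors; each smooth block carries a random-walk penalty prior, f_str an
intrinsic MRF prior on the region graph, f_unstr an iid Gaussian prior, and
the space–time surface a Kronecker-sum penalty.  Every penalized block's
variance has an IG(a, b) hyperprior (defaults a = 1, b = 0.0005).

Estimation is single-chain Gibbs with Pólya–Gamma augmentation: given
ω_i ~ PG(1, η_i), every coefficient block has a Gaussian full conditional
and every variance an inverse-gamma one, so the sampler needs no tuning.
After each sweep the spatial, smooth and interaction blocks are recentered
to sum to zero (the level moves into the intercept; tensor margins move into
the corresponding main effects), which identifies the decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .polya_gamma import polya_gamma
from .smoothers import (bspline_basis, region_indicator_basis, rw_penalty,
                        tensor_basis)
from .spatial import RegionGraph, mrf_precision

FIXED_EFFECT_PRIOR_VAR = 1e4


@dataclass
class SmoothConfig:
    n_inner_knots: int = 20
    degree: int = 3
    penalty_order: int = 2


@dataclass
class ModelSpec:
    """Term structure of the structured additive predictor."""

    linear_terms: list = field(default_factory=list)       # column names
    reference_levels: dict = field(default_factory=dict)   # per categorical
    smooth_terms: dict = field(default_factory=dict)       # name -> SmoothConfig
    time_smooth: SmoothConfig | None = None                # f_y(survey_year)
    spatial_structured: bool = False
    spatial_unstructured: bool = False
    interaction: bool = False
    hyper_a: float = 1.0
    hyper_b: float = 0.0005
    #: "drop" = complete case over all used covariates; "zero" = rows missing
    #: a smooth covariate stay in the likelihood but contribute a zero basis
    #: row to that term (per-term exclusion, for pooled multi-wave fits whose
    #: flagged waves lack an attitude item)
    missing_smooth_policy: str = "drop"

    def __post_init__(self):
        if self.missing_smooth_policy not in ("drop", "zero"):
            raise ValueError("missing_smooth_policy must be 'drop' or 'zero'")
        overlap = set(self.linear_terms) & set(self.smooth_terms)
        if overlap:
            raise ValueError(f"covariates in both linear and smooth blocks: {overlap}")
        if self.hyper_a <= 0 or self.hyper_b <= 0:
            raise ValueError("IG hyperparameters must be positive")
        if self.interaction and not self.spatial_structured:
            raise ValueError("space-time interaction requires the structured "
                             "spatial effect for margin identification")


@dataclass
class MCMCConfig:
    n_iter: int = 20000
    burn_in: int = 2000
    thin: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.n_iter <= self.burn_in:
            raise ValueError("n_iter must exceed burn_in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_stored < 50:
            raise ValueError(f"only {self.n_stored} stored draws; need >= 50")

    @property
    def n_stored(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class Block:
    """One design block of the predictor with its prior precision."""

    name: str
    kind: str                  # linear | smooth | time | str | unstr | interaction
    X: np.ndarray
    K: np.ndarray | None       # prior precision structure (None => fixed-effect)
    rank: int = 0
    columns: list = field(default_factory=list)
    center: str = "none"       # none | obs | units | margins
    basis: object = None       # SplineBasis for prediction
    dims: tuple = None         # (S, K_t) for the interaction block
    obs_rows: np.ndarray = None  # rows contributing to the term (PoU rows)

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class ModelFrame:
    y: np.ndarray
    blocks: list
    region_index: np.ndarray
    graph: RegionGraph
    spec: ModelSpec
    n_dropped: int = 0
    row_index: np.ndarray = None

    @property
    def n(self) -> int:
        return len(self.y)

    def block(self, name) -> Block:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(name)


def _dummy_code(series: pd.Series, name: str, reference=None):
    levels = sorted(series.dropna().unique().tolist())
    if reference is None:
        reference = levels[0]
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} not found for {name}")
    cols, names = [], []
    for lev in levels:
        if lev == reference:
            continue
        cols.append((series == lev).astype(float).to_numpy())
        names.append(f"{name}[{lev}]")
    return cols, names


def build_design(ds, graph: RegionGraph, spec: ModelSpec) -> ModelFrame:
    """Expand a survey dataset into response + design blocks.

    Categorical linear terms are dummy-coded against their reference level;
    smooth terms become P-spline designs; spatial terms become region
    incidence.  Records with a missing value in any used covariate are
    dropped (complete case) and the count reported on the frame.
    """
    df = ds.records if hasattr(ds, "records") else ds
    used = list(spec.linear_terms) + list(spec.smooth_terms)
    for c in used + ["y", "region_id", "survey_year"]:
        if c not in df.columns:
            raise ValueError(f"unknown covariate {c!r}")
    strict = (used if spec.missing_smooth_policy == "drop"
              else list(spec.linear_terms))
    keep = (df[strict].notna().all(axis=1) if strict
            else pd.Series(True, index=df.index))
    n_dropped = int((~keep).sum())
    df = df.loc[keep]
    if len(df) == 0:
        raise ValueError("all rows dropped by complete-case filtering")

    unknown = set(df["region_id"]) - set(graph.region_ids)
    if unknown:
        raise ValueError(f"regions not in graph: {sorted(unknown)}")
    region_index = df["region_id"].map(graph.index).to_numpy()
    y = df["y"].to_numpy(dtype=float)
    n = len(df)

    blocks = []
    lin_cols = [np.ones(n)]
    lin_names = ["(intercept)"]
    for name in spec.linear_terms:
        s = df[name]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            cols, names = _dummy_code(s, name, spec.reference_levels.get(name))
            lin_cols += cols
            lin_names += names
        else:
            lin_cols.append(s.to_numpy(dtype=float))
            lin_names.append(name)
    blocks.append(Block("linear", "linear", np.column_stack(lin_cols), None,
                        columns=lin_names))

    for name, cfg in spec.smooth_terms.items():
        vals = df[name].to_numpy(dtype=float)
        obs = ~np.isnan(vals)
        if not obs.any():
            raise ValueError(f"smooth covariate {name!r} entirely missing")
        basis = bspline_basis(vals[obs], cfg.n_inner_knots, cfg.degree)
        design = np.zeros((n, basis.n_basis))
        design[obs] = basis.design
        pen = rw_penalty(basis.n_basis, cfg.penalty_order)
        blocks.append(Block(f"s({name})", "smooth", design, pen.K,
                            rank=pen.rank, center="obs", basis=basis,
                            obs_rows=obs))

    time_basis = None
    if spec.time_smooth is not None:
        cfg = spec.time_smooth
        time_basis = bspline_basis(df["survey_year"].to_numpy(dtype=float),
                                   cfg.n_inner_knots, cfg.degree)
        pen = rw_penalty(time_basis.n_basis, cfg.penalty_order)
        blocks.append(Block("f(year)", "time", time_basis.design, pen.K,
                            rank=pen.rank, center="obs", basis=time_basis))

    z_region = region_indicator_basis(region_index, graph.n_regions)
    q = mrf_precision(graph) if (spec.spatial_structured or spec.interaction) else None
    if spec.spatial_structured:
        blocks.append(Block("f_str", "str", z_region, q,
                            rank=int(np.linalg.matrix_rank(q)), center="units"))
    if spec.spatial_unstructured:
        blocks.append(Block("f_unstr", "unstr", z_region,
                            np.eye(graph.n_regions), rank=graph.n_regions,
                            center="units"))
    if spec.interaction:
        if time_basis is None:
            raise ValueError("interaction requires a time smooth (shared basis)")
        tb = tensor_basis(z_region, time_basis.design)
        kt = rw_penalty(time_basis.n_basis, spec.time_smooth.penalty_order).K
        k_int = (np.kron(q, np.eye(time_basis.n_basis))
                 + np.kron(np.eye(graph.n_regions), kt))
        blocks.append(Block("f_st", "interaction", tb.design, k_int,
                            rank=int(np.linalg.matrix_rank(k_int)),
                            center="margins", dims=tb.dims))
    return ModelFrame(y=y, blocks=blocks, region_index=region_index,
                      graph=graph, spec=spec, n_dropped=n_dropped,
                      row_index=df.index.to_numpy())


@dataclass
class PosteriorSamples:
    """Stored MCMC draws, one array of shape (n_stored, p_block) per block."""

    coef: dict                    # block name -> draws
    tau2: dict                    # block name -> variance draws (n_stored,)
    columns: dict                 # block name -> column labels
    config: MCMCConfig = None

    @property
    def n_stored(self) -> int:
        return next(iter(self.coef.values())).shape[0]

    @property
    def beta0(self) -> np.ndarray:
        return self.coef["linear"][:, 0]

    def linear_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.coef["linear"], columns=self.columns["linear"])

    def to_frame(self) -> pd.DataFrame:
        """Flatten all draws into one labelled table (plain-text persistable)."""
        parts = {}
        for name, draws in self.coef.items():
            labels = self.columns.get(name) or [f"{name}[{j}]"
                                                for j in range(draws.shape[1])]
            for j, lab in enumerate(labels):
                parts[f"{name}:{lab}"] = draws[:, j]
        for name, d in self.tau2.items():
            parts[f"tau2:{name}"] = d
        return pd.DataFrame(parts)


def assemble_predictor(frame: ModelFrame, params: dict) -> np.ndarray:
    """η from one parameter state {block name -> coefficient vector}."""
    eta = np.zeros(frame.n)
    for b in frame.blocks:
        beta = np.asarray(params[b.name], dtype=float)
        if beta.shape[0] != b.p:
            raise ValueError(f"dimension mismatch for block {b.name}")
        eta += b.X @ beta
    return eta


def _bernoulli_loglik(y, eta):
    # log p(y|eta) = y*eta - log(1+e^eta), computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def log_posterior(frame: ModelFrame, params: dict, tau2: dict) -> float:
    """Unnormalized log posterior (likelihood + all priors).

    Normalizing constants that depend on τ² are kept (they matter for τ²
    conditionals); constants free of all parameters are dropped.
    """
    spec = frame.spec
    eta = assemble_predictor(frame, params)
    lp = _bernoulli_loglik(frame.y, eta)
    for b in frame.blocks:
        beta = np.asarray(params[b.name], dtype=float)
        if b.K is None:
            lp += -0.5 * float(beta @ beta) / FIXED_EFFECT_PRIOR_VAR
            continue
        t2 = tau2[b.name]
        if t2 <= 0:
            raise ValueError(f"nonpositive tau2 for {b.name}")
        lp += -0.5 * float(beta @ b.K @ beta) / t2 - 0.5 * b.rank * np.log(t2)
        # IG(a,b) prior on tau2
        a, bb = spec.hyper_a, spec.hyper_b
        lp += -(a + 1) * np.log(t2) - bb / t2
    return lp


def _recenter(state: dict, frame: ModelFrame) -> None:
    """Sum-to-zero identification; levels/margins move into parent terms."""
    linear = state["linear"]
    for b in frame.blocks:
        beta = state[b.name]
        if b.center == "units":
            c = beta.mean()
            beta -= c
            linear[0] += c
        elif b.center == "obs":
            if b.obs_rows is not None and not b.obs_rows.all():
                # partially observed term: its level is identified by the
                # likelihood (non-contributing rows pin the intercept), and
                # shifting it into the global intercept would alter eta on
                # those rows — leave it uncentered
                continue
            # partition of unity: subtracting c from all coefficients shifts
            # the fitted curve by exactly -c
            c = float(np.mean(b.X @ beta))
            beta -= c
            linear[0] += c
        elif b.center == "margins":
            s_dim, t_dim = b.dims
            theta = beta.reshape(s_dim, t_dim)
            row = theta.mean(axis=1)          # constant-in-time per region
            theta -= row[:, None]
            if "f_str" in state:
                state["f_str"] += row
            else:
                linear[0] += row.mean()
            col = theta.mean(axis=0)          # pure function of time
            theta -= col[None, :]
            if "f(year)" in state:
                state["f(year)"] += col
            else:
                linear[0] += col.mean()
            state[b.name] = theta.ravel()


def run_mcmc(frame: ModelFrame, config: MCMCConfig,
             init_tau2: float = 0.1, progress=None) -> PosteriorSamples:
    """Pólya–Gamma Gibbs sampler for the full model.

    Per sweep: draw ω_i ~ PG(1, η_i); update each coefficient block from its
    Gaussian full conditional N((X'ΩX + P₀)⁻¹ X'(κ - Ω η₋), (X'ΩX + P₀)⁻¹)
    with κ = y - ½; recenter; draw each τ² ~ IG(a + rank/2, b + β'Kβ/2).
    Fixed seed ⇒ bit-identical stored draws.
    """
    y = frame.y
    if y.min() == y.max():
        raise ValueError("response is all 0 or all 1; model not estimable")
    spec = frame.spec
    rng = np.random.default_rng(config.seed)
    pg_seeds = rng.integers(0, 2**31 - 1, size=config.n_iter)

    state = {b.name: np.zeros(b.p) for b in frame.blocks}
    tau2 = {b.name: init_tau2 for b in frame.blocks if b.K is not None}
    kappa = y - 0.5

    stored = {b.name: np.empty((config.n_stored, b.p)) for b in frame.blocks}
    stored_tau2 = {name: np.empty(config.n_stored) for name in tau2}
    k = 0
    for it in range(config.n_iter):
        eta = np.zeros(frame.n)
        for b in frame.blocks:
            eta += b.X @ state[b.name]
        omega = polya_gamma(eta, int(pg_seeds[it]))
        for b in frame.blocks:
            eta -= b.X @ state[b.name]
            xw = b.X * omega[:, None]
            prec = b.X.T @ xw
            if b.K is None:
                prec[np.diag_indices_from(prec)] += 1.0 / FIXED_EFFECT_PRIOR_VAR
            else:
                prec += b.K / tau2[b.name]
            rhs = b.X.T @ (kappa - omega * eta)
            try:
                c, low = cho_factor(prec, lower=True)
            except np.linalg.LinAlgError as e:  # pragma: no cover
                raise RuntimeError(f"non-finite update in block {b.name} at "
                                   f"sweep {it}") from e
            mean = cho_solve((c, low), rhs)
            z = rng.standard_normal(b.p)
            # solve L' u = z gives u with covariance prec^{-1}
            u = solve_triangular(c, z, lower=True, trans="T")
            state[b.name] = mean + u
            eta += b.X @ state[b.name]
        _recenter(state, frame)
        for b in frame.blocks:
            if b.K is None:
                continue
            beta = state[b.name]
            quad = float(beta @ b.K @ beta)
            shape = spec.hyper_a + 0.5 * b.rank
            rate = spec.hyper_b + 0.5 * quad
            tau2[b.name] = 1.0 / rng.gamma(shape, 1.0 / rate)
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0 \
                and k < config.n_stored:
            for b in frame.blocks:
                stored[b.name][k] = state[b.name]
            for name in tau2:
                stored_tau2[name][k] = tau2[name]
            k += 1
        if progress is not None and (it + 1) % progress == 0:
            print(f"  sweep {it + 1}/{config.n_iter}")
    columns = {b.name: b.columns for b in frame.blocks}
    return PosteriorSamples(coef={n: v[:k] for n, v in stored.items()},
                            tau2={n: v[:k] for n, v in stored_tau2.items()},
                            columns=columns, config=config)


def update_variance(block_coefs: np.ndarray, K: np.ndarray, a: float, b: float,
                    rng: np.random.Generator, rank: int | None = None) -> float:
    """Conjugate τ² draw from IG(a + rank(K)/2, b + β'Kβ/2)."""
    if a <= 0 or b <= 0:
        raise ValueError("a, b must be positive")
    beta = np.asarray(block_coefs, dtype=float)
    quad = float(beta @ K @ beta)
    if quad < -1e-8:
        raise ValueError("penalty is not positive semidefinite")
    if rank is None:
        rank = int(np.linalg.matrix_rank(K))
    return float(1.0 / rng.gamma(a + 0.5 * rank, 1.0 / (b + 0.5 * max(quad, 0.0))))


def posterior_eta_draws(frame: ModelFrame, samples: PosteriorSamples) -> np.ndarray:
    """Per-record η for every stored draw, shape (n_stored, n)."""
    out = np.zeros((samples.n_stored, frame.n))
    for b in frame.blocks:
        out += samples.coef[b.name] @ b.X.T
    return out
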