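"""Model assessment: DIC, MCMC effective sample size, posterior odds
ratios, significance-classified regional effects and predicted prevalence.

Two different "effective" quantities are reported and kept clearly apart:
``pd`` is DIC's effective number of parameters (a model-complexity penalty),
while ``ess`` is the effective sample size of an autocorrelated MCMC chain
(a Monte-Carlo precision diagnostic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ModelFrame, PosteriorSamples, posterior_eta_draws

HIGH, LOW, NONSIG = "HIGH", "LOW", "NONSIG"


def _deviance(y, eta):
    return -2.0 * np.sum(y * eta - np.logaddexp(0.0, eta))


def compute_dic(samples: PosteriorSamples, frame: ModelFrame):
    """Deviance information criterion.

    D(θ) = -2 log p(y|η(θ)); dbar is the posterior mean deviance and the
    plug-in deviance is evaluated at the posterior mean of η itself (well
    defined under the sum-to-zero constraints).  pd = dbar - D(η̄),
    dic = dbar + pd.  A negative pd is reported as-is, never clipped.
    """
    etas = posterior_eta_draws(frame, samples)
    if etas.shape[0] < 2:
        raise ValueError("need at least 2 stored draws")
    devs = np.array([_deviance(frame.y, e) for e in etas])
    if not np.isfinite(devs).all():
        raise ValueError("non-finite deviance encountered")
    dbar = float(devs.mean())
    d_at_mean = float(_deviance(frame.y, etas.mean(axis=0)))
    pd_ = dbar - d_at_mean
    return dbar + pd_, pd_, dbar


def mcmc_ess(chain) -> float:
    """Effective sample size N / (1 + 2 Σ ρ_k).

    Autocorrelations are truncated by Geyer's initial positive-sequence
    rule: sums of adjacent autocorrelation pairs are accumulated while they
    stay positive.
    """
    x = np.asarray(chain, dtype=float)
    n = len(x)
    if n < 50:
        raise ValueError("chain too short for ESS")
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var == 0:
        raise ValueError("constant chain: ESS undefined")
    # FFT autocovariance
    m = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, m)
    acov = np.fft.irfft(f * np.conj(f), m)[:n].real / n
    rho = acov / acov[0]
    # Geyer initial positive sequence over pair sums rho[2k]+rho[2k+1]
    s = 0.0
    for k in range(1, n // 2):
        pair = rho[2 * k - 1] + rho[2 * k]
        if pair < 0:
            break
        s += pair
    ess = n / (1.0 + 2.0 * s)
    return float(min(ess, n))


def posterior_odds_ratios(samples: PosteriorSamples,
                          level: float = 0.95) -> pd.DataFrame:
    """POR table: mean of exp(draws) with equal-tail credible interval,
    per non-intercept linear coefficient."""
    draws = samples.coef["linear"]
    names = samples.columns["linear"]
    if draws.shape[1] <= 1:
        raise ValueError("linear block has no covariates")
    lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
    rows = []
    for j in range(1, draws.shape[1]):
        ex = np.exp(draws[:, j])
        rows.append({
            "term": names[j],
            "por": float(ex.mean()),
            f"ci_{lo:g}": float(np.quantile(ex, lo)),
            f"ci_{hi:g}": float(np.quantile(ex, hi)),
        })
    return pd.DataFrame(rows)


def classify_regions(samples: PosteriorSamples, graph, level: float = 0.95,
                     which: str = "total") -> dict:
    """Per-region significance class from the spatial-effect draws.

    HIGH if the equal-tail credible interval lies above 0, LOW if below,
    NONSIG otherwise.  ``which`` selects the total (structured +
    unstructured) or structured-only effect.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0,1)")
    draws = _spatial_draws(samples, which)
    lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
    out = {}
    for j, region in enumerate(graph.region_ids):
        ql, qu = np.quantile(draws[:, j], [lo, hi])
        out[region] = HIGH if ql > 0 else (LOW if qu < 0 else NONSIG)
    return out


def _spatial_draws(samples: PosteriorSamples, which: str) -> np.ndarray:
    if "f_str" not in samples.coef:
        raise ValueError("model has no structured spatial block")
    draws = samples.coef["f_str"]
    if which == "total":
        if "f_unstr" in samples.coef:
            draws = draws + samples.coef["f_unstr"]
    elif which != "structured":
        raise ValueError("which must be 'total' or 'structured'")
    return draws


def spatial_effect_summary(samples: PosteriorSamples, graph,
                           level: float = 0.95,
                           which: str = "total") -> pd.DataFrame:
    draws = _spatial_draws(samples, which)
    lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
    cls = classify_regions(samples, graph, level, which)
    return pd.DataFrame({
        "region_id": graph.region_ids,
        "mean": draws.mean(axis=0),
        f"q{lo:g}": np.quantile(draws, lo, axis=0),
        f"q{hi:g}": np.quantile(draws, hi, axis=0),
        "class": [cls[r] for r in graph.region_ids],
    })


def predict_prevalence(samples: PosteriorSamples, frame: ModelFrame,
                       region, year=None, profile: dict | None = None,
                       level: float = 0.95) -> dict:
    """Posterior predicted prevalence logit⁻¹(η) at a covariate profile.

    ``profile`` maps smooth-term names to values and linear column labels to
    values; anything unspecified defaults to 0 on the design scale (i.e. the
    reference category / centered smooth level).  Years outside the fitted
    spline span are clamped with a warning.
    """
    profile = profile or {}
    graph = frame.graph
    if region not in graph.region_ids:
        raise ValueError(f"unknown region {region!r}")
    sidx = graph.index(region)
    n_draws = samples.n_stored
    eta = np.zeros(n_draws)
    for b in frame.blocks:
        draws = samples.coef[b.name]
        if b.kind == "linear":
            x = np.zeros(b.p)
            x[0] = 1.0
            for j, name in enumerate(b.columns):
                if name in profile:
                    x[j] = profile[name]
            eta += draws @ x
        elif b.kind == "smooth":
            term = b.name[2:-1]  # strip "s(...)"
            if term in profile:
                row = b.basis.evaluate(np.array([float(profile[term])]))[0]
                eta += draws @ row
        elif b.kind == "time":
            if year is not None:
                row = b.basis.evaluate(np.array([float(year)]))[0]
                eta += draws @ row
        elif b.kind in ("str", "unstr"):
            eta += draws[:, sidx]
        elif b.kind == "interaction" and year is not None:
            s_dim, t_dim = b.dims
            trow = frame.block("f(year)").basis.evaluate(
                np.array([float(year)]))[0]
            theta = draws.reshape(n_draws, s_dim, t_dim)
            eta += theta[:, sidx, :] @ trow
    p = 1.0 / (1.0 + np.exp(-eta))
    lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
    return {"mean": float(p.mean()),
            "lower": float(np.quantile(p, lo)),
            "upper": float(np.quantile(p, hi)),
            "eta_draws": eta}


@dataclass
class FitSummary:
    """Everything a run reports for one fitted model."""

    name: str
    dic: float
    pd: float
    dbar: float
    ess: dict
    por_table: pd.DataFrame
    region_table: pd.DataFrame | None = None
    prevalence: pd.DataFrame | None = None
    n_obs: int = 0
    n_dropped: int = 0


def summarize_fit(name: str, samples: PosteriorSamples, frame: ModelFrame,
                  level: float = 0.95,
                  prevalence_profile: dict | None = None) -> FitSummary:
    """Assemble the standard fit report (DIC/pD, ESS, POR table, regional
    classification, prevalence surface where the model supports it)."""
    dic, pd_, dbar = compute_dic(samples, frame)
    ess = {}
    lin = samples.coef["linear"]
    for j, nm in enumerate(samples.columns["linear"]):
        try:
            ess[nm] = mcmc_ess(lin[:, j])
        except ValueError:
            ess[nm] = float("nan")
    por = (posterior_odds_ratios(samples, level)
           if lin.shape[1] > 1 else pd.DataFrame())
    region_table = None
    if "f_str" in samples.coef:
        region_table = spatial_effect_summary(samples, frame.graph, level)
    prev = None
    if "f_str" in samples.coef:
        years = sorted(np.unique(
            frame.block("f(year)").basis.x_range)) if any(
            b.kind == "time" for b in frame.blocks) else [None]
        if any(b.kind == "time" for b in frame.blocks):
            lo, hi = frame.block("f(year)").basis.x_range
            years = list(range(int(lo), int(hi) + 1))
        rows = []
        for region in frame.graph.region_ids:
            for yr in years:
                r = predict_prevalence(samples, frame, region, yr,
                                       prevalence_profile, level)
                rows.append({"region_id": region, "year": yr,
                             "prevalence": r["mean"], "lower": r["lower"],
                             "upper": r["upper"]})
        prev = pd.DataFrame(rows)
    return FitSummary(name=name, dic=dic, pd=pd_, dbar=dbar, ess=ess,
                      por_table=por, region_table=region_table,
                      prevalence=prev, n_obs=frame.n, n_dropped=frame.n_dropped)
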