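"""Independent numerical oracles used by the tests.

Deterministic quadrature for low-dimensional Bayesian logistic posteriors:
nothing here touches the MCMC code path it is used to check.
"""

import numpy as np
from scipy.optimize import minimize


def _log_post(beta, X, y, prior_var):
    eta = X @ beta
    return (np.sum(y * eta - np.logaddexp(0.0, eta))
            - 0.5 * np.sum(beta**2) / prior_var)


def logistic_quadrature(X, y, prior_var=1e4, n_grid=400, half_width=6.0):
    """Posterior means/quantiles for a 1- or 2-parameter logistic model by
    dense grid quadrature centered at the Laplace approximation."""
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    p = X.shape[1]
    assert p in (1, 2)
    res = minimize(lambda b: -_log_post(b, X, y, prior_var), np.zeros(p))
    mode, hess_inv = res.x, res.hess_inv
    sd = np.sqrt(np.diag(hess_inv))
    axes = [np.linspace(mode[j] - half_width * sd[j],
                        mode[j] + half_width * sd[j], n_grid)
            for j in range(p)]
    if p == 1:
        lp = np.array([_log_post(np.array([b]), X, y, prior_var)
                       for b in axes[0]])
        w = np.exp(lp - lp.max())
        w /= w.sum()
        mean = float(np.sum(w * axes[0]))
        cdf = np.cumsum(w)
        q = {lev: float(np.interp(lev, cdf, axes[0]))
             for lev in (0.025, 0.975)}
        # posterior mean of the success probability (intercept-only models)
        pmean = float(np.sum(w / (1 + np.exp(-axes[0]))))
        return {"mean": np.array([mean]), "q": {0: q}, "p_mean": pmean}
    g0, g1 = np.meshgrid(axes[0], axes[1], indexing="ij")
    lp = np.empty(g0.shape)
    for i in range(n_grid):
        etas = np.outer(X[:, 0], np.full(n_grid, axes[0][i])) \
            + np.outer(X[:, 1], axes[1])
        ll = np.sum(y[:, None] * etas - np.logaddexp(0.0, etas), axis=0)
        lp[i] = ll - 0.5 * (axes[0][i]**2 + axes[1]**2) / prior_var
    w = np.exp(lp - lp.max())
    w /= w.sum()
    means = np.array([np.sum(w * g0), np.sum(w * g1)])
    qs = {}
    for j, (grid, marg) in enumerate(
            [(axes[0], w.sum(axis=1)), (axes[1], w.sum(axis=0))]):
        cdf = np.cumsum(marg)
        qs[j] = {lev: float(np.interp(lev, cdf, grid))
                 for lev in (0.025, 0.975)}
    return {"mean": means, "q": qs}


def mc_se(chain):
    """Monte-Carlo standard error of a chain mean via its ESS."""
    from geofgm.assessment import mcmc_ess

    chain = np.asarray(chain, float)
    return float(chain.std(ddof=1) / np.sqrt(mcmc_ess(chain)))


def intercept_only_frame(n_success, n_failure):
    """A minimal one-block model frame for an intercept-only fit."""
    from geofgm.model import Block, ModelFrame, ModelSpec

    y = np.concatenate([np.ones(n_success), np.zeros(n_failure)])
    block = Block("linear", "linear", np.ones((len(y), 1)), None,
                  columns=["(intercept)"])
    return ModelFrame(y=y, blocks=[block], region_index=np.zeros(len(y), int),
                      graph=None, spec=ModelSpec())


def one_covariate_frame(x, y):
    from geofgm.model import Block, ModelFrame, ModelSpec

    X = np.column_stack([np.ones(len(y)), x])
    block = Block("linear", "linear", X, None,
                  columns=["(intercept)", "x"])
    return ModelFrame(y=np.asarray(y, float), blocks=[block],
                      region_index=np.zeros(len(y), int), graph=None,
                      spec=ModelSpec())
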