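"""B-spline bases, random-walk penalties and tensor-product designs.

Smooth terms f(x) = Σ_k β_k B_k(x) use equidistant-knot B-splines with a
random-walk (difference) penalty on the coefficients — the Bayesian P-spline:
the prior density is ∝ exp(-β'Kβ / 2τ²) with K = D'_r D_r for the r-th
difference operator D_r.  The space–time interaction surface is built from
the row-wise Kronecker product of a space basis and a time basis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline


@dataclass
class SplineBasis:
    knots: np.ndarray          # full knot vector incl. boundary extensions
    degree: int
    design: np.ndarray         # n_obs x n_basis
    x_range: tuple = None      # training span, for prediction-time clamping

    @property
    def n_basis(self) -> int:
        return self.design.shape[1]

    def evaluate(self, x) -> np.ndarray:
        """Evaluate the basis at new points, clamping to the training span."""
        x = np.asarray(x, dtype=float)
        lo, hi = self.x_range
        if (x < lo).any() or (x > hi).any():
            warnings.warn("evaluation points outside knot span clamped")
            x = np.clip(x, lo, hi)
        return _design(x, self.knots, self.degree)


@dataclass
class PenaltyMatrix:
    order: int
    K: np.ndarray

    @property
    def rank(self) -> int:
        return self.K.shape[0] - self.order


@dataclass
class TensorBasis:
    design: np.ndarray
    dims: tuple                # (K_s, K_t)
    meta: dict = field(default_factory=dict)


def _design(x, knots, degree):
    d = BSpline.design_matrix(x, knots, degree, extrapolate=False).toarray()
    return d


def bspline_basis(x, n_inner_knots: int = 20, degree: int = 3,
                  x_range=None) -> SplineBasis:
    """Equidistant-knot B-spline design over the data range.

    ``n_inner_knots`` interior knots give n_inner_knots + degree + 1 basis
    functions; the boundary knots are repeated degree+1 times so the basis is
    a partition of unity over the whole span.
    """
    x = np.asarray(x, dtype=float)
    if n_inner_knots < 1:
        raise ValueError("n_inner_knots must be >= 1")
    if degree < 0:
        raise ValueError("degree must be >= 0")
    lo, hi = x_range if x_range is not None else (x.min(), x.max())
    if lo == hi:
        raise ValueError("degenerate data range for spline basis")
    inner = np.linspace(lo, hi, n_inner_knots + 2)
    knots = np.concatenate([np.repeat(lo, degree), inner, np.repeat(hi, degree)])
    design = _design(x, knots, degree)
    n_basis = design.shape[1]
    if len(np.unique(x)) < n_basis:
        warnings.warn(f"fewer distinct x values ({len(np.unique(x))}) than "
                      f"basis functions ({n_basis}); penalty carries the fit")
    return SplineBasis(knots=knots, degree=degree, design=design,
                       x_range=(float(lo), float(hi)))


def rw_penalty(n_basis: int, order: int = 2) -> PenaltyMatrix:
    """Random-walk penalty K = D'_order D_order on spline coefficients.

    β'Kβ is the sum of squared order-th differences; the null space holds
    constants (order 1) and additionally linear trends (order 2), so those
    components are left unpenalized — identification comes from centering.
    """
    if order < 1 or order >= n_basis:
        raise ValueError("need n_basis > order >= 1")
    d = np.diff(np.eye(n_basis), n=order, axis=0)
    return PenaltyMatrix(order=order, K=d.T @ d)


def tensor_basis(design_s: np.ndarray, design_t: np.ndarray,
                 meta: dict | None = None) -> TensorBasis:
    """Row-wise Kronecker product: column (k, j) is B_sk(s_i) · B_tj(t_i).

    When both margins are partitions of unity every row of the tensor design
    sums to one as well.
    """
    a = np.asarray(design_s, dtype=float)
    b = np.asarray(design_t, dtype=float)
    if a.shape[0] != b.shape[0]:
        raise ValueError("marginal designs must share observations")
    n = a.shape[0]
    design = (a[:, :, None] * b[:, None, :]).reshape(n, -1)
    return TensorBasis(design=design, dims=(a.shape[1], b.shape[1]),
                       meta=meta or {})


def region_indicator_basis(region_idx: np.ndarray, n_regions: int) -> np.ndarray:
    """One-hot incidence matrix mapping observations to areal units."""
    z = np.zeros((len(region_idx), n_regions))
    z[np.arange(len(region_idx)), region_idx] = 1.0
    return z
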