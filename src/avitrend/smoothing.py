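"""Penalized-spline smoothing of log index series and annual growth rates.

Each species' index series is smoothed on the natural-log scale with a
penalized cubic B-spline regression: a B-spline basis with an exact
integrated-squared-curvature penalty ∫(f″)².  Observations are weighted by
the inverse of their log-scale error variance, and the smoothing parameter
is chosen by generalized cross-validation.  Because the penalty null space
contains exactly the straight lines, the fit reproduces log-linear input
for any penalty, and in the infinite-penalty limit collapses onto the
weighted least-squares straight line.

Fitted values and standard errors are returned on the log scale at every
calendar year in the observed span, including interior years with no data,
which is what the downstream hierarchical model consumes.

A species' average annual growth rate is the endpoint log difference of its
smoothed series divided by the span in years (a log rate, per year).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

from .datamodel import IndexSeries

_SE_LOG_FLOOR = 1e-6


@dataclass
class SmoothedSeries:
    """Smoothed log index with per-year SEs and the derived growth rate."""

    species_id: str
    years: np.ndarray
    smoothed_log_index: np.ndarray
    se_log: np.ndarray
    growth_rate: float
    observed: np.ndarray | None = None  # mask: year had data
    fallback_linear: bool = False


def log_transform_series(series: IndexSeries) -> tuple[np.ndarray, np.ndarray]:
    """Log index and delta-method log-scale SE (se_log = se/index)."""
    if np.any(series.index <= 0):
        raise ValueError(f"series {series.species_id!r}: non-positive index values")
    log_index = np.log(series.index)
    se_log = np.maximum(series.se / series.index, _SE_LOG_FLOOR)
    return log_index, se_log


def _knot_vector(xmin: float, xmax: float, n_basis: int, degree: int = 3) -> np.ndarray:
    n_interior = n_basis - degree - 1
    if n_interior < 0:
        raise ValueError("n_basis too small for cubic splines")
    interior = np.linspace(xmin, xmax, n_interior + 2)[1:-1]
    return np.concatenate(
        [np.full(degree + 1, xmin), interior, np.full(degree + 1, xmax)]
    )


def bspline_basis(x: np.ndarray, xmin: float, xmax: float, n_basis: int, degree: int = 3) -> np.ndarray:
    """Cubic B-spline design matrix with equally spaced knots over [xmin, xmax]."""
    knots = _knot_vector(xmin, xmax, n_basis, degree)
    return BSpline.design_matrix(x, knots, degree, extrapolate=False).toarray()


def curvature_penalty(xmin: float, xmax: float, n_basis: int, degree: int = 3) -> np.ndarray:
    """Exact ∫(f″)² penalty matrix by two-point Gauss quadrature per interval.

    The null space contains exactly the straight lines, so an infinite
    penalty collapses the fit onto the weighted least-squares line.
    """
    knots = _knot_vector(xmin, xmax, n_basis, degree)
    spl = BSpline(knots, np.eye(n_basis), degree)
    d2 = spl.derivative(2)
    P = np.zeros((n_basis, n_basis))
    g = 1.0 / np.sqrt(3.0)  # 2-point Gauss–Legendre nodes on [-1, 1]
    breaks = np.unique(knots)
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        half = 0.5 * (hi - lo)
        mid = 0.5 * (hi + lo)
        for node in (-g, g):
            B2 = d2(mid + half * node)
            P += half * np.outer(B2, B2)
    return P


def default_basis_size(n_obs: int) -> int:
    """min(10, ceil(n/3)), floored at 4 (the cubic minimum)."""
    return max(4, min(10, int(np.ceil(n_obs / 3))))


def _pspline_solve(
    B: np.ndarray, y: np.ndarray, w: np.ndarray, P: np.ndarray, lam: float
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted penalized LS: coefficients and hat-forming matrix."""
    BtW = B.T * w
    A = BtW @ B + lam * P
    coef = np.linalg.solve(A, BtW @ y)
    # M maps y -> coef; fitted = B @ M @ y
    M = np.linalg.solve(A, BtW)
    return coef, M


def _gcv_score(B, y, w, P, lam) -> float:
    coef, M = _pspline_solve(B, y, w, P, lam)
    fitted = B @ coef
    resid = y - fitted
    edf = np.trace(B @ M)
    n = len(y)
    denom = max(n - edf, 1e-8)
    return float(n * np.sum(w * resid**2) / denom**2)


def fit_gam(
    series: IndexSeries,
    basis_size: int | None = None,
    lam: float | None = None,
) -> SmoothedSeries:
    """Penalized cubic-spline smooth of the log index, weighted by 1/se_log².

    The smoothing parameter is chosen by generalized cross-validation over a
    log-spaced grid unless ``lam`` fixes it.  Series with fewer than 4
    observations fall back to a weighted log-linear fit, flagged on the
    result.  Fitted values and SEs are evaluated at every year in the span.
    """
    y_obs, se_log = log_transform_series(series)
    w = 1.0 / se_log**2
    x_obs = series.years.astype(float)
    years_full = np.arange(series.years[0], series.years[-1] + 1)
    observed = np.isin(years_full, series.years)
    n = len(series)

    if n < 4:
        return _linear_fallback(series, y_obs, w, years_full, observed)

    k = basis_size if basis_size is not None else default_basis_size(n)
    k = min(k, n)  # never more basis functions than observations
    if k < 4:
        return _linear_fallback(series, y_obs, w, years_full, observed)

    xmin, xmax = float(series.years[0]), float(series.years[-1])
    B = bspline_basis(x_obs, xmin, xmax, k)
    P = curvature_penalty(xmin, xmax, k)

    if lam is None:
        grid = np.logspace(-3, 8, 23)
        scores = [_gcv_score(B, y_obs, w, P, g) for g in grid]
        lam = float(grid[int(np.argmin(scores))])

    coef, M = _pspline_solve(B, y_obs, w, P, lam)
    B_full = bspline_basis(years_full.astype(float), xmin, xmax, k)

    fitted_full = B_full @ coef
    # Var(fitted) = B_full M V M' B_full'  with V = diag(se_log^2)
    MV = M * se_log**2
    cov_coef = MV @ M.T
    var_full = np.einsum("ij,jk,ik->i", B_full, cov_coef, B_full)
    se_full = np.sqrt(np.maximum(var_full, 0.0))

    gr = _endpoint_rate(years_full, fitted_full)
    return SmoothedSeries(
        species_id=series.species_id,
        years=years_full,
        smoothed_log_index=fitted_full,
        se_log=se_full,
        growth_rate=gr,
        observed=observed,
    )


def _linear_fallback(series, y_obs, w, years_full, observed) -> SmoothedSeries:
    x = series.years.astype(float)
    X = np.column_stack([np.ones_like(x), x])
    XtW = X.T * w
    A = XtW @ X
    coef = np.linalg.solve(A, XtW @ y_obs)
    cov = np.linalg.inv(A)  # weights are inverse variances, so this is exact
    Xf = np.column_stack([np.ones(len(years_full)), years_full.astype(float)])
    fitted = Xf @ coef
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xf, cov, Xf), 0.0))
    return SmoothedSeries(
        species_id=series.species_id,
        years=years_full,
        smoothed_log_index=fitted,
        se_log=se,
        growth_rate=_endpoint_rate(years_full, fitted),
        observed=observed,
        fallback_linear=True,
    )


def _endpoint_rate(years: np.ndarray, log_values: np.ndarray) -> float:
    span = years[-1] - years[0]
    if span < 1:
        return 0.0
    return float((log_values[-1] - log_values[0]) / span)


def annual_growth_rate(s: SmoothedSeries) -> float:
    """Average log annual rate of change: endpoint log difference / span."""
    return _endpoint_rate(s.years, s.smoothed_log_index)
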