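"""Two-segment continuous breakpoint regression on log total abundance.

The log of the total-abundance series is fit with a continuous piecewise
line: a common intercept and slope plus a hinge term max(0, year − b) whose
coefficient is the change in slope at the breakpoint b.  Every interior year
with at least three points on each side is tried; the fit with minimal
residual sum of squares wins.  Slopes are reported as 100 × the per-year
change in natural-log total (percent-per-annum convention), with normal
95% confidence intervals from segment-wise standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class PiecewiseFit:
    breakpoint_year: int
    slope1: float  # percent per annum
    slope2: float
    slope1_ci: tuple[float, float]
    slope2_ci: tuple[float, float]
    r2: float
    sse: float
    degenerate: bool = False  # straight-line input: breakpoint arbitrary
    single_line: bool = False  # no admissible breakpoint


def _hinge_design(years: np.ndarray, bp: float) -> np.ndarray:
    return np.column_stack(
        [np.ones_like(years), years, np.maximum(years - bp, 0.0)]
    )


def _fit_at(years: np.ndarray, y: np.ndarray, bp: float):
    X = _hinge_design(years, bp)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid), X


def candidate_breakpoints(years: np.ndarray, min_per_side: int = 3) -> np.ndarray:
    """Interior years leaving at least ``min_per_side`` points per segment."""
    return np.array(
        [
            b
            for b in years[1:-1]
            if (years <= b).sum() >= min_per_side and (years > b).sum() >= min_per_side
        ]
    )


def fit_piecewise(years: np.ndarray, log_totals: np.ndarray) -> PiecewiseFit:
    """Grid search over candidate breakpoints; minimal-SSE two-segment fit."""
    years = np.asarray(years, dtype=float)
    y = np.asarray(log_totals, dtype=float)
    if len(years) < 7:
        raise ValueError("need at least 7 observations")

    candidates = candidate_breakpoints(years)
    if candidates.size == 0:
        return _single_line(years, y)

    fits = [( *_fit_at(years, y, b), b) for b in candidates]
    beta, sse, X, bp = min(fits, key=lambda f: f[1])

    n = len(y)
    dof = max(n - 3, 1)
    s2 = sse / dof
    XtX_inv = np.linalg.inv(X.T @ X)
    cov = s2 * XtX_inv
    slope1 = beta[1]
    slope2 = beta[1] + beta[2]
    var1 = cov[1, 1]
    var2 = cov[1, 1] + cov[2, 2] + 2 * cov[1, 2]
    tcrit = stats.t.ppf(0.975, dof)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 1.0

    degenerate = abs(beta[2]) < 1e-10 * max(abs(beta[1]), 1e-12)
    return PiecewiseFit(
        breakpoint_year=int(bp),
        slope1=100.0 * slope1,
        slope2=100.0 * slope2,
        slope1_ci=(
            100.0 * (slope1 - tcrit * np.sqrt(var1)),
            100.0 * (slope1 + tcrit * np.sqrt(var1)),
        ),
        slope2_ci=(
            100.0 * (slope2 - tcrit * np.sqrt(max(var2, 0.0))),
            100.0 * (slope2 + tcrit * np.sqrt(max(var2, 0.0))),
        ),
        r2=max(min(r2, 1.0), 0.0),
        sse=sse,
        degenerate=degenerate,
    )


def _single_line(years: np.ndarray, y: np.ndarray) -> PiecewiseFit:
    X = np.column_stack([np.ones_like(years), years])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sse = float(resid @ resid)
    dof = max(len(y) - 2, 1)
    s2 = sse / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    tcrit = stats.t.ppf(0.975, dof)
    half = tcrit * np.sqrt(cov[1, 1])
    sst = float(((y - y.mean()) ** 2).sum())
    ci = (100.0 * (beta[1] - half), 100.0 * (beta[1] + half))
    return PiecewiseFit(
        breakpoint_year=int(years[len(years) // 2]),
        slope1=100.0 * beta[1],
        slope2=100.0 * beta[1],
        slope1_ci=ci,
        slope2_ci=ci,
        r2=max(min(1.0 - sse / sst if sst > 0 else 1.0, 1.0), 0.0),
        sse=sse,
        single_line=True,
        degenerate=True,
    )
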