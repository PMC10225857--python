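"""Climate suitability trends (CST).

A species' CST is the slope of an ordinary least-squares regression of the
logit of its modelled mean annual climate suitability against year: positive
values mean climatic conditions across the species' range are improving.

Annual suitability series can come from any species distribution model; a
single logistic GLM (linear + quadratic terms in each climate covariate) is
provided here to produce them from occurrence and climate data.  The logit
slope, not the SDM, is the quantity consumed downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .datamodel import ValidationError

_EPS = 1e-6


@dataclass
class SuitabilitySeries:
    """Annual mean climate suitability (probabilities) for one species."""

    species_id: str
    years: np.ndarray
    suitability: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.suitability = np.asarray(self.suitability, dtype=float)
        if len(self.years) != len(self.suitability):
            raise ValidationError(f"{self.species_id!r}: years/suitability length mismatch")


@dataclass(frozen=True)
class CSTValue:
    species_id: str
    slope: float
    se: float
    r2: float
    p_value: float


@dataclass
class SDMFit:
    """Fitted logistic suitability model: linear + quadratic per covariate."""

    covariate_names: list[str]
    coef: np.ndarray  # intercept, then (linear, quadratic) per covariate
    penalized: bool
    result: object

    def predict(self, climate: np.ndarray) -> np.ndarray:
        X = _sdm_design(np.asarray(climate, dtype=float))
        eta = X @ self.coef
        return 1.0 / (1.0 + np.exp(-eta))


def _sdm_design(climate: np.ndarray) -> np.ndarray:
    if climate.ndim == 1:
        climate = climate[:, None]
    return np.column_stack([np.ones(len(climate)), climate, climate**2])


def fit_sdm(
    occurrence: np.ndarray,
    climate: np.ndarray,
    covariate_names: list[str] | None = None,
    min_presences: int = 20,
) -> SDMFit:
    """Logistic regression of presence/absence on climate covariates.

    The design includes linear and quadratic terms for every covariate
    (suitability is expected to peak at intermediate climates).  Complete or
    quasi-complete separation triggers an L2-penalized refit with a warning.
    """
    occurrence = np.asarray(occurrence, dtype=float)
    climate = np.asarray(climate, dtype=float)
    if climate.ndim == 1:
        climate = climate[:, None]
    if not np.all(np.isfinite(climate)):
        raise ValueError("climate covariates must be finite")
    n_pres = int(occurrence.sum())
    if n_pres < min_presences:
        raise ValueError(f"need >= {min_presences} presences, got {n_pres}")
    names = covariate_names or [f"clim{i+1}" for i in range(climate.shape[1])]
    X = _sdm_design(climate)
    penalized = False
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        try:
            res = sm.GLM(occurrence, X, family=sm.families.Binomial()).fit()
            coef = np.asarray(res.params)
            if not np.all(np.isfinite(res.bse)) or np.max(np.abs(coef)) > 1e3:
                raise RuntimeError("separation suspected")
        except Exception:
            penalized = True
    if penalized:
        warnings.warn(
            "separation detected; refitting with a ridge penalty", stacklevel=2
        )
        res = sm.GLM(occurrence, X, family=sm.families.Binomial()).fit_regularized(
            alpha=1e-3, L1_wt=0.0
        )
        coef = np.asarray(res.params)
    return SDMFit(covariate_names=names, coef=coef, penalized=penalized, result=res)


def predict_annual_suitability(
    fit: SDMFit, annual_climate: dict[int, np.ndarray], species_id: str
) -> SuitabilitySeries:
    """Mean predicted occurrence probability across cells, per year."""
    years = sorted(annual_climate)
    suit = np.array([float(np.mean(fit.predict(annual_climate[y]))) for y in years])
    return SuitabilitySeries(species_id, np.array(years), suit)


def cst_slope(series: SuitabilitySeries) -> CSTValue:
    """OLS slope of logit(suitability) on year, with SE, R² and p-value.

    Suitability values outside (0,1) are clamped to [1e-6, 1−1e-6] with a
    warning before the logit.
    """
    if len(series.years) < 5:
        raise ValueError(f"{series.species_id!r}: need >= 5 years for a CST")
    s = series.suitability
    if np.any(s <= 0) or np.any(s >= 1):
        warnings.warn(
            f"{series.species_id!r}: suitability clamped into (0,1)", stacklevel=2
        )
        s = np.clip(s, _EPS, 1 - _EPS)
    y = np.log(s / (1 - s))
    X = sm.add_constant(series.years.astype(float))
    res = sm.OLS(y, X).fit()
    return CSTValue(
        species_id=series.species_id,
        slope=float(res.params[1]),
        se=float(res.bse[1]),
        r2=float(res.rsquared) if np.isfinite(res.rsquared) else 0.0,
        p_value=float(res.pvalues[1]),
    )
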