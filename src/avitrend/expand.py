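"""Reconstruct annual national population series from mean trends.

For species lacking annual monitoring indices, national reporting supplies a
mean multiplicative trend T̄ over a stated period, a mean population estimate
Ē_N and the mean year ȳ the estimate refers to.  The annual multiplier is

    λ = T̄^(1 / trend_period)

and the population in year i is reconstructed geometrically as

    Ē_N(i) = Ē_N(ȳ) · λ^(i − ȳ).

National series are summed across countries to an assemblage-level series,
and 95% bounds are attached by a parametric bootstrap that redraws each
country's population estimate lognormally (median at the point estimate,
log-sd matched to its standard error by the delta method) and each trend
multiplier lognormally when a trend SE is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datamodel import NationalTrendRecord, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ReconstructedSeries:
    """Annual population (individuals) for one species in one country (or summed)."""

    species_id: str
    country: str
    years: np.ndarray
    population: np.ndarray
    lcl: np.ndarray | None = None
    ucl: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.population = np.asarray(self.population, dtype=float)
        if len(self.years) != len(self.population):
            raise ValidationError("years/population length mismatch")


def annual_multiplier(mean_trend: float, trend_period: float) -> float:
    """λ = T̄^(1/period): the per-year multiplicative change."""
    if not (mean_trend > 0):
        raise ValueError(f"mean_trend must be > 0, got {mean_trend}")
    if not (trend_period > 0):
        raise ValueError(f"trend_period must be > 0, got {trend_period}")
    return float(mean_trend ** (1.0 / trend_period))


def reconstruct_series(
    rec: NationalTrendRecord, years: np.ndarray | range
) -> ReconstructedSeries:
    """Geometric reconstruction Ē_N(i) = Ē_N(ȳ)·λ^(i−ȳ) over ``years``."""
    years = np.asarray(list(years), dtype=int)
    lam = annual_multiplier(rec.mean_trend, rec.trend_period)
    pop = rec.mean_pop * lam ** (years - rec.mean_estimate_year)
    horizon = np.max(np.abs(years - rec.mean_estimate_year))
    if horizon > rec.trend_period:
        logger.info(
            "species %s country %s: extrapolating %d years beyond a %g-year trend period",
            rec.species_id,
            rec.country,
            int(horizon),
            rec.trend_period,
        )
    return ReconstructedSeries(rec.species_id, rec.country, years, pop)


def eu_point_estimate(min_sum: float, max_sum: float) -> tuple[float, float]:
    """Point estimate and SE from summed national min/max bounds.

    point = sqrt(min·max) (geometric mean); se = (max − min)/6.  A best-only
    value passed as both min and max yields se = 0.
    """
    if not (0 < min_sum <= max_sum):
        raise ValidationError(f"need 0 < min <= max, got ({min_sum}, {max_sum})")
    point = float(np.sqrt(min_sum * max_sum))
    se = float((max_sum - min_sum) / 6.0)
    return point, se


def sum_national_series(
    series: list[ReconstructedSeries],
) -> ReconstructedSeries:
    """Sum national series on a common year grid into one assemblage series."""
    if not series:
        raise ValueError("no series to sum")
    years = series[0].years
    for s in series[1:]:
        if len(s.years) != len(years) or np.any(s.years != years):
            raise ValueError(
                f"year grids differ between {series[0].country!r} and {s.country!r}"
            )
    total = np.sum([s.population for s in series], axis=0)
    return ReconstructedSeries(series[0].species_id, "ALL", years, total)


def bootstrap_ci(
    estimator,
    draw_inputs,
    n: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical 2.5/97.5 percentile bounds over ``n`` replicate estimates.

    ``draw_inputs(rng)`` must return one random replicate of the estimator's
    inputs; ``estimator(inputs)`` maps them to a scalar or array estimate.
    Deterministic under a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    reps = np.asarray([estimator(draw_inputs(rng)) for _ in range(n)], dtype=float)
    lcl = np.percentile(reps, 2.5, axis=0)
    ucl = np.percentile(reps, 97.5, axis=0)
    return lcl, ucl


def lognormal_sigma(point: float, se: float) -> float:
    """Log-sd matched to a measurement-scale SE by the delta method (σ ≈ se/point)."""
    if point <= 0:
        raise ValueError("point must be > 0")
    return se / point


def reconstruct_species_eu_series(
    records: list[NationalTrendRecord],
    years: np.ndarray | range,
    pop_se: dict[str, float] | None = None,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> ReconstructedSeries:
    """National reconstructions summed across countries, with bootstrap bounds.

    Each bootstrap replicate redraws every country's mean population estimate
    lognormally with median at its point value and log-sd matched to the
    standard error in ``pop_se`` (keyed by country) by the delta method;
    countries are drawn independently.  The summed series' per-year 2.5/97.5
    percentiles become the bounds.  With no uncertainty inputs (or all SEs
    zero) the bounds collapse onto the point series.
    """
    if not records:
        raise ValueError("no national trend records")
    years = np.asarray(list(years), dtype=int)
    point = sum_national_series([reconstruct_series(r, years) for r in records])

    sigmas = {
        r.country: lognormal_sigma(r.mean_pop, (pop_se or {}).get(r.country, 0.0))
        for r in records
    }
    if not any(s > 0 for s in sigmas.values()):
        point.lcl = point.population.copy()
        point.ucl = point.population.copy()
        return point

    def draw(rng: np.random.Generator):
        return [
            NationalTrendRecord(
                r.species_id,
                r.country,
                r.mean_trend,
                r.trend_period,
                r.mean_pop * float(np.exp(rng.normal(0.0, sigmas[r.country]))),
                r.mean_estimate_year,
            )
            for r in records
        ]

    def est(drawn):
        return sum_national_series(
            [reconstruct_series(r, years) for r in drawn]
        ).population

    point.lcl, point.ucl = bootstrap_ci(est, draw, n=n_bootstrap, seed=seed)
    return point
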