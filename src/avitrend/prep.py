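"""Time-series inclusion, zero-handling and coverage rules.

Raw monitoring index series are cleaned before smoothing:

* a series is truncated to start at its first positive count, and if zero
  counts remain in the retained window, 1% of the mean retained raw value is
  added to every retained value so the series can be log-transformed;
* a species is excluded when the monitoring data behind the most recent year
  of its series represent less than 50% of its current population, and
  individual years with coverage below 5% are dropped;
* a series whose first and last years are less than ``min_span_years``
  (default 10) apart is excluded;
* named species can be excluded via the config exclusion list (used in
  practice for species with imprecise, strongly negative trends).

Exclusions are signalled as results carrying machine-readable reasons, never
as exceptions: a filtered species is an expected outcome, not an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import AnalysisConfig, IndexSeries

FINAL_COVERAGE_MIN = 0.5
YEAR_COVERAGE_MIN = 0.05
ZERO_OFFSET_FRACTION = 0.01
MIN_SPAN_YEARS = 10


@dataclass
class PrepReport:
    """Record of which preparation rules fired for one species."""

    species_id: str
    rules_applied: list[str] = field(default_factory=list)
    offset_value: float = 0.0
    excluded: bool = False
    exclusion_reason: str | None = None

    def exclude(self, reason: str) -> "PrepReport":
        self.excluded = True
        self.exclusion_reason = reason
        self.rules_applied.append(reason)
        return self


def truncate_and_offset(series: IndexSeries) -> tuple[IndexSeries | None, PrepReport]:
    """Truncate to the first positive count; offset zeros by 1% of the mean.

    The offset is 1% of the mean of the *retained* (post-truncation) raw
    values, added to every retained value, and only applied when a zero is
    present in the retained window.  An all-zero series is excluded with
    reason ``all_zero``.
    """
    report = PrepReport(species_id=series.species_id)
    positive = np.nonzero(series.index > 0)[0]
    if positive.size == 0:
        return None, report.exclude("all_zero")
    start = positive[0]
    years = series.years[start:]
    values = series.index[start:]
    se = series.se[start:]
    coverage = series.coverage[start:] if series.coverage is not None else None
    if start > 0:
        report.rules_applied.append("truncated_to_first_positive")
    offset = 0.0
    if np.any(values == 0):
        offset = ZERO_OFFSET_FRACTION * float(np.mean(values))
        values = values + offset
        report.rules_applied.append("zero_offset_added")
    report.offset_value = offset
    out = IndexSeries(series.species_id, years, values, se, coverage)
    return out, report


def apply_coverage_filters(
    series: IndexSeries, report: PrepReport | None = None
) -> tuple[IndexSeries | None, PrepReport]:
    """Drop low-coverage years; exclude species with poor final-year coverage.

    Series without coverage information pass through unchanged.
    """
    if report is None:
        report = PrepReport(species_id=series.species_id)
    if series.coverage is None:
        return series, report
    final_cov = series.coverage[-1]
    if np.isfinite(final_cov) and final_cov < FINAL_COVERAGE_MIN:
        return None, report.exclude("excluded_low_final_coverage")
    keep = ~(np.isfinite(series.coverage) & (series.coverage < YEAR_COVERAGE_MIN))
    if not keep.all():
        report.rules_applied.append("years_dropped_low_coverage")
        series = IndexSeries(
            series.species_id,
            series.years[keep],
            series.index[keep],
            series.se[keep],
            series.coverage[keep],
        )
    return series, report


def enforce_span_rule(
    series: IndexSeries,
    min_span_years: int = MIN_SPAN_YEARS,
    report: PrepReport | None = None,
) -> tuple[IndexSeries | None, PrepReport]:
    """Exclude series whose first and last years are < ``min_span_years`` apart."""
    if report is None:
        report = PrepReport(species_id=series.species_id)
    if len(series) == 0 or series.span < min_span_years:
        return None, report.exclude("excluded_span_lt_min")
    return series, report


def prepare_series(
    series: IndexSeries,
    config: AnalysisConfig | None = None,
    min_span_years: int = MIN_SPAN_YEARS,
) -> tuple[IndexSeries | None, PrepReport]:
    """Full preparation: exclusion list, truncate/offset, coverage, span.

    Idempotent: preparing an already-prepared series changes nothing.
    """
    report = PrepReport(species_id=series.species_id)
    if config is not None and series.species_id in config.excluded_species:
        return None, report.exclude("excluded_by_name")
    out, report = truncate_and_offset(series)
    if out is None:
        return None, report
    out, report = apply_coverage_filters(out, report)
    if out is None:
        return None, report
    return enforce_span_rule(out, min_span_years, report)
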