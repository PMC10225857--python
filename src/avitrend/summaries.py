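"""Change decompositions and headline metrics from posterior trajectories.

All decompositions are computed per posterior draw so the accounting
identities hold exactly: summed group net changes equal the assemblage net
change, and total increases (over species whose own change is positive in
that draw) plus total decreases equal the net change.  Summaries are
posterior medians with 2.5/97.5 percentile bounds.

Percent change is 100·(end − start)/start; the per-annum rate is the
geometric rate 100·((end/start)^(1/span) − 1) with span = year_end −
year_start, which compounds back to the percent change exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hierarchical import Posterior, species_trajectories


@dataclass
class Interval:
    estimate: float
    lcl: float
    ucl: float

    @classmethod
    def from_draws(cls, draws: np.ndarray) -> "Interval":
        return cls(
            float(np.median(draws)),
            float(np.percentile(draws, 2.5)),
            float(np.percentile(draws, 97.5)),
        )


@dataclass
class ChangeSummary:
    """Headline change metrics between the first and last year."""

    year_start: int
    year_end: int
    start_total: Interval
    end_total: Interval
    net_change: Interval
    pct_change: Interval
    pct_per_annum: Interval
    total_increase: Interval
    total_decrease: Interval
    n_increasing: int  # by posterior-median species change
    n_decreasing: int


def pct_change(start: float | np.ndarray, end: float | np.ndarray):
    return 100.0 * (end - start) / start


def pct_per_annum(start, end, span: int):
    """Geometric annual rate (%/yr) whose compounding reproduces pct_change."""
    if span < 1:
        raise ValueError("span must be >= 1")
    return 100.0 * ((end / start) ** (1.0 / span) - 1.0)


def summarize_change(
    posterior: Posterior,
    weights: np.ndarray | dict[str, float] | None = None,
) -> ChangeSummary:
    """Per-draw change decomposition between the first and last grid years."""
    per_species = species_trajectories(posterior, weights)  # (D, S, Y)
    start = per_species[:, :, 0]
    end = per_species[:, :, -1]
    change = end - start  # (D, S)
    net = change.sum(axis=1)
    inc = np.where(change > 0, change, 0.0).sum(axis=1)
    dec = np.where(change < 0, change, 0.0).sum(axis=1)
    tot_start = start.sum(axis=1)
    tot_end = end.sum(axis=1)
    span = int(posterior.years[-1] - posterior.years[0])
    median_sign = np.median(change, axis=0)
    return ChangeSummary(
        year_start=int(posterior.years[0]),
        year_end=int(posterior.years[-1]),
        start_total=Interval.from_draws(tot_start),
        end_total=Interval.from_draws(tot_end),
        net_change=Interval.from_draws(net),
        pct_change=Interval.from_draws(pct_change(tot_start, tot_end)),
        pct_per_annum=Interval.from_draws(pct_per_annum(tot_start, tot_end, span)),
        total_increase=Interval.from_draws(inc),
        total_decrease=Interval.from_draws(dec),
        n_increasing=int((median_sign > 0).sum()),
        n_decreasing=int((median_sign < 0).sum()),
    )


def concentration(per_species_changes: np.ndarray, k: int = 8) -> float:
    """Share of same-sign change held by the k species changing most.

    ``per_species_changes`` must be same-sign values (e.g. the declines among
    declining species); the share is the sum of the k largest magnitudes over
    the total magnitude.  With fewer than k species the share is 1.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x = np.abs(np.asarray(per_species_changes, dtype=float))
    total = x.sum()
    if total == 0:
        return float("nan")
    if len(x) <= k:
        return 1.0
    top = np.sort(x)[::-1][:k]
    return float(top.sum() / total)


def median_species_changes(
    posterior: Posterior,
    weights: np.ndarray | dict[str, float] | None = None,
) -> dict[str, float]:
    """Posterior-median end-minus-start change per species."""
    per_species = species_trajectories(posterior, weights)
    change = per_species[:, :, -1] - per_species[:, :, 0]
    med = np.median(change, axis=0)
    return dict(zip(posterior.species_ids, med.astype(float)))


def group_breakdown(
    posterior: Posterior,
    grouping: dict[str, str],
    weights: np.ndarray | dict[str, float] | None = None,
) -> dict[str, ChangeSummary]:
    """Change summaries within groups (abundance class, habitat, migration).

    Groups' net changes sum to the assemblage net change per draw, because
    each group summary is a masked version of the same per-species draws.
    Species absent from ``grouping`` raise; empty groups simply do not appear.
    """
    missing = [s for s in posterior.species_ids if s not in grouping]
    if missing:
        raise ValueError(f"grouping undefined for species: {missing[:5]}")
    out: dict[str, ChangeSummary] = {}
    base = _weights_as_dict(posterior, weights)
    for group in sorted(set(grouping.values())):
        wg = {
            sid: (base[sid] if grouping[sid] == group else 0.0)
            for sid in posterior.species_ids
        }
        if all(v == 0.0 for v in wg.values()):
            continue
        out[group] = summarize_change(posterior, wg)
    return out


def _weights_as_dict(posterior: Posterior, weights) -> dict[str, float]:
    if weights is None:
        return {sid: 1.0 for sid in posterior.species_ids}
    if isinstance(weights, dict):
        return dict(weights)
    return dict(zip(posterior.species_ids, np.asarray(weights, dtype=float)))


def per_area(value: float, area_km2: float) -> float:
    """Change per km² for a user-supplied region area."""
    if area_km2 <= 0:
        raise ValueError("area_km2 must be > 0")
    return value / area_km2
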