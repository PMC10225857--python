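"""Core domain types and table/tree I/O for assemblage trend analysis.

The pipeline works on four tabular inputs (all UTF-8 CSV with a header row,
missing values as empty cells) plus a Newick phylogeny:

* a species table: identity, body mass and categorical traits;
* index series in long format (``species_id, year, index, se[, coverage]``):
  annual relative-abundance values with standard errors from structured
  monitoring, meaningful only as ratios between years;
* population estimates: absolute numbers of breeding individuals anchored to
  a reference year or year range, either as min/max bounds or a best value;
* national trend records: per-country multiplicative trend over a stated
  period plus a mean population estimate, used to reconstruct annual series.

Years are calendar integers, rates are per calendar year, and logarithms are
natural throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml

HABITATS = (
    "human-modified",
    "grassland",
    "forest",
    "woodland/parkland",
    "wetland",
    "riverine",
    "coastal",
    "marine",
    "other",
)

MIGRATIONS = ("resident", "partial", "short-distance", "long-distance")


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """A row violates a domain-type invariant; message names the row."""


@dataclass(frozen=True)
class SpeciesRecord:
    """One species: identity, body mass (g) and categorical traits."""

    species_id: str
    body_mass: float
    habitat: str
    migration: str
    trophic_niche: str
    native: bool = True

    def __post_init__(self) -> None:
        if not self.species_id:
            raise ValidationError("species_id must be non-empty")
        if not (self.body_mass > 0):
            raise ValidationError(
                f"species {self.species_id!r}: body_mass must be > 0, got {self.body_mass}"
            )
        if self.habitat not in HABITATS:
            raise ValidationError(
                f"species {self.species_id!r}: unknown habitat {self.habitat!r}"
            )
        if self.migration not in MIGRATIONS:
            raise ValidationError(
                f"species {self.species_id!r}: unknown migration {self.migration!r}"
            )


@dataclass
class IndexSeries:
    """Per-species annual index values with standard errors.

    Index values are on an arbitrary positive scale; only ratios between
    years carry information.  ``coverage`` is the fraction of the species'
    population represented by the monitoring data in each year, when known.
    """

    species_id: str
    years: np.ndarray
    index: np.ndarray
    se: np.ndarray
    coverage: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.index = np.asarray(self.index, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if self.coverage is not None:
            self.coverage = np.asarray(self.coverage, dtype=float)
        n = len(self.years)
        if len(self.index) != n or len(self.se) != n:
            raise ValidationError(
                f"series {self.species_id!r}: years/index/se length mismatch"
            )
        if self.coverage is not None and len(self.coverage) != n:
            raise ValidationError(
                f"series {self.species_id!r}: coverage length mismatch"
            )
        if n > 1 and not np.all(np.diff(self.years) > 0):
            raise ValidationError(
                f"series {self.species_id!r}: years must be strictly increasing"
            )
        if np.any(self.se < 0):
            raise ValidationError(f"series {self.species_id!r}: negative SE")

    def __len__(self) -> int:
        return len(self.years)

    @property
    def span(self) -> int:
        return int(self.years[-1] - self.years[0])


@dataclass(frozen=True)
class PopulationEstimate:
    """Absolute population size at a reference year (or range of years).

    ``point`` is the geometric mean of min and max when both are given
    (a best-only value is used as both); ``se`` is a sixth of the max-min
    span, so a best-only estimate carries se = 0.
    """

    species_id: str
    min_est: float
    max_est: float
    point: float
    se: float
    ref_year_start: int
    ref_year_end: int

    def __post_init__(self) -> None:
        if self.min_est > self.max_est:
            raise ValidationError(
                f"estimate {self.species_id!r}: min {self.min_est} > max {self.max_est}"
            )
        if not (self.min_est - 1e-9 <= self.point <= self.max_est + 1e-9):
            raise ValidationError(
                f"estimate {self.species_id!r}: point outside [min, max]"
            )
        if self.se < 0:
            raise ValidationError(f"estimate {self.species_id!r}: negative se")
        if self.ref_year_start > self.ref_year_end:
            raise ValidationError(
                f"estimate {self.species_id!r}: ref_year_start > ref_year_end"
            )

    @property
    def ref_year(self) -> int:
        """Reference year: the midpoint of the range, rounded down."""
        return (self.ref_year_start + self.ref_year_end) // 2


@dataclass(frozen=True)
class NationalTrendRecord:
    """Mean multiplicative trend and population estimate for one country.

    ``mean_trend`` is the total multiplicative change over ``trend_period``
    years; ``mean_pop`` is the mean national population estimate made around
    ``mean_estimate_year``.
    """

    species_id: str
    country: str
    mean_trend: float
    trend_period: float
    mean_pop: float
    mean_estimate_year: int

    def __post_init__(self) -> None:
        if not (self.mean_trend > 0):
            raise ValidationError(
                f"trend {self.species_id!r}/{self.country!r}: mean_trend must be > 0"
            )
        if not (self.trend_period >= 1):
            raise ValidationError(
                f"trend {self.species_id!r}/{self.country!r}: trend_period must be >= 1"
            )


@dataclass
class AnalysisConfig:
    """Run-level settings: year windows, bootstrap/MCMC sizes, constants."""

    year_start: int = 1966
    year_end: int = 2018
    bootstrap_n: int = 1000
    mcmc_chains: int = 4
    mcmc_warmup: int = 1000
    mcmc_draws: int = 1000
    seed: int = 0
    quartile_labels: tuple[str, ...] = ("rare", "scarce", "common", "abundant")
    area_km2: float | None = None
    cst_climate_variables: tuple[str, ...] = ()
    excluded_species: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.bootstrap_n < 1:
            raise ValidationError("bootstrap_n must be >= 1")
        if self.year_start >= self.year_end:
            raise ValidationError("year_start must be < year_end")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("quartile_labels", "cst_climate_variables", "excluded_species"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = {
            "year_start": self.year_start,
            "year_end": self.year_end,
            "bootstrap_n": self.bootstrap_n,
            "mcmc_chains": self.mcmc_chains,
            "mcmc_warmup": self.mcmc_warmup,
            "mcmc_draws": self.mcmc_draws,
            "seed": self.seed,
            "quartile_labels": list(self.quartile_labels),
            "area_km2": self.area_km2,
            "cst_climate_variables": list(self.cst_climate_variables),
            "excluded_species": list(self.excluded_species),
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(raw, fh)


# ---------------------------------------------------------------------------
# Table readers / writers
# ---------------------------------------------------------------------------

_SPECIES_COLS = ["species_id", "body_mass", "habitat", "migration", "trophic_niche"]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table missing columns: {missing}")


def read_species_table(path) -> list[SpeciesRecord]:
    """Read a species-trait CSV into validated :class:`SpeciesRecord` rows."""
    df = pd.read_csv(path)
    _require_columns(df, _SPECIES_COLS, "species")
    records = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        sid = str(row["species_id"])
        if sid in seen:
            raise ValidationError(f"row {i}: duplicate species_id {sid!r}")
        seen.add(sid)
        try:
            rec = SpeciesRecord(
                species_id=sid,
                body_mass=float(row["body_mass"]),
                habitat=str(row["habitat"]),
                migration=str(row["migration"]),
                trophic_niche=str(row["trophic_niche"]),
                native=bool(row["native"]) if "native" in df.columns else True,
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
        records.append(rec)
    return records


def write_species_table(records: Iterable[SpeciesRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "species_id": r.species_id,
                "body_mass": r.body_mass,
                "habitat": r.habitat,
                "migration": r.migration,
                "trophic_niche": r.trophic_niche,
                "native": r.native,
            }
            for r in records
        ]
    )
    df.to_csv(path, index=False)


def read_index_series(path) -> dict[str, IndexSeries]:
    """Read long-format index CSV into one :class:`IndexSeries` per species."""
    df = pd.read_csv(path)
    _require_columns(df, ["species_id", "year", "index", "se"], "index series")
    has_cov = "coverage" in df.columns
    out: dict[str, IndexSeries] = {}
    for sid, grp in df.groupby("species_id", sort=True):
        grp = grp.sort_values("year")
        out[str(sid)] = IndexSeries(
            species_id=str(sid),
            years=grp["year"].to_numpy(dtype=int),
            index=grp["index"].to_numpy(dtype=float),
            se=grp["se"].to_numpy(dtype=float),
            coverage=grp["coverage"].to_numpy(dtype=float) if has_cov else None,
        )
    return out


def write_index_series(series: Iterable[IndexSeries], path) -> None:
    frames = []
    for s in series:
        d = {
            "species_id": s.species_id,
            "year": s.years,
            "index": s.index,
            "se": s.se,
        }
        if s.coverage is not None:
            d["coverage"] = s.coverage
        frames.append(pd.DataFrame(d))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_population_estimates(path) -> dict[str, PopulationEstimate]:
    df = pd.read_csv(path)
    _require_columns(
        df,
        ["species_id", "min_est", "max_est", "point", "se", "ref_year_start", "ref_year_end"],
        "population estimate",
    )
    out: dict[str, PopulationEstimate] = {}
    for i, row in df.iterrows():
        sid = str(row["species_id"])
        if sid in out:
            raise ValidationError(f"row {i}: duplicate species_id {sid!r}")
        try:
            out[sid] = PopulationEstimate(
                species_id=sid,
                min_est=float(row["min_est"]),
                max_est=float(row["max_est"]),
                point=float(row["point"]),
                se=float(row["se"]),
                ref_year_start=int(row["ref_year_start"]),
                ref_year_end=int(row["ref_year_end"]),
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
    return out


def write_population_estimates(estimates: Iterable[PopulationEstimate], path) -> None:
    df = pd.DataFrame(
        [
            {
                "species_id": e.species_id,
                "min_est": e.min_est,
                "max_est": e.max_est,
                "point": e.point,
                "se": e.se,
                "ref_year_start": e.ref_year_start,
                "ref_year_end": e.ref_year_end,
            }
            for e in estimates
        ]
    )
    df.to_csv(path, index=False)


def read_national_trends(path) -> list[NationalTrendRecord]:
    df = pd.read_csv(path)
    _require_columns(
        df,
        ["species_id", "country", "mean_trend", "trend_period", "mean_pop", "mean_estimate_year"],
        "national trend",
    )
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                NationalTrendRecord(
                    species_id=str(row["species_id"]),
                    country=str(row["country"]),
                    mean_trend=float(row["mean_trend"]),
                    trend_period=float(row["trend_period"]),
                    mean_pop=float(row["mean_pop"]),
                    mean_estimate_year=int(row["mean_estimate_year"]),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
    return out


def write_national_trends(records: Iterable[NationalTrendRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "species_id": r.species_id,
                "country": r.country,
                "mean_trend": r.mean_trend,
                "trend_period": r.trend_period,
                "mean_pop": r.mean_pop,
                "mean_estimate_year": r.mean_estimate_year,
            }
            for r in records
        ]
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Phylogeny I/O
# ---------------------------------------------------------------------------


def read_newick(path) -> dendropy.Tree:
    """Read a Newick phylogeny with branch lengths.

    Duplicate tip labels raise; a non-ultrametric tree only warns, since the
    downstream phylogenetic regression assumes branch lengths proportional to
    expected trait covariance but does not require a strict molecular clock.
    """
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        if "Duplicate taxon" in str(exc) or "Multiple occurrences" in str(exc):
            raise ValidationError(f"duplicate tip labels in {path}: {exc}") from exc
        raise ValueError(f"could not parse Newick file {path}: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise ValidationError(f"duplicate tip labels: {sorted(dupes)}")
    depths = root_to_tip_depths(tree)
    vals = list(depths.values())
    if vals and (max(vals) - min(vals)) > 1e-6 * max(max(vals), 1.0):
        warnings.warn(
            "tree is not ultrametric (root-to-tip depths vary); PGLS treats "
            "branch lengths as proportional to expected covariance",
            stacklevel=2,
        )
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def root_to_tip_depths(tree: dendropy.Tree) -> dict[str, float]:
    """Root-to-tip path length for every tip, keyed by label."""
    depths: dict[str, float] = {}
    for leaf in tree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths[leaf.taxon.label] = d
    return depths


def tips_missing_from(tree: dendropy.Tree, species_ids: Iterable[str]) -> set[str]:
    """Species ids absent from the tree's tip set."""
    return set(species_ids) - set(tip_labels(tree))
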