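"""Biomass accounting: body-mass scaling of abundance with uncertainty.

A species' biomass estimate is its population estimate (and SE) multiplied
by its average body mass, converted from grams to tonnes (×10⁻⁶).  The
assemblage biomass trajectory is the abundance model's total trajectory
with per-species weights equal to body mass in tonnes, so the scaling is
exact per posterior draw and all abundance-side identities carry over.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .datamodel import PopulationEstimate, SpeciesRecord
from .hierarchical import Posterior, TotalTrajectory, total_trajectory

logger = logging.getLogger(__name__)

GRAMS_PER_TONNE = 1e6


@dataclass(frozen=True)
class BiomassEstimate:
    """Species biomass (tonnes) at the population estimate's reference year."""

    species_id: str
    biomass_point: float
    biomass_se: float
    ref_year_start: int
    ref_year_end: int


def to_biomass(est: PopulationEstimate, mass_g: float) -> BiomassEstimate:
    """biomass = individuals × mass_g × 10⁻⁶ tonnes; SE scales the same way."""
    if not (mass_g > 0):
        raise ValueError(f"species {est.species_id!r}: mass must be > 0")
    factor = mass_g / GRAMS_PER_TONNE
    return BiomassEstimate(
        species_id=est.species_id,
        biomass_point=est.point * factor,
        biomass_se=est.se * factor,
        ref_year_start=est.ref_year_start,
        ref_year_end=est.ref_year_end,
    )


def mass_weights(
    posterior: Posterior, species: list[SpeciesRecord]
) -> dict[str, float]:
    """Body mass in tonnes per species id, for use as trajectory weights.

    Species in the posterior without a mass are assigned weight 0 (dropped
    from the biomass total) with a log entry.
    """
    masses = {r.species_id: r.body_mass / GRAMS_PER_TONNE for r in species}
    out = {}
    for sid in posterior.species_ids:
        if sid not in masses:
            logger.info("species %s dropped from biomass: no body mass", sid)
            out[sid] = 0.0
        else:
            out[sid] = masses[sid]
    return out


def biomass_trajectory(
    posterior: Posterior, species: list[SpeciesRecord]
) -> TotalTrajectory:
    """Total biomass (tonnes) per year: mass-weighted abundance trajectory."""
    return total_trajectory(posterior, mass_weights(posterior, species))
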