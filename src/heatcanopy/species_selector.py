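"""Constraint-based selection among the city-approved tree species.

Users filter the approved-species table by hyper-local site conditions —
available planting area (canopy spread), light availability, street versus
park/yard siting, pollen allergenicity (high-allergen trees can aggravate
asthma), breakage resistance, growth rate. Filters are conjunctive and all
optional; an empty filter returns the whole approved list.

Species with high heat-reduction potential are flagged from the product of
transpiration rate and leaf area — the two drivers of evapotranspirative
cooling — using a cohort quantile cutoff (default: top quartile).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .io_schema import (
    ALLERGENICITY_ORDER,
    GROWTH_ORDER,
    LIGHT_TOLERANCE_ORDER,
    Allergenicity,
    GrowthRate,
    LightRequirement,
    SiteType,
    SpeciesRecord,
    ValidationError,
)

logger = logging.getLogger("heatcanopy")


@dataclass(frozen=True)
class SpeciesFilter:
    """Optional conjunctive constraints on species attributes.

    An unset (None) field matches everything; the empty filter is the
    identity. Light is matched by tolerance: a shade-tolerant tree satisfies
    any requested light level, a partial-shade tree satisfies partial and
    full-sun requests, a full-sun tree only full-sun requests.
    """

    max_canopy_spread_ft: float | None = None
    light: LightRequirement | None = None
    site_type: SiteType | None = None
    max_allergenicity: Allergenicity | None = None
    require_breakage_resistant: bool | None = None
    min_growth_rate: GrowthRate | None = None


def matches(record: SpeciesRecord, f: SpeciesFilter) -> bool:
    """Whether a species satisfies every set constraint of the filter."""
    if f.max_canopy_spread_ft is not None and record.canopy_spread_ft > f.max_canopy_spread_ft:
        return False
    if f.light is not None:
        if LIGHT_TOLERANCE_ORDER[record.light_requirement] < LIGHT_TOLERANCE_ORDER[f.light]:
            return False
    if f.site_type is not None and f.site_type not in record.site_type:
        return False
    if f.max_allergenicity is not None:
        if ALLERGENICITY_ORDER[record.allergenicity] > ALLERGENICITY_ORDER[f.max_allergenicity]:
            return False
    if f.require_breakage_resistant and not record.breakage_resistant:
        return False
    if f.min_growth_rate is not None:
        if GROWTH_ORDER[record.growth_rate] < GROWTH_ORDER[f.min_growth_rate]:
            return False
    return True


def filter_species(records: list[SpeciesRecord], f: SpeciesFilter) -> list[SpeciesRecord]:
    """Species passing the filter, in their original order. Empty result is valid."""
    return [r for r in records if matches(r, f)]


def heat_reduction_score(record: SpeciesRecord) -> float:
    """Heat-reduction potential: transpiration rate times leaf area.

    Both drivers are positive relative measures; their product scales with
    total evapotranspirative cooling.
    """
    if record.transpiration_rate <= 0 or record.leaf_area <= 0:
        raise ValidationError(
            f"{record.species_name}: transpiration_rate and leaf_area must be positive"
        )
    return record.transpiration_rate * record.leaf_area


def flag_high_heat_reduction(
    records: list[SpeciesRecord], quantile: float = 0.75
) -> list[SpeciesRecord]:
    """Set high_heat_reduction on species at or above the score quantile.

    The cutoff is the empirical ``quantile`` of the score distribution over
    the whole table; ties at the cutoff flag True, so when all species score
    identically every one is flagged. Flags depend only on the score vector,
    not record order.
    """
    if not records:
        raise ValidationError("cannot flag an empty species table")
    scores = np.array([heat_reduction_score(r) for r in records])
    cutoff = float(np.quantile(scores, quantile, method="linear"))
    flagged = [replace(r, high_heat_reduction=bool(s >= cutoff))
               for r, s in zip(records, scores)]
    logger.info("%d/%d species flagged high heat-reduction (cutoff %.3g)",
                sum(r.high_heat_reduction for r in flagged), len(flagged), cutoff)
    return flagged
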