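"""Planting feasibility from block-group land cover aggregated to tracts.

Potential canopy is the vegetation (grass/shrub) cover class — land that is
plantable today without demolition or depaving; impervious surfaces never
count as potential canopy. Existing canopy is the tree-canopy class. Both
are reported as square footage and as a percentage of tract area, because
tract sizes vary widely. A tract's feasibility class (high/low) gates the
recommendation between planting trees and alternative heat-mitigation
interventions (cool roofs, depaving, green roofs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_schema import (
    LAND_COVER_CLASSES,
    LandCoverClass,
    LandCoverRecord,
    ValidationError,
)

logger = logging.getLogger("heatcanopy")


class Feasibility(str, Enum):
    HIGH = "high"
    LOW = "low"


@dataclass
class CanopySummary:
    """Per-tract canopy areas, percentages and feasibility class."""

    tract_id: str
    existing_canopy_sqft: float
    potential_canopy_sqft: float
    impervious_sqft: float
    total_sqft: float
    existing_canopy_pct: float
    potential_canopy_pct: float
    feasibility: Feasibility | None = None


def aggregate_to_tracts(records: Iterable[LandCoverRecord]) -> pd.DataFrame:
    """Sum block-group class areas to the parent census tract.

    Returns a tract-by-class frame (columns in the canonical class order,
    zero-filled for classes absent from a tract). Summation is exact and
    order-invariant; tracts absent from the input are absent from the output.
    """
    rows = [
        {"tract_id": r.tract_id, "class": r.cover_class.value, "area_sqft": r.area_sqft}
        for r in records
    ]
    if not rows:
        return pd.DataFrame(columns=list(LAND_COVER_CLASSES)).rename_axis("tract_id")
    df = pd.DataFrame(rows)
    # Sort before summing so totals are bitwise order-invariant.
    df = df.sort_values(["tract_id", "class", "area_sqft"], kind="stable")
    totals = (
        df.groupby(["tract_id", "class"], sort=True)["area_sqft"]
        .sum()
        .unstack(fill_value=0.0)
        .reindex(columns=list(LAND_COVER_CLASSES), fill_value=0.0)
    )
    totals.columns.name = None
    return totals


def canopy_metrics(class_totals: pd.DataFrame) -> list[CanopySummary]:
    """Existing/potential canopy area and percentage per tract.

    Tract total area is the sum over all cover classes, so the five class
    percentages partition 100% exactly. Raises for zero-area tracts.
    """
    out = []
    for tract_id, row in class_totals.iterrows():
        total = float(row.sum())
        if total <= 0:
            raise ValidationError(f"tract {tract_id} has zero total land-cover area")
        existing = float(row[LandCoverClass.TREE_CANOPY.value])
        potential = float(row[LandCoverClass.VEGETATION.value])
        out.append(
            CanopySummary(
                tract_id=str(tract_id),
                existing_canopy_sqft=existing,
                potential_canopy_sqft=potential,
                impervious_sqft=float(row[LandCoverClass.IMPERVIOUS.value]),
                total_sqft=total,
                existing_canopy_pct=100.0 * existing / total,
                potential_canopy_pct=100.0 * potential / total,
            )
        )
    return out


def classify_feasibility(
    summaries: Sequence[CanopySummary],
    *,
    rule: str = "relative",
    threshold_pct: float = 50.0,
) -> list[CanopySummary]:
    """Assign the high/low feasibility class to each tract.

    rule="relative" (default): high feasibility is the top ``threshold_pct``
    percent of tracts by potential canopy percentage, i.e. a tract is high
    iff its potential canopy percentage >= the cohort's
    (100 - threshold_pct)th percentile. The default 50 marks the top half.

    rule="absolute": high iff potential_canopy_pct >= threshold_pct.

    Ties at the threshold classify as high — the tool prefers recommending
    planting when in doubt. Returns new summaries with feasibility set.
    """
    if not 0 <= threshold_pct <= 100:
        raise ValidationError(f"threshold_pct must be in [0,100], got {threshold_pct}")
    if rule == "relative":
        pcts = np.array([s.potential_canopy_pct for s in summaries])
        cutoff = float(np.quantile(pcts, 1 - threshold_pct / 100.0)) if len(pcts) else 0.0
    elif rule == "absolute":
        cutoff = threshold_pct
    else:
        raise ValueError(f"unknown feasibility rule {rule!r}")
    out = []
    for s in summaries:
        out.append(
            CanopySummary(
                **{**s.__dict__, "feasibility": Feasibility.HIGH
                   if s.potential_canopy_pct >= cutoff else Feasibility.LOW}
            )
        )
    n_high = sum(1 for s in out if s.feasibility is Feasibility.HIGH)
    logger.info("feasibility: %d/%d tracts high (rule=%s, cutoff=%.2f%%)",
                n_high, len(out), rule, cutoff)
    return out


def summaries_to_frame(summaries: Sequence[CanopySummary]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "tract_id": s.tract_id,
                "existing_canopy_sqft": s.existing_canopy_sqft,
                "potential_canopy_sqft": s.potential_canopy_sqft,
                "impervious_sqft": s.impervious_sqft,
                "total_sqft": s.total_sqft,
                "existing_canopy_pct": s.existing_canopy_pct,
                "potential_canopy_pct": s.potential_canopy_pct,
                "feasibility": s.feasibility.value if s.feasibility else None,
            }
            for s in summaries
        ]
    )
    return df.set_index("tract_id")
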