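"""Tract prioritization: combine vulnerability, heat exposure and feasibility.

A tract is a planting priority when canopy expansion is feasible there AND
it is either highly heat-vulnerable (HVI) or highly heat-exposed (LST):

    priority = high_feasibility AND (high_hvi OR high_lst)

HVI and LST are kept as two separate flags, never merged into one index —
vulnerability and surface temperature can anti-correlate across a city, and
decision-makers may weigh them differently. "High" defaults to the top
quartile of the cohort for each measure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .io_schema import JoinError, ValidationError

logger = logging.getLogger("heatcanopy")


class Recommendation(str, Enum):
    PLANT_TREES = "plant_trees"
    ALTERNATIVE_INTERVENTIONS = "alternative_interventions"


@dataclass(frozen=True)
class PriorityResult:
    tract_id: str
    high_hvi: bool
    high_lst: bool
    high_feasibility: bool
    priority: bool
    recommendation: Recommendation


def quantile_flag(values: pd.Series, q: float = 0.75) -> pd.Series:
    """Flag tracts at or above the empirical q-quantile of the cohort.

    The quantile uses numpy's linear-interpolation convention. Ties at the
    threshold flag True. Requires at least two distinct values; an
    all-identical cohort has no meaningful "high" end.
    """
    if not 0 < q < 1:
        raise ValidationError(f"q must be in (0,1), got {q}")
    arr = values.to_numpy(dtype=float)
    if np.unique(arr).size < 2:
        raise ValidationError(
            "all values identical; quantile flagging is degenerate — "
            "use an absolute threshold instead"
        )
    cutoff = float(np.quantile(arr, q, method="linear"))
    return (values >= cutoff).rename(values.name)


def prioritize_tracts(
    hvi: pd.Series,
    lst: pd.Series,
    high_feasibility: pd.Series,
    *,
    hvi_q: float = 0.75,
    lst_q: float = 0.75,
) -> list[PriorityResult]:
    """Per-tract priority flags and intervention recommendation.

    ``hvi`` and ``lst`` are numeric per-tract series; ``high_feasibility``
    is a boolean per-tract series. All three must cover exactly the same
    tract set. The recommendation is plant_trees iff feasibility is high;
    otherwise alternative interventions (cool roofs, depaving, green roofs)
    are suggested regardless of vulnerability.
    """
    sets = [set(s.index) for s in (hvi, lst, high_feasibility)]
    if not (sets[0] == sets[1] == sets[2]):
        union = sets[0] | sets[1] | sets[2]
        inter = sets[0] & sets[1] & sets[2]
        raise JoinError(f"tract sets differ; symmetric difference: {sorted(union - inter)}")

    high_hvi = quantile_flag(hvi, hvi_q)
    high_lst = quantile_flag(lst, lst_q)
    results = []
    for tract_id in hvi.index:
        feas = bool(high_feasibility.loc[tract_id])
        hh = bool(high_hvi.loc[tract_id])
        hl = bool(high_lst.loc[tract_id])
        results.append(
            PriorityResult(
                tract_id=str(tract_id),
                high_hvi=hh,
                high_lst=hl,
                high_feasibility=feas,
                priority=feas and (hh or hl),
                recommendation=Recommendation.PLANT_TREES
                if feas
                else Recommendation.ALTERNATIVE_INTERVENTIONS,
            )
        )
    n_priority = sum(r.priority for r in results)
    logger.info("%d/%d tracts flagged as planting priorities", n_priority, len(results))
    return results


def priority_to_frame(results: list[PriorityResult]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "tract_id": r.tract_id,
                "high_hvi": r.high_hvi,
                "high_lst": r.high_lst,
                "high_feasibility": r.high_feasibility,
                "priority": r.priority,
                "recommendation": r.recommendation.value,
            }
            for r in results
        ]
    )
    return df.set_index("tract_id")
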