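"""Hard risk classification and carbon-at-risk accounting.

The soft risk map says how likely each cell is to be cleared; the projected
rate says how much forest will be cleared.  The hard map joins the two:
select the highest-risk forest cells until the selected area matches the
projected loss, with the threshold restricted to a 0.01-step ladder
(1.00, 0.99, ..., 0.00) — thresholds are quoted to whole percents, so the
achieved area is the closest attainable under that quantization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import Grid
from .rates import CarbonParams, emissions

__all__ = ["HardMap", "harden", "carbon_at_risk"]


@dataclass
class HardMap:
    """Boolean selection of forest at highest risk plus bookkeeping."""

    selected_mask: Grid
    threshold: float  # p* on the 0.01 ladder
    target_area_ha: float
    achieved_area_ha: float


def harden(risk: Grid, forest_mask: Grid, target_area_ha: float,
           quantum: float = 0.01) -> HardMap:
    """Select forest cells with risk >= p*, p* on the quantized ladder.

    Evaluates every ladder value {1.00, 0.99, ..., 0.00} and keeps the one
    whose selected area is nearest the target; ties go to the higher
    threshold (the more conservative selection).  Only currently forested,
    non-nodata cells are selectable.
    """
    p = np.asarray(risk.values, dtype=float)
    forest = np.asarray(forest_mask.values, dtype=bool)
    eligible = forest & ~risk.nodata_mask & ~forest_mask.nodata_mask
    cell_area = risk.cell_area_ha
    forest_area = float(eligible.sum()) * cell_area
    if target_area_ha < 0:
        raise ValueError("target area must be non-negative")
    if target_area_ha > forest_area:
        raise ValueError(
            f"target area {target_area_ha} ha exceeds available forest ({forest_area} ha)"
        )

    n_steps = int(round(1.0 / quantum))
    ladder = np.round(np.linspace(1.0, 0.0, n_steps + 1), 10)
    pe = p[eligible]
    best = None
    for thr in ladder:  # descending: at equal distance the higher p* wins
        achieved = float((pe >= thr).sum()) * cell_area
        gap = abs(achieved - target_area_ha)
        if best is None or gap < best[0]:
            best = (gap, thr, achieved)
    _, thr, achieved = best
    selected = eligible & (p >= thr)
    return HardMap(
        selected_mask=risk.copy_with(values=selected),
        threshold=float(thr),
        target_area_ha=float(target_area_ha),
        achieved_area_ha=achieved,
    )


def carbon_at_risk(hard: HardMap, params: CarbonParams | None = None,
                   carbon_grid: Grid | None = None) -> tuple[float, float]:
    """Committed (Mg C, Mg CO2) of the selected cells.

    With a per-cell carbon-density grid, sums density x cell area over the
    selection; otherwise multiplies the achieved area by the median density
    in ``params``.
    """
    if carbon_grid is not None:
        sel = np.asarray(hard.selected_mask.values, dtype=bool) & ~carbon_grid.nodata_mask
        dens = np.asarray(carbon_grid.values, dtype=float)
        c = float(dens[sel].sum()) * carbon_grid.cell_area_ha
        factor = (params or CarbonParams()).co2_per_c
        return c, c * factor
    return emissions(hard.achieved_area_ha, params or CarbonParams())
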