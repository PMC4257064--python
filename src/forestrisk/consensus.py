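"""Multi-source change consensus and point sampling.

Independent forest/non-forest classifications of the same landscape rarely
agree everywhere, and cloud cover leaves per-source gaps.  Rather than trust
any single classifier, a cell is called *deforested* only when every source
saw forest at the period start and non-forest at the period end; it is
*stable forest* only when every source saw forest at both dates.  Everything
else — disagreement, or nodata in any source — is *undetermined* and never
treated as absence.  This is why the downstream risk model is presence-only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import AlignmentError, Grid, LandscapeStack

__all__ = ["ChangeLayer", "consensus", "sample_presence", "sample_background", "points_table"]


@dataclass
class ChangeLayer:
    """Consensus deforested / stable-forest / undetermined partition."""

    deforested_mask: Grid
    stable_forest_mask: Grid
    undetermined_mask: Grid

    def __post_init__(self) -> None:
        d = np.asarray(self.deforested_mask.values, dtype=bool)
        s = np.asarray(self.stable_forest_mask.values, dtype=bool)
        u = np.asarray(self.undetermined_mask.values, dtype=bool)
        study = ~self.deforested_mask.nodata_mask
        if not np.array_equal(d.astype(int) + s.astype(int) + u.astype(int), study.astype(int)):
            raise ValueError("masks must partition the non-nodata study area")


def consensus(sources: list[tuple[Grid, Grid]]) -> ChangeLayer:
    """Combine >=1 (forest_t_start, forest_t_end) grid pairs.

    deforested: forest at start and non-forest at end in EVERY source;
    stable forest: forest at both dates in every source; all other study
    cells (any disagreement or any per-source nodata) undetermined.
    """
    if not sources:
        raise ValueError("consensus requires at least one source")
    ref = sources[0][0]
    for k, (g1, g2) in enumerate(sources):
        for g in (g1, g2):
            if not g.aligned_with(ref):
                raise AlignmentError(f"source {k} is not aligned with source 0")

    study = ~np.logical_or.reduce(
        [g.nodata_mask for pair in sources for g in pair]
    )
    deforested = np.ones(ref.shape, dtype=bool)
    stable = np.ones(ref.shape, dtype=bool)
    for g1, g2 in sources:
        f1 = np.asarray(g1.values, dtype=bool)
        f2 = np.asarray(g2.values, dtype=bool)
        deforested &= f1 & ~f2
        stable &= f1 & f2
    deforested &= study
    stable &= study
    undetermined = study & ~deforested & ~stable
    nodata = ~study
    return ChangeLayer(
        deforested_mask=ref.copy_with(values=deforested, nodata_mask=nodata),
        stable_forest_mask=ref.copy_with(values=stable, nodata_mask=nodata),
        undetermined_mask=ref.copy_with(values=undetermined, nodata_mask=nodata),
    )


def _sample_cells(eligible: np.ndarray, n: int, seed: int, what: str) -> np.ndarray:
    cells = np.argwhere(eligible)
    if n > len(cells):
        raise ValueError(
            f"requested {n} {what} points but only {len(cells)} eligible cells exist"
        )
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(cells), size=n, replace=False)
    return cells[picks]


def sample_presence(change: ChangeLayer, n: int = 500, seed: int = 0) -> np.ndarray:
    """Uniform sample without replacement of (row, col) deforested cells.

    One point per cell, at the cell center.  Deterministic given the seed.
    n defaults to 500, a typical presence count for this class of model.
    """
    d = np.asarray(change.deforested_mask.values, dtype=bool) & ~change.deforested_mask.nodata_mask
    return _sample_cells(d, n, seed, "presence")


def sample_background(stack: LandscapeStack, n: int = 500, seed: int = 0) -> np.ndarray:
    """Uniform sample of (row, col) over all non-nodata study cells."""
    eligible = ~stack.nodata_mask
    return _sample_cells(eligible, n, seed, "background")


def points_table(points: np.ndarray, grid: Grid, label: str) -> pd.DataFrame:
    """Tabulate sampled cells as id, row, col, x, y, class."""
    rows = []
    for i, (r, c) in enumerate(points):
        x, y = grid.cell_center(int(r), int(c))
        rows.append({"id": i, "row": int(r), "col": int(c), "x": x, "y": y, "class": label})
    return pd.DataFrame(rows)
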