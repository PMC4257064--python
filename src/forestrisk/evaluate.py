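"""Validation of predicted risk against later observed change.

A risk map fitted on one period is judged against the next period's
observed change: the centroids of large consensus-deforested patches
(>= 10 ha by default, so single noisy cells don't count as events) should
carry higher predicted risk than random stable-forest locations.  The
contrast is tested with a two-sided Mann-Whitney U test, and the two
groups' risk distributions are binned for a histogram comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .consensus import ChangeLayer, sample_background
from .grid import Grid, LandscapeStack, connected_patches

__all__ = ["ValidationReport", "validation_points", "mann_whitney", "evaluate"]


def validation_points(change: ChangeLayer, stack: LandscapeStack,
                      min_patch_ha: float = 10.0, n_nochange: int = 500,
                      seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Deforested-patch centroids and stable-forest no-change points.

    Centroids come from 8-connected consensus-deforested patches with area
    >= ``min_patch_ha`` (inclusive), snapped to the nearest cell.  No-change
    points are ``n_nochange`` uniform study-area points filtered to those
    falling on consensus stable forest, so their count is at most
    ``n_nochange``.
    """
    patches = [p for p in connected_patches(change.deforested_mask)
               if p.area_ha >= min_patch_ha]
    if not patches:
        raise ValueError(f"no deforested patches of at least {min_patch_ha} ha")
    grid = change.deforested_mask
    x0, y0 = grid.origin
    cell = grid.cell_size_m
    cents = []
    for p in patches:
        cx, cy = p.centroid
        row = int(round((y0 - cy) / cell - 0.5))
        col = int(round((cx - x0) / cell - 0.5))
        cents.append((row, col))
    centroids = np.array(cents)

    candidates = sample_background(stack, n=n_nochange, seed=seed)
    stable = np.asarray(change.stable_forest_mask.values, dtype=bool)
    keep = stable[candidates[:, 0], candidates[:, 1]]
    return centroids, candidates[keep]


def mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns (U, p) with U the smaller of the two U statistics (ties counted
    0.5).  The p-value is from exact enumeration when n_a * n_b <= 400 and
    there are no ties, otherwise from the normal approximation with tie and
    continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    n_ab = len(a) * len(b)
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (n_ab <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u = float(min(res.statistic, n_ab - res.statistic))
    return u, float(res.pvalue)


@dataclass
class ValidationReport:
    """Risk contrast between observed-deforestation and no-change points."""

    n_deforested_points: int
    n_nochange_points: int
    mean_risk_deforested: float
    sd_risk_deforested: float
    mean_risk_nochange: float
    sd_risk_nochange: float
    U: float
    p_value: float
    histogram_deforested: np.ndarray  # counts per risk bin
    histogram_nochange: np.ndarray
    bin_edges: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        mids = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        return pd.DataFrame(
            {
                "risk_bin_mid": mids,
                "deforested": self.histogram_deforested,
                "no_change": self.histogram_nochange,
            }
        )

    def summary(self) -> str:
        return "\n".join(
            [
                "Risk-map validation against later observed change",
                "=" * 49,
                f"deforested-patch centroids: {self.n_deforested_points}"
                f"  mean risk {100 * self.mean_risk_deforested:.0f}%"
                f" (SD {100 * self.sd_risk_deforested:.0f})",
                f"no-change points:           {self.n_nochange_points}"
                f"  mean risk {100 * self.mean_risk_nochange:.0f}%"
                f" (SD {100 * self.sd_risk_nochange:.0f})",
                f"Mann-Whitney U = {self.U:.1f}, two-sided p = {self.p_value:.3g}",
            ]
        )


def evaluate(risk: Grid, change_later: ChangeLayer, stack: LandscapeStack,
             min_patch_ha: float = 10.0, n_nochange: int = 500, seed: int = 0,
             n_bins: int = 10) -> ValidationReport:
    """Score a risk map against later observed change.

    Extracts predicted risk at deforested-patch centroids and at no-change
    points, summarizes both groups, tests the shift with Mann-Whitney, and
    bins both into ``n_bins`` equal-width risk bins.
    """
    cents, nochange = validation_points(change_later, stack, min_patch_ha,
                                        n_nochange, seed)
    p = np.asarray(risk.values, dtype=float)
    r_def = p[cents[:, 0], cents[:, 1]]
    r_no = p[nochange[:, 0], nochange[:, 1]]
    if len(r_no) == 0:
        raise ValueError("no no-change points fell on stable forest")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    U, pval = mann_whitney(r_def, r_no)
    return ValidationReport(
        n_deforested_points=len(r_def),
        n_nochange_points=len(r_no),
        mean_risk_deforested=float(r_def.mean()),
        sd_risk_deforested=float(r_def.std(ddof=1)) if len(r_def) > 1 else 0.0,
        mean_risk_nochange=float(r_no.mean()),
        sd_risk_nochange=float(r_no.std(ddof=1)) if len(r_no) > 1 else 0.0,
        U=U,
        p_value=pval,
        histogram_deforested=np.histogram(r_def, bins=edges)[0],
        histogram_nochange=np.histogram(r_no, bins=edges)[0],
        bin_edges=edges,
    )
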