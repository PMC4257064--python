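"""Friction surfaces and least-cost travel-time accessibility.

A friction surface assigns each cell a traversal cost in minutes per meter,
derived from the speed at which one can move across its land cover
(overridden on road and river cells, where travel is faster) and a slope
penalty.  Accessibility is then a monotone-decreasing transform of the
minimal cumulative travel time from the nearest access source (towns by
default; roads and rivers act through their low friction, not as sources).

Moves are 8-connected; the cost of a step is the step length (cell size,
x sqrt(2) on diagonals) times the mean of the two cells' per-meter costs —
standard cost-distance semantics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .grid import Grid

__all__ = [
    "FrictionTable",
    "AccessibilitySurface",
    "default_friction_table",
    "read_friction_table",
    "write_friction_table",
    "build_friction",
    "cost_distance",
    "accessibility_index",
]


@dataclass
class FrictionTable:
    """Travel speeds (km/h) per land-cover category plus overrides.

    Override precedence on a cell: road > river > land-cover category.
    The slope penalty is multiplicative: speed is divided by (1 + s/s0)
    with s the slope in degrees; s0 (default 30) sets how quickly terrain
    slows travel.  Sources are "towns", "roads", or "both".
    """

    speeds: dict[int, float] = field(default_factory=dict)  # category code -> km/h
    road_speed: float = 60.0
    river_speed: float = 10.0
    slope_s0: float = 30.0
    sources: str = "towns"

    def __post_init__(self) -> None:
        for cat, v in self.speeds.items():
            if v <= 0:
                raise ValueError(f"speed for category {cat} must be positive, got {v}")
        if self.road_speed <= 0 or self.river_speed <= 0:
            raise ValueError("override speeds must be positive")
        if self.sources not in ("towns", "roads", "both"):
            raise ValueError(f"unknown source selector {self.sources!r}")

    def slope_penalty(self, slope_deg: np.ndarray) -> np.ndarray:
        """Multiplier on speed; 1 on flat ground, decreasing with slope."""
        return 1.0 / (1.0 + np.asarray(slope_deg, dtype=float) / self.slope_s0)


#: Default speeds, editable via a friction file.  These are placeholder
#: calibration values in the spirit of regional travel-speed tables
#: (walking through closed forest ~2 km/h, cleared land ~4 km/h, boat
#: travel ~10 km/h, dirt road ~30 km/h, paved road ~60 km/h).
DEFAULT_SPEEDS = {"forest": 2.0, "cleared": 4.0}


def default_friction_table(categories: dict[int, str]) -> FrictionTable:
    """Build the default table for a land-cover grid's category set."""
    speeds = {}
    for code, label in categories.items():
        speeds[code] = DEFAULT_SPEEDS.get(label, 4.0)
    return FrictionTable(speeds=speeds)


def write_friction_table(table: FrictionTable, path, categories: dict[int, str] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("category\tspeed_kmh\toverride_class\n")
        for code, v in sorted(table.speeds.items()):
            label = (categories or {}).get(code, str(code))
            fh.write(f"{code}\t{v!r}\t{label}\n")
        fh.write(f"road\t{table.road_speed!r}\troad\n")
        fh.write(f"river\t{table.river_speed!r}\triver\n")
        fh.write(f"slope_s0\t{table.slope_s0!r}\tslope\n")


def read_friction_table(path) -> FrictionTable:
    speeds: dict[int, float] = {}
    kw: dict[str, float] = {}
    with open(path) as fh:
        next(fh)  # header
        for line in fh:
            key, val, _ = line.rstrip("\n").split("\t")
            if key == "road":
                kw["road_speed"] = float(val)
            elif key == "river":
                kw["river_speed"] = float(val)
            elif key == "slope_s0":
                kw["slope_s0"] = float(val)
            else:
                speeds[int(key)] = float(val)
    return FrictionTable(speeds=speeds, **kw)


def build_friction(stack, table: FrictionTable) -> Grid:
    """Per-cell traversal cost in minutes per meter.

    cost = 60 / (1000 * effective_speed_kmh); effective speed is the
    override-or-category speed times the slope penalty.  Raises if the
    land-cover grid contains a category the table does not price.
    """
    land_cover = stack["land_cover"]
    codes = np.asarray(land_cover.values)
    present = np.unique(codes[~land_cover.nodata_mask])
    for code in present:
        if int(code) not in table.speeds:
            label = (land_cover.categories or {}).get(int(code), "?")
            raise KeyError(
                f"land-cover category {int(code)} ({label!r}) has no speed in the friction table"
            )
    speed = np.zeros(codes.shape, dtype=float)
    for code, v in table.speeds.items():
        speed[codes == code] = v
    if "rivers" in stack:
        speed[np.asarray(stack["rivers"].values, dtype=bool)] = table.river_speed
    if "roads" in stack:
        speed[np.asarray(stack["roads"].values, dtype=bool)] = table.road_speed
    if "slope" in stack:
        speed = speed * table.slope_penalty(stack["slope"].values)
    speed = np.maximum(speed, 1e-9)
    cost = 60.0 / (1000.0 * speed)
    return land_cover.copy_with(values=cost, nodata_mask=stack.nodata_mask)


_MOVES = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def cost_distance(sources: Grid | np.ndarray, friction: Grid) -> Grid:
    """Minimal cumulative travel time (minutes) from any source cell.

    ``sources`` is a boolean grid/array marking source cells (travel time 0).
    Nodata cells in the friction grid are impassable and keep time +inf.
    """
    src = np.asarray(sources.values if isinstance(sources, Grid) else sources, dtype=bool)
    cost = np.asarray(friction.values, dtype=float)
    nodata = friction.nodata_mask
    if src.shape != cost.shape:
        raise ValueError("sources and friction shapes differ")
    src = src & ~nodata
    if not src.any():
        raise ValueError("cost_distance: no source cells")

    h, w = cost.shape
    n = h * w
    cell = friction.cell_size_m
    rows_idx, cols_idx, weights = [], [], []
    passable = ~nodata
    for di, dj in _MOVES[4:]:  # (0,1),(1,-1),(1,0),(1,1): each undirected edge once
        length = cell * math.hypot(di, dj)
        i0, i1 = max(0, -di), min(h, h - di)
        j0, j1 = max(0, -dj), min(w, w - dj)
        a = np.arange(i0, i1)[:, None] * w + np.arange(j0, j1)[None, :]
        b = a + di * w + dj
        ok = passable[i0:i1, j0:j1] & passable[i0 + di:i1 + di, j0 + dj:j1 + dj]
        a, b = a[ok].ravel(), b[ok].ravel()
        wgt = length * 0.5 * (cost.ravel()[a] + cost.ravel()[b])
        rows_idx.append(a)
        cols_idx.append(b)
        weights.append(wgt)
    graph = coo_matrix(
        (np.concatenate(weights), (np.concatenate(rows_idx), np.concatenate(cols_idx))),
        shape=(n, n),
    ).tocsr()
    src_idx = np.flatnonzero(src.ravel())
    times = dijkstra(graph, directed=False, indices=src_idx, min_only=True)
    tt = times.reshape(h, w)
    tt[nodata] = np.inf
    return friction.copy_with(values=tt)


def accessibility_index(travel_time: Grid, tau: float | None = None) -> Grid:
    """Map travel time to an accessibility index in [0, 1].

    index = exp(-t / tau).  tau defaults to the median finite travel time of
    the study area, so "typically reachable" cells score around exp(-1).
    Sources (t = 0) score 1; unreachable cells score 0.
    """
    t = np.asarray(travel_time.values, dtype=float)
    if tau is None:
        finite = t[np.isfinite(t) & ~travel_time.nodata_mask]
        if finite.size == 0:
            raise ValueError("no finite travel times to set tau from")
        tau = float(np.median(finite))
        if tau <= 0:
            tau = 1.0
    if tau <= 0:
        raise ValueError("tau must be positive")
    idx = np.exp(-t / tau)
    idx[~np.isfinite(t)] = 0.0
    return travel_time.copy_with(values=idx)


@dataclass
class AccessibilitySurface:
    """Travel time (minutes) and its [0, 1] accessibility transform."""

    travel_time: Grid
    index: Grid
    tau: float

    @classmethod
    def from_stack(cls, stack, table: FrictionTable, tau: float | None = None) -> "AccessibilitySurface":
        friction = build_friction(stack, table)
        if table.sources == "towns":
            src = np.asarray(stack["towns"].values, dtype=bool)
        elif table.sources == "roads":
            src = np.asarray(stack["roads"].values, dtype=bool)
        else:
            src = np.asarray(stack["towns"].values, dtype=bool) | np.asarray(
                stack["roads"].values, dtype=bool
            )
        tt = cost_distance(src, friction)
        t = tt.values
        if tau is None:
            finite = t[np.isfinite(t) & ~tt.nodata_mask]
            tau = float(np.median(finite)) or 1.0
        return cls(travel_time=tt, index=accessibility_index(tt, tau), tau=tau)
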