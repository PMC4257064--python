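"""Seed-reproducible synthetic landscapes with simulated deforestation.

The generator produces the kind of landscape the risk pipeline assumes:
roads and rivers crossing the grid, towns sitting on roads, a smooth slope
field, a Voronoi partition into land-designation zones, an initial band of
prior deforestation near the most accessible cells, and then clearing that
is drawn cell-by-cell from a logistic model of accessibility, distance to
prior deforestation and designation — so that "future deforestation follows
past patterns" holds by construction and parameter-recovery tests are
direct.  Classifier outputs are emulated by flipping cells at a per-source
noise rate and masking per-source cloud patches.

Everything is driven by :class:`SimConfig` and a single seed; the same
config and seed give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line

from .access import AccessibilitySurface, FrictionTable
from .grid import Grid, LandscapeStack, distance_transform

__all__ = [
    "SimConfig",
    "generate_landscape",
    "simulate_deforestation",
    "emit_classifications",
    "DESIGNATIONS",
]

#: Land-designation categories: tenure/management zones with different
#: deforestation pressure (offsets on the logistic scale).
DESIGNATIONS = {
    0: "unrestricted",
    1: "agricultural_concession",
    2: "forestry_concession",
    3: "indigenous_reserve",
    4: "protected_area",
}

LAND_COVER = {0: "forest", 1: "cleared"}


@dataclass
class SimConfig:
    """All knobs of the synthetic landscape, fixed up front.

    Defaults are the study conditions used throughout the test-suite: a
    200x200 grid of 1-ha cells (20 km x 20 km), three classifier sources
    with 2% flip noise and 5% cloud cover each, a clearing model dominated
    by accessibility (b_acc large relative to the others), and a target
    annualized loss rate of 0.3%/yr — a business-as-usual rate typical of
    an active deforestation frontier.
    """

    shape: tuple[int, int] = (200, 200)
    cell_size_m: float = 100.0
    seed: int = 0
    n_roads: int = 2
    n_rivers: int = 2
    n_towns: int = 3
    n_zones: int = 5
    max_slope_deg: float = 30.0
    noise_rates: tuple[float, ...] = (0.02, 0.02, 0.02)
    cloud_fraction: float = 0.05
    # clearing model (logistic scale)
    b0: float = -4.0
    b_acc: float = 6.0
    b_dist: float = 2.0
    designation_offsets: dict[int, float] = field(
        default_factory=lambda: {0: 0.0, 1: 0.5, 2: -0.5, 3: -1.0, 4: -2.0}
    )
    # frontier hotspots: blobby zones of concentrated clearing (farms and
    # settlements expand in patches, not single cells), sited preferentially
    # where the base risk is high
    b_hotspot: float = 6.0
    hotspot_fraction: float = 0.008
    r_target: float = 0.003  # annualized loss rate per epoch
    prior_deforestation_frac: float = 0.01

    def __post_init__(self) -> None:
        for nr in self.noise_rates:
            if not 0.0 <= nr <= 1.0:
                raise ValueError("noise rates must be in [0, 1]")
        if not 0.0 <= self.cloud_fraction <= 1.0:
            raise ValueError("cloud fraction must be in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    f -= f.min()
    if f.max() > 0:
        f /= f.max()
    return f


def _polyline_mask(rng: np.random.Generator, shape, n_waypoints: int = 3) -> np.ndarray:
    """Rasterize a piecewise-linear path between two random opposite edges."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    if rng.random() < 0.5:  # left -> right
        pts = [(int(rng.integers(h)), 0)]
        for k in range(1, n_waypoints):
            pts.append((int(rng.integers(h)), int(k * (w - 1) / n_waypoints)))
        pts.append((int(rng.integers(h)), w - 1))
    else:  # top -> bottom
        pts = [(0, int(rng.integers(w)))]
        for k in range(1, n_waypoints):
            pts.append((int(k * (h - 1) / n_waypoints), int(rng.integers(w))))
        pts.append((h - 1, int(rng.integers(w))))
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        rr, cc = draw_line(r0, c0, r1, c1)
        mask[rr, cc] = True
    return mask


def _voronoi_zones(rng: np.random.Generator, shape, n_zones: int) -> np.ndarray:
    h, w = shape
    seeds_r = rng.integers(0, h, n_zones)
    seeds_c = rng.integers(0, w, n_zones)
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    d2 = (rr[..., None] - seeds_r) ** 2 + (cc[..., None] - seeds_c) ** 2
    return np.argmin(d2, axis=-1).astype(np.int64)


def generate_landscape(config: SimConfig) -> LandscapeStack:
    """Build a fully forested landscape at t0 with all explanatory layers.

    Layers produced: roads, rivers, towns (boolean), slope (degrees),
    land_cover and land_designation (categorical), accessibility (index in
    [0,1] from towns through the default friction table), prior
    deforestation and distance_to_prior_deforestation (m), and the forest
    mask at year 0.
    """
    if config.n_roads + config.n_rivers + config.n_towns == 0:
        raise ValueError("landscape needs at least one access source (roads/rivers/towns)")
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.shape)
    cell = config.cell_size_m

    def mk(values, **kw):
        return Grid(values=values, cell_size_m=cell, **kw)

    roads = np.zeros(shape, dtype=bool)
    for _ in range(config.n_roads):
        roads |= _polyline_mask(rng, shape)
    rivers = np.zeros(shape, dtype=bool)
    for _ in range(config.n_rivers):
        rivers |= _polyline_mask(rng, shape, n_waypoints=5)

    towns = np.zeros(shape, dtype=bool)
    road_cells = np.argwhere(roads) if roads.any() else np.argwhere(np.ones(shape, bool))
    picks = rng.choice(len(road_cells), size=min(config.n_towns, len(road_cells)), replace=False)
    for k in np.atleast_1d(picks):
        r, c = road_cells[k]
        towns[r, c] = True

    slope = _smooth_field(rng, shape, sigma=8.0) * config.max_slope_deg

    zones = _voronoi_zones(rng, shape, config.n_zones)
    designation = zones % len(DESIGNATIONS)
    if not np.isin(designation, list(DESIGNATIONS)).all():
        raise ValueError("designation zones do not cover the grid")

    land_cover = np.zeros(shape, dtype=np.int64)  # all forest at t0
    forest0 = np.ones(shape, dtype=bool)

    stack = LandscapeStack()
    stack.add("roads", mk(roads))
    stack.add("rivers", mk(rivers))
    stack.add("towns", mk(towns))
    stack.add("slope", mk(slope))
    stack.add("land_designation", mk(designation, categories=dict(DESIGNATIONS)))
    stack.add("land_cover", mk(land_cover, categories=dict(LAND_COVER)))
    stack.add_forest(0, mk(forest0))

    table = FrictionTable(speeds={0: 2.0, 1: 4.0})
    surf = AccessibilitySurface.from_stack(stack, table)
    stack.add("accessibility", surf.index)

    # prior deforestation: seeded in the most accessible forest, a small
    # fraction of the grid, so distance-to-prior-deforestation is informative
    n_prior = max(1, int(config.prior_deforestation_frac * forest0.size))
    acc = surf.index.values
    order = np.argsort(acc.ravel())[::-1]
    prior = np.zeros(shape, dtype=bool)
    prior.ravel()[order[:n_prior]] = True
    stack.add("prior_deforestation", mk(prior))
    stack.add("distance_to_prior_deforestation", distance_transform(mk(prior)))

    return stack


def _annual_to_epoch_fraction(r_target: float, years: float) -> float:
    # A_end = A0 * exp(-r*years) -> cleared fraction of standing forest
    return 1.0 - np.exp(-r_target * years)


def _hotspot_mask(rng: np.random.Generator, siting_eta: np.ndarray,
                  fraction: float) -> np.ndarray:
    """Blobby clearing-frontier zones, centers drawn ~ exp(siting_eta).

    Siting follows accessibility alone — settlement fronts track roads and
    rivers regardless of tenure — so designation affects clearing only
    through its own logistic offset.
    """
    shape = siting_eta.shape
    n_target = int(round(fraction * siting_eta.size))
    mask = np.zeros(shape, dtype=bool)
    if n_target == 0:
        return mask
    w = np.exp(siting_eta - siting_eta.max()).ravel()
    w /= w.sum()
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    while mask.sum() < n_target:
        center = rng.choice(siting_eta.size, p=w)
        r0, c0 = divmod(int(center), shape[1])
        rad = int(rng.integers(2, 5))
        mask |= (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
    return mask


def clearing_probability(stack: LandscapeStack, config: SimConfig,
                         years: float = 1.0, epoch: int = 1) -> np.ndarray:
    """Per-cell clearing probability over the epoch, intercept-calibrated so
    the expected cleared fraction of standing forest matches r_target/yr.

    The logistic predictor combines accessibility, (negated, max-scaled)
    distance to prior deforestation, a per-designation offset, and the
    epoch's frontier-hotspot zones.
    """
    if not 0.0 < config.r_target < 0.5:
        raise ValueError(f"r_target must be in (0, 0.5), got {config.r_target}")
    acc = np.asarray(stack["accessibility"].values, dtype=float)
    dist = np.asarray(stack["distance_to_prior_deforestation"].values, dtype=float)
    dist_scaled = dist / max(dist.max(), 1.0)
    desig = np.asarray(stack["land_designation"].values)
    offsets = np.zeros(acc.shape)
    for code, off in config.designation_offsets.items():
        offsets[desig == code] = off
    eta = config.b0 + config.b_acc * acc + config.b_dist * (-dist_scaled) + offsets
    if config.b_hotspot != 0.0 and config.hotspot_fraction > 0.0:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 15485863, epoch]))
        eta = eta + config.b_hotspot * _hotspot_mask(
            rng, config.b_acc * acc, config.hotspot_fraction
        )

    target = _annual_to_epoch_fraction(config.r_target, years)
    forest = np.asarray(stack.forest[max(stack.forest)].values, dtype=bool) & ~stack.nodata_mask

    def mean_p(delta: float) -> float:
        s = 1.0 / (1.0 + np.exp(-(eta[forest] + delta)))
        return float(s.mean())

    lo, hi = -30.0, 30.0
    for _ in range(100):  # bisection on the intercept shift
        mid = 0.5 * (lo + hi)
        if mean_p(mid) < target:
            lo = mid
        else:
            hi = mid
    p = 1.0 / (1.0 + np.exp(-(eta + 0.5 * (lo + hi))))
    p[~forest] = 0.0
    return p


def simulate_deforestation(stack: LandscapeStack, config: SimConfig,
                           epoch: int = 1, years: float = 1.0) -> Grid:
    """Draw one epoch of clearing; returns the forest mask at epoch end.

    Bernoulli draws use a seed derived from (config.seed, epoch), so epochs
    are independent but jointly reproducible.
    """
    p = clearing_probability(stack, config, years, epoch)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7919, epoch]))
    cleared = rng.random(p.shape) < p
    start_year = max(stack.forest)
    forest_start = np.asarray(stack.forest[start_year].values, dtype=bool)
    ref = stack.forest[start_year]
    return ref.copy_with(values=forest_start & ~cleared)


def _cloud_mask(rng: np.random.Generator, shape, fraction: float) -> np.ndarray:
    """Blobby nodata patches covering exactly round(fraction * n) cells."""
    n_target = int(round(fraction * shape[0] * shape[1]))
    mask = np.zeros(shape, dtype=bool)
    if n_target == 0:
        return mask
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    while mask.sum() < n_target:
        r0, c0 = rng.integers(shape[0]), rng.integers(shape[1])
        rad = rng.integers(2, max(3, min(shape) // 10))
        mask |= (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
    # trim randomly back to the exact target count
    on = np.flatnonzero(mask.ravel())
    drop = rng.choice(on, size=len(on) - n_target, replace=False)
    mask.ravel()[drop] = False
    return mask


def emit_classifications(truth: Grid, config: SimConfig) -> list[Grid]:
    """Emulate independent classifiers observing the same forest state.

    Each source flips cells independently at its noise rate and masks its
    own random cloud/nodata patches.  Returns one grid per entry of
    ``config.noise_rates``.
    """
    t = np.asarray(truth.values, dtype=bool)
    out: list[Grid] = []
    for k, noise in enumerate(config.noise_rates):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 104729, k]))
        flips = rng.random(t.shape) < noise
        clouds = _cloud_mask(rng, t.shape, config.cloud_fraction)
        out.append(truth.copy_with(values=t ^ flips, nodata_mask=truth.nodata_mask | clouds))
    return out
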