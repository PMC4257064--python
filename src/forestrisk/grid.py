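"""Raster data model and spatial primitives.

Every layer in an analysis is a :class:`Grid`: a planar, axis-aligned raster
with a fixed cell size (default 100 m, i.e. 1-ha cells) and an explicit
nodata mask.  Row 0 is the top of the map; cell (i, j) has its center at
``(x0 + (j + 0.5) * cell, y0 - (i + 0.5) * cell)``.  There is no CRS
handling: all computation is grid-local, and all grids taking part in one
analysis must be mutually aligned (same shape, cell size and origin).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "Grid",
    "LandscapeStack",
    "Patch",
    "AlignmentError",
    "read_grid",
    "write_grid",
    "distance_transform",
    "connected_patches",
    "area_ha",
]


class AlignmentError(ValueError):
    """Two grids that must be co-registered are not."""


@dataclass
class Grid:
    """A single-variable raster on a regular square lattice.

    Parameters
    ----------
    values : ndarray (2-D)
        Cell values; numeric or small-integer categorical codes.
    cell_size_m : float
        Edge length of a cell in meters (100 m -> 1-ha cells).
    nodata_mask : ndarray of bool, optional
        True where the cell carries no observation.  Nodata cells never
        contribute to areas, distances, samples or model fits.
    origin : (float, float)
        Planar (x0, y0) of the grid's top-left corner.
    categories : dict, optional
        For categorical grids, code -> label.
    """

    values: np.ndarray
    cell_size_m: float = 100.0
    nodata_mask: np.ndarray | None = None
    origin: tuple[float, float] = (0.0, 0.0)
    categories: dict[int, str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("Grid values must be 2-D")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.values.shape:
                raise ValueError("nodata_mask shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_area_ha(self) -> float:
        return self.cell_size_m**2 / 10_000.0

    def aligned_with(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.cell_size_m, other.cell_size_m)
            and math.isclose(self.origin[0], other.origin[0])
            and math.isclose(self.origin[1], other.origin[1])
        )

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        c = self.cell_size_m
        return (x0 + (col + 0.5) * c, y0 - (row + 0.5) * c)

    def copy_with(self, values: np.ndarray, **kw) -> "Grid":
        """New grid sharing this grid's geometry."""
        return replace(self, values=values, categories=None, **kw)


@dataclass
class LandscapeStack:
    """Co-registered grids of forest state and explanatory variables.

    ``forest`` maps a year to the boolean forest/non-forest grid for that
    date.  ``variables`` holds the explanatory layers by name (slope in
    degrees, accessibility index, distance_to_prior_deforestation in meters,
    categorical land_cover and land_designation, boolean roads / rivers /
    towns, optional carbon_density in Mg C/ha).
    """

    forest: dict[int, Grid] = field(default_factory=dict)
    variables: dict[str, Grid] = field(default_factory=dict)

    def _reference(self) -> Grid | None:
        for g in list(self.forest.values()) + list(self.variables.values()):
            return g
        return None

    def add_forest(self, year: int, grid: Grid) -> None:
        self._check(grid, f"forest[{year}]")
        self.forest[year] = grid

    def add(self, name: str, grid: Grid) -> None:
        self._check(grid, name)
        self.variables[name] = grid

    def _check(self, grid: Grid, name: str) -> None:
        ref = self._reference()
        if ref is not None and not grid.aligned_with(ref):
            raise AlignmentError(
                f"grid '{name}' (shape {grid.shape}, cell {grid.cell_size_m} m, "
                f"origin {grid.origin}) is not aligned with the stack "
                f"(shape {ref.shape}, cell {ref.cell_size_m} m, origin {ref.origin})"
            )

    def __getitem__(self, name: str) -> Grid:
        return self.variables[name]

    def __contains__(self, name: str) -> bool:
        return name in self.variables

    @property
    def nodata_mask(self) -> np.ndarray:
        """Union of member nodata masks: the cells outside the study area."""
        ref = self._reference()
        if ref is None:
            raise ValueError("empty stack")
        mask = np.zeros(ref.shape, dtype=bool)
        for g in list(self.forest.values()) + list(self.variables.values()):
            mask |= g.nodata_mask
        return mask


# ---------------------------------------------------------------------------
# I/O: ESRI ASCII grid and GeoTIFF


def _read_ascii(path: Path) -> Grid:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(p) for p in parts])
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    cell = header["cellsize"]
    if "xllcorner" in header:
        x0 = header["xllcorner"]
        yll = header["yllcorner"]
    else:  # center registration
        x0 = header["xllcenter"] - cell / 2
        yll = header["yllcenter"] - cell / 2
    values = np.array(rows)
    if values.shape != (nrows, ncols):
        values = values.reshape(nrows, ncols)
    nodata = header.get("nodata_value")
    mask = np.zeros(values.shape, dtype=bool)
    if nodata is not None:
        mask = values == nodata
    if np.all(values == np.floor(values)) and np.all(np.abs(values) < 2**31):
        values = values.astype(np.int64) if not mask.any() else values
    origin = (x0, yll + nrows * cell)
    return Grid(values=values, cell_size_m=cell, nodata_mask=mask, origin=origin)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def _write_ascii(grid: Grid, path: Path, nodata_value: float = -9999.0) -> None:
    nrows, ncols = grid.shape
    x0, y0 = grid.origin
    vals = np.array(grid.values, dtype=float)
    vals[grid.nodata_mask] = nodata_value
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {float(x0)!r}\n")
        fh.write(f"yllcorner {float(y0 - nrows * grid.cell_size_m)!r}\n")
        fh.write(f"cellsize {float(grid.cell_size_m)!r}\n")
        fh.write(f"NODATA_value {float(nodata_value)!r}\n")
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


# GeoTIFF tags: ModelPixelScale/ModelTiepoint fix the geotransform,
# GDAL_NODATA (42113) carries the nodata value as ASCII.
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def _write_geotiff(grid: Grid, path: Path, nodata_value: float = -9999.0) -> None:
    import tifffile

    vals = np.asarray(grid.values)
    if np.issubdtype(vals.dtype, np.integer):
        vals = vals.astype(np.int32)
    else:
        vals = vals.astype(np.float32)
    vals = vals.copy()
    vals[grid.nodata_mask] = nodata_value
    c = float(grid.cell_size_m)
    x0, y0 = grid.origin
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (c, c, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata_value)),
    ]
    tifffile.imwrite(path, vals, extratags=extratags)


def _read_geotiff(path: Path) -> Grid:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray()
        cell, origin = 100.0, (0.0, 0.0)
        nodata = None
        if _TAG_PIXEL_SCALE in page.tags:
            cell = float(page.tags[_TAG_PIXEL_SCALE].value[0])
        if _TAG_TIEPOINT in page.tags:
            tp = page.tags[_TAG_TIEPOINT].value
            origin = (float(tp[3]), float(tp[4]))
        if _TAG_GDAL_NODATA in page.tags:
            nodata = float(page.tags[_TAG_GDAL_NODATA].value)
    mask = np.zeros(values.shape, dtype=bool)
    if nodata is not None:
        mask = values == (int(nodata) if np.issubdtype(values.dtype, np.integer) else nodata)
    return Grid(values=values, cell_size_m=cell, nodata_mask=mask, origin=origin)


def read_grid(path: str | Path, format: str | None = None) -> Grid:
    """Read a :class:`Grid` from an ESRI ASCII grid or GeoTIFF file.

    ``format`` is "ascii" or "geotiff"; inferred from the suffix when omitted
    (.asc -> ascii, .tif/.tiff -> geotiff).
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "ascii":
        grid = _read_ascii(path)
    elif fmt == "geotiff":
        grid = _read_geotiff(path)
    else:
        raise ValueError(f"unknown grid format: {fmt!r}")
    sidecar = path.with_suffix(path.suffix + ".categories")
    if sidecar.exists():
        grid.categories = _read_categories(sidecar)
    return grid


def write_grid(grid: Grid, path: str | Path, format: str | None = None,
               nodata_value: float = -9999.0) -> None:
    """Write a :class:`Grid`; round-trip through :func:`read_grid` preserves
    values, shape, cell size and nodata exactly (int and float32 data)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "ascii":
        _write_ascii(grid, path, nodata_value)
    elif fmt == "geotiff":
        _write_geotiff(grid, path, nodata_value)
    else:
        raise ValueError(f"unknown grid format: {fmt!r}")
    if grid.categories:
        _write_categories(grid.categories, path.with_suffix(path.suffix + ".categories"))


def _infer_format(path: Path) -> str:
    suf = path.suffix.lower()
    if suf in (".asc", ".txt"):
        return "ascii"
    if suf in (".tif", ".tiff"):
        return "geotiff"
    raise ValueError(f"cannot infer grid format from {path.name!r}")


def _read_categories(path: Path) -> dict[int, str]:
    cats: dict[int, str] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        cats[int(key.strip())] = val.strip()
    return cats


def _write_categories(categories: dict[int, str], path: Path) -> None:
    path.write_text("".join(f"{k}={v}\n" for k, v in sorted(categories.items())))


# ---------------------------------------------------------------------------
# Spatial primitives


def distance_transform(mask: Grid) -> Grid:
    """Euclidean distance (meters, center-to-center) to the nearest True cell.

    True cells map to 0.  Raises if the mask has no True cell, since a
    distance to nothing is undefined.
    """
    m = np.asarray(mask.values, dtype=bool)
    if not m.any():
        raise ValueError("distance_transform: mask has no True cells to measure to")
    dist = ndimage.distance_transform_edt(~m) * mask.cell_size_m
    return mask.copy_with(values=dist)


@dataclass(frozen=True)
class Patch:
    """A connected component of True cells (8-connectivity)."""

    cells: tuple[tuple[int, int], ...]
    area_ha: float
    centroid: tuple[float, float]  # planar (x, y) of mean cell center


_EIGHT = np.ones((3, 3), dtype=int)


def connected_patches(mask: Grid) -> list[Patch]:
    """Label 8-connected patches of True, non-nodata cells.

    Centroid is the mean of member cell centers in planar coordinates;
    area is the member count times the cell area in hectares.
    """
    m = np.asarray(mask.values, dtype=bool) & ~mask.nodata_mask
    labels, n = ndimage.label(m, structure=_EIGHT)
    patches: list[Patch] = []
    x0, y0 = mask.origin
    c = mask.cell_size_m
    for lbl in range(1, n + 1):
        rows, cols = np.nonzero(labels == lbl)
        cx = x0 + (cols.mean() + 0.5) * c
        cy = y0 - (rows.mean() + 0.5) * c
        patches.append(
            Patch(
                cells=tuple(zip(rows.tolist(), cols.tolist())),
                area_ha=len(rows) * mask.cell_area_ha,
                centroid=(cx, cy),
            )
        )
    return patches


def area_ha(mask: Grid) -> float:
    """Hectares covered by True, non-nodata cells."""
    m = np.asarray(mask.values, dtype=bool) & ~mask.nodata_mask
    return float(m.sum()) * mask.cell_area_ha
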