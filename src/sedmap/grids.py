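"""Raster data model, GeoTIFF I/O, and a nodata-aware focal-statistics engine.

A :class:`Grid` is a single-band raster on a square-celled, north-up grid:
a 2-D value array, a cell size in metres, the map coordinates of the
upper-left corner, and a boolean nodata mask.  Every terrain attribute and
every multiscale averaging step in this package is built on the focal
engine here, which computes neighbourhood statistics (mean, sd, min, max)
over square windows or annuli while excluding masked cells.

Edge behaviour: the footprint shrinks at grid edges, i.e. the statistic is
taken over the in-grid, unmasked part of the footprint.  A cell whose
footprint contains no unmasked cell is nodata in the output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
import tifffile

__all__ = [
    "Grid",
    "FocalSpec",
    "read_raster",
    "write_raster",
    "focal",
    "annulus_mean",
    "extract_at",
]

# GeoTIFF tag codes used for plain north-up rasters.
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass
class Grid:
    """Single-band raster with square cells and an explicit nodata mask.

    Parameters
    ----------
    values : 2-D float array
        Cell values (metres for bathymetry, dB for backscatter, attribute
        units otherwise).  Values under the mask are ignored everywhere.
    cellsize : float
        Cell edge length in metres; cells are square.
    origin : (float, float)
        Map coordinates (x, y) of the outer corner of the upper-left cell.
        Rows run south (decreasing y), columns run east (increasing x).
    nodata_mask : 2-D bool array, optional
        True where the cell holds no data.  Defaults to all-valid.
    """

    values: np.ndarray
    cellsize: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("Grid values must be a 2-D array")
        if self.cellsize <= 0:
            raise ValueError(f"cellsize must be positive, got {self.cellsize}")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise ValueError(
                f"mask shape {self.nodata_mask.shape} != values shape {self.values.shape}"
            )
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def same_geometry(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cellsize, other.cellsize)
            and np.allclose(self.origin, other.origin)
        )

    def require_same_geometry(self, other: "Grid") -> None:
        if not self.same_geometry(other):
            raise ValueError(
                "grid geometries differ (shape/cellsize/origin): "
                f"{self.shape}/{self.cellsize}/{self.origin} vs "
                f"{other.shape}/{other.cellsize}/{other.origin}; resample inputs "
                "to a common grid before stacking"
            )

    def with_values(self, values: np.ndarray, mask: np.ndarray | None = None) -> "Grid":
        """New Grid on the same geometry with different values/mask."""
        m = self.nodata_mask.copy() if mask is None else np.asarray(mask, bool)
        return Grid(np.asarray(values, float), self.cellsize, self.origin, m)

    def copy(self) -> "Grid":
        return Grid(self.values.copy(), self.cellsize, self.origin, self.nodata_mask.copy())

    # -- coordinates ------------------------------------------------------
    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates (x, y) of every cell center, as 2-D arrays."""
        nr, nc = self.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(nc) + 0.5) * self.cellsize
        ys = y0 - (np.arange(nr) + 0.5) * self.cellsize
        return np.meshgrid(xs, ys)

    def index_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the cells containing map points; may be out of range."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        col = np.floor((x - self.origin[0]) / self.cellsize).astype(int)
        row = np.floor((self.origin[1] - y) / self.cellsize).astype(int)
        return row, col

    def filled(self, fill: float = np.nan) -> np.ndarray:
        """Values with masked cells replaced by ``fill``."""
        out = self.values.copy()
        out[self.nodata_mask] = fill
        return out


@dataclass(frozen=True)
class FocalSpec:
    """Specification of a focal-statistics pass.

    ``shape='square'`` uses an odd ``width`` × ``width`` window;
    ``shape='annulus'`` uses cells at centre distance d (cell units) with
    inner_radius < d <= outer_radius.  ``statistic`` is one of
    mean / sd / min / max (sd is the population standard deviation).
    """

    shape: str = "square"
    width: int = 3
    inner_radius: int = 0
    outer_radius: int = 0
    statistic: str = "mean"

    def __post_init__(self) -> None:
        if self.shape not in ("square", "annulus"):
            raise ValueError(f"unknown footprint shape {self.shape!r}")
        if self.statistic not in ("mean", "sd", "min", "max"):
            raise ValueError(f"unknown statistic {self.statistic!r}")
        if self.shape == "square":
            if self.width < 3 or self.width % 2 == 0:
                raise ValueError(f"square width must be odd and >= 3, got {self.width}")
        else:
            if self.inner_radius < 1 or self.outer_radius <= self.inner_radius:
                raise ValueError(
                    "annulus requires outer_radius > inner_radius >= 1, got "
                    f"inner={self.inner_radius} outer={self.outer_radius}"
                )


# ---------------------------------------------------------------------------
# GeoTIFF I/O
# ---------------------------------------------------------------------------

def read_raster(path: str | Path, nodata: float | None = None) -> Grid:
    """Read a single-band GeoTIFF into a :class:`Grid`.

    Cells equal to ``nodata`` (or the file's GDAL nodata tag when ``nodata``
    is None), and non-finite cells, are masked.  Requires square cells.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        values = page.asarray()
        if values.ndim != 2:
            raise ValueError(f"{path} is not single-band (shape {values.shape})")
        scale_tag = page.tags.get(_TAG_MODEL_PIXEL_SCALE)
        tie_tag = page.tags.get(_TAG_MODEL_TIEPOINT)
        if scale_tag is not None:
            sx, sy = float(scale_tag.value[0]), float(scale_tag.value[1])
        else:
            sx = sy = 1.0
        if not np.isclose(sx, sy):
            raise ValueError(f"non-square cells in {path}: dx={sx} dy={sy}")
        if tie_tag is not None:
            t = tie_tag.value
            origin = (float(t[3]) - float(t[0]) * sx, float(t[4]) + float(t[1]) * sy)
        else:
            origin = (0.0, 0.0)
        if nodata is None:
            nd_tag = page.tags.get(_TAG_GDAL_NODATA)
            if nd_tag is not None:
                try:
                    nodata = float(nd_tag.value)
                except ValueError:
                    nodata = None
    values = np.asarray(values, dtype=float)
    mask = ~np.isfinite(values)
    if nodata is not None:
        mask |= values == nodata
    values = values.copy()
    values[mask] = np.nan
    return Grid(values, cellsize=sx, origin=origin, nodata_mask=mask)


def write_raster(grid: Grid, path: str | Path, nodata: float = -9999.0) -> Path:
    """Write a :class:`Grid` as a single-band float32 GeoTIFF with geo tags."""
    path = Path(path)
    data = grid.values.astype(np.float32)
    data[grid.nodata_mask] = np.float32(nodata)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (grid.cellsize, grid.cellsize, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.origin[0], grid.origin[1], 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata)),
    ]
    tifffile.imwrite(path, data, extratags=extratags)
    return path


# ---------------------------------------------------------------------------
# Focal engine
#
# Footprints are decomposed into per-row runs (dy, dx_lo, dx_hi); window sums
# then reduce to differences of row-wise cumulative sums, which makes square
# windows and annuli O(rows-in-footprint x cells) with exact edge shrinking.
# ---------------------------------------------------------------------------

def _footprint_offsets(spec: FocalSpec) -> list[tuple[int, int, int]]:
    """Decompose a footprint into runs (dy, dx_lo, dx_hi), inclusive."""
    runs: list[tuple[int, int, int]] = []
    if spec.shape == "square":
        r = spec.width // 2
        for dy in range(-r, r + 1):
            runs.append((dy, -r, r))
        return runs
    inner, outer = spec.inner_radius, spec.outer_radius
    for dy in range(-outer, outer + 1):
        row = []
        for dx in range(-outer, outer + 1):
            d = np.hypot(dy, dx)
            if inner < d <= outer:
                row.append(dx)
        # an annulus row is one run, or two runs split by the inner hole
        if not row:
            continue
        row = np.array(row)
        breaks = np.where(np.diff(row) > 1)[0]
        lo = 0
        for b in list(breaks) + [len(row) - 1]:
            runs.append((dy, int(row[lo]), int(row[b])))
            lo = b + 1
    return runs


def _run_sums(arr: np.ndarray, runs: list[tuple[int, int, int]]) -> np.ndarray:
    """Sum of ``arr`` over the footprint at every cell, shrinking at edges.

    ``arr`` must already be zero on cells that should not contribute.
    """
    nr, nc = arr.shape
    # row-wise cumulative sums, padded with a leading zero column
    csum = np.zeros((nr, nc + 1))
    np.cumsum(arr, axis=1, out=csum[:, 1:])
    out = np.zeros((nr, nc))
    cols = np.arange(nc)
    for dy, dx_lo, dx_hi in runs:
        hi = np.clip(cols + dx_hi + 1, 0, nc)
        lo = np.clip(cols + dx_lo, 0, nc)
        src_lo, src_hi = max(0, dy), min(nr, nr + dy)
        dst_lo, dst_hi = max(0, -dy), min(nr, nr - dy)
        out[dst_lo:dst_hi] += csum[src_lo:src_hi, hi] - csum[src_lo:src_hi, lo]
    return out


def _footprint_mean_sd(
    grid: Grid, runs: list[tuple[int, int, int]], want_sd: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(mean, sd, count) over the footprint; sd is population sd."""
    valid = (~grid.nodata_mask).astype(float)
    vals = np.where(grid.nodata_mask, 0.0, grid.values)
    count = _run_sums(valid, runs)
    total = _run_sums(vals, runs)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count > 0, total / count, np.nan)
        if want_sd:
            sq = _run_sums(vals * vals, runs)
            var = np.where(count > 0, sq / count - mean * mean, np.nan)
            sd = np.sqrt(np.clip(var, 0.0, None))
        else:
            sd = np.full_like(mean, np.nan)
    return mean, sd, count


def _footprint_minmax(grid: Grid, spec: FocalSpec, statistic: str) -> np.ndarray:
    footprint_runs = _footprint_offsets(spec)
    size = 2 * max(abs(r[0]) for r in footprint_runs) + 1 if spec.shape == "annulus" else spec.width
    fp = np.zeros((size, size), dtype=bool)
    c = size // 2
    for dy, lo, hi in footprint_runs:
        fp[c + dy, c + lo : c + hi + 1] = True
    if statistic == "max":
        arr = np.where(grid.nodata_mask, -np.inf, grid.values)
        out = ndimage.maximum_filter(arr, footprint=fp, mode="constant", cval=-np.inf)
        out[~np.isfinite(out)] = np.nan
    else:
        arr = np.where(grid.nodata_mask, np.inf, grid.values)
        out = ndimage.minimum_filter(arr, footprint=fp, mode="constant", cval=np.inf)
        out[~np.isfinite(out)] = np.nan
    return out


def focal(grid: Grid, spec: FocalSpec) -> Grid:
    """Nodata-aware focal statistic over a square or annulus footprint.

    Output nodata where the (edge-shrunk) footprint holds no unmasked cell.
    The input's own mask is kept on the output so that derived layers stay
    aligned with the source coverage.
    """
    if spec.shape == "square" and spec.width > min(grid.shape):
        raise ValueError(
            f"footprint width {spec.width} exceeds grid dimensions {grid.shape}"
        )
    if spec.shape == "annulus" and 2 * spec.outer_radius + 1 > min(grid.shape):
        raise ValueError(
            f"annulus outer radius {spec.outer_radius} exceeds grid dimensions {grid.shape}"
        )
    runs = _footprint_offsets(spec)
    if spec.statistic in ("mean", "sd"):
        mean, sd, count = _footprint_mean_sd(grid, runs, want_sd=spec.statistic == "sd")
        out = mean if spec.statistic == "mean" else sd
        empty = count == 0
    else:
        out = _footprint_minmax(grid, spec, spec.statistic)
        empty = np.isnan(out)
    mask = empty | grid.nodata_mask
    out = np.where(mask, np.nan, out)
    return grid.with_values(out, mask)


def annulus_mean(grid: Grid, inner: int, outer: int) -> Grid:
    """Mean over unmasked cells at centre distance d with inner < d <= outer.

    Distances are Euclidean, centre to centre, in cell units.  Near edges the
    annulus is partial; if the annulus does not fit the grid at all a warning
    is emitted and partial annuli are used throughout.
    """
    if not (outer > inner >= 1):
        raise ValueError(f"require outer > inner >= 1, got inner={inner} outer={outer}")
    if outer >= min(grid.shape) / 2:
        warnings.warn(
            f"annulus outer radius {outer} is large for grid {grid.shape}; "
            "annuli are partial at edges",
            stacklevel=2,
        )
    spec = FocalSpec(shape="annulus", inner_radius=inner, outer_radius=outer, statistic="mean")
    runs = _footprint_offsets(spec)
    mean, _, count = _footprint_mean_sd(grid, runs, want_sd=False)
    mask = (count == 0) | grid.nodata_mask
    return grid.with_values(np.where(mask, np.nan, mean), mask)


def extract_at(grid: Grid, points: np.ndarray) -> np.ndarray:
    """Value of the containing cell for each (x, y) map point.

    Points outside the extent or on nodata cells yield NaN.  ``points`` is an
    (n, 2) array-like of map coordinates; returns a length-n float array.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if points.size == 0:
        return np.empty(0)
    row, col = grid.index_of(points[:, 0], points[:, 1])
    nr, nc = grid.shape
    inside = (row >= 0) & (row < nr) & (col >= 0) & (col < nc)
    out = np.full(len(points), np.nan)
    r, c = row[inside], col[inside]
    vals = grid.values[r, c]
    vals[grid.nodata_mask[r, c]] = np.nan
    out[inside] = vals
    return out
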