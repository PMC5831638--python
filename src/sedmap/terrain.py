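"""Per-cell terrain and acoustic attributes from bathymetry and backscatter.

All attributes are derived from the native-resolution grids using a 3x3
window of analysis (the benthic-position indices use annuli instead):

* slope (degrees, Horn's method) and its aspect decomposed into eastness and
  northness (sin/cos of the downslope direction);
* RDMV, the relative difference to the mean value, a unitless topographic
  position index;
* focal standard deviation (metres);
* general / profile / plan curvature (Zevenbergen-Thorne polynomial fit with
  the conventional GIS x100 scaling and signs);
* benthic position index (BPI) over an annulus: centre depth minus annulus
  mean depth, positive on topographic highs;
* triangulated surface area and rugosity (surface area / planar area,
  Jenness's method);
* vector ruggedness measure (VRM, Sappington): dispersion of surface unit
  normals over the 3x3 neighbourhood;
* backscatter heterogeneity (focal max minus focal min of backscatter, dB);
* Euclidean distance from the coast (metres).

Nodata handling: a cell is nodata in every derivative if it is nodata in the
source; masked or off-grid neighbours are substituted by the centre value,
which makes the operators behave as if the surface were locally flat toward
missing data.
"""

from __future__ import annotations

import numpy as np
import shapely

from .grids import FocalSpec, Grid, annulus_mean, focal

__all__ = [
    "MULTISCALE_ATTRIBUTES",
    "ATTRIBUTE_NAMES",
    "slope",
    "aspect_components",
    "rdmv",
    "stdev",
    "curvatures",
    "bpi",
    "surface_area_and_rugosity",
    "vrm",
    "delta_backscatter",
    "distance_from_coast",
]

#: The 16 attributes that enter the multiscale candidate ladder.  Distance
#: from the coast is single-scale and excluded; so is the local mean, which
#: duplicates the bathymetry layer itself.
MULTISCALE_ATTRIBUTES = (
    "bathymetry",
    "eastness",
    "northness",
    "rdmv",
    "stdev",
    "slope",
    "fine_bpi",
    "broad_bpi",
    "curvature",
    "profile_curvature",
    "plan_curvature",
    "area",
    "rugosity",
    "ruggedness",
    "backscatter",
    "delta_backscatter",
)

ATTRIBUTE_NAMES = MULTISCALE_ATTRIBUTES + ("distance_from_coast",)

#: Annulus radii (cells) for the benthic position indices.
FINE_BPI_RADII = (1, 20)
BROAD_BPI_RADII = (15, 50)


def _neighbors(grid: Grid) -> np.ndarray:
    """3x3 neighbourhood stack, shape (3, 3, nr, nc).

    ``out[1 + dy, 1 + dx]`` is the value dy rows down / dx cols right of each
    cell.  Off-grid or masked neighbours are replaced by the centre value.
    """
    z = grid.values
    nan = grid.filled(np.nan)
    padded = np.pad(nan, 1, mode="constant", constant_values=np.nan)
    out = np.empty((3, 3) + z.shape)
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            nb = padded[1 + dy : padded.shape[0] - 1 + dy, 1 + dx : padded.shape[1] - 1 + dx]
            out[1 + dy, 1 + dx] = np.where(np.isnan(nb), z, nb)
    return out


def _horn_gradient(grid: Grid) -> tuple[np.ndarray, np.ndarray]:
    """(dz/dx, dz/dy) with x increasing east, y increasing north (Horn 3x3)."""
    n = _neighbors(grid)
    L = grid.cellsize
    # compass neighbours: rows increase southward
    nw, nn, ne = n[0, 0], n[0, 1], n[0, 2]
    w, e = n[1, 0], n[1, 2]
    sw, ss, se = n[2, 0], n[2, 1], n[2, 2]
    dzdx = ((ne + 2 * e + se) - (nw + 2 * w + sw)) / (8 * L)
    dzdy = ((nw + 2 * nn + ne) - (sw + 2 * ss + se)) / (8 * L)
    return dzdx, dzdy


def slope(bathy: Grid) -> Grid:
    """Slope angle in degrees from the Horn 3x3 gradient; 0 on flat cells."""
    dzdx, dzdy = _horn_gradient(bathy)
    s = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    return bathy.with_values(np.where(bathy.nodata_mask, np.nan, s))


def aspect_components(bathy: Grid) -> tuple[Grid, Grid]:
    """(eastness, northness): sin/cos of the downslope direction.

    Aspect is the compass direction of steepest descent (clockwise from grid
    north).  Flat cells (zero gradient) are assigned 0 for both components so
    the pair stays defined as a continuous predictor.
    """
    dzdx, dzdy = _horn_gradient(bathy)
    g = np.hypot(dzdx, dzdy)
    with np.errstate(invalid="ignore", divide="ignore"):
        east = np.where(g > 0, -dzdx / g, 0.0)
        north = np.where(g > 0, -dzdy / g, 0.0)
    nodata = bathy.nodata_mask
    return (
        bathy.with_values(np.where(nodata, np.nan, east)),
        bathy.with_values(np.where(nodata, np.nan, north)),
    )


def rdmv(bathy: Grid) -> Grid:
    """Relative difference to the mean value over 3x3; in [-1, 1].

    (centre - mean) / (max - min) of the neighbourhood, with 0 where the
    neighbourhood range is zero.
    """
    mean = focal(bathy, FocalSpec(statistic="mean")).values
    hi = focal(bathy, FocalSpec(statistic="max")).values
    lo = focal(bathy, FocalSpec(statistic="min")).values
    rng = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(rng > 0, (bathy.values - mean) / rng, 0.0)
    return bathy.with_values(np.where(bathy.nodata_mask, np.nan, out))


def stdev(bathy: Grid) -> Grid:
    """Population standard deviation over the 3x3 neighbourhood (metres)."""
    return focal(bathy, FocalSpec(statistic="sd"))


def curvatures(bathy: Grid) -> tuple[Grid, Grid, Grid]:
    """(curvature, profile, plan) by the Zevenbergen-Thorne 3x3 fit.

    Uses the conventional GIS scaling of 1/100 z-units per map unit and the
    usual sign conventions: general curvature negative in depressions,
    profile curvature negative where the surface is convex-up along the
    slope line, plan curvature positive where it is laterally convex.
    Profile and plan are 0 on zero-gradient cells; all three are 0 on planes.
    """
    n = _neighbors(bathy)
    L = bathy.cellsize
    z1, z2, z3 = n[0, 0], n[0, 1], n[0, 2]
    z4, z5, z6 = n[1, 0], n[1, 1], n[1, 2]
    z7, z8, z9 = n[2, 0], n[2, 1], n[2, 2]
    D = ((z4 + z6) / 2 - z5) / L**2
    E = ((z2 + z8) / 2 - z5) / L**2
    F = (-z1 + z3 + z7 - z9) / (4 * L**2)
    G = (-z4 + z6) / (2 * L)
    H = (z2 - z8) / (2 * L)
    g2 = G * G + H * H
    curv = -2 * (D + E) * 100
    with np.errstate(invalid="ignore", divide="ignore"):
        prof = np.where(g2 > 0, 200 * (D * G * G + E * H * H + F * G * H) / g2, 0.0)
        plan = np.where(g2 > 0, -200 * (D * H * H + E * G * G - F * G * H) / g2, 0.0)
    nodata = bathy.nodata_mask
    nanify = lambda a: np.where(nodata, np.nan, a)  # noqa: E731
    return (
        bathy.with_values(nanify(curv)),
        bathy.with_values(nanify(prof)),
        bathy.with_values(nanify(plan)),
    )


def bpi(bathy: Grid, inner: int, outer: int) -> Grid:
    """Benthic position index: centre value minus the annulus mean (metres).

    Positive on topographic highs, negative in depressions; 0 on any linear
    surface at interior cells.
    """
    ring = annulus_mean(bathy, inner, outer)
    out = bathy.values - ring.values
    mask = bathy.nodata_mask | ring.nodata_mask
    return bathy.with_values(np.where(mask, np.nan, out), mask)


def surface_area_and_rugosity(bathy: Grid) -> tuple[Grid, Grid]:
    """(surface area, rugosity) by Jenness's triangulated method.

    Eight triangles connect the cell centre to the midpoints toward its eight
    neighbours (taken in compass order); their summed Heron areas approximate
    the surface area apportioned to the cell.  Rugosity is surface area over
    planar cell area and is exactly 1 on flat terrain, 1/cos(slope) on
    planes.
    """
    n = _neighbors(bathy)
    L = bathy.cellsize
    z0 = n[1, 1]
    # compass ring, clockwise from north: (dy, dx) offsets in array indexing
    ring = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
    zr = [n[1 + dy, 1 + dx] for dy, dx in ring]
    plan = [L * np.hypot(dy, dx) for dy, dx in ring]
    # half 3-D distances centre -> neighbour
    half_c = [0.5 * np.hypot(p, z - z0) for p, z in zip(plan, zr)]
    area = np.zeros_like(z0)
    for i in range(8):
        j = (i + 1) % 8
        a = half_c[i]
        b = half_c[j]
        # consecutive ring cells are one cell apart in plan
        c = 0.5 * np.hypot(L, zr[i] - zr[j])
        s = (a + b + c) / 2
        area += np.sqrt(np.clip(s * (s - a) * (s - b) * (s - c), 0.0, None))
    rug = area / (L * L)
    nodata = bathy.nodata_mask
    return (
        bathy.with_values(np.where(nodata, np.nan, area)),
        bathy.with_values(np.where(nodata, np.nan, rug)),
    )


def vrm(bathy: Grid) -> Grid:
    """Sappington vector ruggedness measure over 3x3; in [0, 1).

    Each cell contributes a unit normal built from its slope and aspect; the
    measure is 1 - |resultant| / n over the neighbourhood.  Exactly 0 on any
    plane (all normals parallel).
    """
    dzdx, dzdy = _horn_gradient(bathy)
    s = np.arctan(np.hypot(dzdx, dzdy))
    g = np.hypot(dzdx, dzdy)
    sin_s = np.sin(s)
    with np.errstate(invalid="ignore", divide="ignore"):
        nx = np.where(g > 0, sin_s * (-dzdx) / g, 0.0)
        ny = np.where(g > 0, sin_s * (-dzdy) / g, 0.0)
    nz = np.cos(s)
    spec = FocalSpec(statistic="mean", width=3)
    parts = []
    for comp in (nx, ny, nz):
        cg = bathy.with_values(np.where(bathy.nodata_mask, np.nan, comp))
        parts.append(focal(cg, spec).values)
    resultant = np.sqrt(parts[0] ** 2 + parts[1] ** 2 + parts[2] ** 2)
    out = 1.0 - resultant
    out = np.clip(out, 0.0, None)
    return bathy.with_values(np.where(bathy.nodata_mask, np.nan, out))


def delta_backscatter(bs: Grid) -> Grid:
    """Backscatter heterogeneity: focal 3x3 max minus min (dB, >= 0)."""
    hi = focal(bs, FocalSpec(statistic="max"))
    lo = focal(bs, FocalSpec(statistic="min"))
    out = hi.values - lo.values
    mask = hi.nodata_mask | lo.nodata_mask
    return bs.with_values(np.where(mask, np.nan, out), mask)


def _as_geometry(coast) -> shapely.Geometry:
    if isinstance(coast, shapely.Geometry):
        geom = coast
    elif isinstance(coast, str):
        geom = shapely.from_wkt(coast)
    elif isinstance(coast, dict):
        geom = shapely.geometry.shape(coast)
    else:
        raise TypeError(f"unsupported coast geometry type {type(coast)!r}")
    if geom.is_empty:
        raise ValueError("coast geometry is empty")
    return geom


def distance_from_coast(template: Grid, coast) -> Grid:
    """Euclidean distance (metres) from each cell centre to the coast.

    ``coast`` may be a shapely geometry, WKT string, or GeoJSON-like mapping
    (polygon boundary or polyline), in the same map coordinates as the grid.
    """
    geom = _as_geometry(coast)
    if geom.geom_type in ("Polygon", "MultiPolygon"):
        geom = geom.boundary
    xs, ys = template.cell_centers()
    pts = shapely.points(xs.ravel(), ys.ravel())
    d = shapely.distance(pts, geom).reshape(template.shape)
    return template.with_values(np.where(template.nodata_mask, np.nan, d))
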