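"""Multiscale candidate layers: Fibonacci windows and scale bookkeeping.

The multiscale strategy is "derive, then average": every attribute is
computed once at the native resolution and then focal-mean averaged over a
ladder of square windows whose widths follow the Fibonacci sequence
(rounded up when even): 3, 5, 9, 13, 21, 35, 55 cells, with window 1 denoting
the native layer.  At 5-m cells the analysis scales are 5-275 m.  The
benthic position indices additionally carry an effective scale of
(outer annulus radius x cellsize) x window, e.g. 100 m and 250 m scale
factors at 5-m cells.

A :class:`LayerStack` holds the full candidate set - 16 attributes x the
window ladder plus the single-scale distance-from-coast layer, 129 layers
with the default ladder - all on the native grid geometry (no resampling).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import terrain
from .grids import FocalSpec, Grid, extract_at, focal
from .terrain import MULTISCALE_ATTRIBUTES

__all__ = [
    "FIBONACCI_WINDOWS",
    "ScaledLayer",
    "LayerStack",
    "fibonacci_windows",
    "rescale",
    "derive_native",
    "build_stack",
    "layer_column",
    "extract_stack",
]

#: Window ladder in cells: 1 is the native layer; 8 and 34 in the Fibonacci
#: sequence are rounded up to the nearest odd width.
FIBONACCI_WINDOWS = (1, 3, 5, 9, 13, 21, 35, 55)


def fibonacci_windows() -> list[int]:
    """The default window ladder [1, 3, 5, 9, 13, 21, 35, 55] (cells)."""
    return list(FIBONACCI_WINDOWS)


def _effective_scale(attribute: str, window: int, cellsize: float) -> float:
    if attribute == "fine_bpi":
        return terrain.FINE_BPI_RADII[1] * cellsize * window
    if attribute == "broad_bpi":
        return terrain.BROAD_BPI_RADII[1] * cellsize * window
    return window * cellsize


@dataclass
class ScaledLayer:
    """A grid tagged with its attribute name and analysis scale."""

    grid: Grid
    attribute: str
    window: int | None  # None marks a single-scale layer (distance from coast)

    @property
    def analysis_scale(self) -> float:
        """Ground extent of the averaging window, metres."""
        if self.window is None:
            return float("nan")
        return self.window * self.grid.cellsize

    @property
    def effective_scale(self) -> float:
        """Analysis scale, except for BPI where the annulus footprint
        (scale factor = outer radius x cellsize) multiplies the window."""
        if self.window is None:
            return float("nan")
        return _effective_scale(self.attribute, self.window, self.grid.cellsize)

    @property
    def name(self) -> str:
        return layer_column(self.attribute, self.window)


def layer_column(attribute: str, window: int | None) -> str:
    """Canonical column/layer name, e.g. ``slope_w9``; single-scale layers
    (window None) keep their bare attribute name."""
    if window is None:
        return attribute
    return f"{attribute}_w{window}"


@dataclass
class LayerStack:
    """Ordered collection of :class:`ScaledLayer` sharing one grid geometry."""

    template: Grid
    layers: list[ScaledLayer] = field(default_factory=list)

    def add(self, layer: ScaledLayer) -> None:
        self.template.require_same_geometry(layer.grid)
        key = (layer.attribute, layer.window)
        if any((l.attribute, l.window) == key for l in self.layers):
            raise ValueError(f"duplicate layer {key} in stack")
        self.layers.append(layer)

    def get(self, attribute: str, window: int | None | str = "any") -> ScaledLayer:
        for l in self.layers:
            if l.attribute == attribute and (window == "any" or l.window == window):
                return l
        raise KeyError(f"layer ({attribute}, window={window}) not in stack")

    def get_named(self, name: str) -> ScaledLayer:
        for l in self.layers:
            if l.name == name:
                return l
        raise KeyError(f"layer {name!r} not in stack")

    def __len__(self) -> int:
        return len(self.layers)

    def __iter__(self):
        return iter(self.layers)

    def names(self) -> list[str]:
        return [l.name for l in self.layers]

    def manifest(self) -> pd.DataFrame:
        """Stack roster as a table (attribute, window, scales)."""
        rows = [
            {
                "layer": l.name,
                "attribute": l.attribute,
                "window": l.window,
                "analysis_scale_m": l.analysis_scale,
                "effective_scale_m": l.effective_scale,
            }
            for l in self.layers
        ]
        return pd.DataFrame(rows)

    def write(self, directory: str | Path, nodata: float = -9999.0) -> Path:
        """Write every layer as GeoTIFF plus a manifest CSV; returns the
        manifest path."""
        from .grids import write_raster

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = self.manifest()
        paths = []
        for l in self.layers:
            p = directory / f"{l.name}.tif"
            write_raster(l.grid, p, nodata=nodata)
            paths.append(p.name)
        manifest["path"] = paths
        out = directory / "manifest.csv"
        manifest.to_csv(out, index=False)
        return out


def read_stack(directory: str | Path) -> LayerStack:
    """Rebuild a :class:`LayerStack` from a directory written by
    :meth:`LayerStack.write` (GeoTIFFs plus manifest.csv)."""
    from .grids import read_raster

    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    stack: LayerStack | None = None
    for _, row in manifest.iterrows():
        grid = read_raster(directory / row["path"])
        window = None if pd.isna(row["window"]) else int(row["window"])
        if stack is None:
            stack = LayerStack(template=grid)
        stack.add(ScaledLayer(grid, row["attribute"], window))
    if stack is None:
        raise ValueError(f"empty manifest in {directory}")
    return stack


def rescale(layer: ScaledLayer, window: int) -> ScaledLayer:
    """Focal-mean a native (window=1) layer over ``window`` x ``window``.

    The result stays on the native grid geometry - no resampling - so all
    scales remain cell-aligned for extraction and prediction.
    """
    if layer.window != 1:
        raise ValueError("rescale expects a native (window=1) layer")
    if window == 1:
        return ScaledLayer(layer.grid.copy(), layer.attribute, 1)
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    import warnings

    if window not in FIBONACCI_WINDOWS:
        warnings.warn(f"window {window} is not on the default ladder", stacklevel=2)
    g = focal(layer.grid, FocalSpec(statistic="mean", width=window))
    return ScaledLayer(g, layer.attribute, window)


def derive_native(bathy: Grid, bs: Grid, coast=None) -> dict[str, Grid]:
    """All native-resolution attribute grids keyed by attribute name."""
    bathy.require_same_geometry(bs)
    east, north = terrain.aspect_components(bathy)
    area, rug = terrain.surface_area_and_rugosity(bathy)
    curv, prof, plan = terrain.curvatures(bathy)
    native: dict[str, Grid] = {
        "bathymetry": bathy.copy(),
        "eastness": east,
        "northness": north,
        "rdmv": terrain.rdmv(bathy),
        "stdev": terrain.stdev(bathy),
        "slope": terrain.slope(bathy),
        "fine_bpi": terrain.bpi(bathy, *terrain.FINE_BPI_RADII),
        "broad_bpi": terrain.bpi(bathy, *terrain.BROAD_BPI_RADII),
        "curvature": curv,
        "profile_curvature": prof,
        "plan_curvature": plan,
        "area": area,
        "rugosity": rug,
        "ruggedness": terrain.vrm(bathy),
        "backscatter": bs.copy(),
        "delta_backscatter": terrain.delta_backscatter(bs),
    }
    if coast is not None:
        native["distance_from_coast"] = terrain.distance_from_coast(bathy, coast)
    return native


def build_stack(
    bathy: Grid,
    bs: Grid,
    coast,
    windows: list[int] | None = None,
) -> LayerStack:
    """Build the full multiscale candidate stack.

    16 attributes x each window in the ladder, plus distance-from-coast once:
    129 layers with the default eight windows.
    """
    windows = fibonacci_windows() if windows is None else list(windows)
    native = derive_native(bathy, bs, coast)
    stack = LayerStack(template=bathy)
    for attr in MULTISCALE_ATTRIBUTES:
        base = ScaledLayer(native[attr], attr, 1)
        for w in windows:
            stack.add(rescale(base, w))
    stack.add(ScaledLayer(native["distance_from_coast"], "distance_from_coast", None))
    return stack


def extract_stack(stack: LayerStack, points: np.ndarray) -> pd.DataFrame:
    """Layer values at map points (n, 2) as a DataFrame, one column per
    layer; missing extractions are NaN."""
    points = np.asarray(points, float).reshape(-1, 2)
    data = {l.name: extract_at(l.grid, points) for l in stack}
    df = pd.DataFrame(data)
    df.insert(0, "x", points[:, 0])
    df.insert(1, "y", points[:, 1])
    return df
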