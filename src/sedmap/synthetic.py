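"""Synthetic multibeam scenes with a known multiscale generative model.

Every stage of the mapping workflow can be exercised without survey data by
simulating:

* **bathymetry** - a sum of Gaussian random fields (GRFs) at chosen
  correlation lengths and amplitudes plus a planar trend, negative-down in
  metres.  GRFs are white noise smoothed with a Gaussian kernel on a
  periodic domain; a component's ``correlation_length`` is defined as the
  practical variogram range (the lag where the semivariogram reaches 95% of
  its sill) and its ``amplitude`` as the field's standard deviation.
* **backscatter** - linear in an independent latent coarse-sediment GRF
  plus Gaussian noise (dB).  The truth model below gives the gravel/sand
  log-ratio a backscatter coefficient, which makes the backscatter field
  correlated with the coarse-sediment distribution, as on a real survey.
* **truth** - ALR response fields that are linear in standardised layers of
  the multiscale candidate stack plus Gaussian noise, back-transformed to
  closed fraction maps.
* **grab samples** - compositions read off the truth maps at uniformly
  sampled cells, with mud/gravel censored to exact zeros below a detection
  threshold and re-closed, emulating laboratory grain-size tables.

Default conditions: a 400 x 400-cell scene at 5-m resolution (2 x 2 km, so
the 55-cell windows and the broad-BPI annulus fit with margin), 300 grab
samples, and generative signals at a signal-to-noise ratio of 4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage

from . import composition
from .grids import Grid
from .mapping import FractionMaps
from .multiscale import LayerStack, layer_column

__all__ = [
    "SceneConfig",
    "TruthModel",
    "generate_scene",
    "generate_truth",
    "sample_sites",
    "gaussian_random_field",
    "empirical_correlation_range",
]

# 95% practical range of a Gaussian covariance exp(-d^2 / (4 sigma^2))
# produced by smoothing white noise with a Gaussian kernel of std sigma:
# d95 = 2 sigma sqrt(ln 20).
_RANGE_PER_SIGMA = 2.0 * np.sqrt(np.log(20.0))


@dataclass(frozen=True)
class TruthModel:
    """Linear generative model for one ALR response.

    ``terms`` are (attribute, window, coefficient); layers are standardised
    (zero mean, unit sd over valid cells) before the coefficients apply, so
    with mutually uncorrelated layers the signal sd is sqrt(sum coef^2).
    """

    intercept: float
    terms: tuple[tuple[str, int | None, float], ...]
    noise_sd: float


def _default_truth() -> dict[str, TruthModel]:
    # Intercepts put mean fractions near mud 7% / sand 82% / gravel 11%,
    # typical of a sandy shelf; noise sd = signal sd / 5 (SNR 5).  Both
    # responses are driven by the same three-layer generative set - relative
    # seabed position at a broad scale, native-scale aspect, and mid-scale
    # averaged backscatter - with balanced coefficients so each scale is
    # identifiable: finer grain in depressions and on west-facing slopes,
    # coarser grain where backscatter is strong.
    ms_terms = (("broad_bpi", 35, -0.50), ("eastness", 1, 0.30), ("backscatter", 9, -0.40))
    gs_terms = (("backscatter", 9, 0.45), ("broad_bpi", 35, -0.50), ("eastness", 1, 0.35))
    return {
        "alr_ms": TruthModel(-1.08, ms_terms, float(np.sqrt(sum(c**2 for *_, c in ms_terms))) / 5),
        "alr_gs": TruthModel(-0.88, gs_terms, float(np.sqrt(sum(c**2 for *_, c in gs_terms))) / 5),
    }


@dataclass
class SceneConfig:
    """Study conditions for a synthetic scene."""

    shape: tuple[int, int] = (400, 400)
    cellsize: float = 5.0
    origin: tuple[float, float] = (0.0, 0.0)
    #: (correlation_length m, amplitude m) of each bathymetry GRF component;
    #: three distinct spectral bands - cell-scale roughness, mesoscale
    #: bedforms, and basin-scale relief - so that fine-, mid- and
    #: broad-scale derivatives carry separable information
    bathy_components: tuple[tuple[float, float], ...] = (
        (20.0, 2.0),
        (150.0, 5.0),
        (600.0, 10.0),
    )
    #: planar trend: (depth at west edge m, east-west gradient m per m)
    trend: tuple[float, float] = (-20.0, -0.035)
    #: latent coarse-sediment field correlation length (m)
    latent_corr_length: float = 75.0
    #: backscatter = intercept + slope * latent + N(0, noise_sd), in dB;
    #: uncompensated MBES backscatter is speckle-noisy, hence the heavy
    #: white-noise component that focal averaging progressively removes
    backscatter_link: tuple[float, float, float] = (-25.0, 5.0, 6.0)
    truth_model: dict[str, TruthModel] = field(default_factory=_default_truth)
    n_samples: int = 300
    zero_censor: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape) < 4:
            raise ValueError(f"degenerate scene shape {self.shape}")
        for length, _ in self.bathy_components:
            if length <= self.cellsize:
                raise ValueError("correlation lengths must exceed the cell size")


def gaussian_random_field(
    shape: tuple[int, int],
    correlation_length: float,
    cellsize: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-variance GRF with the requested practical variogram range.

    White noise is smoothed with a periodic Gaussian kernel whose std is
    chosen so the semivariogram reaches 95% of its sill at
    ``correlation_length`` metres, then rescaled to unit variance.
    """
    sigma_cells = correlation_length / cellsize / _RANGE_PER_SIGMA
    white = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(white, sigma_cells, mode="wrap")
    sd = f.std()
    if sd == 0:
        return np.zeros(shape)
    return (f - f.mean()) / sd


def empirical_correlation_range(field_values: np.ndarray, cellsize: float) -> float:
    """Estimate the 95% variogram range of a periodic field, in metres.

    Uses the FFT autocorrelation (exact over all pairs on the periodic
    domain), radially averaged; the range is the first lag where the
    correlation drops to 0.05.
    """
    f = field_values - field_values.mean()
    F = np.fft.rfft2(f)
    acov = np.fft.irfft2(F * np.conj(F), s=f.shape) / f.size
    rho = acov / acov[0, 0]
    nr, nc = f.shape
    dy = np.minimum(np.arange(nr), nr - np.arange(nr))
    dx = np.minimum(np.arange(nc), nc - np.arange(nc))
    d = np.hypot(dy[:, None], dx[None, :]).ravel()
    r = rho.ravel()
    bins = np.arange(0, d.max() + 1)
    idx = np.digitize(d, bins)
    prof = np.array([r[idx == i].mean() for i in range(1, len(bins))])
    below = np.nonzero(prof <= 0.05)[0]
    if len(below) == 0:
        return float(len(prof) * cellsize)
    return float((below[0] + 1) * cellsize)


def generate_scene(config: SceneConfig) -> tuple[Grid, Grid, shapely.Geometry]:
    """(bathymetry, backscatter, coast) for the configured scene.

    Deterministic under ``config.seed``.  The coast is the western map edge
    as a north-south polyline.
    """
    rng = np.random.default_rng(config.seed)
    nr, nc = config.shape
    L = config.cellsize
    x = (np.arange(nc) + 0.5) * L  # distance east of the west edge

    bathy = np.zeros(config.shape)
    for length, amp in config.bathy_components:
        bathy += amp * gaussian_random_field(config.shape, length, L, rng)
    bathy += config.trend[0] + config.trend[1] * x[None, :]

    latent = gaussian_random_field(config.shape, config.latent_corr_length, L, rng)
    b0, b1, b_sd = config.backscatter_link
    bs = b0 + b1 * latent + b_sd * rng.standard_normal(config.shape)

    x0, y0 = config.origin
    coast = shapely.LineString([(x0, y0), (x0, y0 - nr * L)])
    return (
        Grid(bathy, cellsize=L, origin=config.origin),
        Grid(bs, cellsize=L, origin=config.origin),
        coast,
    )


def _standardize(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    v = values[valid]
    sd = v.std()
    if sd == 0:
        return np.zeros_like(values)
    return (values - v.mean()) / sd


def generate_truth(
    config: SceneConfig, stack: LayerStack
) -> tuple[Grid, Grid, FractionMaps]:
    """True ALR fields and closed fraction maps from the candidate stack.

    Each response is intercept + sum(coef x standardised layer) + noise.
    Noise streams derive from ``config.seed`` and are independent of the
    scene's own randomness.
    """
    rng = np.random.default_rng((config.seed, 12345))
    t = stack.template
    alr = {}
    valid_all = np.ones(t.shape, dtype=bool)
    for response in ("alr_ms", "alr_gs"):
        model = config.truth_model[response]
        out = np.full(t.shape, model.intercept)
        valid = np.ones(t.shape, dtype=bool)
        for attr, window, coef in model.terms:
            name = layer_column(attr, window)
            try:
                layer = stack.get_named(name)
            except KeyError:
                raise KeyError(f"truth model names layer {name!r} absent from stack")
            valid &= ~layer.grid.nodata_mask
            out = out + coef * _standardize(layer.grid.values, ~layer.grid.nodata_mask)
        if model.noise_sd > 0:
            out = out + model.noise_sd * rng.standard_normal(t.shape)
        alr[response] = (out, valid)
        valid_all &= valid
    mask = ~valid_all
    pair = np.stack([alr["alr_ms"][0], alr["alr_gs"][0]], axis=-1)
    frac = composition.alr_backward(pair)
    frac[mask] = np.nan
    maps = FractionMaps(
        mud=t.with_values(frac[..., 0], mask),
        sand=t.with_values(frac[..., 1], mask),
        gravel=t.with_values(frac[..., 2], mask),
    )
    ms = t.with_values(np.where(valid_all, alr["alr_ms"][0], np.nan), mask)
    gs = t.with_values(np.where(valid_all, alr["alr_gs"][0], np.nan), mask)
    return ms, gs, maps


def sample_sites(
    fractions: FractionMaps,
    n: int,
    zero_censor: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Grab-sample table: n distinct cells drawn uniformly over valid cells.

    Observed compositions equal the true fractions except that mud and
    gravel below ``zero_censor`` are recorded as exact zeros (sand is always
    measurable) and the parts re-closed, emulating detection limits.
    Columns: x, y, mud, sand, gravel.
    """
    valid = ~fractions.mud.nodata_mask
    idx = np.flatnonzero(valid)
    if n > len(idx):
        raise ValueError(f"requested {n} samples but only {len(idx)} valid cells")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(idx, size=n, replace=False)
    rows, cols = np.unravel_index(chosen, valid.shape)
    g = fractions.mud
    xs = g.origin[0] + (cols + 0.5) * g.cellsize
    ys = g.origin[1] - (rows + 0.5) * g.cellsize
    comp = np.stack(
        [fractions.mud.values[rows, cols],
         fractions.sand.values[rows, cols],
         fractions.gravel.values[rows, cols]],
        axis=-1,
    )
    if zero_censor > 0:
        for j in (0, 2):  # mud, gravel
            comp[comp[:, j] < zero_censor, j] = 0.0
        comp /= comp.sum(axis=1, keepdims=True)
    return pd.DataFrame(
        {"x": xs, "y": ys, "mud": comp[:, 0], "sand": comp[:, 1], "gravel": comp[:, 2]}
    )
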