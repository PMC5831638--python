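"""Shared fixtures: small grids, brute-force focal oracles, and a compact
synthetic scene reused across mapping/selection tests."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from sedmap import multiscale, pipeline, synthetic
from sedmap.grids import Grid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_grid(rng) -> Grid:
    """Random 20x20 grid (cellsize 5 m) with a few masked cells."""
    values = rng.normal(size=(20, 20))
    mask = np.zeros((20, 20), dtype=bool)
    mask[3:5, 7:10] = True
    mask[15, 2] = True
    return Grid(values, cellsize=5.0, nodata_mask=mask)


def brute_focal(values: np.ndarray, mask: np.ndarray, width: int, stat: str) -> np.ndarray:
    """Independent nested-loop focal statistic with edge shrink."""
    r = width // 2
    nr, nc = values.shape
    out = np.full(values.shape, np.nan)
    for i in range(nr):
        for j in range(nc):
            acc = []
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < nr and 0 <= jj < nc and not mask[ii, jj]:
                        acc.append(values[ii, jj])
            if not acc:
                continue
            if stat == "mean":
                out[i, j] = np.mean(acc)
            elif stat == "sd":
                out[i, j] = np.std(acc)
            elif stat == "min":
                out[i, j] = np.min(acc)
            elif stat == "max":
                out[i, j] = np.max(acc)
    return out


def brute_annulus_mean(values: np.ndarray, mask: np.ndarray, inner: int, outer: int) -> np.ndarray:
    """Independent distance-filtered annulus mean (inner < d <= outer)."""
    nr, nc = values.shape
    out = np.full(values.shape, np.nan)
    for i in range(nr):
        for j in range(nc):
            acc = []
            for ii in range(nr):
                for jj in range(nc):
                    d = np.hypot(ii - i, jj - j)
                    if inner < d <= outer and not mask[ii, jj]:
                        acc.append(values[ii, jj])
            if acc:
                out[i, j] = np.mean(acc)
    return out


@pytest.fixture(scope="session")
def small_scene():
    """150x150-cell scene with full stack, truth and sample table.

    Compact analogue of the default study conditions, sized so the broad-BPI
    annulus still fits; shared (read-only) across tests.
    """
    cfg = synthetic.SceneConfig(shape=(150, 150), n_samples=300, seed=42)
    bathy, bs, coast = synthetic.generate_scene(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stack = multiscale.build_stack(bathy, bs, coast)
        alr_ms, alr_gs, frac = synthetic.generate_truth(cfg, stack)
    samples = synthetic.sample_sites(frac, cfg.n_samples, cfg.zero_censor, seed=43)
    table = pipeline.build_sample_table(stack, samples)
    return {
        "config": cfg,
        "bathy": bathy,
        "backscatter": bs,
        "coast": coast,
        "stack": stack,
        "alr_ms": alr_ms,
        "alr_gs": alr_gs,
        "fractions": frac,
        "samples": samples,
        "table": table,
    }
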