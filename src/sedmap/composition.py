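"""Compositional mathematics for mud/sand/gravel fractions.

Grain-size fractions are compositional: (mud, sand, gravel) lie on the
ternary simplex and sum to 1.  Modelling works on the additive log-ratio
(ALR) scale with sand as the reference part and base-10 logs:

    alr_ms = log10(mud / sand),   alr_gs = log10(gravel / sand)

and the closed-form inverse

    mud    = 10^alr_ms / (10^alr_ms + 10^alr_gs + 1)
    gravel = 10^alr_gs / (10^alr_ms + 10^alr_gs + 1)
    sand   = 1 - mud - gravel.

Observed zeros (a size class absent or below measurement precision) are
replaced by a small delta (default 1e-4, below typical lab precision) with
the nonzero parts rescaled so closure is preserved.

Classification follows Long's four-class simplification of the Folk ternary
scheme, driven by gravel percentage G and the sand:mud ratio R:

    G < 5%,  R < 1            -> mud and sandy mud
    G < 5%,  R >= 1           -> sand and muddy sand
    5% <= G < 80%, R < 9      -> mixed sediment
    (G >= 5% and R >= 9) or G >= 80%  -> coarse sediment

Boundaries are closed on the coarser side.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "CLASS_CODES",
    "CLASS_NAMES",
    "replace_zeros",
    "alr_forward",
    "alr_backward",
    "classify",
    "class_name",
]

#: Map class name -> integer code used in classified rasters.
CLASS_CODES = {
    "mud_sandy_mud": 1,
    "sand_muddy_sand": 2,
    "mixed": 3,
    "coarse": 4,
}
CLASS_NAMES = {v: k for k, v in CLASS_CODES.items()}


def _as_comp(c) -> np.ndarray:
    arr = np.asarray(c, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError("composition must have 3 parts (mud, sand, gravel) on the last axis")
    return arr


def replace_zeros(c, delta: float = 1e-4) -> np.ndarray:
    """Replace exact zeros with ``delta`` and rescale the nonzero parts.

    Each zero part becomes ``delta``; the k nonzero parts are multiplied by
    (1 - n_zeros * delta) / (their sum), so the output sums to 1 and no part
    is zero.  Raises if a composition is all zeros.
    """
    arr = _as_comp(c)
    if delta <= 0:
        raise ValueError("delta must be positive")
    zeros = arr == 0.0
    nz_sum = np.where(~zeros, arr, 0.0).sum(axis=-1)
    if np.any(nz_sum == 0):
        raise ValueError("composition with all parts zero cannot be closed")
    k = zeros.sum(axis=-1)
    scale = (1.0 - k * delta) / nz_sum
    out = np.where(zeros, delta, arr * scale[..., None])
    return out


def alr_forward(c) -> np.ndarray:
    """(alr_ms, alr_gs) = (log10(mud/sand), log10(gravel/sand)).

    Zero parts are rejected; run :func:`replace_zeros` first.
    """
    arr = _as_comp(c)
    if np.any(arr == 0.0):
        raise ValueError("composition contains zeros; apply replace_zeros first")
    mud, sand, gravel = arr[..., 0], arr[..., 1], arr[..., 2]
    return np.stack([np.log10(mud / sand), np.log10(gravel / sand)], axis=-1)


def alr_backward(a) -> np.ndarray:
    """Inverse ALR: (alr_ms, alr_gs) -> (mud, sand, gravel), sum exactly 1."""
    arr = np.asarray(a, dtype=float)
    if arr.shape[-1] != 2:
        raise ValueError("ALR pair must have 2 components on the last axis")
    pm = np.power(10.0, arr[..., 0])
    pg = np.power(10.0, arr[..., 1])
    denom = pm + pg + 1.0
    mud = pm / denom
    gravel = pg / denom
    sand = 1.0 - (mud + gravel)
    return np.stack([mud, sand, gravel], axis=-1)


def classify(c) -> np.ndarray:
    """Long/Folk four-class sediment code for each composition.

    Returns integer codes per :data:`CLASS_CODES`; total and deterministic on
    the closed simplex (R = sand/mud is +inf where mud = 0).
    """
    arr = _as_comp(c)
    mud, sand, gravel = arr[..., 0], arr[..., 1], arr[..., 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mud > 0, sand / np.where(mud > 0, mud, 1.0), np.inf)
    out = np.full(arr.shape[:-1], 0, dtype=np.int16)
    fine = gravel < 0.05
    out[fine & (ratio < 1)] = CLASS_CODES["mud_sandy_mud"]
    out[fine & (ratio >= 1)] = CLASS_CODES["sand_muddy_sand"]
    out[~fine & (ratio < 9) & (gravel < 0.80)] = CLASS_CODES["mixed"]
    out[~fine & ((ratio >= 9) | (gravel >= 0.80))] = CLASS_CODES["coarse"]
    return out


def class_name(code: int) -> str:
    return CLASS_NAMES[int(code)]
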