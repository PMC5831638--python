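"""Glue between grab-sample tables, the layer stack, and the models."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import composition
from .multiscale import LayerStack, extract_stack

__all__ = ["build_sample_table"]


def build_sample_table(
    stack: LayerStack, grabs: pd.DataFrame, delta: float = 1e-4
) -> pd.DataFrame:
    """Model table: predictor columns extracted at grab-sample sites plus
    ALR responses.

    ``grabs`` needs columns x, y, mud, sand, gravel (fractions closing to 1;
    exact zeros allowed).  Zeros are replaced at ``delta`` and the base-10
    ALR pair appended as ``alr_ms`` / ``alr_gs``.  Rows whose site falls on
    nodata or outside the stack extent are dropped.
    """
    required = {"x", "y", "mud", "sand", "gravel"}
    missing = required - set(grabs.columns)
    if missing:
        raise KeyError(f"grab table missing columns {sorted(missing)}")
    pts = grabs[["x", "y"]].to_numpy(float)
    table = extract_stack(stack, pts)
    for col in ("mud", "sand", "gravel"):
        table[col] = grabs[col].to_numpy(float)
    comp = composition.replace_zeros(table[["mud", "sand", "gravel"]].to_numpy(), delta)
    alr = composition.alr_forward(comp)
    table["alr_ms"] = alr[:, 0]
    table["alr_gs"] = alr[:, 1]
    predictor_cols = [c for c in table.columns if c not in ("x", "y")]
    keep = ~table[predictor_cols].isna().any(axis=1)
    return table.loc[keep].reset_index(drop=True)
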