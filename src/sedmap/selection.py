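"""Multi-scale variable screening, filtering, correlation pruning, and the
final two-response BRT fits.

The workflow mirrors the scale-selection procedure used in multiscale
substrate modelling:

1. *Screen* - for each attribute, fit a single BRT on all of its scale
   columns at once; the percent relative influence of the columns says which
   scales matter, and the residual deviance ranks attributes against each
   other (smaller is better).
2. *Filter* - keep only scales contributing >= 10% to their attribute's
   screening model.
3. *Prune within* - among the surviving scales of one attribute, sweep in
   descending contribution and drop any scale whose Spearman |rho| with an
   already-kept scale is >= 0.7.
4. *Prune across* - visit attributes in ascending residual-deviance rank and
   keep each surviving layer only if its Spearman |rho| with every layer
   retained so far (any attribute) stays < 0.7.  Pruning acts at the layer
   level, so an attribute can lose some scales and keep others.
5. *Final fit* - one BRT per response on the retained layers.

Distance from the coast has a single scale: it skips the multi-scale screen,
is ranked by its own single-predictor fit, and competes in the
across-attribute pruning like any other candidate.

Ties in contribution or rank break toward the finer scale first, then
alphabetically by attribute, so the procedure is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import brt
from .brt import BRTConfig, FitReport
from .multiscale import layer_column

__all__ = [
    "ScreenResult",
    "SelectionReport",
    "screen_variable",
    "filter_contributions",
    "prune_within",
    "prune_across",
    "run_selection",
]

CONTRIBUTION_THRESHOLD = 10.0  # percent
RHO_THRESHOLD = 0.7


@dataclass
class ScreenResult:
    """Outcome of the single-attribute, all-scales screening fit."""

    attribute: str
    per_scale_contribution: pd.Series  # percent per window, sums to 100
    residual_deviance: float
    report: FitReport
    rank: int | None = None

    @property
    def windows(self) -> list[int | None]:
        return list(self.per_scale_contribution.index)


@dataclass
class SelectionReport:
    """Audit trail of the selection pipeline for one response."""

    response: str
    retained: list[tuple[str, int | None]]
    dropped: list[tuple[str, int | None, str]]  # (attribute, window, reason)
    screen_results: dict[str, ScreenResult]
    contribution_threshold: float = CONTRIBUTION_THRESHOLD
    rho_threshold: float = RHO_THRESHOLD

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for attr, window in self.retained:
            rows.append({"attribute": attr, "window": window, "retained": True, "reason": ""})
        for attr, window, reason in self.dropped:
            rows.append({"attribute": attr, "window": window, "retained": False, "reason": reason})
        return pd.DataFrame(rows)


def _window_of(column: str, attribute: str) -> int | None:
    if column == attribute:
        return None
    return int(column.rsplit("_w", 1)[1])


def screen_variable(
    samples: pd.DataFrame,
    attribute: str,
    response: str,
    config: BRTConfig | None = None,
) -> ScreenResult:
    """One BRT on all scale columns of ``attribute`` against ``response``.

    Scale columns are those named ``{attribute}_w{window}`` in ``samples``.
    Contributions are reported per window; the residual deviance of the fit
    ranks this attribute against the others.
    """
    cols = [c for c in samples.columns if c.startswith(f"{attribute}_w")]
    if not cols:
        raise KeyError(f"no scale columns for attribute {attribute!r}")
    X = samples[cols]
    if any(X[c].nunique() <= 1 for c in cols):
        warnings.warn(f"attribute {attribute!r} has constant scale columns", stacklevel=2)
    y = samples[response].to_numpy()
    rep = brt.fit(X, y, config)
    contrib = pd.Series(
        rep.influence.to_numpy(), index=[_window_of(c, attribute) for c in cols]
    )
    return ScreenResult(
        attribute=attribute,
        per_scale_contribution=contrib,
        residual_deviance=_cv_residual_deviance(rep, y),
        report=rep,
    )


def _cv_residual_deviance(rep: FitReport, y: np.ndarray) -> float:
    """Cross-validated residual deviance of a screening fit.

    Held-out deviance (null deviance scaled by the unexplained CV fraction)
    ranks attributes without the overfitting bias that training deviance
    carries when the CV-chosen tree counts differ between fits.
    """
    null = float(np.mean((y - y.mean()) ** 2))
    return (1.0 - rep.cv_deviance_explained / 100.0) * null


def _order_scales(items: list[tuple[int | None, float]]) -> list[tuple[int | None, float]]:
    """Sort (window, contribution) descending by contribution, ties to the
    finer (smaller) window."""
    return sorted(items, key=lambda t: (-t[1], t[0] if t[0] is not None else -1))


def filter_contributions(
    result: ScreenResult, threshold: float = CONTRIBUTION_THRESHOLD
) -> list[tuple[str, int | None]]:
    """Scales contributing >= threshold percent, ordered by contribution
    descending (boundary inclusive)."""
    items = [
        (w, c) for w, c in result.per_scale_contribution.items() if c >= threshold
    ]
    return [(result.attribute, w) for w, c in _order_scales(items)]


def _spearman(samples: pd.DataFrame, col_a: str, col_b: str) -> float:
    rho = stats.spearmanr(samples[col_a], samples[col_b]).statistic
    return 0.0 if np.isnan(rho) else float(rho)


def prune_within(
    layers: list[tuple[str, int | None]],
    contributions: dict[int | None, float],
    samples: pd.DataFrame,
    threshold: float = RHO_THRESHOLD,
) -> tuple[list[tuple[str, int | None]], list[tuple[str, int | None]]]:
    """Greedy correlation pruning among scales of one attribute.

    ``layers`` are (attribute, window) pairs of a single attribute with their
    screening ``contributions``.  Sweeping in descending contribution, a
    scale is kept iff its Spearman |rho| with every already-kept scale is
    below ``threshold``.  Returns (kept, dropped).
    """
    if not layers:
        return [], []
    attr = layers[0][0]
    ordered = _order_scales([(w, contributions[w]) for _, w in layers])
    kept: list[tuple[str, int | None]] = []
    dropped: list[tuple[str, int | None]] = []
    for w, _ in ordered:
        col = layer_column(attr, w)
        ok = all(
            abs(_spearman(samples, col, layer_column(a, kw))) < threshold
            for a, kw in kept
        )
        (kept if ok else dropped).append((attr, w))
    return kept, dropped


def prune_across(
    per_variable_survivors: list[list[tuple[str, int | None]]],
    samples: pd.DataFrame,
    threshold: float = RHO_THRESHOLD,
) -> tuple[list[tuple[str, int | None]], list[tuple[str, int | None]]]:
    """Layer-level correlation pruning across attributes.

    ``per_variable_survivors`` lists the within-pruned survivors of each
    attribute, already ordered by ascending residual-deviance rank.  Each
    layer is kept iff its Spearman |rho| with every layer retained so far
    (any attribute) is below ``threshold``.  Returns (retained, dropped).
    """
    retained: list[tuple[str, int | None]] = []
    dropped: list[tuple[str, int | None]] = []
    for survivors in per_variable_survivors:
        for attr, w in survivors:
            col = layer_column(attr, w)
            ok = all(
                abs(_spearman(samples, col, layer_column(a, kw))) < threshold
                for a, kw in retained
            )
            (retained if ok else dropped).append((attr, w))
    return retained, dropped


def run_selection(
    samples: pd.DataFrame,
    roster: list[str],
    response: str,
    config: BRTConfig | None = None,
    contribution_threshold: float = CONTRIBUTION_THRESHOLD,
    rho_threshold: float = RHO_THRESHOLD,
    single_scale: tuple[str, ...] = ("distance_from_coast",),
) -> tuple[SelectionReport, FitReport]:
    """Full screen -> filter -> prune-within -> prune-across -> final fit.

    ``samples`` must hold one column per candidate layer plus the response;
    ``roster`` names the multiscale attributes to screen.  Returns the
    selection audit and the final BRT fit on the retained layers.
    """
    config = config or BRTConfig()
    screens: dict[str, ScreenResult] = {}
    dropped: list[tuple[str, int | None, str]] = []

    for attr in roster:
        screens[attr] = screen_variable(samples, attr, response, config)
    # single-scale candidates are ranked by their own single-predictor fit
    for attr in single_scale:
        if attr not in samples.columns:
            continue
        y = samples[response].to_numpy()
        rep = brt.fit(samples[[attr]], y, config)
        screens[attr] = ScreenResult(
            attribute=attr,
            per_scale_contribution=pd.Series({None: 100.0}),
            residual_deviance=_cv_residual_deviance(rep, y),
            report=rep,
        )

    # rank ascending by residual deviance, ties alphabetical
    ranked = sorted(screens.values(), key=lambda s: (s.residual_deviance, s.attribute))
    for i, s in enumerate(ranked):
        s.rank = i + 1

    per_variable_survivors: list[list[tuple[str, int | None]]] = []
    for s in ranked:
        candidates = filter_contributions(s, contribution_threshold)
        for w in s.windows:
            if (s.attribute, w) not in candidates:
                dropped.append((s.attribute, w, "below_10pct"))
        kept, corr_dropped = prune_within(
            candidates, dict(s.per_scale_contribution.items()), samples, rho_threshold
        )
        dropped.extend((a, w, "corr_within") for a, w in corr_dropped)
        if kept:
            per_variable_survivors.append(kept)

    retained, across_dropped = prune_across(per_variable_survivors, samples, rho_threshold)
    dropped.extend((a, w, "corr_across") for a, w in across_dropped)

    if not retained:
        raise ValueError(
            "no layer survived selection; consider relaxing the contribution "
            "or correlation thresholds"
        )

    report = SelectionReport(
        response=response,
        retained=retained,
        dropped=dropped,
        screen_results=screens,
        contribution_threshold=contribution_threshold,
        rho_threshold=rho_threshold,
    )
    cols = [layer_column(a, w) for a, w in retained]
    final = brt.fit(samples[cols], samples[response].to_numpy(), config)
    return report, final
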