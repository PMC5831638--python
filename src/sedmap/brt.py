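"""Boosted regression trees with internal cross-validation.

This module reproduces the conventions of the gbm / Elith-Leathwick BRT
workflow for continuous (Gaussian) responses: a stagewise ensemble of small
regression trees is grown to ``max_trees`` boosting iterations; k-fold
cross-validation chooses the iteration count that minimises held-out
deviance; the final ensemble is refit on all data at that size.  The report
carries percent relative influence per predictor (summing to 100), percent
cross-validated deviance explained, and the training residual deviance.

The backing engine is scikit-learn's ``GradientBoostingRegressor``; the
``tree_complexity`` setting (gbm's interaction depth, i.e. splits per tree)
maps to ``max_leaf_nodes = tree_complexity + 1``.  The report fields, not
the engine, are the API.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.model_selection import KFold

__all__ = ["BRTConfig", "FitReport", "fit", "deviance_explained", "partial_dependence"]


@dataclass(frozen=True)
class BRTConfig:
    """Boosting hyperparameters.

    Defaults follow the Elith-Leathwick tutorial conventions (slow learning
    rate, moderate tree complexity, 50% bagging).  ``max_trees`` bounds the
    stagewise search; cross-validation picks the optimum below it.
    """

    learning_rate: float = 0.005
    tree_complexity: int = 5
    bag_fraction: float = 0.5
    max_trees: int = 10000
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.learning_rate <= 0.1):
            raise ValueError("learning_rate must be in (0, 0.1]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not (0 < self.bag_fraction <= 1):
            raise ValueError("bag_fraction must be in (0, 1]")


@dataclass
class FitReport:
    """Fitted ensemble plus the cross-validation accounting."""

    model: GradientBoostingRegressor | None
    predictor_names: list[str]
    n_trees_opt: int
    influence: pd.Series  # percent, sums to 100
    cv_deviance_explained: float  # percent
    residual_deviance: float  # training MSE at n_trees_opt
    config: BRTConfig
    fold_models: list[GradientBoostingRegressor] = field(default_factory=list)
    cv_deviance_curve: np.ndarray | None = None
    training_frame: pd.DataFrame | None = None
    constant: float = 0.0  # prediction used when model is None (constant response)

    def predict(self, X) -> np.ndarray:
        X = _frame(X, self.predictor_names)
        if self.model is None:  # constant-response degenerate fit
            return np.full(len(X), self.constant)
        return self.model.predict(X.to_numpy())


def _frame(X, names: list[str] | None = None) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        df = X
    else:
        arr = np.asarray(X, dtype=float)
        df = pd.DataFrame(arr, columns=[f"x{i}" for i in range(arr.shape[1])])
    if names is not None:
        missing = [n for n in names if n not in df.columns]
        if missing:
            raise KeyError(f"missing predictors {missing}")
        df = df[names]
    return df


def _engine(config: BRTConfig, n_estimators: int, seed: int) -> GradientBoostingRegressor:
    return GradientBoostingRegressor(
        loss="squared_error",
        learning_rate=config.learning_rate,
        n_estimators=n_estimators,
        subsample=config.bag_fraction,
        max_leaf_nodes=config.tree_complexity + 1,
        random_state=seed,
    )


def deviance_explained(observed, predicted) -> float:
    """Percent of Gaussian deviance explained: 100 (D0 - D) / D0.

    Deviance is the mean squared error; the null model predicts the mean of
    the observations.  Raises on constant observations (zero null deviance).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("observed and predicted must be equal-length vectors (n >= 2)")
    null = np.mean((obs - obs.mean()) ** 2)
    if null == 0:
        raise ValueError("observations are constant; null deviance is zero")
    resid = np.mean((obs - pred) ** 2)
    return 100.0 * (null - resid) / null


def fit(X, y, config: BRTConfig | None = None) -> FitReport:
    """Fit a BRT with k-fold CV selection of the tree count.

    ``X`` is a predictor matrix (DataFrame or array), ``y`` the continuous
    response.  Deterministic for a fixed config (fold split and per-fold
    bagging streams all derive from ``config.seed``).
    """
    config = config or BRTConfig()
    X = _frame(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < config.cv_folds:
        raise ValueError(f"{n} rows is fewer than cv_folds={config.cv_folds}")
    names = list(X.columns)
    Xa = X.to_numpy()

    if np.all(y == y[0]):
        # constant response: no deviance to explain, uniform influence
        rep = FitReport(
            model=None,
            predictor_names=names,
            n_trees_opt=0,
            influence=pd.Series(100.0 / len(names), index=names),
            cv_deviance_explained=0.0,
            residual_deviance=0.0,
            config=config,
            training_frame=X.copy(),
            constant=float(y[0]),
        )
        return rep

    kf = KFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed % (2**31))
    cv_sse = np.zeros(config.max_trees)  # summed squared error per iteration
    null_sse = 0.0
    fold_models: list[GradientBoostingRegressor] = []
    fold_index: list[tuple[np.ndarray, np.ndarray]] = []
    for i, (tr, te) in enumerate(kf.split(Xa)):
        m = _engine(config, config.max_trees, seed=(config.seed + 1000003 * (i + 1)) % (2**31))
        m.fit(Xa[tr], y[tr])
        fold_models.append(m)
        fold_index.append((tr, te))
        null_sse += np.sum((y[te] - y[tr].mean()) ** 2)
        stage_pred = np.empty((config.max_trees, len(te)))
        for s, p in enumerate(m.staged_predict(Xa[te])):
            stage_pred[s] = p
        cv_sse += np.sum((stage_pred - y[te]) ** 2, axis=1)

    n_opt = int(np.argmin(cv_sse)) + 1
    cv_dev = 100.0 * (null_sse - cv_sse[n_opt - 1]) / null_sse

    final = _engine(config, n_opt, seed=config.seed % (2**31))
    final.fit(Xa, y)
    imp = final.feature_importances_
    tot = imp.sum()
    influence = pd.Series(
        100.0 * imp / tot if tot > 0 else np.full(len(names), 100.0 / len(names)),
        index=names,
    )
    resid = float(np.mean((y - final.predict(Xa)) ** 2))
    return FitReport(
        model=final,
        predictor_names=names,
        n_trees_opt=n_opt,
        influence=influence,
        cv_deviance_explained=float(cv_dev),
        residual_deviance=resid,
        config=config,
        fold_models=fold_models,
        cv_deviance_curve=cv_sse / max(null_sse, np.finfo(float).tiny),
        training_frame=X.copy(),
    )


def partial_dependence(
    report: FitReport, predictor: str, grid=None, n_points: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Marginal response curve for one predictor.

    Averages model predictions over the empirical distribution of the other
    predictors with ``predictor`` fixed at each grid value.  Returns
    (grid, curve).
    """
    if predictor not in report.predictor_names:
        raise KeyError(f"predictor {predictor!r} not in model")
    if report.training_frame is None:
        raise ValueError("report carries no training data for marginalisation")
    X = report.training_frame
    if grid is None:
        col = X[predictor].to_numpy()
        grid = np.linspace(col.min(), col.max(), n_points)
    grid = np.asarray(grid, dtype=float)
    curve = np.empty(len(grid))
    work = X.copy()
    for i, v in enumerate(grid):
        work[predictor] = v
        curve[i] = float(np.mean(report.predict(work)))
    return grid, curve
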