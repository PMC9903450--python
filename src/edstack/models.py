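"""Level-0 tree-ensemble regressors: service capacity and population health.

Both are random forests.  The capacity model is trained on monthly rows with
three per-10,000 capacity rates as predictors; the population-health model on
region-year rows with population, age structure and the three health-index
domains.  Predictions are clipped to the training-target range (tree
ensembles cannot extrapolate, and the range is part of the model contract).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from edstack.curation import CAPACITY_COLUMNS, HEALTH_COLUMNS, TARGET_COLUMN

CAPACITY_PREDICTORS = list(CAPACITY_COLUMNS)
HEALTH_PREDICTORS = list(HEALTH_COLUMNS)

#: Search grid for the two tuned hyper-parameters.
DEFAULT_GRID: list[tuple[int, int | None]] = [
    (n, d) for n in (50, 100, 200, 500) for d in (2, 4, 8, None)
]


@dataclass(frozen=True)
class HyperParams:
    n_trees: int = 100
    max_depth: int | None = None

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be positive")
        if self.max_depth is not None and self.max_depth < 1:
            raise ValueError("max_depth must be positive or None")

    @property
    def complexity_key(self) -> tuple[int, float]:
        depth = np.inf if self.max_depth is None else float(self.max_depth)
        return (self.n_trees, depth)


@dataclass
class ForestModel:
    """A fitted forest plus the metadata needed to use it safely."""

    forest: RandomForestRegressor
    predictors: list[str]
    target_range: tuple[float, float]
    hyperparams: HyperParams = field(default_factory=HyperParams)

    @property
    def gini_importances(self) -> dict[str, float]:
        """Impurity-decrease importances, non-negative and summing to 1."""
        imp = np.asarray(self.forest.feature_importances_, float)
        total = imp.sum()
        if total <= 0:  # degenerate fit (constant target): spread uniformly
            imp = np.full(len(self.predictors), 1.0 / len(self.predictors))
        else:
            imp = imp / total
        return dict(zip(self.predictors, imp))

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.predictors if c not in rows.columns]
        if missing:
            raise KeyError(f"rows lack predictor columns: {missing}")
        if len(rows) == 0:
            return np.empty(0)
        raw = self.forest.predict(rows[self.predictors].to_numpy(float))
        lo, hi = self.target_range
        return np.clip(raw, lo, hi)


def _fit_forest(
    rows: pd.DataFrame,
    predictors: list[str],
    hp: HyperParams,
    seed: int,
    target: str = TARGET_COLUMN,
) -> ForestModel:
    if len(rows) < 2:
        raise ValueError("need at least 2 rows to fit a model")
    cols = predictors + [target]
    missing = [c for c in cols if c not in rows.columns]
    if missing:
        raise KeyError(f"rows lack columns: {missing}")
    if rows[cols].isna().any().any():
        raise ValueError("missing values in model input; curate the panel first")
    X = rows[predictors].to_numpy(float)
    y = rows[target].to_numpy(float)
    forest = RandomForestRegressor(
        n_estimators=hp.n_trees, max_depth=hp.max_depth, random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return ForestModel(
        forest=forest,
        predictors=list(predictors),
        target_range=(float(y.min()), float(y.max())),
        hyperparams=hp,
    )


def fit_capacity(
    rows: pd.DataFrame, hp: HyperParams | None = None, seed: int = 0
) -> ForestModel:
    """Fit the monthly capacity model (GP / 111 / ambulance rates -> rate)."""
    return _fit_forest(rows, CAPACITY_PREDICTORS, hp or HyperParams(), seed)


def fit_health(
    annual_rows: pd.DataFrame, hp: HyperParams | None = None, seed: int = 0
) -> ForestModel:
    """Fit the annual population-health model on region-year rows."""
    return _fit_forest(annual_rows, HEALTH_PREDICTORS, hp or HyperParams(), seed)


def select_hyperparams(
    rows: pd.DataFrame,
    predictors: list[str],
    grid: list[tuple[int, int | None]] | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> HyperParams:
    """Pick the least complex grid point within one sd of the best mean CV R².

    Complexity is ordered by (n_trees, max_depth) with None treated as
    unbounded depth; ties favour fewer trees, then shallower trees.
    """
    grid = DEFAULT_GRID if grid is None else list(grid)
    if not grid:
        raise ValueError("empty hyper-parameter grid")
    candidates = [HyperParams(n, d) for n, d in grid]
    if len(candidates) == 1:
        return candidates[0]

    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    X = rows[predictors].to_numpy(float)
    y = rows[TARGET_COLUMN].to_numpy(float)
    scores = {}
    for hp in candidates:
        fold_scores = []
        for train_idx, val_idx in kf.split(X):
            forest = RandomForestRegressor(
                n_estimators=hp.n_trees, max_depth=hp.max_depth,
                random_state=seed, n_jobs=1,
            )
            forest.fit(X[train_idx], y[train_idx])
            pred = forest.predict(X[val_idx])
            resid = y[val_idx] - pred
            tot = y[val_idx] - y[val_idx].mean()
            fold_scores.append(1.0 - (resid @ resid) / (tot @ tot))
        scores[hp] = (float(np.mean(fold_scores)), float(np.std(fold_scores)))

    best_hp = max(scores, key=lambda h: scores[h][0])
    best_mean, best_sd = scores[best_hp]
    admissible = [h for h in candidates if scores[h][0] >= best_mean - best_sd]
    return min(admissible, key=lambda h: h.complexity_key)


def save_model(model: ForestModel, path: str) -> None:
    joblib.dump(
        {
            "kind": "forest",
            "predictors": model.predictors,
            "target_range": model.target_range,
            "hyperparams": (model.hyperparams.n_trees, model.hyperparams.max_depth),
            "forest": model.forest,
        },
        path,
    )


def load_model(path: str) -> ForestModel:
    blob = joblib.load(path)
    return ForestModel(
        forest=blob["forest"],
        predictors=list(blob["predictors"]),
        target_range=tuple(blob["target_range"]),
        hyperparams=HyperParams(*blob["hyperparams"]),
    )
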