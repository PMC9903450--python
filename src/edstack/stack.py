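"""The stacked regression: nested splits, level-0 fits, level-1 combiner.

Per fold, rows are partitioned 70/10/20: the two level-0 forests are fit on
the 70% portion (the health model on annual mean targets derived from those
rows only, so no validation data leaks into it), the least-squares combiner
on the 10% portion, and the remaining 20% is held out for validation.

The combiner is an ordinary least-squares fit with intercept on the two
level-0 predictions; the health prediction for a monthly row is obtained from
the row's own annual covariates, which makes it constant across all months of
a region-year (broadcast of the annual prediction).
"""

from __future__ import annotations

from dataclasses import dataclass

import joblib
import numpy as np
import pandas as pd

from edstack.curation import ALL_COVARIATES, TARGET_COLUMN, annual_frame
from edstack.models import (
    ForestModel,
    HyperParams,
    fit_capacity,
    fit_health,
    load_model,
    save_model,
)


@dataclass
class SplitPlan:
    """One fold's three-way row partition (positional indices)."""

    level0_idx: np.ndarray
    level1_idx: np.ndarray
    validation_idx: np.ndarray
    seed: int
    fold_id: int
    repeat_id: int = 0

    def validate(self, n: int) -> None:
        parts = [self.level0_idx, self.level1_idx, self.validation_idx]
        combined = np.concatenate(parts)
        if len(combined) != n or len(np.unique(combined)) != n:
            raise AssertionError("split does not partition the rows")


def make_splits(
    n: int, n_folds: int = 5, seed: int = 0, repeat_id: int = 0
) -> list[SplitPlan]:
    """Shuffle n rows and cut them into `n_folds` nested 70/10/20 splits.

    Each fold's validation set is one fifth of the data; of the remainder,
    one eighth goes to the level-1 combiner and seven eighths to the level-0
    models.  Across the folds every row is validated exactly once.
    """
    if n < 2 * n_folds:
        raise ValueError(f"too few rows ({n}) for {n_folds}-fold splitting")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)
    plans = []
    for fold_id, val in enumerate(folds):
        rest = np.concatenate([f for i, f in enumerate(folds) if i != fold_id])
        n_level1 = int(round(len(rest) / 8.0))
        plans.append(
            SplitPlan(
                level0_idx=rest[n_level1:],
                level1_idx=rest[:n_level1],
                validation_idx=val,
                seed=seed,
                fold_id=fold_id,
                repeat_id=repeat_id,
            )
        )
        plans[-1].validate(n)
    return plans


def make_train_split(
    n: int, seed: int = 0, level1_fraction: float = 0.125
) -> SplitPlan:
    """A refit split with no validation set: 1/8 level-1, 7/8 level-0."""
    if not 0 < level1_fraction < 1:
        raise ValueError("level1_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_level1 = int(round(n * level1_fraction))
    return SplitPlan(
        level0_idx=perm[n_level1:],
        level1_idx=perm[:n_level1],
        validation_idx=np.empty(0, dtype=int),
        seed=seed,
        fold_id=-1,
    )


def fit_combiner(
    capacity_pred: np.ndarray, health_pred: np.ndarray, target: np.ndarray
) -> tuple[float, float, float]:
    """Least-squares (beta0, beta_capacity, beta_health) with intercept."""
    X = np.column_stack(
        [np.ones_like(capacity_pred), capacity_pred, health_pred]
    ).astype(float)
    beta, *_ = np.linalg.lstsq(X, np.asarray(target, float), rcond=None)
    return float(beta[0]), float(beta[1]), float(beta[2])


@dataclass
class StackedRegression:
    """Fitted capacity + health forests and the affine level-1 combiner."""

    capacity_model: ForestModel
    health_model: ForestModel
    beta0: float
    beta_capacity: float
    beta_health: float
    n_level1_dropped: int = 0

    def level0_predictions(self, rows: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        return self.capacity_model.predict(rows), self.health_model.predict(rows)

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        missing = [c for c in ALL_COVARIATES if c not in rows.columns]
        if missing:
            raise KeyError(f"rows lack covariate columns: {missing}")
        cap, health = self.level0_predictions(rows)
        return self.beta0 + self.beta_capacity * cap + self.beta_health * health

    def save(self, path: str) -> None:
        joblib.dump(
            {
                "kind": "stack",
                "beta": (self.beta0, self.beta_capacity, self.beta_health),
                "capacity": path + ".capacity",
                "health": path + ".health",
            },
            path,
        )
        save_model(self.capacity_model, path + ".capacity")
        save_model(self.health_model, path + ".health")

    @classmethod
    def load(cls, path: str) -> "StackedRegression":
        blob = joblib.load(path)
        b0, bc, bh = blob["beta"]
        return cls(
            capacity_model=load_model(blob["capacity"]),
            health_model=load_model(blob["health"]),
            beta0=b0,
            beta_capacity=bc,
            beta_health=bh,
        )


def fit_stack(
    panel: pd.DataFrame,
    split: SplitPlan,
    hp_capacity: HyperParams | None = None,
    hp_health: HyperParams | None = None,
    seed: int = 0,
) -> StackedRegression:
    """Fit the full stack on one split plan.

    The health model's annual targets are derived from level-0 rows only;
    partial region-years use the mean over the months available there.
    """
    level0 = panel.iloc[split.level0_idx]
    level1 = panel.iloc[split.level1_idx]
    capacity = fit_capacity(level0, hp_capacity, seed)
    health = fit_health(annual_frame(level0), hp_health, seed)
    cap_pred = capacity.predict(level1)
    health_pred = health.predict(level1)
    beta0, beta_c, beta_h = fit_combiner(
        cap_pred, health_pred, level1[TARGET_COLUMN].to_numpy(float)
    )
    return StackedRegression(
        capacity_model=capacity,
        health_model=health,
        beta0=beta0,
        beta_capacity=beta_c,
        beta_health=beta_h,
    )


def predict_stack(model: StackedRegression, rows: pd.DataFrame) -> np.ndarray:
    return model.predict(rows)
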