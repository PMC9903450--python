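"""Performance metrics, repeated cross-validation and variable importance.

Headline scores come from repeated 5-fold cross-validation (5 repeats by
default, giving 25 validation sets).  R² is reported both averaged over folds
(primary) and pooled over the concatenated validation predictions.
Permutation importance permutes one covariate at a time within the validation
split, holding the fitted stack fixed; annual covariates are permuted at
region-year level and re-broadcast to their months.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from edstack.curation import (
    ALL_COVARIATES,
    HEALTH_COLUMNS,
    TARGET_COLUMN,
)
from edstack.models import HyperParams
from edstack.months import calendar_month, month_year
from edstack.stack import SplitPlan, fit_stack, make_splits, make_train_split

WINTER_MONTHS = (12, 1, 2)


def r_squared(truth, predicted) -> float:
    """Coefficient of determination, 1 - SS_res/SS_tot."""
    y = np.asarray(truth, float)
    p = np.asarray(predicted, float)
    if y.shape != p.shape or y.ndim != 1 or len(y) < 2:
        raise ValueError("truth and predicted must be equal-length 1-d, n >= 2")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ValueError("R-squared undefined for constant truth")
    ss_res = float(((y - p) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def mape(truth, predicted) -> float:
    """Mean absolute percentage error as a fraction (0.03 == 3%)."""
    y = np.asarray(truth, float)
    p = np.asarray(predicted, float)
    if y.shape != p.shape:
        raise ValueError("truth and predicted must have equal length")
    if (y <= 0).any():
        raise ValueError("MAPE undefined for non-positive truth values")
    return float(np.mean(np.abs(y - p) / y))


@dataclass
class EvaluationReport:
    fold_r2: list[float]
    fold_mape: list[float]
    fold_ids: list[tuple[int, int]]  # (repeat, fold)
    validation_sets: list[tuple[int, ...]]
    pooled_r2: float
    monthly_errors: dict[str, float] = field(default_factory=dict)
    winter_error: float | None = None
    mape_value: float | None = None

    @property
    def r2_mean(self) -> float:
        return float(np.mean(self.fold_r2))

    @property
    def r2_sd(self) -> float:
        return float(np.std(self.fold_r2))

    @property
    def mape_mean(self) -> float:
        return float(np.mean(self.fold_mape))

    @property
    def n_distinct_validation_sets(self) -> int:
        return len(set(self.validation_sets))

    def to_dict(self) -> dict:
        return {
            "r2_mean": self.r2_mean,
            "r2_sd": self.r2_sd,
            "pooled_r2": self.pooled_r2,
            "mape_mean": self.mape_mean,
            "mape": self.mape_value,
            "n_folds": len(self.fold_r2),
            "n_distinct_validation_sets": self.n_distinct_validation_sets,
            "fold_r2": self.fold_r2,
            "fold_mape": self.fold_mape,
            "monthly_errors": self.monthly_errors,
            "winter_error": self.winter_error,
        }


def _score_fold(
    panel: pd.DataFrame, split: SplitPlan, hp_capacity, hp_health, seed
):
    model = fit_stack(panel, split, hp_capacity, hp_health, seed)
    val = panel.iloc[split.validation_idx]
    pred = model.predict(val)
    y = val[TARGET_COLUMN].to_numpy(float)
    return model, y, pred


def cross_validate(
    panel: pd.DataFrame,
    hp_capacity: HyperParams | None = None,
    hp_health: HyperParams | None = None,
    n_repeats: int = 5,
    n_folds: int = 5,
    seed: int = 0,
) -> EvaluationReport:
    """Repeated k-fold CV of the full stack; one score per validation set."""
    fold_r2, fold_mape, fold_ids, val_sets = [], [], [], []
    pooled_y, pooled_p = [], []
    for repeat in range(n_repeats):
        splits = make_splits(len(panel), n_folds, seed=seed + repeat, repeat_id=repeat)
        for split in splits:
            _, y, pred = _score_fold(panel, split, hp_capacity, hp_health, seed)
            fold_r2.append(r_squared(y, pred))
            fold_mape.append(mape(y, pred))
            fold_ids.append((repeat, split.fold_id))
            val_sets.append(tuple(sorted(int(i) for i in split.validation_idx)))
            pooled_y.append(y)
            pooled_p.append(pred)
    pooled = r_squared(np.concatenate(pooled_y), np.concatenate(pooled_p))
    return EvaluationReport(
        fold_r2=fold_r2,
        fold_mape=fold_mape,
        fold_ids=fold_ids,
        validation_sets=val_sets,
        pooled_r2=pooled,
    )


def forecast_accuracy(
    panel: pd.DataFrame,
    train_year: int,
    test_year: int,
    hp_capacity: HyperParams | None = None,
    hp_health: HyperParams | None = None,
    seed: int = 0,
) -> EvaluationReport:
    """Train on one year, forecast the next; score the cross-region mean series.

    The target series is mean monthly attendance rate across regions; MAPE is
    taken over the test year's months and the winter error over Dec-Feb.
    """
    years = set(panel["year"]) if "year" in panel else set(
        panel["month"].map(month_year)
    )
    for y in (train_year, test_year):
        if y not in years:
            raise ValueError(f"year {y} not present in the panel")
    if "year" not in panel.columns:
        panel = panel.assign(year=panel["month"].map(month_year))
    train = panel[panel["year"] == train_year].reset_index(drop=True)
    test = panel[panel["year"] == test_year].reset_index(drop=True)
    split = make_train_split(len(train), seed=seed)
    model = fit_stack(train, split, hp_capacity, hp_health, seed)
    pred = model.predict(test)
    obs = (
        test.assign(_pred=pred)
        .groupby("month")[[TARGET_COLUMN, "_pred"]]
        .mean()
        .sort_index()
    )
    y_true = obs[TARGET_COLUMN].to_numpy(float)
    y_pred = obs["_pred"].to_numpy(float)
    monthly = {
        month: 100.0 * (p - t) / t
        for month, t, p in zip(obs.index, y_true, y_pred)
    }
    winter = [
        abs(monthly[m]) for m in obs.index if calendar_month(m) in WINTER_MONTHS
    ]
    return EvaluationReport(
        fold_r2=[r_squared(y_true, y_pred)] if len(y_true) > 1 else [],
        fold_mape=[mape(y_true, y_pred)],
        fold_ids=[(0, 0)],
        validation_sets=[tuple(range(len(test)))],
        pooled_r2=r_squared(y_true, y_pred) if len(y_true) > 1 else float("nan"),
        monthly_errors=monthly,
        winter_error=float(np.mean(winter)) if winter else None,
        mape_value=mape(y_true, y_pred),
    )


def _permute_column(
    val: pd.DataFrame, column: str, rng: np.random.Generator
) -> pd.DataFrame:
    """Permute one covariate within the validation frame.

    Annual covariates are permuted across region-years (all months of a
    region-year receive the same permuted value); monthly covariates are
    permuted row-wise.
    """
    out = val.copy()
    if column in HEALTH_COLUMNS:
        if "year" not in out.columns:
            out["year"] = out["month"].map(month_year)
        ry = out[["region_id", "year"]].drop_duplicates().reset_index(drop=True)
        values = (
            out.groupby(["region_id", "year"])[column].first().loc[
                pd.MultiIndex.from_frame(ry)
            ].to_numpy()
        )
        shuffled = values[rng.permutation(len(values))]
        lookup = dict(zip(map(tuple, ry.to_numpy()), shuffled))
        out[column] = [
            lookup[(r, y)] for r, y in zip(out["region_id"], out["year"])
        ]
    else:
        out[column] = out[column].to_numpy()[rng.permutation(len(out))]
    return out


@dataclass
class ImportanceReport:
    gini: dict[str, dict[str, float]]
    permutation: dict[str, tuple[float, float]]  # variable -> (mean dR2, sd)
    baseline_r2: float

    def to_dict(self) -> dict:
        return {
            "gini": self.gini,
            "permutation": {
                k: {"mean": m, "sd": s} for k, (m, s) in self.permutation.items()
            },
            "baseline_r2": self.baseline_r2,
        }


def permutation_importance(
    panel: pd.DataFrame,
    covariates: list[str] | None = None,
    hp_capacity: HyperParams | None = None,
    hp_health: HyperParams | None = None,
    n_repeats: int = 5,
    n_folds: int = 5,
    seed: int = 0,
) -> ImportanceReport:
    """Stack-wide permutation importance over repeated 5-fold CV.

    For each fold and covariate, PI = R²(validation) - R²(validation with the
    covariate permuted).  Scores are averaged over all folds of all repeats.
    """
    covariates = list(ALL_COVARIATES) if covariates is None else list(covariates)
    rng = np.random.default_rng(seed)
    deltas: dict[str, list[float]] = {c: [] for c in covariates}
    baselines = []
    gini_cap: list[dict[str, float]] = []
    gini_health: list[dict[str, float]] = []
    for repeat in range(n_repeats):
        splits = make_splits(len(panel), n_folds, seed=seed + repeat, repeat_id=repeat)
        for split in splits:
            model, y, pred = _score_fold(panel, split, hp_capacity, hp_health, seed)
            base = r_squared(y, pred)
            baselines.append(base)
            gini_cap.append(model.capacity_model.gini_importances)
            gini_health.append(model.health_model.gini_importances)
            val = panel.iloc[split.validation_idx].reset_index(drop=True)
            for cov in covariates:
                permuted = _permute_column(val, cov, rng)
                perm_pred = model.predict(permuted)
                deltas[cov].append(base - r_squared(y, perm_pred))
    gini = {
        "capacity": {
            k: float(np.mean([g[k] for g in gini_cap])) for k in gini_cap[0]
        },
        "health": {
            k: float(np.mean([g[k] for g in gini_health])) for k in gini_health[0]
        },
    }
    permutation = {
        c: (float(np.mean(v)), float(np.std(v))) for c, v in deltas.items()
    }
    return ImportanceReport(
        gini=gini, permutation=permutation, baseline_r2=float(np.mean(baselines))
    )
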