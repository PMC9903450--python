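"""Long-horizon what-if forecasts of mean monthly attendance rates.

A future panel is built by repeating the baseline year's covariates over the
horizon, substituting projected population and % over 65 each year.  Scenario
transformations then either uplift one capacity rate by a fixed fraction in
every future month, or ramp below-average health indices towards the
baseline average by a fixed step per year.  The fitted stack predicts each
future region-month; the series reported is the cross-region mean per month,
with a trailing 4-month rolling average for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from edstack.curation import TARGET_COLUMN
from edstack.months import month_year, shift_month
from edstack.stack import StackedRegression

SCENARIO_NAMES = (
    "do_nothing",
    "uplift_111",
    "uplift_gp",
    "uplift_ambulance",
    "health_ramp",
)
SERVICE_COLUMNS = {
    "gp": "gp_capacity",
    "111": "capacity_111",
    "ambulance": "ambulance_capacity",
}
HEALTH_INDEX_COLUMNS = ("people_index", "places_index", "lives_index")


@dataclass(frozen=True)
class ScenarioSpec:
    name: str = "do_nothing"
    uplift_fraction: float = 0.10
    ramp_step: float = 0.2
    horizon_years: int = 4

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise ValueError(f"unknown scenario {self.name!r}")
        if self.uplift_fraction < 0:
            raise ValueError("uplift_fraction must be non-negative")
        if self.ramp_step <= 0:
            raise ValueError("ramp_step must be positive")
        if self.horizon_years < 1:
            raise ValueError("horizon_years must be >= 1")


@dataclass
class ForecastSeries:
    scenario: str
    months: list[str]          # baseline months followed by forecast months
    values: list[float]        # observed baseline means, then predictions
    n_baseline: int
    rolling: list[float] = field(default_factory=list)

    @property
    def forecast_months(self) -> list[str]:
        return self.months[self.n_baseline:]

    @property
    def forecast_values(self) -> list[float]:
        return self.values[self.n_baseline:]

    def to_frame(self) -> pd.DataFrame:
        pad = [np.nan] * (len(self.values) - len(self.rolling))
        return pd.DataFrame(
            {
                "month": self.months,
                "mean_attendances": self.values,
                "rolling_4m": pad + list(self.rolling),
                "segment": ["baseline"] * self.n_baseline
                + ["forecast"] * (len(self.months) - self.n_baseline),
                "scenario": self.scenario,
            }
        )


def build_future_panel(
    baseline: pd.DataFrame, projections: pd.DataFrame, horizon_years: int
) -> pd.DataFrame:
    """Repeat baseline covariates over the horizon with projected populations.

    Capacity rates and health indices are frozen at their month-matched
    baseline values; population_scaled and pct_over_65 take the projected
    figures of each future year.
    """
    if "year" not in baseline.columns:
        baseline = baseline.assign(year=baseline["month"].map(month_year))
    base_year = int(baseline["year"].max())
    proj = projections.copy()
    proj["region_id"] = proj["region_id"].astype(str)
    proj = proj.set_index(["region_id", "year"])
    regions = baseline["region_id"].astype(str).unique()
    for k in range(1, horizon_years + 1):
        year = base_year + k
        missing = [
            r for r in regions if (r, year) not in proj.index
        ]
        if missing:
            raise ValueError(
                f"projections missing year {year} for regions {missing[:5]}"
            )
    chunks = []
    for k in range(1, horizon_years + 1):
        year = base_year + k
        chunk = baseline[baseline["year"] == base_year].copy()
        chunk["month"] = chunk["month"].map(lambda m: shift_month(m, 12 * k))
        chunk["year"] = year
        key = pd.MultiIndex.from_arrays(
            [chunk["region_id"].astype(str), chunk["year"]]
        )
        pop = proj["population"].loc[key].to_numpy(float)
        over65 = proj["population_over_65"].loc[key].to_numpy(float)
        chunk["population_scaled"] = pop / 10_000.0
        chunk["pct_over_65"] = 100.0 * over65 / pop
        chunk[TARGET_COLUMN] = np.nan  # future attendances are unknown
        chunks.append(chunk)
    return pd.concat(chunks, ignore_index=True)


def apply_uplift(rows: pd.DataFrame, service: str, fraction: float) -> pd.DataFrame:
    """Multiply one capacity rate by (1 + fraction) in every row."""
    if service not in SERVICE_COLUMNS:
        raise ValueError(
            f"unknown service {service!r}; expected one of {sorted(SERVICE_COLUMNS)}"
        )
    out = rows.copy()
    out[SERVICE_COLUMNS[service]] = out[SERVICE_COLUMNS[service]] * (1.0 + fraction)
    return out


def baseline_health_averages(baseline: pd.DataFrame) -> dict[str, float]:
    """Unweighted per-variable means over regions in the baseline year."""
    if "year" not in baseline.columns:
        baseline = baseline.assign(year=baseline["month"].map(month_year))
    last = baseline[baseline["year"] == baseline["year"].max()]
    per_region = last.groupby("region_id")[list(HEALTH_INDEX_COLUMNS)].first()
    return {c: float(per_region[c].mean()) for c in HEALTH_INDEX_COLUMNS}


def apply_health_ramp(
    rows: pd.DataFrame,
    baseline_averages: dict[str, float],
    step: float,
    baseline_year: int,
) -> pd.DataFrame:
    """Raise below-average health indices by `step` per year, capped at average.

    For a region whose baseline value v is below the average a, the value in
    future year (baseline_year + k) is min(v + k*step, a).  Regions at or
    above the average are untouched.
    """
    out = rows.copy()
    k = out["year"].to_numpy(int) - baseline_year
    for col in HEALTH_INDEX_COLUMNS:
        avg = baseline_averages[col]
        v = out[col].to_numpy(float)
        below = v < avg
        ramped = np.minimum(v + k * step, avg)
        out[col] = np.where(below, ramped, v)
    return out


def rolling_mean(series, window: int = 4) -> np.ndarray:
    """Trailing mean over each window of `window` consecutive values."""
    x = np.asarray(series, float)
    if len(x) < window:
        raise ValueError(f"series shorter than window ({len(x)} < {window})")
    kernel = np.full(window, 1.0 / window)
    return np.convolve(x, kernel, mode="valid")


def forecast_scenario(
    model: StackedRegression,
    baseline: pd.DataFrame,
    projections: pd.DataFrame,
    spec: ScenarioSpec,
) -> ForecastSeries:
    """Predict the cross-region mean monthly rate over the horizon.

    The series starts with the observed baseline-year means and continues
    with model predictions on the transformed future panel.
    """
    if "year" not in baseline.columns:
        baseline = baseline.assign(year=baseline["month"].map(month_year))
    base_year = int(baseline["year"].max())
    base = baseline[baseline["year"] == base_year]
    future = build_future_panel(baseline, projections, spec.horizon_years)

    if spec.name == "uplift_111":
        future = apply_uplift(future, "111", spec.uplift_fraction)
    elif spec.name == "uplift_gp":
        future = apply_uplift(future, "gp", spec.uplift_fraction)
    elif spec.name == "uplift_ambulance":
        future = apply_uplift(future, "ambulance", spec.uplift_fraction)
    elif spec.name == "health_ramp":
        future = apply_health_ramp(
            future, baseline_health_averages(baseline), spec.ramp_step, base_year
        )

    pred = model.predict(future)
    fut = (
        future.assign(_pred=pred).groupby("month")["_pred"].mean().sort_index()
    )
    obs = base.groupby("month")[TARGET_COLUMN].mean().sort_index()
    months = list(obs.index) + list(fut.index)
    values = [float(v) for v in obs.to_numpy()] + [float(v) for v in fut.to_numpy()]
    series = ForecastSeries(
        scenario=spec.name,
        months=months,
        values=values,
        n_baseline=len(obs),
    )
    series.rolling = [float(v) for v in rolling_mean(values, 4)]
    return series
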