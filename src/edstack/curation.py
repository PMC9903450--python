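"""Curation of raw multi-source service records into a region-month panel.

The pipeline turns provider-level attendance counts, contract-level call
counts, per-region GP appointment counts and an annual region registry into a
single table with one row per region per month, rates scaled per 10,000
people, and no missing values.  Every removal is accounted for in a
:class:`CurationLog`.

Processing order
----------------
1. aggregate provider counts to region-month attendance totals;
2. drop regions whose attendance series does not cover every study month;
3. aggregate merger groups (counts and populations summed, unit-free indices
   combined as population-weighted means);
4. apportion contract-level counts to regions by population share;
5. scale counts to rates per 10,000 people, attach annual covariates;
6. remove incomplete rows, attributing each to the first missing variable in
   a fixed order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from edstack.months import month_year

#: Panel covariate columns, in canonical order.
CAPACITY_COLUMNS = ["gp_capacity", "capacity_111", "ambulance_capacity"]
HEALTH_COLUMNS = [
    "population_scaled",
    "pct_over_65",
    "people_index",
    "places_index",
    "lives_index",
]
ALL_COVARIATES = CAPACITY_COLUMNS + HEALTH_COLUMNS
TARGET_COLUMN = "ed_attendances"

#: Missing-row attribution: a row missing several variables is charged to the
#: first group in this order that has a gap.
MISSING_ATTRIBUTION_ORDER: list[tuple[str, list[str]]] = [
    ("health_index", ["people_index", "places_index", "lives_index"]),
    ("capacity_111", ["capacity_111"]),
    ("ambulance_capacity", ["ambulance_capacity"]),
    ("gp_capacity", ["gp_capacity"]),
    ("ed_attendances", ["ed_attendances"]),
    ("population", ["population_scaled", "pct_over_65"]),
]


@dataclass
class CurationLog:
    """Accounting of what curation kept and removed."""

    n_regions_initial: int
    n_regions_dropped: int
    n_potential_records: int
    n_dropped_by_variable: dict[str, int]
    n_final_records: int
    dropped_regions: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if self.n_final_records != self.n_potential_records - sum(
            self.n_dropped_by_variable.values()
        ):
            raise AssertionError("curation log accounting identity violated")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "CurationLog":
        return cls(**json.loads(Path(path).read_text()))


class RegionRegistry:
    """Annual per-region figures: populations, over-65 counts, health indices.

    Backed by the ``regions.csv`` frame (region_id, year, population,
    population_over_65, people, places, lives, merger_group).
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"region_id", "year", "population", "population_over_65"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"region registry missing columns: {sorted(missing)}")
        frame = frame.copy()
        frame["region_id"] = frame["region_id"].astype(str)
        frame["year"] = frame["year"].astype(int)
        bad = frame["population_over_65"] > frame["population"]
        if bad.any():
            raise ValueError("population_over_65 exceeds population for some rows")
        if "merger_group" not in frame.columns:
            frame["merger_group"] = ""
        frame["merger_group"] = frame["merger_group"].fillna("").astype(str)
        groups = frame.groupby("region_id")["merger_group"].nunique()
        if (groups > 1).any():
            raise ValueError(
                "conflicting merger groups for regions: "
                f"{sorted(groups.index[groups > 1])}"
            )
        self.frame = frame
        self._pop = {
            (r, y): float(p)
            for r, y, p in zip(frame["region_id"], frame["year"], frame["population"])
        }

    @property
    def region_ids(self) -> list[str]:
        return sorted(self.frame["region_id"].unique())

    def population(self, region_id: str, year: int) -> float:
        try:
            return self._pop[(str(region_id), int(year))]
        except KeyError:
            raise KeyError(f"no population for region {region_id!r}, year {year}")

    def merger_map(self) -> dict[str, str]:
        """region_id -> merged identifier (merger_group, or itself if ungrouped)."""
        out: dict[str, str] = {}
        for region_id, group in (
            self.frame.groupby("region_id")["merger_group"].first().items()
        ):
            out[str(region_id)] = group if group else str(region_id)
        return out

    def merged(self) -> "RegionRegistry":
        """Aggregate merger groups: sum populations, population-weight the indices."""
        frame = self.frame.copy()
        mapping = self.merger_map()
        frame["merged_id"] = frame["region_id"].map(mapping)

        def _combine(group: pd.DataFrame) -> pd.Series:
            pop = group["population"].to_numpy(float)
            out = {
                "population": pop.sum(),
                "population_over_65": group["population_over_65"].sum(),
                "merger_group": "",
            }
            for col in ("people", "places", "lives"):
                if col in group:
                    vals = group[col].to_numpy(float)
                    if np.isnan(vals).any():
                        out[col] = np.nan  # any missing member poisons the merge
                    else:
                        out[col] = float(np.average(vals, weights=pop))
            return pd.Series(out)

        merged = (
            frame.groupby(["merged_id", "year"])
            .apply(_combine, include_groups=False)
            .reset_index()
            .rename(columns={"merged_id": "region_id"})
        )
        return RegionRegistry(merged)


def aggregate_providers(
    counts: pd.DataFrame, mapping: Mapping[str, str]
) -> pd.DataFrame:
    """Sum provider-month counts to region-month totals.

    `counts` needs columns (provider_id, month, count); every provider_id must
    appear in `mapping` (provider -> region), else KeyError naming the culprit.
    """
    counts = counts.copy()
    counts["provider_id"] = counts["provider_id"].astype(str)
    unmapped = set(counts["provider_id"]) - set(map(str, mapping))
    if unmapped:
        raise KeyError(f"providers not in region mapping: {sorted(unmapped)}")
    counts["region_id"] = counts["provider_id"].map(
        {str(k): str(v) for k, v in mapping.items()}
    )
    return (
        counts.groupby(["region_id", "month"], as_index=False)["count"]
        .sum()
        .sort_values(["region_id", "month"], ignore_index=True)
    )


def stratify_by_population(
    counts: pd.DataFrame,
    mapping: Mapping[str, list[str]],
    registry: RegionRegistry,
) -> pd.DataFrame:
    """Apportion contract-month counts to member regions by population share.

    The population used is that of the calendar year of the record's month.
    Allocations over a contract sum to the contract count.
    """
    rows = []
    for rec in counts.itertuples(index=False):
        contract = str(rec.contract_id)
        regions = [str(r) for r in mapping.get(contract, [])]
        if not regions:
            raise ValueError(f"contract {contract!r} has an empty region set")
        year = month_year(rec.month)
        pops = np.array([registry.population(r, year) for r in regions], float)
        total = pops.sum()
        if total <= 0:
            raise ValueError(f"zero total population for contract {contract!r}")
        for region, pop in zip(regions, pops):
            rows.append((region, rec.month, float(rec.count) * pop / total))
    out = pd.DataFrame(rows, columns=["region_id", "month", "count"])
    return (
        out.groupby(["region_id", "month"], as_index=False)["count"]
        .sum()
        .sort_values(["region_id", "month"], ignore_index=True)
    )


def scale_per_10k(raw_value: float, population: float) -> float:
    """Rate per 10,000 people. Population must be positive."""
    if population <= 0:
        raise ValueError(f"population must be positive, got {population}")
    return raw_value * 10_000.0 / population


def derive_pct_over_65(registry: RegionRegistry, region_id: str, year: int) -> float:
    """100 * population_over_65 / population for one region-year."""
    frame = registry.frame
    sel = frame[(frame["region_id"] == str(region_id)) & (frame["year"] == int(year))]
    if sel.empty:
        raise KeyError(f"no registry row for region {region_id!r}, year {year}")
    row = sel.iloc[0]
    return 100.0 * float(row["population_over_65"]) / float(row["population"])


def merge_regions(counts: pd.DataFrame, registry: RegionRegistry) -> pd.DataFrame:
    """Re-label region-month counts by merger group and sum within groups."""
    mapping = registry.merger_map()
    out = counts.copy()
    out["region_id"] = out["region_id"].astype(str).map(mapping)
    return (
        out.groupby(["region_id", "month"], as_index=False)["count"]
        .sum()
        .sort_values(["region_id", "month"], ignore_index=True)
    )


def drop_missing(panel: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Remove rows with any missing variable; count drops per attribution group.

    Returns (complete rows, {group: n_dropped}).  A row missing several
    variables is counted once, under the first group in
    :data:`MISSING_ATTRIBUTION_ORDER` with a gap.
    """
    dropped = {name: 0 for name, _ in MISSING_ATTRIBUTION_ORDER}
    charged = np.zeros(len(panel), dtype=bool)
    for name, cols in MISSING_ATTRIBUTION_ORDER:
        present = [c for c in cols if c in panel.columns]
        if not present:
            continue
        gap = panel[present].isna().any(axis=1).to_numpy() & ~charged
        dropped[name] = int(gap.sum())
        charged |= gap
    keep = panel.loc[~charged].reset_index(drop=True)
    return keep, {k: v for k, v in dropped.items() if v}


def annual_mean_target(panel: pd.DataFrame) -> pd.DataFrame:
    """Mean monthly attendance rate per (region, year) over surviving months."""
    if "year" not in panel.columns:
        panel = panel.assign(year=panel["month"].map(month_year))
    return (
        panel.groupby(["region_id", "year"], as_index=False)[TARGET_COLUMN]
        .mean()
        .sort_values(["region_id", "year"], ignore_index=True)
    )


def annual_frame(panel: pd.DataFrame) -> pd.DataFrame:
    """One row per region-year: annual covariates plus the mean monthly target.

    Annual covariates are constant within a region-year by construction; the
    first observed value is taken.
    """
    if "year" not in panel.columns:
        panel = panel.assign(year=panel["month"].map(month_year))
    agg = {col: "first" for col in HEALTH_COLUMNS}
    agg[TARGET_COLUMN] = "mean"
    return (
        panel.groupby(["region_id", "year"], as_index=False)
        .agg(agg)
        .sort_values(["region_id", "year"], ignore_index=True)
    )


def _region_month_lookup(counts: pd.DataFrame) -> pd.Series:
    return counts.set_index(["region_id", "month"])["count"]


def curate_frames(
    providers: pd.DataFrame,
    contracts: pd.DataFrame,
    contract_map: pd.DataFrame,
    gp: pd.DataFrame,
    regions: pd.DataFrame,
    months: list[str] | None = None,
) -> tuple[pd.DataFrame, CurationLog]:
    """Run the full curation pipeline on in-memory raw frames.

    Returns the curated panel (one complete RegionMonthRecord per row) and the
    curation log. `months` defaults to the sorted union of months observed in
    the provider and GP files.
    """
    registry = RegionRegistry(regions)
    providers = providers.copy()
    providers["region_id"] = providers["region_id"].astype(str)

    if months is None:
        months = sorted(set(providers["month"]) | set(gp["month"]))
    if not months:
        raise ValueError("no study months found in the input files")

    provider_map = dict(
        zip(providers["provider_id"].astype(str), providers["region_id"])
    )
    ed = aggregate_providers(
        providers[["provider_id", "month", "count"]], provider_map
    )

    # Regions with incomplete attendance coverage are removed outright and do
    # not contribute potential records.
    ed_cov = ed.dropna(subset=["count"]).groupby("region_id")["month"].nunique()
    complete = set(ed_cov.index[ed_cov == len(months)])
    initial = registry.region_ids
    dropped_regions = sorted(set(initial) - complete)
    ed = ed[ed["region_id"].isin(complete)].reset_index(drop=True)

    keep_frame = registry.frame[registry.frame["region_id"].isin(complete)]
    registry = RegionRegistry(keep_frame.reset_index(drop=True))

    # Merger groups: aggregate counts and the registry before any scaling.
    merge_map = registry.merger_map()
    ed = merge_regions(ed, registry)
    gp_counts = gp.copy()
    gp_counts["region_id"] = gp_counts["region_id"].astype(str)
    gp_counts = gp_counts[gp_counts["region_id"].isin(complete)]
    gp_counts = merge_regions(gp_counts[["region_id", "month", "count"]], registry)
    merged_registry = registry.merged()

    # Stratification uses every region a contract covers — including regions
    # later dropped for incomplete attendance data — so retained regions are
    # not over-allocated; dropped regions' allocations are then discarded.
    full_registry = RegionRegistry(regions)
    full_merge_map = full_registry.merger_map()
    full_merged = full_registry.merged()
    retained = {full_merge_map[r] for r in complete}
    cmap: dict[str, list[str]] = {}
    for rec in contract_map.itertuples(index=False):
        region = str(rec.region_id)
        if region not in full_merge_map:
            continue
        cmap.setdefault(str(rec.contract_id), []).append(full_merge_map[region])
    for contract, members in cmap.items():
        cmap[contract] = sorted(set(members))

    by_service = {}
    for service in ("111", "ambulance"):
        sub = contracts[contracts["service"].astype(str) == service]
        sub = sub[[c for c in ("contract_id", "month", "count") if c in sub.columns]]
        sub = sub[sub["contract_id"].astype(str).isin(cmap)]
        if sub.empty:
            by_service[service] = pd.DataFrame(
                columns=["region_id", "month", "count"]
            )
        else:
            alloc = stratify_by_population(sub, cmap, full_merged)
            by_service[service] = alloc[alloc["region_id"].isin(retained)]

    region_ids = merged_registry.region_ids
    grid = pd.MultiIndex.from_product(
        [region_ids, months], names=["region_id", "month"]
    )
    panel = pd.DataFrame(index=grid).reset_index()
    panel["year"] = panel["month"].map(month_year)

    lookups = {
        TARGET_COLUMN: _region_month_lookup(ed),
        "gp_capacity": _region_month_lookup(gp_counts),
        "capacity_111": _region_month_lookup(by_service["111"]),
        "ambulance_capacity": _region_month_lookup(by_service["ambulance"]),
    }
    key = pd.MultiIndex.from_frame(panel[["region_id", "month"]])
    for col, series in lookups.items():
        panel[col] = series.reindex(key).to_numpy()

    reg = merged_registry.frame.set_index(["region_id", "year"])
    ry = pd.MultiIndex.from_frame(panel[["region_id", "year"]])
    pop = reg["population"].reindex(ry).to_numpy(float)
    over65 = reg["population_over_65"].reindex(ry).to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        for col in (TARGET_COLUMN, "gp_capacity", "capacity_111", "ambulance_capacity"):
            panel[col] = panel[col].to_numpy(float) * 10_000.0 / pop
        panel["population_scaled"] = pop / 10_000.0
        panel["pct_over_65"] = 100.0 * over65 / pop
    for col, src in (
        ("people_index", "people"),
        ("places_index", "places"),
        ("lives_index", "lives"),
    ):
        panel[col] = (
            reg[src].reindex(ry).to_numpy(float) if src in reg.columns else np.nan
        )

    n_potential = len(region_ids) * len(months)
    kept, drops = drop_missing(panel)
    log = CurationLog(
        n_regions_initial=len(initial),
        n_regions_dropped=len(dropped_regions),
        n_potential_records=n_potential,
        n_dropped_by_variable=drops,
        n_final_records=len(kept),
        dropped_regions=dropped_regions,
    )
    log.validate()
    order = ["region_id", "month", "year", TARGET_COLUMN] + ALL_COVARIATES
    return kept[order], log


def read_input_dir(path: str | Path) -> dict[str, pd.DataFrame]:
    """Read the five raw CSVs from a directory into frames keyed by stem."""
    path = Path(path)
    out = {}
    for name in ("providers", "contracts", "contract_map", "gp", "regions"):
        f = path / f"{name}.csv"
        if not f.exists():
            raise FileNotFoundError(f"missing input file: {f}")
        out[name] = pd.read_csv(f, dtype={"month": str})
    return out


def curate_dir(path: str | Path) -> tuple[pd.DataFrame, CurationLog]:
    """Curate the raw CSVs found in `path` (see :func:`read_input_dir`)."""
    raw = read_input_dir(path)
    return curate_frames(
        raw["providers"], raw["contracts"], raw["contract_map"], raw["gp"],
        raw["regions"],
    )
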