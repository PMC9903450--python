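"""Seeded generator for raw multi-source inputs with known ground truth.

The latent monthly attendance rate for region r in month m is

    y = w_h * f_h(r, year)  +  w_c * f_c(r, m)  +  seasonal(m)  +  eps

    f_h = 140 + 2.2*pop_scaled + 2.5*(pct65 - 19) + 1.5*(100 - lives)
          + 0.8*(100 - people) + 0.4*(100 - places)
          + 0.01*pop_scaled*(100 - lives)
    f_c = 0.02*gp + 0.25*c111 + 0.30*amb + 40*tanh(amb/500)
    seasonal(m) = amplitude * cos(2*pi*(calendar_month(m) - 1)/12)   # Jan peak
    eps ~ Normal(0, noise_sd)

so attendances fall as the health indices improve and rise with service
capacity.  Health covariates are constant within a region-year; capacity
covariates vary month to month.  The dominant driver by variance contribution
is population.

File-level conventions
----------------------
* Missing records are represented by *absent rows* in the emitted CSVs.
* 111 contracts are one-per-region (so region-month missingness is exact);
  ambulance contracts span ``ambulance_contract_size`` regions, exercising
  population-share apportionment.  Ambulance missingness therefore comes in
  whole contract-months, and health-index missingness in whole region-years
  (multiples of 12 panel rows).
* Seeding is hierarchical (numpy ``SeedSequence.spawn``): each region's
  level draws precede its monthly innovations, so changing ``n_months`` does
  not reshuffle region-level draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from edstack.months import calendar_month, month_range, month_year

#: The generator covariate whose variance contribution to y is largest.
DOMINANT_DRIVER = "population_scaled"
MONTHS_PER_YEAR = 12


@dataclass
class GeneratorConfig:
    n_regions: int = 76
    n_months: int = 24
    start_month: str = "2018-01"
    seed: int = 0
    capacity_weight: float = 0.4
    health_weight: float = 0.6
    noise_sd: float = 8.0
    seasonal_amplitude: float = 5.0
    missing_counts: dict[str, int] = field(default_factory=dict)
    population_range: tuple[float, float] = (150_000.0, 1_500_000.0)
    index_sd: float = 5.0
    pct_over_65_mean: float = 19.0
    pct_over_65_sd: float = 4.0
    gp_rate_mean: float = 4382.0
    gp_rate_sd: float = 786.0
    rate_111_mean: float = 354.0
    rate_111_sd: float = 176.0
    ambulance_rate_mean: float = 352.0
    ambulance_rate_sd: float = 286.0
    base_sd_scale: float = 0.4
    monthly_sd_scale: float = 0.95
    ambulance_contract_size: int = 4
    n_incomplete_regions: int = 0
    incomplete_months: int = 3

    def validate(self) -> None:
        if self.n_regions < 1 or self.n_months < 1:
            raise ValueError("n_regions and n_months must be >= 1")
        if min(self.capacity_weight, self.health_weight) < 0:
            raise ValueError("effect weights must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        cells = self.n_regions * self.n_months
        for var, n in self.missing_counts.items():
            if n < 0 or n > cells:
                raise ValueError(f"infeasible missing count for {var!r}: {n}")
        if self.missing_counts.get("health_index", 0) % MONTHS_PER_YEAR:
            raise ValueError(
                "health_index missing count must be a multiple of 12 "
                "(indices are blanked per region-year)"
            )
        amb = self.missing_counts.get("ambulance_capacity", 0)
        if amb % self.ambulance_contract_size:
            raise ValueError(
                "ambulance_capacity missing count must be a multiple of the "
                "contract size (rows are blanked per contract-month)"
            )
        if self.n_incomplete_regions >= self.n_regions:
            raise ValueError("n_incomplete_regions must leave at least one region")


def health_component(
    pop_scaled: np.ndarray,
    pct_over_65: np.ndarray,
    people: np.ndarray,
    places: np.ndarray,
    lives: np.ndarray,
) -> np.ndarray:
    return (
        140.0
        + 2.2 * pop_scaled
        + 2.5 * (pct_over_65 - 19.0)
        + 1.5 * (100.0 - lives)
        + 0.8 * (100.0 - people)
        + 0.4 * (100.0 - places)
        + 0.01 * pop_scaled * (100.0 - lives)
    )


def capacity_component(
    gp: np.ndarray, c111: np.ndarray, amb: np.ndarray
) -> np.ndarray:
    return 0.02 * gp + 0.25 * c111 + 0.30 * amb + 40.0 * np.tanh(amb / 500.0)


def seasonal_term(month_label: str, amplitude: float) -> float:
    m = calendar_month(month_label)
    return amplitude * np.cos(2.0 * np.pi * (m - 1) / 12.0)


@dataclass
class GroundTruth:
    """Row-aligned latent components for the generated panel."""

    frame: pd.DataFrame  # region_id, month + rates, components, noise, latent_rate
    capacity_weight: float
    health_weight: float
    dominant_driver: str = DOMINANT_DRIVER


def _region_level_draws(cfg: GeneratorConfig, rng: np.random.Generator, years):
    """Per-region annual covariates and capacity base rates (one region)."""
    lo, hi = cfg.population_range
    pop0 = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    over65_frac = float(np.clip(
        rng.normal(cfg.pct_over_65_mean / 100.0, cfg.pct_over_65_sd / 100.0),
        0.05, 0.45,
    ))
    base = {
        "people": float(rng.normal(100.0, cfg.index_sd)),
        "places": float(rng.normal(100.0, cfg.index_sd)),
        "lives": float(rng.normal(100.0, cfg.index_sd)),
    }
    gp_base = max(float(rng.normal(cfg.gp_rate_mean, cfg.base_sd_scale * cfg.gp_rate_sd)), 50.0)
    r111_base = max(
        float(rng.normal(cfg.rate_111_mean, cfg.base_sd_scale * cfg.rate_111_sd)), 5.0
    )
    annual = {}
    pop = pop0
    for year in years:
        annual[year] = {
            "population": pop,
            "population_over_65": over65_frac * pop,
            "people": base["people"] + float(rng.normal(0.0, 0.5)),
            "places": base["places"] + float(rng.normal(0.0, 0.5)),
            "lives": base["lives"] + float(rng.normal(0.0, 0.5)),
        }
        pop *= 1.0 + float(rng.normal(0.01, 0.004))
    return annual, gp_base, r111_base


def generate(cfg: GeneratorConfig) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Generate the raw curation-schema frames plus row-aligned ground truth.

    Returns ``(frames, truth)`` where frames holds providers, contracts,
    contract_map, gp, regions and projections tables.
    """
    cfg.validate()
    months = month_range(cfg.start_month, cfg.n_months)
    years = sorted({month_year(m) for m in months})
    region_ids = [f"R{i:03d}" for i in range(cfg.n_regions)]

    root = np.random.SeedSequence(cfg.seed)
    region_ss, global_ss = root.spawn(cfg.n_regions), root.spawn(2)[1]
    grng = np.random.default_rng(global_ss)

    n_contracts = -(-cfg.n_regions // cfg.ambulance_contract_size)
    amb_contracts = {
        f"AMB{c:02d}": region_ids[
            c * cfg.ambulance_contract_size : (c + 1) * cfg.ambulance_contract_size
        ]
        for c in range(n_contracts)
    }
    amb_of_region = {
        r: cid for cid, members in amb_contracts.items() for r in members
    }
    amb_rng = np.random.default_rng(root.spawn(3)[2])
    amb_base = {
        cid: max(
            float(amb_rng.normal(cfg.ambulance_rate_mean, cfg.base_sd_scale * cfg.ambulance_rate_sd)),
            20.0,
        )
        for cid in amb_contracts
    }
    amb_monthly = {
        cid: amb_rng.normal(
            0.0, cfg.monthly_sd_scale * cfg.ambulance_rate_sd, cfg.n_months
        )
        for cid in amb_contracts
    }

    region_rows, truth_rows, reg_rows = [], [], []
    annual_by_region: dict[str, dict] = {}
    for rid, ss in zip(region_ids, region_ss):
        rng = np.random.default_rng(ss)
        annual, gp_base, r111_base = _region_level_draws(cfg, rng, years)
        annual_by_region[rid] = annual
        n_providers = int(rng.integers(1, 4))
        shares = rng.dirichlet(np.ones(n_providers))
        gp_innov = rng.normal(0.0, cfg.monthly_sd_scale * cfg.gp_rate_sd, cfg.n_months)
        r111_innov = rng.normal(
            0.0, cfg.monthly_sd_scale * cfg.rate_111_sd, cfg.n_months
        )
        noise = rng.normal(0.0, cfg.noise_sd, cfg.n_months) if cfg.noise_sd else (
            np.zeros(cfg.n_months)
        )
        for year in years:
            a = annual[year]
            reg_rows.append(
                {
                    "region_id": rid,
                    "year": year,
                    "population": a["population"],
                    "population_over_65": a["population_over_65"],
                    "people": a["people"],
                    "places": a["places"],
                    "lives": a["lives"],
                    "merger_group": "",
                }
            )
        for k, month in enumerate(months):
            a = annual[month_year(month)]
            pop = a["population"]
            pop_scaled = pop / 10_000.0
            pct65 = 100.0 * a["population_over_65"] / pop
            gp_rate = max(gp_base + gp_innov[k], 10.0)
            # every region in an ambulance contract inherits the contract rate
            cid = amb_of_region[rid]
            amb_rate = max(amb_base[cid] + amb_monthly[cid][k], 5.0)
            r111 = max(r111_base + r111_innov[k], 2.0)
            f_h = float(
                health_component(
                    np.asarray(pop_scaled), np.asarray(pct65),
                    np.asarray(a["people"]), np.asarray(a["places"]),
                    np.asarray(a["lives"]),
                )
            )
            f_c = float(capacity_component(
                np.asarray(gp_rate), np.asarray(r111), np.asarray(amb_rate)
            ))
            seas = float(seasonal_term(month, cfg.seasonal_amplitude))
            y = cfg.health_weight * f_h + cfg.capacity_weight * f_c + seas + noise[k]
            y = max(y, 1.0)
            region_rows.append(
                {
                    "region_id": rid,
                    "month": month,
                    "gp_rate": gp_rate,
                    "rate_111": r111,
                    "amb_rate": amb_rate,
                    "population": pop,
                    "latent_rate": y,
                    "n_providers": n_providers,
                    "shares": shares,
                    "contract_amb": cid,
                }
            )
            truth_rows.append(
                {
                    "region_id": rid,
                    "month": month,
                    "gp_capacity": gp_rate,
                    "capacity_111": r111,
                    "ambulance_capacity": amb_rate,
                    "population_scaled": pop_scaled,
                    "pct_over_65": pct65,
                    "people_index": a["people"],
                    "places_index": a["places"],
                    "lives_index": a["lives"],
                    "capacity_component": f_c,
                    "health_component": f_h,
                    "seasonal": seas,
                    "noise": float(noise[k]),
                    "latent_rate": y,
                }
            )

    cells = pd.DataFrame(region_rows)
    truth = GroundTruth(
        frame=pd.DataFrame(truth_rows),
        capacity_weight=cfg.capacity_weight,
        health_weight=cfg.health_weight,
    )

    # ---- choose missingness victims (disjoint across variables) ----------
    incomplete = list(
        grng.choice(region_ids, size=cfg.n_incomplete_regions, replace=False)
    )
    eligible = [r for r in region_ids if r not in incomplete]

    blanked_ry: set[tuple[str, int]] = set()
    n_health = cfg.missing_counts.get("health_index", 0)
    if n_health:
        all_ry = [(r, y) for r in eligible for y in years]
        idx = grng.choice(len(all_ry), size=n_health // MONTHS_PER_YEAR, replace=False)
        blanked_ry = {all_ry[i] for i in sorted(idx)}

    def _pick_cells(n: int, taken: set[tuple[str, str]]) -> set[tuple[str, str]]:
        avail = [
            (r, m)
            for r in eligible
            for m in months
            if (r, month_year(m)) not in blanked_ry and (r, m) not in taken
        ]
        if n > len(avail):
            raise ValueError("infeasible missing counts: not enough eligible cells")
        idx = grng.choice(len(avail), size=n, replace=False)
        return {avail[i] for i in sorted(idx)}

    taken: set[tuple[str, str]] = set()
    miss_111 = _pick_cells(cfg.missing_counts.get("capacity_111", 0), taken)
    taken |= miss_111
    miss_gp = _pick_cells(cfg.missing_counts.get("gp_capacity", 0), taken)
    taken |= miss_gp

    n_amb = cfg.missing_counts.get("ambulance_capacity", 0)
    miss_amb_cm: set[tuple[str, str]] = set()
    if n_amb:
        cm = [
            (cid, m)
            for cid, members in amb_contracts.items()
            for m in months
            if all(
                r in eligible
                and (r, month_year(m)) not in blanked_ry
                and (r, m) not in taken
                for r in members
            )
        ]
        need = n_amb // cfg.ambulance_contract_size
        if need > len(cm):
            raise ValueError("infeasible ambulance missing count")
        idx = grng.choice(len(cm), size=need, replace=False)
        miss_amb_cm = {cm[i] for i in sorted(idx)}

    # ---- emit raw files ---------------------------------------------------
    prov_rows = []
    for rec in cells.itertuples(index=False):
        if rec.region_id in incomplete and months.index(rec.month) < cfg.incomplete_months:
            continue  # incomplete-attendance region: early months absent
        raw_total = rec.latent_rate * rec.population / 10_000.0
        for p in range(rec.n_providers):
            prov_rows.append(
                {
                    "provider_id": f"{rec.region_id}-P{p}",
                    "region_id": rec.region_id,
                    "month": rec.month,
                    "count": raw_total * rec.shares[p],
                }
            )
    providers = pd.DataFrame(prov_rows)

    gp_rows = [
        {
            "region_id": rec.region_id,
            "month": rec.month,
            "count": rec.gp_rate * rec.population / 10_000.0,
        }
        for rec in cells.itertuples(index=False)
        if (rec.region_id, rec.month) not in miss_gp
    ]
    gp = pd.DataFrame(gp_rows)

    contract_rows, map_rows = [], []
    for rec in cells.itertuples(index=False):
        if (rec.region_id, rec.month) in miss_111:
            continue
        contract_rows.append(
            {
                "contract_id": f"C111-{rec.region_id}",
                "month": rec.month,
                "count": rec.rate_111 * rec.population / 10_000.0,
                "service": "111",
            }
        )
    for rid in region_ids:
        map_rows.append({"contract_id": f"C111-{rid}", "region_id": rid})
    for cid, members in amb_contracts.items():
        for rid in members:
            map_rows.append({"contract_id": cid, "region_id": rid})
        for k, month in enumerate(months):
            if (cid, month) in miss_amb_cm:
                continue
            year = month_year(month)
            total_pop = sum(
                annual_by_region[r][year]["population"] for r in members
            )
            rate = max(amb_base[cid] + amb_monthly[cid][k], 5.0)
            contract_rows.append(
                {
                    "contract_id": cid,
                    "month": month,
                    "count": rate * total_pop / 10_000.0,
                    "service": "ambulance",
                }
            )
    contracts = pd.DataFrame(contract_rows)
    contract_map = pd.DataFrame(map_rows)

    regions = pd.DataFrame(reg_rows)
    if blanked_ry:
        mask = regions.apply(
            lambda r: (r["region_id"], r["year"]) in blanked_ry, axis=1
        )
        regions.loc[mask, ["people", "places", "lives"]] = np.nan

    # population projections beyond the study window, for scenario forecasting
    proj_rows = []
    last_year = years[-1]
    for rid in region_ids:
        a = annual_by_region[rid][last_year]
        pop, o65 = a["population"], a["population_over_65"]
        for k in range(1, 11):
            pop, o65 = pop * 1.01, o65 * 1.015
            proj_rows.append(
                {
                    "region_id": rid,
                    "year": last_year + k,
                    "population": pop,
                    "population_over_65": min(o65, 0.45 * pop),
                }
            )
    projections = pd.DataFrame(proj_rows)

    frames = {
        "providers": providers,
        "contracts": contracts,
        "contract_map": contract_map,
        "gp": gp,
        "regions": regions,
        "projections": projections,
    }
    return frames, truth


def write_frames(
    frames: dict[str, pd.DataFrame], out_dir: str | Path, truth: GroundTruth | None = None
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, frame in frames.items():
        frame.to_csv(out / f"{name}.csv", index=False)
    if truth is not None:
        truth.frame.to_csv(out / "ground_truth.csv", index=False)


def generate_panel(cfg: GeneratorConfig):
    """Generate raw inputs and run curation; returns (panel, log, truth, frames)."""
    from edstack.curation import curate_frames

    frames, truth = generate(cfg)
    panel, log = curate_frames(
        frames["providers"], frames["contracts"], frames["contract_map"],
        frames["gp"], frames["regions"],
    )
    return panel, log, truth, frames


def reference_fixture(seed: int = 0) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Raw inputs shaped like the real study's accounting.

    81 regions of which 5 have incomplete attendance data; 24 months; 48 rows
    blanked on the health indices and 158 on 111 capacity (disjoint), so
    curation yields 1824 potential and 1618 final records over 76 regions.
    """
    cfg = GeneratorConfig(
        n_regions=81,
        n_months=24,
        seed=seed,
        n_incomplete_regions=5,
        missing_counts={"health_index": 48, "capacity_111": 158},
    )
    return generate(cfg)
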