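import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edstack.curation import (
    CurationLog,
    RegionRegistry,
    aggregate_providers,
    annual_mean_target,
    curate_frames,
    derive_pct_over_65,
    drop_missing,
    merge_regions,
    scale_per_10k,
    stratify_by_population,
)


def _counts(rows):
    return pd.DataFrame(rows, columns=["provider_id", "month", "count"])


class TestAggregateProviders:
    def test_two_providers_one_region(self):
        out = aggregate_providers(
            _counts([("p1", "2018-01", 100), ("p2", "2018-01", 200)]),
            {"p1": "A", "p2": "A"},
        )
        assert out.loc[0, "count"] == 300

    def test_zero_count(self):
        out = aggregate_providers(_counts([("p1", "2018-01", 0)]), {"p1": "A"})
        assert out.loc[0, "count"] == 0

    def test_unmapped_provider_is_hard_error(self):
        with pytest.raises(KeyError, match="p2"):
            aggregate_providers(_counts([("p2", "2018-01", 5)]), {"p1": "A"})

    def test_matches_brute_force_grouping(self):
        rng = np.random.default_rng(42)
        providers = [f"p{i}" for i in range(10)]
        mapping = {p: f"R{rng.integers(3)}" for p in providers}
        rows = [
            (p, m, int(rng.integers(0, 1000)))
            for p in providers
            for m in ("2018-01", "2018-02")
        ]
        out = aggregate_providers(_counts(rows), mapping)
        # independent brute-force oracle
        expect = {}
        for p, m, c in rows:
            expect[(mapping[p], m)] = expect.get((mapping[p], m), 0) + c
        for rec in out.itertuples(index=False):
            assert rec.count == expect[(rec.region_id, rec.month)]
        assert out["count"].sum() == sum(c for _, _, c in rows)


class TestStratifyByPopulation:
    def test_proportional_allocation(self, tiny_registry):
        counts = pd.DataFrame(
            [("c1", "2018-03", 300)], columns=["contract_id", "month", "count"]
        )
        # populations 100k / 300k / 50k -> shares 2/9, 6/9, 1/9
        out = stratify_by_population(
            counts, {"c1": ["A", "B", "C"]}, tiny_registry
        ).set_index("region_id")["count"]
        assert out["A"] == pytest.approx(300 * 100 / 450)
        assert out["B"] == pytest.approx(300 * 300 / 450)
        assert out["C"] == pytest.approx(300 * 50 / 450)

    def test_single_region_identity(self, tiny_registry):
        counts = pd.DataFrame(
            [("c1", "2018-01", 42)], columns=["contract_id", "month", "count"]
        )
        out = stratify_by_population(counts, {"c1": ["B"]}, tiny_registry)
        assert out.loc[0, "count"] == pytest.approx(42)

    def test_empty_region_set_errors(self, tiny_registry):
        counts = pd.DataFrame(
            [("c1", "2018-01", 1)], columns=["contract_id", "month", "count"]
        )
        with pytest.raises(ValueError, match="empty region set"):
            stratify_by_population(counts, {"c1": []}, tiny_registry)

    def test_uses_population_of_record_year(self, tiny_registry):
        c18 = pd.DataFrame(
            [("c1", "2018-06", 100)], columns=["contract_id", "month", "count"]
        )
        c19 = pd.DataFrame(
            [("c1", "2019-06", 100)], columns=["contract_id", "month", "count"]
        )
        m = {"c1": ["A", "B"]}
        a18 = stratify_by_population(c18, m, tiny_registry).set_index("region_id")
        a19 = stratify_by_population(c19, m, tiny_registry).set_index("region_id")
        assert a18.loc["A", "count"] == pytest.approx(100 * 100 / 400)
        assert a19.loc["A", "count"] == pytest.approx(100 * 101 / 404)

    @given(st.data())
    @settings(max_examples=25, deadline=None)
    def test_conservation_random_structures(self, data):
        n_regions = data.draw(st.integers(2, 6))
        regs = [f"R{i}" for i in range(n_regions)]
        registry = RegionRegistry(
            pd.DataFrame(
                {
                    "region_id": regs,
                    "year": [2018] * n_regions,
                    "population": data.draw(
                        st.lists(
                            st.floats(1e3, 1e6), min_size=n_regions,
                            max_size=n_regions,
                        )
                    ),
                    "population_over_65": [100.0] * n_regions,
                }
            )
        )
        contracts = []
        mapping = {}
        for c in range(data.draw(st.integers(1, 4))):
            cid = f"c{c}"
            members = data.draw(
                st.lists(st.sampled_from(regs), min_size=1, unique=True)
            )
            mapping[cid] = members
            contracts.append((cid, "2018-01", data.draw(st.floats(0, 1e6))))
        frame = pd.DataFrame(
            contracts, columns=["contract_id", "month", "count"]
        )
        out = stratify_by_population(frame, mapping, registry)
        total_in = frame["count"].sum()
        total_out = out["count"].sum()
        assert total_out == pytest.approx(total_in, rel=1e-9, abs=1e-9)


class TestScalePer10k:
    def test_arithmetic(self):
        assert scale_per_10k(5000, 250_000) == pytest.approx(200)

    def test_zero_events(self):
        assert scale_per_10k(0, 1234) == 0

    def test_nonpositive_population_errors(self):
        with pytest.raises(ValueError):
            scale_per_10k(1, 0)
        with pytest.raises(ValueError):
            scale_per_10k(1, -5)

    @given(
        raw=st.floats(0, 1e9),
        pop=st.floats(1.0, 1e8),
    )
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, raw, pop):
        rate = scale_per_10k(raw, pop)
        assert rate * pop / 10_000.0 == pytest.approx(raw, rel=1e-9, abs=1e-9)


class TestDerivePctOver65:
    def test_simple_fraction(self, tiny_registry):
        assert derive_pct_over_65(tiny_registry, "A", 2018) == pytest.approx(19.0)

    def test_missing_year_errors(self, tiny_registry):
        with pytest.raises(KeyError):
            derive_pct_over_65(tiny_registry, "A", 2031)

    def test_matches_direct_formula(self, tiny_registry):
        frame = tiny_registry.frame
        for rec in frame.itertuples(index=False):
            got = derive_pct_over_65(tiny_registry, rec.region_id, rec.year)
            assert got == pytest.approx(
                100 * rec.population_over_65 / rec.population
            )

    def test_all_over_65_is_100(self):
        reg = RegionRegistry(
            pd.DataFrame(
                {
                    "region_id": ["A"],
                    "year": [2018],
                    "population": [1000],
                    "population_over_65": [1000],
                }
            )
        )
        assert derive_pct_over_65(reg, "A", 2018) == pytest.approx(100.0)


class TestMergeRegions:
    def _registry(self, merger):
        return RegionRegistry(
            pd.DataFrame(
                {
                    "region_id": ["A", "B"],
                    "year": [2018, 2018],
                    "population": [100_000, 300_000],
                    "population_over_65": [20_000, 50_000],
                    "people": [96.0, 104.0],
                    "places": [100.0, 100.0],
                    "lives": [100.0, 100.0],
                    "merger_group": merger,
                }
            )
        )

    def test_population_weighted_index(self):
        merged = self._registry(["M", "M"]).merged()
        row = merged.frame.iloc[0]
        assert row["people"] == pytest.approx(
            (96 * 100_000 + 104 * 300_000) / 400_000
        )  # = 102
        assert row["population"] == 400_000

    def test_counts_summed(self):
        counts = pd.DataFrame(
            [("A", "2018-01", 400), ("B", "2018-01", 600)],
            columns=["region_id", "month", "count"],
        )
        out = merge_regions(counts, self._registry(["M", "M"]))
        assert len(out) == 1
        assert out.loc[0, "count"] == 1000

    def test_singleton_group_unchanged(self):
        counts = pd.DataFrame(
            [("A", "2018-01", 400), ("B", "2018-01", 600)],
            columns=["region_id", "month", "count"],
        )
        out = merge_regions(counts, self._registry(["", ""]))
        assert sorted(out["count"]) == [400, 600]

    def test_conflicting_merger_definition_errors(self):
        frame = pd.DataFrame(
            {
                "region_id": ["A", "A"],
                "year": [2018, 2019],
                "population": [1, 1],
                "population_over_65": [1, 1],
                "merger_group": ["M1", "M2"],
            }
        )
        with pytest.raises(ValueError, match="conflicting merger"):
            RegionRegistry(frame)


class TestDropMissing:
    def _panel(self, n=10):
        return pd.DataFrame(
            {
                "region_id": [f"R{i}" for i in range(n)],
                "month": ["2018-01"] * n,
                "ed_attendances": 1.0,
                "gp_capacity": 1.0,
                "capacity_111": 1.0,
                "ambulance_capacity": 1.0,
                "population_scaled": 1.0,
                "pct_over_65": 10.0,
                "people_index": 100.0,
                "places_index": 100.0,
                "lives_index": 100.0,
            }
        )

    def test_no_missing_no_drops(self):
        kept, drops = drop_missing(self._panel())
        assert len(kept) == 10 and drops == {}

    def test_row_missing_two_variables_counted_once_under_first(self):
        panel = self._panel()
        panel.loc[0, ["lives_index", "capacity_111"]] = np.nan
        kept, drops = drop_missing(panel)
        assert len(kept) == 9
        assert drops == {"health_index": 1}  # 111 gap not double-counted

    def test_attribution_is_disjoint_recount(self):
        panel = self._panel(20)
        panel.loc[0:2, "people_index"] = np.nan
        panel.loc[3:7, "capacity_111"] = np.nan
        panel.loc[8, "gp_capacity"] = np.nan
        kept, drops = drop_missing(panel)
        # independent scan oracle
        n_bad = panel[
            ["people_index", "capacity_111", "gp_capacity"]
        ].isna().any(axis=1).sum()
        assert sum(drops.values()) == n_bad == 9
        assert drops == {"health_index": 3, "capacity_111": 5, "gp_capacity": 1}
        assert len(kept) == 11


class TestAnnualMeanTarget:
    def test_constant_year(self):
        panel = pd.DataFrame(
            {
                "region_id": ["A"] * 12,
                "month": [f"2018-{m:02d}" for m in range(1, 13)],
                "ed_attendances": [100.0] * 12,
            }
        )
        out = annual_mean_target(panel)
        assert out.loc[0, "ed_attendances"] == pytest.approx(100.0)

    def test_partial_year_mean(self):
        panel = pd.DataFrame(
            {
                "region_id": ["A", "A"],
                "month": ["2018-01", "2018-07"],
                "ed_attendances": [90.0, 110.0],
            }
        )
        assert annual_mean_target(panel).loc[0, "ed_attendances"] == 100.0

    def test_matches_group_mean_oracle(self):
        rng = np.random.default_rng(7)
        rows = []
        for r in ("A", "B"):
            for y in (2018, 2019):
                for m in range(1, 13):
                    if rng.random() < 0.8:
                        rows.append((r, f"{y}-{m:02d}", rng.uniform(50, 400)))
        panel = pd.DataFrame(rows, columns=["region_id", "month", "ed_attendances"])
        out = annual_mean_target(panel).set_index(["region_id", "year"])
        for (r, y), grp in panel.groupby(
            [panel["region_id"], panel["month"].str[:4].astype(int)]
        ):
            assert out.loc[(r, y), "ed_attendances"] == pytest.approx(
                grp["ed_attendances"].mean()
            )


class TestCurationLog:
    def test_accounting_identity_enforced(self):
        log = CurationLog(81, 5, 1824, {"health_index": 48, "capacity_111": 158}, 1618)
        log.validate()
        bad = CurationLog(81, 5, 1824, {"health_index": 48}, 1618)
        with pytest.raises(AssertionError):
            bad.validate()

    def test_round_trip(self, tmp_path):
        log = CurationLog(81, 5, 1824, {"health_index": 48}, 1776)
        log.to_json(tmp_path / "log.json")
        assert CurationLog.from_json(tmp_path / "log.json") == log


class TestCurateFrames:
    def test_deterministic(self, ref_fixture):
        frames, _, panel, _ = ref_fixture
        panel2, _ = curate_frames(
            frames["providers"], frames["contracts"], frames["contract_map"],
            frames["gp"], frames["regions"],
        )
        pd.testing.assert_frame_equal(panel, panel2)

    def test_no_missing_values_survive(self, ref_fixture):
        _, _, panel, _ = ref_fixture
        assert not panel.isna().any().any()

    def test_rates_match_ground_truth(self, default_panel):
        panel, _, truth, _ = default_panel
        merged = panel.merge(
            truth.frame, on=["region_id", "month"], suffixes=("", "_t")
        )
        assert len(merged) == len(panel)
        for col, tcol in [
            ("gp_capacity", "gp_capacity_t"),
            ("capacity_111", "capacity_111_t"),
            ("ambulance_capacity", "ambulance_capacity_t"),
            ("ed_attendances", "latent_rate"),
        ]:
            np.testing.assert_allclose(
                merged[col], merged[tcol], rtol=1e-9, atol=1e-9
            )

    def test_log_accounting(self, ref_fixture):
        _, _, panel, log = ref_fixture
        log.validate()
        assert log.n_final_records == len(panel)
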