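"""Target extraction, interpolation, classification and the allocation engine."""

import numpy as np
import pandas as pd
import pytest
from scipy.interpolate import PchipInterpolator

from ar_overshoot import scenario as sc
from ar_overshoot.synthetic import REGIONS

from conftest import epsilon_step_allocation, make_toy_grid, water_filling


def make_db(records):
    """records: list of (scenario_id, scope, variable, year, value)."""
    return pd.DataFrame(
        records, columns=["scenario_id", "scope", "variable", "year", "value"]
    )


class TestPooledPercentile:
    def test_single_scenario_returns_own_increments(self):
        rows = [("a", "WORLD", "forest", 2015 + 5 * k, 100.0 + 7.0 * k) for k in range(4)]
        ts = sc.pooled_percentile_increments(make_db(rows), "WORLD", 37.0)
        assert np.allclose(ts.increments, [0, 7, 7, 7])

    def test_median_of_three_scenarios(self):
        rows = []
        for sid, inc in (("a", 1.0), ("b", 2.0), ("c", 10.0)):
            rows += [("%s" % sid, "WORLD", "forest", 2015, 100.0),
                     ("%s" % sid, "WORLD", "forest", 2020, 100.0 + inc)]
        ts = sc.pooled_percentile_increments(make_db(rows), "WORLD", 50.0)
        assert ts.increments[1] == pytest.approx(2.0)

    def test_negative_percentile_floored_at_zero(self):
        rows = [("a", "WORLD", "forest", 2015, 100.0), ("a", "WORLD", "forest", 2020, 90.0)]
        ts = sc.pooled_percentile_increments(make_db(rows), "WORLD", 90.0)
        assert ts.increments[1] == 0.0

    def test_missing_year_scenario_skipped_for_step(self):
        rows = [
            ("a", "WORLD", "forest", 2015, 100.0),
            ("a", "WORLD", "forest", 2020, 105.0),
            ("a", "WORLD", "forest", 2025, 110.0),
            ("b", "WORLD", "forest", 2015, 100.0),
            ("b", "WORLD", "forest", 2025, 130.0),  # missing 2020
        ]
        ts = sc.pooled_percentile_increments(make_db(rows), "WORLD", 50.0)
        assert ts.increments[1] == pytest.approx(5.0)  # only scenario a

    def test_cumulative_target_reproduced(self, small_db):
        ts = sc.pooled_percentile_increments(small_db, "WORLD", 90.0)
        # direct summation oracle: cumulative = running sum of the pooled
        # percentile steps computed independently
        wide = (
            small_db[(small_db.scope == "WORLD") & (small_db.variable == "forest")]
            .pivot(index="scenario_id", columns="year", values="value")
        )
        steps = wide.diff(axis=1).iloc[:, 1:]
        expected = np.concatenate(
            [[0.0], np.maximum(np.percentile(steps.to_numpy(), 90, axis=0), 0.0)]
        ).cumsum()
        assert np.allclose(ts.cumulative, expected)

    def test_bad_percentile_rejected(self, small_db):
        with pytest.raises(ValueError):
            sc.pooled_percentile_increments(small_db, "WORLD", 100.0)


class TestRescaleRegional:
    def _ts(self, scope, incs):
        years = 2015 + 5 * np.arange(len(incs))
        return sc.TargetSeries(scope=scope, years=years, increments=np.asarray(incs, float))

    def test_proportionality(self):
        out = sc.rescale_regional(
            {"A": self._ts("A", [0, 4.0]), "B": self._ts("B", [0, 2.0])},
            self._ts("WORLD", [0, 9.0]),
        )
        assert out["A"].increments[1] == pytest.approx(6.0)
        assert out["B"].increments[1] == pytest.approx(3.0)

    def test_already_matching_unchanged(self):
        out = sc.rescale_regional(
            {"A": self._ts("A", [0, 4.0]), "B": self._ts("B", [0, 5.0])},
            self._ts("WORLD", [0, 9.0]),
        )
        assert out["A"].increments[1] == pytest.approx(4.0)

    def test_sum_identity(self, small_db):
        g = sc.pooled_percentile_increments(small_db, "WORLD", 90.0)
        reg = {r: sc.pooled_percentile_increments(small_db, r, 90.0) for r in REGIONS}
        out = sc.rescale_regional(reg, g)
        total = sum(t.increments for t in out.values())
        assert np.allclose(total, g.increments, atol=1e-9)

    def test_all_zero_regional_with_positive_global_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            sc.rescale_regional(
                {"A": self._ts("A", [0, 0.0])}, self._ts("WORLD", [0, 5.0])
            )


class TestInterpolateYearly:
    def test_knots_reproduced_exactly(self):
        ts = sc.TargetSeries("WORLD", [2015, 2020, 2025], [0.0, 10.0, 3.0])
        annual = sc.interpolate_yearly(ts)
        for y, c in zip(ts.years, ts.cumulative):
            assert annual.cumulative[annual.years == y][0] == pytest.approx(c)

    def test_linear_cumulative_constant_increments(self):
        ts = sc.TargetSeries("WORLD", [2015, 2020, 2025], [0.0, 5.0, 5.0])
        annual = sc.interpolate_yearly(ts)
        assert np.allclose(annual.increments[1:], 1.0)

    def test_monotone_inputs_give_nonnegative_increments(self):
        rng = np.random.default_rng(0)
        years = 2015 + 5 * np.arange(10)
        incs = np.concatenate([[0.0], rng.uniform(0, 20, 9)])
        annual = sc.interpolate_yearly(sc.TargetSeries("WORLD", years, incs))
        assert np.all(annual.increments >= 0)
        # dense-evaluation oracle of the shape-preserving Hermite interpolant
        dense = PchipInterpolator(years.astype(float), incs.cumsum())(
            np.arange(2015, 2061).astype(float)
        )
        assert np.allclose(annual.cumulative, dense)

    def test_single_knot_rejected(self):
        with pytest.raises(ValueError):
            sc.interpolate_yearly(sc.TargetSeries("WORLD", [2015], [0.0]))


class TestClassifyRangelands:
    def test_vlhi_rangeland_excluded(self):
        g = make_toy_grid(2, rangeland=0.4, pasture=0.1, vlhi=[1, 0], lhi=2)
        aug = sc.classify_rangelands(g)
        avail = sum(aug[f"frac_rangeland_g{k}"].values[0] for k in range(1, 5))
        assert avail[0] == 0.0 and avail[1] == pytest.approx(0.4)
        assert aug["frac_rangeland_excluded"].values[0, 0] == pytest.approx(0.4)

    def test_lhi_zero_joins_group_one(self):
        g = make_toy_grid(1, rangeland=0.3, lhi=0)
        aug = sc.classify_rangelands(g)
        assert aug["frac_rangeland_g1"].values[0, 0] == pytest.approx(0.3)

    def test_biodiversity_off_everything_group_one(self):
        g = make_toy_grid(2, rangeland=0.4, vlhi=1, lhi=3)
        aug = sc.classify_rangelands(g, sc.sensitivity_config("no_biodiversity"))
        assert np.allclose(aug["frac_rangeland_g1"].values, 0.4)
        assert np.allclose(aug["frac_rangeland_excluded"].values, 0.0)

    def test_invalid_lhi_rejected(self):
        g = make_toy_grid(1, rangeland=0.3)
        g["lhi_agreement"].values[:] = 7
        with pytest.raises(ValueError, match="lhi"):
            sc.classify_rangelands(g)


class TestAllocateYear:
    def test_zero_target_no_change(self):
        g = make_toy_grid(3)
        state = sc.AllocationState.from_grid(g)
        before = state.forest.copy()
        sc.allocate_year(state, {r: 0.0 for r in REGIONS})
        assert np.array_equal(state.forest, before)

    def test_single_cell_pasture_first(self):
        g = make_toy_grid(1, pasture=0.3, rangeland=0.3, cell_area=100.0, grs=1.0)
        cfg = sc.AllocationConfig(yearly_cap_frac=1.0)
        state = sc.AllocationState.from_grid(g, cfg)
        sc.allocate_year(state, {"ASIA": 5.0})
        assert state.forest[0] == pytest.approx(5.0)
        assert state.pasture[0] == pytest.approx(30.0 - 5.0)
        assert state.range_avail.sum() == pytest.approx(30.0)

    def test_water_filling_capacities_2_3_10(self):
        # capacities bound by the 10%/yr cap: areas (20, 30, 100) Mha
        g = make_toy_grid(3, cell_area=[20.0, 30.0, 100.0], pasture=0.9)
        state = sc.AllocationState.from_grid(g)
        sc.allocate_year(state, {"ASIA": 9.0})
        assert np.allclose(state.forest, [2.0, 3.0, 4.0], atol=1e-9)

    def test_infeasible_target_records_shortfall(self):
        g = make_toy_grid(2, cell_area=20.0, pasture=0.9)  # capacity 2+2 under cap
        state = sc.AllocationState.from_grid(g)
        sc.allocate_year(state, {"ASIA": 9.0})
        assert state.forest.sum() == pytest.approx(4.0)
        assert state.shortfall[(2015, "ASIA")] == pytest.approx(5.0)

    def test_rangeland_groups_in_biodiversity_order(self):
        # two cells, one rangeland-only in group 1, one in group 4: the
        # group-1 cell must be drained before group 4 is touched
        g = make_toy_grid(
            2, pasture=0.0, rangeland=0.1, cell_area=100.0, lhi=[1, 4],
        )
        cfg = sc.AllocationConfig(yearly_cap_frac=1.0)
        state = sc.AllocationState.from_grid(g, cfg)
        sc.allocate_year(state, {"ASIA": 12.0})
        # 10 Mha available in g1 cell, 2 Mha taken from g4 cell
        assert state.forest[0] == pytest.approx(10.0)
        assert state.forest[1] == pytest.approx(2.0)
        assert state.range_avail[0].sum() == pytest.approx(0.0)
        assert state.range_avail[3, 1] == pytest.approx(8.0)

    def test_cells_without_grazing_never_eligible(self):
        g = make_toy_grid(2, pasture=[0.0, 0.5])
        state = sc.AllocationState.from_grid(g)
        sc.allocate_year(state, {"ASIA": 4.0})
        assert state.forest[0] == 0.0
        assert state.forest[1] == pytest.approx(4.0)

    def test_min_forest_rule_excludes_cells(self):
        g = make_toy_grid(2, potential=[0.1, 0.6], forest_1850=[0.05, 0.0])
        state = sc.AllocationState.from_grid(g)
        sc.allocate_year(state, {"ASIA": 4.0})
        assert state.forest[0] == 0.0
        assert state.forest[1] == pytest.approx(4.0)

    def test_tier_cascade_grs_then_atl_then_other(self):
        # GRS 2 Mha in cell0, ATL 3 Mha in cell1, no potential in cell2
        g = make_toy_grid(
            3, pasture=0.9, cell_area=100.0,
            grs=[0.02, 0.0, 0.0], atl=[0.02, 0.03, 0.0],
        )
        state = sc.AllocationState.from_grid(g)
        sc.allocate_year(state, {"ASIA": 9.0})
        assert state.tier_total["GRS"] == pytest.approx(2.0)
        assert state.tier_total["ATL"] == pytest.approx(3.0)
        assert state.tier_total["other"] == pytest.approx(4.0)
        # records appear in tier order within the year
        tiers = [r["tier"] for r in state.records]
        assert tiers == sorted(tiers, key=("GRS", "ATL", "other").index)

    def test_matches_water_filling_oracle_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = rng.integers(2, 11)
            caps = rng.uniform(0.5, 10.0, n)
            target = rng.uniform(0.5, caps.sum() * 1.3)
            areas = caps * 10.0  # cap-bound capacities via 10%/yr rule
            g = make_toy_grid(int(n), cell_area=areas, pasture=0.9)
            state = sc.AllocationState.from_grid(g)
            sc.allocate_year(state, {"ASIA": float(target)})
            expected = water_filling(caps, target)
            assert np.allclose(state.forest, expected, atol=1e-6)

    def test_epsilon_step_simulation_agrees(self):
        caps = np.array([2.0, 3.0, 10.0])
        assert np.allclose(
            water_filling(caps, 9.0), epsilon_step_allocation(caps, 9.0), atol=1e-2
        )


class TestBuildScenario:
    def _annual_targets(self, total_per_region, years):
        n = years.size
        out = {}
        for r in REGIONS:
            incs = np.zeros(n)
            incs[1:] = total_per_region / (n - 1)
            out[r] = sc.TargetSeries(r, years, incs)
        return out

    def test_zero_targets_constant_trajectory(self, small_world):
        years = np.arange(2015, 2021)
        targets = {r: sc.TargetSeries(r, years, np.zeros(6)) for r in REGIONS}
        traj = sc.build_scenario(small_world, targets)
        f = traj.dataset["frac_forest"].values
        assert np.allclose(f, f[0][None])
        assert traj.ar_area_series().iloc[-1] == 0.0

    def test_capacity_saturation(self):
        # cumulative target far above capacity: final AR = capacity
        g = make_toy_grid(4, pasture=0.2, rangeland=0.0, cell_area=50.0, region=0)
        years = np.arange(2015, 2041)
        targets = self._annual_targets(200.0, years)
        traj = sc.build_scenario(g, targets)
        capacity = 4 * 0.2 * 50.0
        assert traj.ar_area_series().iloc[-1] == pytest.approx(capacity, abs=1e-6)
        gains = np.diff(traj.ar_area_series().to_numpy())
        assert np.all(gains >= -1e-9)

    def test_conservation_and_ledger_consistency(self, small_world, small_db):
        g = sc.pooled_percentile_increments(small_db, "WORLD", 90.0)
        reg = sc.rescale_regional(
            {r: sc.pooled_percentile_increments(small_db, r, 90.0) for r in REGIONS}, g
        )
        annual = {r: sc.interpolate_yearly(t) for r, t in reg.items()}
        traj = sc.build_scenario(small_world, annual)
        ds = traj.dataset
        area = ds["cell_area"].values
        total = (
            ds["frac_forest"].values + ds["frac_pasture"].values
            + ds["frac_rangeland"].values
        ) * area
        assert np.max(np.abs(total - total[0][None])) < 1e-6
        # ledgers sum to total forest gain
        gain = traj.ar_area_series().iloc[-1]
        assert sum(traj.tier_total.values()) == pytest.approx(gain, abs=1e-6)
        assert sum(traj.source_total.values()) == pytest.approx(gain, abs=1e-6)
        assert traj.reforestation + traj.afforestation == pytest.approx(gain, abs=1e-6)

    @pytest.mark.parametrize("name", ["no_biodiversity", "grs_only", "no_maps"])
    def test_sensitivity_configurations_run_and_conserve(self, small_world, small_db, name):
        g = sc.pooled_percentile_increments(small_db, "WORLD", 90.0)
        reg = sc.rescale_regional(
            {r: sc.pooled_percentile_increments(small_db, r, 90.0) for r in REGIONS}, g
        )
        annual = {r: sc.interpolate_yearly(t) for r, t in reg.items()}
        traj = sc.build_scenario(small_world, annual, sc.sensitivity_config(name))
        ds = traj.dataset
        area = ds["cell_area"].values
        total = (
            ds["frac_forest"].values + ds["frac_pasture"].values
            + ds["frac_rangeland"].values
        ) * area
        assert np.max(np.abs(total - total[0][None])) < 1e-6
        if name == "no_maps":
            assert traj.tier_total["GRS"] == 0.0 and traj.tier_total["ATL"] == 0.0


class TestOverlays:
    def _toy_traj(self):
        g = make_toy_grid(2, pasture=0.9, cell_area=[100.0, 100.0])
        years = np.arange(2015, 2026)
        # steer AR into cell 0 (10 Mha) and cell 1 (30 Mha) via region split:
        # both cells are region 0, so use per-cell caps instead
        g2 = make_toy_grid(2, pasture=[0.1, 0.3], rangeland=0.0, cell_area=100.0)
        incs = np.zeros(years.size)
        incs[1:] = 4.0
        targets = {r: sc.TargetSeries(r, years, incs if r == "ASIA" else np.zeros(years.size))
                   for r in REGIONS}
        return sc.build_scenario(g2, targets)

    def test_two_cell_overlay_fraction(self):
        traj = self._toy_traj()
        ar = traj.ar_per_cell()
        assert ar.sum() == pytest.approx(40.0, abs=1e-6)
        assert np.allclose(np.sort(ar), [10.0, 30.0], atol=1e-6)
        indicator = np.array([[1.0, 0.0]]) if ar[0] == 10.0 else np.array([[0.0, 1.0]])
        pct, mha = sc.overlay_indicator(traj, indicator, threshold=0.5)
        assert (pct, mha) == (pytest.approx(25.0), pytest.approx(10.0))

    def test_overlay_extremes(self):
        traj = self._toy_traj()
        pct, mha = sc.overlay_indicator(traj, np.zeros((1, 2)), threshold=0.5)
        assert (pct, mha) == (0.0, 0.0)
        pct, mha = sc.overlay_indicator(traj, np.ones((1, 2)), threshold=0.5)
        assert pct == pytest.approx(100.0)
        assert mha == pytest.approx(40.0, abs=1e-6)

    def test_overlay_shape_mismatch_rejected(self):
        traj = self._toy_traj()
        with pytest.raises(ValueError, match="shape"):
            sc.overlay_indicator(traj, np.zeros((2, 2)), threshold=0.5)


class TestCompositeGovernance:
    def test_hand_mean(self):
        df = pd.DataFrame([[0, 0.3, 0.6, 0.9, 0.3, 0.9]], index=["X"])
        assert sc.composite_governance(df).loc["X"] == pytest.approx(0.5)

    def test_equal_components(self):
        df = pd.DataFrame([[0.7] * 6], index=["X"])
        assert sc.composite_governance(df).loc["X"] == pytest.approx(0.7)

    def test_missing_filled_by_subregion_mean(self):
        df = pd.DataFrame(
            [[0.4] * 6, [np.nan] + [0.4] * 5], index=["A", "B"], dtype=float
        )
        sub = pd.Series({"A": "s1", "B": "s1"})
        out = sc.composite_governance(df, sub)
        assert out.loc["B"] == pytest.approx(0.4)

    def test_all_missing_after_fill_rejected(self):
        df = pd.DataFrame([[np.nan] * 6], index=["A"], dtype=float)
        with pytest.raises(ValueError, match="missing"):
            sc.composite_governance(df, pd.Series({"A": "s1"}))
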