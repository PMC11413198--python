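"""Generators: determinism, configured totals, noise structure, conservation."""

import numpy as np
import pytest

from ar_overshoot import synthetic as syn
from ar_overshoot.overshoot import fit_ar1


class TestWorldGrid:
    def test_same_seed_bit_identical(self):
        a = syn.gen_world_grid(6, 12, seed=5)
        b = syn.gen_world_grid(6, 12, seed=5)
        assert a.identical(b)

    def test_different_seed_differs(self):
        a = syn.gen_world_grid(6, 12, seed=5)
        b = syn.gen_world_grid(6, 12, seed=6)
        assert not np.allclose(a["frac_forest"].values, b["frac_forest"].values)

    def test_configured_pasture_total_hit_exactly(self):
        cfg = syn.GridConfig(pasture_total=1000.0)
        g = syn.gen_world_grid(10, 20, seed=1, config=cfg)
        total = float((g["frac_pasture"] * g["cell_area"]).sum())
        assert total == pytest.approx(1000.0, abs=0.1)

    def test_zero_pasture_config(self):
        g = syn.gen_world_grid(6, 12, seed=2, config=syn.GridConfig(pasture_total=0.0))
        assert np.all(g["frac_pasture"].values == 0.0)

    def test_invariants_hold(self):
        g = syn.gen_world_grid(12, 24, seed=3)
        syn.validate_world_grid(g)  # raises on violation
        cover = sum(g[v].values for v in syn.COVER_VARS)
        assert np.all(cover <= 1 + 1e-9)
        assert np.all(g["grs_potential"].values <= g["atl_potential"].values + 1e-12)

    def test_cell_areas_sum_to_earth_surface(self):
        g = syn.gen_world_grid(16, 32, seed=1)
        # 5.1e8 km^2 = 5.1e4 Mha
        assert float(g["cell_area"].sum()) == pytest.approx(51007, rel=1e-3)

    def test_unreachable_target_rejected(self):
        with pytest.raises(ValueError, match="unreachable"):
            syn.gen_world_grid(4, 8, seed=1, config=syn.GridConfig(forest_total=1e6))

    def test_tiny_grid_rejected(self):
        with pytest.raises(ValueError):
            syn.gen_world_grid(1, 8, seed=1)


class TestScenarioDb:
    def test_single_constant_scenario_zero_increments(self):
        shape = syn.ScenarioShape(q90_first=1e-9, q90_last=1e-9, sigma=1e-9)
        db = syn.gen_scenario_db(1, scopes=("WORLD",), seed=1, shape=shape)
        forest = db[db["variable"] == "forest"].sort_values("year")["value"].to_numpy()
        assert np.allclose(np.diff(forest), 0.0, atol=1e-6)

    def test_lognormal_pooled_percentile_matches_closed_form(self):
        # increments iid LogNormal(mu, sigma): the 90th percentile is
        # exp(mu + 1.2816 sigma); constant profile, no shift
        q90 = 50.0
        shape = syn.ScenarioShape(q90_first=q90, q90_last=q90, sigma=0.8, shift=0.0)
        db = syn.gen_scenario_db(1000, scopes=("WORLD",), seed=7, shape=shape)
        wide = (
            db[db["variable"] == "forest"]
            .pivot(index="scenario_id", columns="year", values="value")
        )
        increments = wide.diff(axis=1).iloc[:, 1:].to_numpy().ravel()
        assert np.percentile(increments, 90) == pytest.approx(q90, rel=0.05)

    def test_regional_percentiles_do_not_sum_to_global(self):
        # motivates the rescaling step: sum of regional percentiles is a
        # different statistic from the global percentile
        db = syn.gen_scenario_db(300, seed=9)
        from ar_overshoot.scenario import pooled_percentile_increments

        g = pooled_percentile_increments(db, "WORLD", 90)
        total = sum(
            pooled_percentile_increments(db, r, 90).increments for r in syn.REGIONS
        )
        assert not np.allclose(total[1:], g.increments[1:], rtol=1e-3)

    def test_determinism(self):
        a = syn.gen_scenario_db(10, seed=3)
        b = syn.gen_scenario_db(10, seed=3)
        assert a.equals(b)


class TestForcedTrajectory:
    def test_known_crossings_consistent(self):
        f = syn.ForcedTrajectory.overshoot()
        up, down = f.known_crossings[1.5]
        above = f.years[f.values >= 1.5]
        assert (above[0], above[-1]) == (up, down) == (2035, 2099)

    def test_inconsistent_crossings_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            syn.ForcedTrajectory(
                years=np.arange(2000, 2010),
                values=np.zeros(10),
                known_crossings={1.5: (2001, 2005)},
            )

    def test_bad_ordering_rejected(self):
        with pytest.raises(ValueError):
            syn.ForcedTrajectory.overshoot(up_year=2060, peak_year=2058)


class TestEnsembles:
    def test_sigma_zero_members_equal_forced(self):
        f = syn.ForcedTrajectory.overshoot()
        ens = syn.gen_esm_ensemble(f, phi=0.5, sigma=0.0, n_members=3, seed=1)
        assert np.allclose(ens.values, f.values[None, :])

    def test_phi_zero_residuals_uncorrelated(self):
        years = np.arange(2000, 2500)
        f = syn.ForcedTrajectory(years=years, values=np.zeros(years.size))
        ens = syn.gen_esm_ensemble(f, phi=0.0, sigma=1.0, n_members=1, seed=2)
        r = ens.values[0]
        r1 = np.corrcoef(r[:-1], r[1:])[0, 1]
        assert abs(r1) < 0.1

    def test_ensemble_mean_within_clt_band(self):
        years = np.arange(2000, 2100)
        f = syn.ForcedTrajectory(years=years, values=np.linspace(1, 2, years.size))
        phi, sigma, M = 0.5, 0.1, 100
        ens = syn.gen_esm_ensemble(f, phi=phi, sigma=sigma, n_members=M, seed=3)
        band = 3.0 * sigma / np.sqrt(M * (1 - phi) ** 2)
        assert np.all(np.abs(ens.mean() - f.values) < band)

    def test_ar1_fit_recovery(self):
        years = np.arange(2000, 2500)
        f = syn.ForcedTrajectory(years=years, values=np.zeros(years.size))
        fits = [
            fit_ar1(
                syn.gen_esm_ensemble(f, 0.6, 1.0, 1, seed=s).values[0]
            ).phi
            for s in range(10)
        ]
        assert abs(np.mean(fits) - 0.6) < 0.1

    def test_stationary_initialization_no_spinup(self):
        # variance of the first year across members matches the stationary
        # variance, not the innovation variance
        years = np.arange(0, 5)
        f = syn.ForcedTrajectory(years=years, values=np.zeros(5))
        ens = syn.gen_esm_ensemble(f, phi=0.9, sigma=1.0, n_members=4000, seed=4)
        v0 = ens.values[:, 0].var()
        assert v0 == pytest.approx(1.0 / (1 - 0.81), rel=0.1)

    def test_invalid_phi_rejected(self):
        f = syn.ForcedTrajectory.overshoot()
        with pytest.raises(ValueError):
            syn.gen_esm_ensemble(f, phi=1.0, sigma=0.1, n_members=2, seed=1)

    def test_gridded_shares_offset_between_experiments(self, small_world):
        years = np.arange(2015, 2025)
        f = syn.ForcedTrajectory(years=years, values=np.zeros(years.size))
        a = syn.gen_esm_ensemble(
            f, 0.5, 0.0, 2, seed=1, grid=small_world, offset_seed=99
        )
        b = syn.gen_esm_ensemble(
            f, 0.5, 0.0, 2, seed=2, grid=small_world, offset_seed=99
        )
        assert np.allclose(a.values, b.values)  # noiseless: offsets identical

    def test_csv_roundtrip(self, tmp_path):
        f = syn.ForcedTrajectory.overshoot()
        ens = syn.gen_esm_ensemble(f, 0.5, 0.1, 3, seed=5, experiment="REF")
        ens.to_csv(tmp_path / "e.csv")
        back = syn.EnsembleSeries.from_csv(tmp_path / "e.csv")
        assert np.allclose(back.values, ens.values)
        assert np.array_equal(back.years, ens.years)


class TestCarbonPools:
    def test_zero_emissions_zero_noise_constant(self):
        years = np.arange(2015, 2101)
        pools = syn.gen_carbon_pools(np.zeros(years.size), years, seed=1)
        for p in pools.values():
            assert np.allclose(p.values, 0.0)

    def test_mass_conservation_exact(self):
        years = np.arange(2015, 2101)
        em = syn.ssp534os_like_emissions(years)
        pools = syn.gen_carbon_pools(
            em, years, seed=2, noise_sd=0.5, n_members=5,
            extra_land_sink=np.linspace(0, 5, years.size),
        )
        total = sum(p.values for p in pools.values())
        cum = np.cumsum(em)
        cum -= cum[0]
        assert np.max(np.abs(total - cum[None, :])) < 1e-9

    def test_overshoot_emissions_atmospheric_pool_peaks_then_declines(self):
        # net-zero ~2070 then net-negative: the atmospheric pool must rise,
        # peak, and decline by the end of the century
        years = np.arange(2015, 2101)
        em = syn.ssp534os_like_emissions(years)
        pools = syn.gen_carbon_pools(em, years, seed=3)
        atmo = pools["atmosphere"].mean()
        peak = atmo.argmax()
        assert 0 < peak < years.size - 1
        assert atmo[-1] < atmo[peak]
        assert np.all(np.diff(atmo[: peak + 1]) >= 0)

    def test_bad_partition_rejected(self):
        years = np.arange(2015, 2020)
        with pytest.raises(ValueError, match="sum to 1"):
            syn.gen_carbon_pools(np.ones(5), years, partition=(0.5, 0.5, 0.5))
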