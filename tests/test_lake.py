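"""Layered lake model: supply terms, attenuation, stepping and summaries."""

import numpy as np
import pytest
from scipy.constants import N_A
from scipy.integrate import solve_ivp

import cyanoshade as cs
from cyanoshade.lake import SECONDS_PER_DAY, SECONDS_PER_YEAR
from cyanoshade.spectra import AttenuationCurve

BAND_GRID = np.arange(200.0, 401.0)


def flat_curve(eps, species="flat"):
    return AttenuationCurve(BAND_GRID, np.full(BAND_GRID.size, float(eps)), species=species)


ZERO = flat_curve(0.0, "transparent")


def single_layer_config(**kw):
    kw.setdefault("depth", 0.01)
    kw.setdefault("layer_thickness", 0.01)
    kw.setdefault("record_every", 1)
    return cs.LakeConfig(**kw)


class TestSupplyAndHaze:
    def test_nitrate_supply_printed_constants(self):
        assert cs.nitrate_supply_rate(cs.LakeConfig(depth=1.0)) == pytest.approx(6.5e-14, rel=1e-12)

    def test_supply_zero_without_catchment(self):
        assert cs.nitrate_supply_rate(cs.LakeConfig(catchment=0.0)) == 0.0

    def test_supply_scales_with_inverse_depth(self):
        one = cs.nitrate_supply_rate(cs.LakeConfig(depth=1.0))
        five = cs.nitrate_supply_rate(cs.LakeConfig(depth=5.0))
        assert five == pytest.approx(one / 5.0, rel=1e-12)

    def test_default_initial_ferrocyanide_is_cap(self):
        state = cs.init_haze_phase(cs.LakeConfig(depth=1.0))
        np.testing.assert_allclose(state.ferrocyanide, 0.1)
        assert np.all(state.nitroprusside == 0.0)

    def test_rainout_accumulation_uncapped_value(self):
        cfg = cs.LakeConfig(depth=1.0, initial_ferrocyanide=None)
        state = cs.init_haze_phase(cfg)
        # C * Phi * t / (6 N_A * depth_cm), in mol/cm^3, times 1000 for mol/dm^3
        expected = 500.0 * 1e8 * (1e3 * SECONDS_PER_YEAR) / (6 * N_A * 100.0) * 1000.0
        assert expected == pytest.approx(4.367e-3, rel=1e-3)  # below the 0.1 M cap
        np.testing.assert_allclose(state.ferrocyanide, expected, rtol=1e-12)

    def test_explicit_initial_concentration_is_capped(self):
        state = cs.init_haze_phase(cs.LakeConfig(initial_ferrocyanide=0.5))
        np.testing.assert_allclose(state.ferrocyanide, 0.1)

    def test_haze_nitrate_accumulation(self):
        state = cs.init_haze_phase(cs.LakeConfig(depth=1.0))
        np.testing.assert_allclose(state.nitrate, 2.051e-3, rtol=1e-3)

    def test_zero_haze_duration_gives_empty_lake(self):
        cfg = cs.LakeConfig(haze_duration_years=0.0, initial_ferrocyanide=None)
        state = cs.init_haze_phase(cfg)
        assert np.all(state.ferrocyanide == 0.0)
        assert np.all(state.nitrate == 0.0)


class TestConfigValidation:
    def test_depth_must_tile_into_layers(self):
        with pytest.raises(ValueError):
            cs.LakeConfig(depth=1.005)

    def test_unresolved_rate_rejected(self):
        # k2 = 4.43 day^-1; dt = 0.3 d gives k*dt > 1
        with pytest.raises(ValueError):
            cs.LakeConfig(dt=0.3)

    def test_bad_nitrate_mode_rejected(self):
        with pytest.raises(ValueError):
            cs.LakeConfig(nitrate_mode="zeroth-order")

    def test_threshold_must_be_fraction(self):
        with pytest.raises(ValueError):
            cs.LakeConfig(survival_threshold=1.5)


class TestTransmissionAndChi:
    def test_empty_lake_is_transparent(self, ferro, nitro):
        cfg = cs.LakeConfig(depth=0.05, initial_ferrocyanide=0.0)
        state = cs.init_haze_phase(cfg)
        z = cs.layer_transmission(state, (ferro, nitro), cfg)
        np.testing.assert_array_equal(z, 1.0)

    @pytest.mark.parametrize("conc, od", [(0.1, 22.0), (1e-4, 0.022)])
    def test_single_layer_decadal_depth_at_peak(self, ferro, nitro, conc, od):
        cfg = single_layer_config(initial_ferrocyanide=conc)
        state = cs.init_haze_phase(cfg)
        z = cs.layer_transmission(state, (ferro, nitro), cfg, grid=BAND_GRID)
        j = int(np.where(BAND_GRID == 340.0)[0][0])
        assert z[0, j] == pytest.approx(10.0 ** (-od), rel=1e-9)

    def test_chi_transparent_column(self):
        flux = cs.make_actinic_flux("flat", grid=BAND_GRID)
        z = np.ones((4, BAND_GRID.size))
        np.testing.assert_array_equal(cs.chi(flux, z, (300.0, 400.0)), 1.0)

    def test_chi_uniform_unit_depth(self):
        flux = cs.make_actinic_flux("flat", grid=BAND_GRID)
        z = np.full((2, BAND_GRID.size), 0.1)
        chis = cs.chi(flux, z, (300.0, 400.0))
        assert chis[0] == 1.0
        assert chis[1] == pytest.approx(0.1, rel=1e-12)
        assert chis[2] == pytest.approx(0.01, rel=1e-12)  # stacked layers multiply

    def test_chi_monotone_for_random_column(self, rng):
        flux = cs.make_actinic_flux("flat", grid=BAND_GRID)
        z = rng.uniform(0.2, 1.0, size=(8, BAND_GRID.size))
        chis = cs.chi(flux, z, (200.0, 300.0))
        assert np.all(np.diff(chis) <= 1e-15)

    def test_chi_rejects_fluxless_band(self):
        grid = BAND_GRID
        flux = cs.FluxSpectrum(grid, np.where(grid >= 300.0, 1.0, 0.0))
        with pytest.raises(ValueError):
            cs.chi(flux, np.ones((2, grid.size)), (200.0, 300.0))


class TestStepping:
    def test_fully_shaded_layer_only_accumulates_nitrate(self):
        cfg = single_layer_config()
        state = cs.LakeState(0.0, np.array([0.05]), np.array([1e-4]), np.array([1e-3]))
        new = cs.step(state, np.array([0.0]), np.array([0.0]), cfg)
        assert new.ferrocyanide[0] == state.ferrocyanide[0]
        assert new.nitroprusside[0] == state.nitroprusside[0]
        expected_supply = cs.nitrate_supply_rate(cfg) * SECONDS_PER_DAY * cfg.dt
        assert new.nitrate[0] == pytest.approx(1e-3 + expected_supply, rel=1e-12)

    def test_without_photo_oxidation_no_nitroprusside_forms(self):
        cfg = single_layer_config(k1=0.0)
        state = cs.LakeState(0.0, np.array([0.1]), np.array([0.0]), np.array([1.0]))
        for _ in range(5):
            state = cs.step(state, np.array([1.0]), np.array([1.0]), cfg)
        assert state.nitroprusside[0] == 0.0
        assert state.ferrocyanide[0] == pytest.approx(
            0.1 * np.exp(-cfg.k2_per_day * 5 * cfg.dt), rel=1e-12
        )

    def test_nitrate_consumption_never_exceeds_supply(self):
        cfg = single_layer_config()
        state = cs.LakeState(0.0, np.array([0.1]), np.array([0.0]), np.array([1e-12]))
        new = cs.step(state, np.array([1.0]), np.array([1.0]), cfg)
        avail = 1e-12 + cs.nitrate_supply_rate(cfg) * SECONDS_PER_DAY * cfg.dt
        assert new.nitrate[0] >= 0.0
        assert new.nitroprusside[0] <= avail * (1 + 1e-9)

    def test_closed_form_single_layer_trajectories(self):
        """Unshaded layer matches the analytic linear-pair solution."""
        cfg = single_layer_config(horizon_days=2.0, survival_threshold=0.0)
        res = cs.run(cfg, curves=(ZERO, ZERO))
        k1, k2 = cfg.k1_per_day, cfg.k2_per_day
        t = res.times[1:]
        a_exact = 0.1 * np.exp(-(k1 + k2) * t)
        b_exact = 0.1 * (np.exp(-k2 * t) - np.exp(-(k1 + k2) * t))
        np.testing.assert_allclose(res.ferrocyanide[1:, 0], a_exact, rtol=5e-3)
        np.testing.assert_allclose(res.nitroprusside[1:, 0], b_exact, rtol=5e-3)
        # peak [B] ~ k1 A0 / (k2 e)
        t_star = np.log((k1 + k2) / k2) / k1
        b_star = 0.1 * (np.exp(-k2 * t_star) - np.exp(-(k1 + k2) * t_star))
        assert res.peak_nitroprusside[0] == pytest.approx(b_star, rel=1e-2)
        assert b_star == pytest.approx(1.86e-4, rel=1e-2)

    def test_unshaded_survival_matches_closed_form(self):
        cfg = single_layer_config(horizon_days=5.0)
        res = cs.run(cfg, curves=(ZERO, ZERO))
        expected = np.log(100.0) / (cfg.k1_per_day + cfg.k2_per_day)
        assert abs(res.survival_days[0] - expected) <= cfg.dt

    def test_total_threshold_gives_zero_survival(self):
        cfg = single_layer_config(survival_threshold=1.0, horizon_days=1.0)
        res = cs.run(cfg, curves=(ZERO, ZERO))
        assert res.survival_days[0] == 0.0

    def test_bimolecular_mode_produces_less_nitroprusside(self):
        saturated = cs.run(single_layer_config(horizon_days=2.0), curves=(ZERO, ZERO))
        bimol = cs.run(
            single_layer_config(horizon_days=2.0, nitrate_mode="bimolecular"),
            curves=(ZERO, ZERO),
        )
        assert bimol.peak_nitroprusside[0] < saturated.peak_nitroprusside[0]

    def test_opaque_layer_shields_the_one_below(self, grid):
        """Photon-shadow limit: below an optically thick layer nothing happens."""
        cfg = cs.LakeConfig(depth=0.03, record_every=1)
        opaque = flat_curve(2000.0)  # decadal OD 20 per layer at 0.1 M
        state = cs.init_haze_phase(cfg)
        flux = cs.make_actinic_flux("flat", grid=BAND_GRID)
        z = cs.layer_transmission(state, (opaque, ZERO), cfg, grid=BAND_GRID)
        chi1 = cs.chi(flux, z, cfg.band_k1)[:-1]
        chi2 = cs.chi(flux, z, cfg.band_k2)[:-1]
        new = cs.step(state, chi1, chi2, cfg)
        rel_change = abs(new.ferrocyanide[1] - 0.1) / 0.1
        assert rel_change < 1e-8


@pytest.fixture(scope="module")
def small_run():
    return cs.run(cs.LakeConfig(depth=0.1, horizon_days=60.0, record_every=5))


class TestRunOutputs:

    def test_concentrations_stay_physical(self, small_run):
        assert np.all(small_run.ferrocyanide >= 0.0)
        assert np.all(small_run.nitroprusside >= 0.0)
        assert np.all(small_run.nitrate >= 0.0)
        assert np.all(small_run.ferrocyanide <= 0.1 + 1e-15)
        # after the haze clears ferrocyanide only decays
        assert np.all(np.diff(small_run.ferrocyanide, axis=0) <= 1e-15)

    def test_chi_ordering_every_record(self, small_run):
        assert np.all(np.diff(small_run.chi_k1, axis=1) <= 1e-12)
        assert np.all(np.diff(small_run.chi_k2, axis=1) <= 1e-12)

    def test_survival_monotone_with_depth(self, small_run):
        surv = small_run.survival_days
        assert not np.any(np.isnan(surv))
        assert np.all(np.diff(surv) >= 0.0)

    def test_exposure_delay_matches_layer_above(self, small_run):
        assert small_run.exposure_delay(0.005) == 0.0
        deep = small_run.exposure_delay(0.1)
        assert deep == small_run.survival_days[-2]

    def test_dt_halving_shifts_survival_under_two_percent(self):
        coarse = cs.run(cs.LakeConfig(depth=0.2, dt=0.07)).survival_days
        fine = cs.run(cs.LakeConfig(depth=0.2, dt=0.035)).survival_days
        assert np.nanmax(np.abs(coarse - fine) / fine) < 0.02

    def test_flux_shape_barely_matters_when_opaque(self):
        cfg = cs.LakeConfig(depth=0.5)
        flat = cs.run(cfg).shadow_slope().slope
        bb = cs.run(cfg, flux=cs.make_actinic_flux("blackbody")).shadow_slope().slope
        assert abs(bb - flat) / flat < 0.10

    def test_no_ferrocyanide_variant_leaves_rates_unattenuated(self):
        res = cs.run(cs.LakeConfig(depth=0.05, initial_ferrocyanide=0.0, horizon_days=1.0))
        np.testing.assert_array_equal(res.chi_k1, 1.0)
        np.testing.assert_array_equal(res.chi_k2, 1.0)
        np.testing.assert_array_equal(res.survival_days, 0.0)

    def test_zero_horizon_returns_initial_state_only(self):
        res = cs.run(cs.LakeConfig(depth=0.05, horizon_days=0.0))
        assert res.times.size == 1
        assert np.all(res.censored)

    def test_matches_independent_ode_integration(self):
        """Dual-route check: the stepped model against scipy's solve_ivp."""
        n, eps, a0 = 6, 1500.0, 0.1
        cfg = cs.LakeConfig(depth=0.06, horizon_days=60.0)
        k = cfg.k1_per_day + cfg.k2_per_day
        beta = cfg.layer_thickness_dm

        def rhs(t, a):
            od = eps * a * beta
            chi_top = 10.0 ** (-(np.cumsum(od) - od))
            return -k * chi_top * a

        sol = solve_ivp(rhs, (0.0, 40.0), np.full(n, a0), rtol=1e-10, atol=1e-14, dense_output=True)
        ts = np.linspace(0.0, 40.0, 200_000)
        a_ref = sol.sol(ts)
        surv_ref = np.array([ts[np.argmax(a_ref[j] < 0.01 * a0)] for j in range(n)])

        res = cs.run(cfg, curves=(flat_curve(eps), ZERO))
        np.testing.assert_allclose(res.survival_days, surv_ref, rtol=0.05)


class TestSummaries:
    def test_shadow_slope_recovers_exact_line(self):
        depths = np.linspace(0.5, 5.0, 10)
        fit = cs.shadow_slope(depths, 58.9 * depths)
        assert fit.slope == pytest.approx(58.9, rel=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(fit.predict(7.0), 58.9 * 7.0, rtol=1e-9)

    def test_shadow_slope_excludes_censored(self):
        depths = np.array([1.0, 2.0, 3.0, 4.0])
        surv = np.array([10.0, 20.0, 30.0, np.nan])
        assert cs.shadow_slope(depths, surv).n_points == 3
        with pytest.raises(ValueError):
            cs.shadow_slope(depths, np.array([10.0, 20.0, np.nan, np.nan]))

    def test_survival_time_custom_threshold(self):
        cfg = single_layer_config(horizon_days=5.0)
        res = cs.run(cfg, curves=(ZERO, ZERO))
        t10 = cs.survival_time(res, 0.1)[0]
        expected = np.log(10.0) / (cfg.k1_per_day + cfg.k2_per_day)
        assert abs(t10 - expected) <= 2 * cfg.dt

    def test_protected_lifetime_adds_durations(self):
        assert cs.protected_lifetime(0.0, 180.0) == 180.0
        assert cs.protected_lifetime(60.0, 180.0) == 240.0
        with pytest.raises(ValueError):
            cs.protected_lifetime(-1.0, 180.0)

    def test_frames_have_expected_shapes(self):
        res = cs.run(cs.LakeConfig(depth=0.05, horizon_days=2.0, record_every=2))
        surv = res.survival_frame()
        assert list(surv.columns) == [
            "depth_m",
            "survival_days",
            "censored",
            "peak_nitroprusside_M",
        ]
        traj = res.trajectory_frame()
        assert traj.shape[0] == res.times.size * res.config.n_layers
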