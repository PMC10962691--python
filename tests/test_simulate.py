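"""The synthetic experiment generator: kinetics, drivers, chamber inversion."""

import numpy as np
import pytest

from isopulse import closed_chamber_flux, correct_geogenic, steady_state_flux
from isopulse.simulate import (
    AMBIENT_SOIL_TEMP_C,
    PlotDesign,
    SimConfig,
    WARMING_FERTILIZED,
    WARMING_UNFERTILIZED,
    _chain_matrix,
    closed_ramp_from_flux,
    default_design,
    effective_parameters,
    sample_pools,
    simulate_drivers,
    simulate_sr_observations,
    simulate_tracer,
    steady_pair_from_flux,
)
from isopulse._errors import ConfigError


class TestDesign:
    def test_replicates_study_layout(self):
        plots = default_design()
        assert len(plots) == 14
        assert tuple(p.warming_dt for p in plots if p.n_addition == 0) == (
            WARMING_UNFERTILIZED)
        assert tuple(p.warming_dt for p in plots if p.n_addition > 0) == (
            WARMING_FERTILIZED)
        assert sum(p.sr_mode == "steady" for p in plots) == 8


class TestCompartmentChain:
    def test_label_conservation_machine_precision(self, sim_config, warmed_plot):
        tr = simulate_tracer(sim_config, warmed_plot, [0.0, 0.5, 1, 3, 6, 10])
        total = (tr["shoot"] + tr["root"] + tr["eoc"] + tr["microbial"]
                 + tr["cum_sr"] + tr["cum_shoot_resp"])
        np.testing.assert_allclose(total, sim_config.pulse_mg_13c, rtol=1e-12)

    def test_shoot_pool_is_exact_exponential(self, sim_config, unwarmed_plot):
        t = np.array([0.0, 1.0, 2.5, 7.0])
        tr = simulate_tracer(sim_config, unwarmed_plot, t)
        expected = sim_config.pulse_mg_13c * np.exp(-sim_config.k_shoot_out * t)
        np.testing.assert_allclose(tr["shoot"], expected, rtol=1e-10)

    def test_full_transfer_no_loss_limit(self, unwarmed_plot):
        cfg = SimConfig(seed=0, f_root=1.0, f_eoc=1.0, f_mb=1.0, k_mb_out=1e-9)
        tr = simulate_tracer(cfg, unwarmed_plot, [0.0, 2.0, 10.0])
        pools = tr["shoot"] + tr["root"] + tr["eoc"] + tr["microbial"]
        np.testing.assert_allclose(pools, cfg.pulse_mg_13c, rtol=1e-6)

    def test_matches_euler_oracle(self, sim_config, warmed_plot):
        """Brute-force forward-Euler integration agrees with the exact solution."""
        p = effective_parameters(sim_config, warmed_plot)
        A = _chain_matrix(p)
        dt, t_end = 5e-5, 2.0
        y = np.array([sim_config.pulse_mg_13c, 0, 0, 0, 0, 0], dtype=float)
        eye = np.eye(6)
        step = eye + A * dt
        for _ in range(int(round(t_end / dt))):
            y = step @ y
        tr = simulate_tracer(sim_config, warmed_plot, [t_end])
        exact = np.array([tr["shoot"][0], tr["root"][0], tr["eoc"][0],
                          tr["microbial"][0], tr["cum_sr"][0],
                          tr["cum_shoot_resp"][0]])
        np.testing.assert_allclose(y, exact, atol=1e-5 * sim_config.pulse_mg_13c)

    def test_invalid_rates_rejected(self, unwarmed_plot):
        with pytest.raises(ConfigError):
            simulate_tracer(SimConfig(seed=0, k_root_out=0.0), unwarmed_plot, [1.0])
        with pytest.raises(ConfigError):
            simulate_tracer(SimConfig(seed=0, f_mb=1.4), unwarmed_plot, [1.0])


class TestTreatmentEffects:
    def test_warming_accelerates_turnover(self, sim_config):
        cold = effective_parameters(sim_config, PlotDesign("a", 0.0, 0))
        hot = effective_parameters(sim_config, PlotDesign("b", 8.0, 0))
        for k in ("k_shoot_out", "k_root_out", "k_eoc_out", "k_mb_out"):
            assert hot[k] > cold[k]
        assert hot["f_mb"] > cold["f_mb"]
        assert hot["f_root"] < cold["f_root"]

    def test_n_addition_slows_belowground_turnover(self, sim_config):
        unfert = effective_parameters(sim_config, PlotDesign("a", 2.0, 0))
        fert = effective_parameters(sim_config, PlotDesign("b", 2.0, 50))
        for k in ("k_root_out", "k_eoc_out", "k_mb_out"):
            assert fert[k] < unfert[k]
        assert fert["f_root"] > unfert["f_root"]
        assert fert["k_shoot_out"] == unfert["k_shoot_out"]

    def test_warming_multiplier_monotone_in_fitted_decay(self, unwarmed_plot):
        """Larger warming sensitivity gives faster fitted SR decay, on average."""
        from isopulse import fit_exponential, prepare_sr_series

        plot = PlotDesign("w", 6.0, 0)
        mean_b = []
        for mult in (1.0, 1.04, 1.08):
            bs = []
            for seed in range(20):
                cfg = SimConfig(seed=seed, warming_k_mult=mult)
                obs = simulate_sr_observations(cfg, plot, noiseless=False)
                t, y = prepare_sr_series(obs["t_h"], obs["sr13_excess_rate_mg_h"])
                bs.append(fit_exponential(t, y, units="h").b)
            mean_b.append(np.mean(bs))
        assert mean_b[0] < mean_b[1] < mean_b[2]


class TestDrivers:
    def test_par_zero_every_night(self, sim_config, unwarmed_plot):
        drv = simulate_drivers(sim_config, unwarmed_plot, duration_d=5,
                               noiseless=True)
        night = (drv["t_h"] % 24.0 < 6.0) | (drv["t_h"] % 24.0 >= 18.0)
        assert np.all(drv["par"][night] <= 1e-9)  # sin underflow at dusk
        assert drv["par"].max() > 0

    def test_soil_temp_mean_is_ambient_plus_warming(self, sim_config):
        plot = PlotDesign("x", 3.5, 0)
        drv = simulate_drivers(sim_config, plot, duration_d=4, step_h=0.1,
                               noiseless=True)
        assert drv["soil_temp_c"].mean() == pytest.approx(
            AMBIENT_SOIL_TEMP_C + 3.5, abs=1e-6)

    def test_swc_flat_and_wet(self, sim_config, unwarmed_plot):
        drv = simulate_drivers(sim_config, unwarmed_plot, duration_d=3,
                               noiseless=True)
        assert np.ptp(drv["swc_vol_pct"]) == 0.0
        assert drv["swc_vol_pct"].min() >= 35.0

    def test_configured_lag_recovered_end_to_end(self, unwarmed_plot):
        from isopulse import lag_scan

        cfg = SimConfig(seed=0, sr_par_lag_h=4.8)
        obs = simulate_sr_observations(cfg, unwarmed_plot, noiseless=True)
        drv = simulate_drivers(cfg, unwarmed_plot, t_h=obs["t_h"], noiseless=True)
        scan = lag_scan(obs["t_h"], obs["sr_total_flux"], drv["par"],
                        detrend="diel")
        assert scan.best_lag == pytest.approx(-4.8)


class TestChamberInversion:
    def test_steady_pair_round_trip(self):
        cha, buf = steady_pair_from_flux(3.7, x_source=0.02)
        assert steady_state_flux(cha, buf).flux == pytest.approx(3.7, abs=1e-9)

    def test_closed_ramp_round_trip(self):
        series = closed_ramp_from_flux(6.1)
        res = closed_chamber_flux(series)
        assert res.flux == pytest.approx(6.1, rel=1e-9)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_geogenic_round_trip_through_mixing(self):
        # mixture delta from a configured geogenic fraction feeds the
        # two-pool correction, which must return that fraction
        f_geo = 0.3
        delta_mix = f_geo * (-4.7) + (1 - f_geo) * (-28.0)
        sr_bio, mix = correct_geogenic(5.0, delta_mix)
        assert mix.f_geo == pytest.approx(f_geo, abs=1e-12)
        assert sr_bio == pytest.approx(5.0 * 0.7, abs=1e-9)


class TestReproducibility:
    def test_seed_required_for_stochastic_output(self, unwarmed_plot):
        cfg = SimConfig()
        with pytest.raises(ConfigError):
            simulate_sr_observations(cfg, unwarmed_plot, noiseless=False)

    def test_same_seed_same_output(self, unwarmed_plot):
        a = simulate_sr_observations(SimConfig(seed=5), unwarmed_plot)
        b = simulate_sr_observations(SimConfig(seed=5), unwarmed_plot)
        np.testing.assert_array_equal(a["sr_total_flux"], b["sr_total_flux"])
        pa = sample_pools(SimConfig(seed=5), [unwarmed_plot])
        pb = sample_pools(SimConfig(seed=5), [unwarmed_plot])
        assert pa.equals(pb)
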