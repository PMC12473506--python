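"""Drift simulation, parameter modulation, time-varying integration, envelope."""

import numpy as np
import pytest

import pulsema as pm
from pulsema.dynamics import instantaneous_envelope
from pulsema.errors import ConfigurationError, DomainError

from conftest import rel_l2


class TestSimulateBaseline:
    def test_empty_ma_gives_zero_drift(self, params_1dof, grid):
        out = pm.simulate_baseline(params_1dof, pm.MotionArtifactSignal(),
                                   grid, "1dof")
        assert np.all(out["x_b"] == 0.0)

    def test_amplitude_matches_frequency_response(self, params_1dof, grid):
        ma = pm.MotionArtifactSignal(((1.0, 0.1, 0.0),))
        out = pm.simulate_baseline(params_1dof, ma, grid, "1dof")
        g = abs(pm.gain_baseline_1dof(params_1dof, 2 * np.pi * 0.1))
        # use the final full period of the 0.1 Hz tone for the peak
        assert np.max(np.abs(out["x_b"][2000:])) == pytest.approx(g, rel=0.01)

    def test_linearity_in_ma_amplitude(self, params_1dof, grid):
        ma1 = pm.canonical_ma(amplitude=1.0)
        ma3 = pm.canonical_ma(amplitude=3.0)
        x1 = pm.simulate_baseline(params_1dof, ma1, grid, "1dof")["x_b"]
        x3 = pm.simulate_baseline(params_1dof, ma3, grid, "1dof")["x_b"]
        np.testing.assert_allclose(x3, 3.0 * x1, atol=1e-10)

    def test_2dof_wall_drift_smaller_than_mass_drift(self, params_2dof, grid):
        out = pm.simulate_baseline(params_2dof, pm.canonical_ma(), grid, "2dof")
        assert np.max(np.abs(out["x1b"])) < np.max(np.abs(out["x2b"]))

    def test_ode_route_agrees_with_closed_form(self, params_1dof, params_2dof):
        grid = pm.TimeGrid(0.0, 12.0, 1e-3)
        ma = pm.canonical_ma()
        mask = grid.mask_after(2.0)
        cf = pm.simulate_baseline(params_1dof, ma, grid, "1dof")
        ode = pm.simulate_baseline(params_1dof, ma, grid, "1dof", method="ode")
        assert rel_l2(ode["x_b"][mask], cf["x_b"][mask]) < 1e-6
        cf2 = pm.simulate_baseline(params_2dof, ma, grid, "2dof")
        ode2 = pm.simulate_baseline(params_2dof, ma, grid, "2dof", method="ode")
        assert rel_l2(ode2["x2b"][mask], cf2["x2b"][mask]) < 1e-6

    def test_mode_mismatch(self, params_1dof, grid):
        with pytest.raises(ConfigurationError):
            pm.simulate_baseline(params_1dof, pm.canonical_ma(), grid, "2dof")


class TestTvspFromDrift:
    def test_zero_coupling_keeps_nominal_ratios(self, params_1dof, grid):
        drift = np.sin(grid.t)
        tvsp = pm.tvsp_from_drift(pm.TvspCoupling(0, 0, 0), drift,
                                  params_1dof, grid)
        assert np.all(tvsp.m == 0) and np.all(tvsp.c == 0) and np.all(tvsp.k == 0)
        np.testing.assert_allclose(tvsp.r, 2.0, atol=1e-12)
        np.testing.assert_allclose(tvsp.zeta, 1.5, atol=1e-12)

    def test_constant_drift_at_reference_gives_exact_modulation(
            self, params_1dof, grid):
        drift = np.full(grid.n, 0.7)
        coupling = pm.TvspCoupling(kappa_m=0.0, kappa_c=0.0, kappa_k=0.05,
                                   x_ref=0.7)
        tvsp = pm.tvsp_from_drift(coupling, drift, params_1dof, grid)
        np.testing.assert_allclose(tvsp.k, 0.05 * params_1dof.k0, rtol=1e-12)

    def test_r_total_exceeds_r_pointwise(self, params_1dof, grid):
        drift = 0.5 * np.sin(0.3 * grid.t)
        tvsp = pm.tvsp_from_drift(pm.TvspCoupling(), drift, params_1dof, grid)
        assert np.all(tvsp.r_total > tvsp.r)

    def test_r_total_variants_2dof(self, params_2dof, grid):
        drift = 0.5 * np.sin(0.3 * grid.t)
        ser = pm.tvsp_from_drift(pm.TvspCoupling(), drift, params_2dof, grid,
                                 r_total_variant="series")
        par = pm.tvsp_from_drift(pm.TvspCoupling(), drift, params_2dof, grid,
                                 r_total_variant="parallel")
        assert np.all(par.r_total > ser.r_total)
        assert np.all(ser.r_total > ser.r)

    def test_zero_xref_with_nonzero_coupling_rejected(self, params_1dof, grid):
        with pytest.raises(DomainError, match="x_ref"):
            pm.tvsp_from_drift(pm.TvspCoupling(), np.zeros(grid.n),
                               params_1dof, grid)

    def test_clamp_engages_on_extreme_modulation(self, params_1dof, grid):
        drift = -np.ones(grid.n)
        coupling = pm.TvspCoupling(kappa_m=2.0, kappa_c=2.0, kappa_k=2.0,
                                   x_ref=1.0)
        tvsp = pm.tvsp_from_drift(coupling, drift, params_1dof, grid)
        assert tvsp.clamped
        assert np.all(params_1dof.k0 + tvsp.k > 0)
        assert np.all(params_1dof.m0 + tvsp.m > 0)


class TestSimulateTvsp:
    def test_zero_coupling_matches_closed_form_1dof(self, params_1dof, grid,
                                                    analysis_window):
        pulse = pm.canonical_pulse()
        drift = np.zeros(grid.n)
        tvsp = pm.tvsp_from_drift(pm.TvspCoupling(0, 0, 0), drift,
                                  params_1dof, grid)
        sol = pm.simulate_tvsp(params_1dof, pulse, tvsp, grid)
        x_C = pm.measured_free(params_1dof, pulse, grid)["x_C"]
        assert rel_l2(sol["x_M"][analysis_window], x_C[analysis_window]) < 1e-4

    def test_zero_coupling_matches_closed_form_2dof(self, params_2dof, grid,
                                                    analysis_window):
        pulse = pm.canonical_pulse("pulsatile_pressure")
        tvsp = pm.tvsp_from_drift(pm.TvspCoupling(0, 0, 0), np.zeros(grid.n),
                                  params_2dof, grid)
        sol = pm.simulate_tvsp(params_2dof, pulse, tvsp, grid)
        free = pm.measured_free(params_2dof, pulse, grid)
        assert rel_l2(sol["x1M"][analysis_window],
                      free["x1C"][analysis_window]) < 1e-4
        assert rel_l2(sol["x2M"][analysis_window],
                      free["x2C"][analysis_window]) < 1e-4

    def test_canonical_distortion_is_small_perturbation(
            self, canonical_1dof_result, analysis_window):
        s = canonical_1dof_result.measured.series
        x_TVSP = s["x_TVSP"][analysis_window]
        x_C = s["x_C"][analysis_window]
        assert np.abs(x_TVSP).max() > 0.0
        assert np.abs(x_TVSP).max() / np.abs(x_C).max() < 0.15
        rms = lambda v: np.sqrt(np.mean(v**2))
        assert rms(x_TVSP) / rms(x_C) < 0.10


class TestComposeMeasured:
    def test_identities_1dof(self, canonical_1dof_result):
        s = canonical_1dof_result.measured.series
        np.testing.assert_allclose(s["x_TVSP"], s["x_M"] - s["x_C"], atol=1e-10)
        np.testing.assert_allclose(
            s["x_tactile"], s["x_M"] + s["x_b"] - s["z_b"], atol=1e-10)
        np.testing.assert_allclose(
            s["x_tactile_MA"], s["x_TVSP"] + s["x_b"] - s["z_b"], atol=1e-10)

    def test_identities_2dof(self, canonical_2dof_result):
        s = canonical_2dof_result.measured.series
        np.testing.assert_allclose(s["x2TVSP"], s["x2M"] - s["x2C"], atol=1e-10)
        np.testing.assert_allclose(
            s["x_tactile"], s["x2M"] + s["x2b"] - s["z_b"], atol=1e-10)
        np.testing.assert_allclose(s["x_wall"], s["x1M"] + s["x1b"], atol=1e-10)
        np.testing.assert_allclose(
            s["x_wall_MA"], s["x1TVSP"] + s["x1b"], atol=1e-10)

    def test_measured_drift_attenuated_and_opposed(
            self, canonical_1dof_result, analysis_window):
        s = canonical_1dof_result.measured.series
        drift = (s["x_b"] - s["z_b"])[analysis_window]
        z_b = s["z_b"][analysis_window]
        assert np.abs(drift).max() < np.abs(z_b).max()
        assert np.corrcoef(drift, z_b)[0, 1] < 0

    def test_no_ma_zero_coupling_collapses_to_free(self, params_1dof, grid):
        pulse = pm.canonical_pulse()
        ma = pm.MotionArtifactSignal()
        baseline = pm.simulate_baseline(params_1dof, ma, grid, "1dof")
        tvsp = pm.tvsp_from_drift(pm.TvspCoupling(0, 0, 0), baseline["drift"],
                                  params_1dof, grid)
        sol = pm.simulate_tvsp(params_1dof, pulse, tvsp, grid)
        measured = pm.compose_measured(params_1dof, pulse, ma, grid,
                                       baseline, sol)
        x_C = measured["x_C"]
        assert rel_l2(measured["x_tactile"], x_C) < 1e-6


class TestInstantaneousEnvelope:
    def test_pure_tone(self):
        dt = 1e-3
        t = np.arange(0, 10, dt)
        w = 2 * np.pi * 1.0
        env = instantaneous_envelope(2.0 * np.cos(w * t), dt)
        core = ~env.edge_unreliable
        assert np.max(np.abs(env.amplitude[core] - 2.0)) < 2e-3 * 2.0
        assert np.max(np.abs(env.omega[core] - w)) < 0.005 * w

    def test_amplitude_modulated_tone(self):
        dt = 1e-3
        t = np.arange(0, 20, dt)
        carrier = np.cos(2 * np.pi * t)
        modulation = 1.0 + 0.1 * np.cos(0.2 * np.pi * t)
        env = instantaneous_envelope(modulation * carrier, dt)
        core = ~env.edge_unreliable
        assert np.max(np.abs(env.amplitude[core] - modulation[core])) < 0.02

    def test_multi_harmonic_cycle_average_frequency(self, params_1dof):
        grid = pm.TimeGrid(0.0, 12.0, 1e-3)
        x_C = pm.measured_free(params_1dof, pm.canonical_pulse(), grid)["x_C"]
        env = instantaneous_envelope(x_C, grid.dt)
        # average over whole cycles away from the edges: samples 1000..11000
        mean_omega = np.mean(env.omega[1000:11000])
        assert mean_omega == pytest.approx(2 * np.pi, rel=0.005)

    def test_constant_series_rejected(self):
        with pytest.raises(DomainError):
            instantaneous_envelope(np.ones(100), 1e-3)
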