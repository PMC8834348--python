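"""Virtual detector and autocorrelation estimators."""

import numpy as np
import pytest

from raftdyn.acf_fit import fit_acf, model_g
from raftdyn.errors import ConfigError, DegenerateTraceError
from raftdyn.fcs import (ACFCurve, DetectionProfile, IntensityTrace,
                         average_runs, direct_acf, intensity_trace,
                         multitau_acf)
from raftdyn.sim import SimulationConfig, simulate


def make_trace(values, bin_time=1e-3):
    values = np.asarray(values, dtype=float)
    return IntensityTrace(counts=values, bin_time=bin_time,
                          duration=values.size * bin_time)


class TestIntensityTrace:
    def test_immobile_particle_at_center(self, static_ensemble_factory):
        ens = static_ensemble_factory([[1.5, 1.5]])
        prof = DetectionProfile(waist=0.25, center=(1.5, 1.5), brightness=100.0)
        tr = intensity_trace(ens, prof, ens.dt, poisson=False)
        assert np.allclose(tr.counts, 100.0)

    def test_immobile_particle_one_waist_away(self, static_ensemble_factory):
        ens = static_ensemble_factory([[1.5 + 0.25, 1.5]])
        prof = DetectionProfile(waist=0.25, center=(1.5, 1.5), brightness=100.0)
        tr = intensity_trace(ens, prof, ens.dt, poisson=False)
        assert np.allclose(tr.counts, 100.0 * np.exp(-2.0))

    def test_minimum_image_detection(self, static_ensemble_factory):
        # particle just across the periodic boundary is seen at short range
        ens = static_ensemble_factory([[2.95, 0.05]], box=3.0)
        prof = DetectionProfile(waist=0.3, center=(0.05, 2.95), brightness=10.0)
        tr = intensity_trace(ens, prof, ens.dt, poisson=False)
        d2 = 0.1 ** 2 + 0.1 ** 2
        assert np.allclose(tr.counts, 10.0 * np.exp(-2 * d2 / 0.09))

    def test_poisson_counts_have_correct_mean(self, static_ensemble_factory,
                                              rng):
        ens = static_ensemble_factory([[1.5, 1.5]], n_frames=4000)
        prof = DetectionProfile(waist=0.25, center=(1.5, 1.5), brightness=100.0)
        tr = intensity_trace(ens, prof, ens.dt, rng=rng, poisson=True)
        assert tr.counts.mean() == pytest.approx(
            100.0, abs=3 * np.sqrt(100.0 / tr.counts.size))

    def test_bin_time_must_be_multiple_of_dt(self, static_ensemble_factory):
        ens = static_ensemble_factory([[1.5, 1.5]])
        prof = DetectionProfile(waist=0.25, center=(1.5, 1.5), brightness=1.0)
        with pytest.raises(ConfigError):
            intensity_trace(ens, prof, 1.5 * ens.dt)

    def test_binning_averages_frames(self, static_ensemble_factory):
        ens = static_ensemble_factory([[1.5, 1.5]], n_frames=40)
        prof = DetectionProfile(waist=0.25, center=(1.5, 1.5), brightness=8.0)
        tr = intensity_trace(ens, prof, 4 * ens.dt, poisson=False)
        assert tr.counts.size == 10
        assert np.allclose(tr.counts, 8.0)


class TestDirectACF:
    def test_hand_computed_lag_zero(self):
        # [1,2,1,2]: G(0) = Var/mean^2 = 0.25/2.25
        curve = direct_acf(make_trace([1, 2, 1, 2]), max_lag=1)
        assert curve.g[0] == pytest.approx(0.25 / 2.25, rel=1e-12)

    def test_alternating_trace_negative_at_lag_one(self):
        curve = direct_acf(make_trace([1, 2] * 50), max_lag=3)
        assert curve.g[1] < 0

    def test_constant_trace_is_degenerate(self):
        with pytest.raises(DegenerateTraceError):
            direct_acf(make_trace(np.ones(100)), max_lag=10)
        with pytest.raises(DegenerateTraceError):
            multitau_acf(make_trace(np.full(100, 7.0)))

    def test_max_lag_bounds(self):
        with pytest.raises(ConfigError):
            direct_acf(make_trace([1, 2, 1, 2]), max_lag=10)


class TestMultitau:
    def test_agrees_with_direct_estimator(self, rng):
        # shared lags must agree within 1 % relative error
        lam = 5.0 * (1 + 0.5 * np.sin(np.arange(20000) / 300.0))
        counts = rng.poisson(lam).astype(float)
        tr = make_trace(counts, bin_time=1e-4)
        mt = multitau_acf(tr, m=16)
        dc = direct_acf(tr, max_lag=16)
        for k in range(1, 17):
            i = int(np.argmin(np.abs(mt.lags - k * 1e-4)))
            assert mt.g[i] == pytest.approx(dc.g[k], rel=1e-2, abs=1e-12)

    def test_white_noise_has_no_correlation(self, rng):
        curves = [multitau_acf(make_trace(rng.poisson(50.0, 5000)))
                  for _ in range(20)]
        avg = average_runs(curves)
        sel = avg.g_err > 0
        assert np.all(np.abs(avg.g[sel]) <= 3.0 * avg.g_err[sel] + 1e-3)

    def test_quasi_log_grid_increases(self, rng):
        mt = multitau_acf(make_trace(rng.poisson(10.0, 4096)))
        assert np.all(np.diff(mt.lags) > 0)

    def test_alternating_trace_negative_at_lag_one(self):
        mt = multitau_acf(make_trace([1.0, 2.0] * 200))
        assert mt.g[0] < 0

    def test_rescaling_intensity_leaves_g_unchanged(self, rng):
        counts = rng.poisson(20.0, 4000).astype(float)
        g1 = multitau_acf(make_trace(counts)).g
        g2 = multitau_acf(make_trace(counts * 7.3)).g
        assert np.allclose(g1, g2, rtol=1e-12)


class TestAverageRuns:
    def test_identical_curves(self):
        c = ACFCurve(lags=np.array([1e-3, 2e-3]), g=np.array([0.5, 0.2]))
        avg = average_runs([c] * 20)
        assert np.allclose(avg.g, c.g)
        assert np.allclose(avg.g_err, 0.0)
        assert avg.n_runs == 20

    def test_two_point_standard_error(self):
        lags = np.array([1e-3])
        a = ACFCurve(lags=lags, g=np.array([0.2]))
        b = ACFCurve(lags=lags, g=np.array([0.4]))
        avg = average_runs([a, b])
        assert avg.g[0] == pytest.approx(0.3)
        assert avg.g_err[0] == pytest.approx(0.1)

    def test_mismatched_grids_rejected(self):
        a = ACFCurve(lags=np.array([1e-3]), g=np.array([0.2]))
        b = ACFCurve(lags=np.array([2e-3]), g=np.array([0.2]))
        with pytest.raises(ConfigError):
            average_runs([a, b])

    def test_noisy_replicates_recover_analytic_curve(self, rng):
        lags = np.geomspace(1e-4, 0.1, 30)
        truth = model_g(lags, amplitude=0.5, tau_d=5e-3, baseline=0.0)
        curves = [ACFCurve(lags=lags, g=truth + rng.normal(0, 0.01, 30))
                  for _ in range(20)]
        avg = average_runs(curves)
        assert np.all(np.abs(avg.g - truth) <= 3.0 * avg.g_err + 1e-4)


class TestFreeDiffusionEndToEnd:
    def test_fitted_tau_d_matches_spot_transit_time(self):
        # tau_d = w^2/(4D) within 10 % for simulated free diffusion
        D, w = 1.0, 0.25
        c = SimulationConfig(box_size=3.0, n_particles=40, dt=5e-5,
                             duration=5.0, d_out=D, d_in=D,
                             p_enter=1.0, p_escape=1.0, seed=3)
        prof = DetectionProfile(waist=w, center=(1.5, 1.5), brightness=2.0)
        rng = np.random.default_rng(5)
        curves, state = [], None
        for run in range(20):
            ens = simulate(c, rng=rng, initial_state=state)
            state = ens.final_state
            curves.append(multitau_acf(intensity_trace(ens, prof, c.dt,
                                                       rng=rng)))
        avg = average_runs(curves)
        pilot = fit_acf(avg, min_lag=3 * c.dt, max_lag=0.2)
        fit = fit_acf(avg, min_lag=3 * c.dt, max_lag=6 * pilot.tau_d)
        assert fit.converged
        assert fit.tau_d == pytest.approx(w ** 2 / (4 * D), rel=0.10)

    def test_amplitude_scales_inversely_with_density(self):
        # doubling particle density halves G(0) (within 15 %)
        amps = []
        for n, seed in ((40, 11), (80, 12)):
            c = SimulationConfig(box_size=3.0, n_particles=n, dt=1e-4,
                                 duration=10.0, d_out=2.0, d_in=2.0,
                                 p_enter=1.0, p_escape=1.0, seed=seed)
            prof = DetectionProfile(waist=0.3, center=(1.5, 1.5),
                                    brightness=2.0)
            rng = np.random.default_rng(seed)
            ens = simulate(c, rng=rng)
            avg = average_runs([multitau_acf(
                intensity_trace(ens, prof, c.dt, rng=rng))])
            fit = fit_acf(avg, min_lag=3 * c.dt, max_lag=0.1)
            amps.append(fit.amplitude)
        assert amps[0] / amps[1] == pytest.approx(2.0, rel=0.15)

    def test_acf_decays_ergodically(self):
        c = SimulationConfig(box_size=3.0, n_particles=40, dt=1e-4,
                             duration=5.0, d_out=2.0, d_in=2.0,
                             p_enter=1.0, p_escape=1.0, seed=21)
        prof = DetectionProfile(waist=0.25, center=(1.5, 1.5), brightness=2.0)
        rng = np.random.default_rng(21)
        ens = simulate(c, rng=rng)
        mt = multitau_acf(intensity_trace(ens, prof, c.dt, rng=rng))
        amp = mt.g[mt.lags < 1e-3].mean()
        tail = np.abs(mt.g[mt.lags > 1.5]).mean()
        assert tail < 0.1 * amp
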