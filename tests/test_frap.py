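"""FRAP simulation, normalization and recovery fitting."""

import numpy as np
import pytest

from raftdyn.errors import (ConfigError, DegenerateNormalizationError,
                            UnderdeterminedFitError)
from raftdyn.frap import (FRAPConfig, FRAPCurve, disk_half_time_factor,
                          fit_frap, normalize_frap, simulate_frap, soumpasis)


def curve_from(d=None, mobile=42.13, t_half=13.7, **cfg_kw):
    """Noiseless (unless noise_cv given) curve with a chosen half-time."""
    config = FRAPConfig(**cfg_kw)
    if d is None:
        r = config.roi_diameter / 2.0
        tau_d = t_half / disk_half_time_factor()
        d = r ** 2 / (4.0 * tau_d)
    return simulate_frap(d, mobile, config,
                         rng=np.random.default_rng(5)), d


class TestSoumpasis:
    def test_limits(self):
        assert soumpasis(np.array([0.0]), 1.0)[0] == 0.0
        assert soumpasis(np.array([1e6]), 1.0)[0] == pytest.approx(1.0,
                                                                   abs=1e-3)

    def test_monotone_recovery(self):
        t = np.linspace(0.0, 50.0, 500)
        f = soumpasis(t, 5.0)
        assert np.all(np.diff(f) > 0)

    def test_half_time_factor_definition(self):
        tau = 7.0
        t_half = disk_half_time_factor() * tau
        assert soumpasis(np.array([t_half]), tau)[0] == pytest.approx(0.5,
                                                                      abs=1e-9)

    def test_matches_lattice_diffusion_oracle(self):
        # finite-difference diffusion of a bleached disk on a 256^2 grid
        n, box, d = 256, 10.0, 1.0
        h = box / n
        r = 1.25
        xx = (np.arange(n) + 0.5) * h - box / 2
        X, Y = np.meshgrid(xx, xx, indexing="ij")
        roi = X ** 2 + Y ** 2 <= r ** 2
        c = np.where(roi, 0.0, 1.0)
        tau_d = r ** 2 / (4 * d)
        dt = 0.2 * h ** 2 / d
        checkpoints = {0.5 * tau_d: None, tau_d: None, 2 * tau_d: None}
        t = 0.0
        remaining = sorted(checkpoints)
        while remaining:
            lap = (np.roll(c, 1, 0) + np.roll(c, -1, 0) +
                   np.roll(c, 1, 1) + np.roll(c, -1, 1) - 4 * c) / h ** 2
            c = c + d * dt * lap
            t += dt
            if t >= remaining[0]:
                checkpoints[remaining.pop(0)] = c[roi].mean()
        for tk, lattice_val in checkpoints.items():
            assert soumpasis(np.array([tk]), tau_d)[0] == pytest.approx(
                lattice_val, rel=0.02)


class TestSimulateFrap:
    def test_immobile_pool_gives_flat_recovery(self):
        raw, _ = curve_from(mobile=0.0)
        post = raw.times >= 0
        assert np.allclose(raw.intensity[post], 0.0)  # full-depth bleach
        assert np.allclose(raw.intensity[~post], 1.0)

    def test_full_mobility_recovers_to_prebleach(self):
        raw, _ = curve_from(mobile=100.0, t_half=2.0, n_postbleach=200)
        assert raw.intensity[-1] == pytest.approx(1.0, abs=0.02)

    def test_partial_bleach_depth_floor(self):
        raw, _ = curve_from(mobile=0.0, bleach_depth=0.6)
        post = raw.times >= 0
        assert np.allclose(raw.intensity[post], 0.4)

    def test_invalid_mobile_fraction(self):
        with pytest.raises(ConfigError):
            simulate_frap(1.0, 120.0, FRAPConfig())


class TestNormalizeFrap:
    def test_midpoint_maps_to_half(self):
        times = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        inten = np.array([100.0, 100.0, 40.0, 70.0, 100.0])
        norm = normalize_frap(FRAPCurve(times=times, intensity=inten))
        assert norm.normalized[3] == pytest.approx(0.5)
        assert norm.normalized[:2].mean() == pytest.approx(1.0)

    def test_already_normalized_curve_unchanged(self):
        times = np.array([-1.0, 0.0, 1.0, 2.0])
        inten = np.array([1.0, 0.0, 0.5, 0.8])
        norm = normalize_frap(FRAPCurve(times=times, intensity=inten))
        assert np.allclose(norm.normalized, inten)

    def test_constant_curve_is_degenerate(self):
        times = np.array([-1.0, 0.0, 1.0, 2.0])
        with pytest.raises(DegenerateNormalizationError):
            normalize_frap(FRAPCurve(times=times, intensity=np.ones(4)))

    def test_requires_pre_and_post_frames(self):
        with pytest.raises(ConfigError):
            normalize_frap(FRAPCurve(times=np.array([0.0, 1.0]),
                                     intensity=np.array([0.0, 1.0])))


class TestFitFrap:
    def test_noiseless_round_trip(self):
        raw, _ = curve_from(mobile=42.13, t_half=13.7)
        fit = fit_frap(normalize_frap(raw))
        assert fit.converged
        assert fit.t_half == pytest.approx(13.7, rel=1e-3)
        assert fit.mobile_fraction == pytest.approx(42.13, rel=1e-3)

    def test_exponential_model_half_time(self):
        # f = 1 - exp(-t/tau), tau = 10 s -> t_half = 10 ln 2
        times = np.concatenate([[-3.0, -1.5], np.arange(100) * 1.5])
        post = times >= 0
        inten = np.where(post, 1.0 - np.exp(-times / 10.0), 1.0)
        inten[~post] = 1.0
        fit = fit_frap(FRAPCurve(times=times, intensity=inten,
                                 normalized=inten), model="exp")
        assert fit.t_half == pytest.approx(10 * np.log(2), rel=1e-3)
        assert fit.mobile_fraction == pytest.approx(100.0, rel=1e-3)

    def test_noisy_round_trip_unbiased(self):
        # 50 replicates at 2 % noise: mean recovered t_half within 3 %
        rng = np.random.default_rng(31)
        config = FRAPConfig(noise_cv=0.02)
        r = config.roi_diameter / 2.0
        d = r ** 2 / (4.0 * 13.7 / disk_half_time_factor())
        fits = [fit_frap(normalize_frap(
            simulate_frap(d, 42.13, config, rng=rng))) for _ in range(50)]
        t_halves = [f.t_half for f in fits]
        mobiles = [f.mobile_fraction for f in fits]
        assert np.mean(t_halves) == pytest.approx(13.7, rel=0.03)
        assert np.mean(mobiles) == pytest.approx(42.13, abs=2.0)

    def test_flat_curve_reports_zero_mobility(self):
        times = np.concatenate([[-1.5], np.arange(50) * 1.5])
        inten = np.where(times >= 0, 0.0, 1.0)
        fit = fit_frap(FRAPCurve(times=times, intensity=inten))
        assert fit.mobile_fraction == pytest.approx(0.0, abs=1e-4)
        assert np.isnan(fit.t_half)

    def test_mobile_fraction_never_exceeds_100(self, rng):
        raw, _ = curve_from(mobile=100.0, t_half=5.0, noise_cv=0.05)
        fit = fit_frap(normalize_frap(raw))
        assert fit.mobile_fraction <= 100.0

    def test_half_time_invariant_to_bleach_depth(self):
        fits = []
        for depth in (1.0, 0.5):
            raw, _ = curve_from(mobile=60.0, t_half=8.0, bleach_depth=depth)
            fits.append(fit_frap(normalize_frap(raw)))
        assert fits[0].t_half == pytest.approx(fits[1].t_half, rel=1e-6)

    def test_affine_rescaling_of_raw_intensities_is_invariant(self):
        raw, _ = curve_from(mobile=42.13, t_half=13.7, noise_cv=0.01)
        scaled = FRAPCurve(times=raw.times, intensity=3.7 * raw.intensity + 11)
        f1 = fit_frap(normalize_frap(raw))
        f2 = fit_frap(normalize_frap(scaled))
        assert f1.t_half == pytest.approx(f2.t_half, rel=1e-9)
        assert f1.mobile_fraction == pytest.approx(f2.mobile_fraction,
                                                   rel=1e-9)

    def test_too_few_frames_rejected(self):
        times = np.array([-1.0, 0.0, 1.0, 2.0, 3.0])
        inten = np.array([1.0, 0.0, 0.2, 0.3, 0.4])
        with pytest.raises(UnderdeterminedFitError):
            fit_frap(FRAPCurve(times=times, intensity=inten,
                               normalized=inten))
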