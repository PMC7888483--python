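"""Rate estimation, cycle folding / FWHM oracles, and the spatial fit."""

import math

import numpy as np
import pytest

from chr2net.analysis import (RateTrace, boxcar_rate, fold_cycles,
                              open_state_pulse_statistics,
                              population_activity, pulse_locked_fraction,
                              pulse_statistics, spatial_gaussian_fit)


class TestBoxcarRate:
    def test_no_spikes(self):
        grid = np.arange(0, 1, 1e-3)
        r = boxcar_rate([np.array([])], 1e-3, grid)
        assert np.all(r.rate == 0.0)

    def test_single_spike_counting(self):
        grid = np.arange(0, 1, 1e-3)
        trains = [np.array([0.5])] * 4
        r = boxcar_rate(trains, 10e-3, grid)
        inside = np.abs(grid - 0.5) < 4e-3
        assert np.allclose(r.rate[inside], 1 / 10e-3)
        assert r.rate[np.abs(grid - 0.5) > 6e-3].max() == 0.0

    def test_poisson_mean(self):
        rng = np.random.default_rng(0)
        rate0, t_max, n = 5.0, 10.0, 900
        trains = [np.sort(rng.uniform(0, t_max, rng.poisson(rate0 * t_max)))
                  for _ in range(n)]
        grid = np.arange(0.05, t_max - 0.05, 1e-2)
        r = boxcar_rate(trains, 0.1, grid)
        se = math.sqrt(rate0 / (0.1 * n * grid.size))  # generous bound
        assert abs(r.rate.mean() - rate0) < 3 * math.sqrt(rate0 / (0.1 * n))

    def test_rate_normalization(self):
        """Integral of the rate equals spikes per trial up to boundary error."""
        rng = np.random.default_rng(1)
        trains = [np.sort(rng.uniform(0.1, 9.9, 50)) for _ in range(10)]
        grid = np.arange(0, 10, 1e-3)
        r = boxcar_rate(trains, 5e-3, grid)
        integral = np.trapezoid(r.rate, grid)
        assert integral == pytest.approx(50.0, rel=0.01)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            boxcar_rate([], 1e-3, np.arange(0, 1, 1e-3))


def _trace(times, values):
    return RateTrace(times=times, rate=values, window=1e-3, n_trials=1)


class TestPulseStatistics:
    def test_constant_trace_flagged(self):
        t = np.arange(0, 2, 1e-4)
        with pytest.warns(RuntimeWarning):
            s = pulse_statistics(_trace(t, np.full_like(t, 7.0)), 10.0,
                                 onset_skip=0.1)
        assert s.resp_min == s.resp_max == pytest.approx(7.0)
        assert not s.fwhm_defined and math.isnan(s.fwhm)

    def test_triangle_cycle_geometry(self):
        """Isoceles triangle pulse, base 10 ms on baseline b: FWHM = 5 ms."""
        f, b, h = 20.0, 2.0, 10.0
        t = np.arange(0, 3, 1e-4)
        period = 1 / f
        phase = t % period
        tri = np.where(phase < 10e-3, h * (1 - np.abs(phase - 5e-3) / 5e-3), 0)
        s = pulse_statistics(_trace(t, b + tri), f, onset_skip=0.1)
        assert s.resp_min == pytest.approx(b, abs=1e-6)
        assert s.resp_max == pytest.approx(b + h, abs=1e-3)
        assert s.fwhm == pytest.approx(5e-3, abs=2e-4)

    @pytest.mark.parametrize("shape, width", [("gauss", None), ("rect", 6e-3)])
    def test_fwhm_oracle_shapes(self, shape, width):
        """FWHM matches the analytic half-width within one sample step."""
        f = 10.0
        t = np.arange(0, 2, 1e-4)
        phase = t % (1 / f)
        if shape == "gauss":
            sig = 3e-3
            y = 4.0 + 10.0 * np.exp(-((phase - 20e-3) ** 2) / (2 * sig**2))
            expected = 2 * math.sqrt(2 * math.log(2)) * sig
        else:
            y = 4.0 + 10.0 * ((phase >= 10e-3) & (phase < 10e-3 + width))
            expected = width
        s = pulse_statistics(_trace(t, y), f, onset_skip=0.1)
        assert s.fwhm == pytest.approx(expected, abs=1.5e-4)

    def test_wrap_around_pulse(self):
        """A response straddling the cycle boundary is measured circularly."""
        f = 50.0
        t = np.arange(0, 2, 1e-4)
        phase = t % (1 / f)
        y = 1.0 + 8.0 * ((phase < 3e-3) | (phase >= 17e-3))
        s = pulse_statistics(_trace(t, y), f, onset_skip=0.1)
        assert s.fwhm == pytest.approx(6e-3, abs=2e-4)

    def test_too_few_cycles(self):
        t = np.arange(0, 0.25, 1e-4)
        with pytest.raises(ValueError):
            pulse_statistics(_trace(t, np.sin(t)), 10.0, onset_skip=0.1)

    def test_open_state_variant(self):
        f = 10.0
        t = np.arange(0, 2, 1e-5)
        phase = t % (1 / f)
        o = 0.05 + 0.2 * np.exp(-np.abs(phase - 8e-3) / 2e-3)
        s = open_state_pulse_statistics(t, o, f, onset_skip=0.1)
        assert s.resp_max == pytest.approx(0.25, abs=1e-3)
        assert s.resp_min == pytest.approx(0.05, abs=1e-2)


class TestSpatialGaussianFit:
    @staticmethod
    def _profile(r, sigma, nu_max, nu_base):
        return (nu_max - nu_base) * np.exp(-(r**2) / (2 * sigma**2)) + nu_base

    def test_exact_recovery_noiseless(self):
        r = np.linspace(-42, 42, 3600)
        y = self._profile(r, 12.0, 30.0, 4.0)
        fit = spatial_gaussian_fit(r, y, sigma0=8.0)
        assert fit.ok
        assert fit.sigma_FR == pytest.approx(12.0, rel=1e-6)
        assert fit.nu_max == pytest.approx(30.0, rel=1e-6)
        assert fit.nu_base == pytest.approx(4.0, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_recovery_under_noise(self):
        """0.2 Hz iid noise on 3600 neurons: width recovered within 5%."""
        rng = np.random.default_rng(7)
        for _ in range(3):
            r = np.linspace(-42, 42, 3600)
            y = self._profile(r, 14.0, 25.0, 3.0) + rng.normal(0, 0.2, r.size)
            fit = spatial_gaussian_fit(r, y)
            assert abs(fit.sigma_FR - 14.0) / 14.0 < 0.05

    def test_flat_profile_flagged(self):
        r = np.linspace(-30, 30, 100)
        fit = spatial_gaussian_fit(r, np.full(100, 5.0))
        assert not fit.ok
        assert fit.nu_max == pytest.approx(5.0)
        assert fit.nu_base == pytest.approx(5.0)
        assert math.isnan(fit.sigma_FR)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            spatial_gaussian_fit(np.arange(5), np.arange(5.0))
        with pytest.raises(ValueError):
            spatial_gaussian_fit(np.arange(20), np.full(20, np.nan))


class TestPopulationActivity:
    def test_mean(self):
        assert population_activity([5.0, 5.0]) == 5.0
        assert population_activity([0.0, 10.0]) == 5.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            population_activity([])


class TestPulseLockedFraction:
    def test_counting(self):
        onsets = np.array([0.0, 0.1, 0.2])
        trains = [np.array([0.005, 0.205]), np.array([0.15])]
        # windows of 10 ms: trial 1 hits pulses 0 and 2, trial 2 hits none
        assert pulse_locked_fraction(trains, onsets, 0.01) == pytest.approx(2 / 6)
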