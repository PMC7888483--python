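"""Channel kinetics: photon flux, activation, desensitization, photocurrent,
Euler stepping against closed-form oracles, and the analytic mean opening rate."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chr2net.channel import (ChannelParams, ChannelState, activation,
                             desensitization_rate, mean_opening_rate,
                             photocurrent, photon_flux, simulate_channel,
                             steady_state_open, step_channel)
from chr2net.protocols import StimulusProtocol


@pytest.fixture
def params():
    return ChannelParams()


class TestPhotonFlux:
    def test_zero_and_linearity(self, params):
        assert photon_flux(0.0, params) == 0.0
        e = 1234.5
        assert photon_flux(2 * e, params) == pytest.approx(2 * photon_flux(e, params))

    def test_reference_value(self, params):
        # 4 mW/mm^2 = 4000 W/m^2 with the tabulated cross-section/wavelength
        assert photon_flux(4000.0, params) == pytest.approx(873.6, rel=1e-3)

    def test_negative_intensity_rejected(self, params):
        with pytest.raises(ValueError):
            photon_flux(-1.0, params)


class TestActivation:
    @pytest.mark.parametrize("elapsed, expected", [
        (0.0, 0.0),
        (1.3e-3, 1 - math.exp(-1)),
        (1.0, 1.0),
    ])
    def test_closed_form(self, params, elapsed, expected):
        assert activation(elapsed, 0.0, params) == pytest.approx(expected, abs=1e-9)

    def test_monotone_and_domain(self, params):
        t = np.linspace(0, 10e-3, 50)
        p = activation(t, 0.0, params)
        assert np.all(np.diff(p) > 0)
        with pytest.raises(ValueError):
            activation(-1e-3, 0.0, params)


class TestDesensitizationRate:
    def test_reference_values(self, params):
        assert desensitization_rate(-70e-3, params) == pytest.approx(126.74)
        assert desensitization_rate(-55e-3, params) == pytest.approx(
            126.74 * (1 - 0.0056 * 15), rel=1e-9)

    def test_decreasing_in_v(self, params):
        v = np.linspace(-90e-3, -40e-3, 20)
        assert np.all(np.diff(desensitization_rate(v, params)) < 0)

    def test_clamped_at_zero(self, params):
        with pytest.warns(RuntimeWarning):
            assert desensitization_rate(0.5, params) == 0.0


class TestPhotocurrent:
    def test_zero_cases(self, params):
        assert photocurrent(ChannelState(), -70e-3, params) == 0.0
        assert photocurrent(ChannelState(O=0.3), params.E_ChR2, params) == 0.0

    def test_reference_value(self):
        p = ChannelParams(N_ChR2=300_000, g_ChR2=100e-15, E_ChR2=0.0)
        i = photocurrent(ChannelState(O=0.2), -70e-3, p)
        assert i == pytest.approx(0.42e-9, rel=1e-9)


class TestStepChannel:
    def test_dark_absorbing_state(self, params):
        state = ChannelState()
        out = step_channel(state, -70e-3, 0.0, 1e-5, params)
        assert out.O == 0.0 and out.D == 0.0

    def test_light_off_exponential_decay(self, params):
        # with E = 0 and V clamped, O decays as O(0) exp(-Gamma_d t)
        dt, v = 1e-5, -70e-3
        state = ChannelState(O=0.5, D=0.2)
        n = 1000
        for _ in range(n):
            state = step_channel(state, v, 0.0, dt, params)
        expected = 0.5 * math.exp(-desensitization_rate(v, params) * n * dt)
        assert state.O == pytest.approx(expected, rel=1e-3)

    def test_invalid_dt(self, params):
        with pytest.raises(ValueError):
            step_channel(ChannelState(), -70e-3, 0.0, 0.0, params)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(o=st.floats(0, 1), frac=st.floats(0, 1),
           e=st.floats(0, 10000), v=st.floats(-90e-3, -40e-3))
    def test_simplex_preserved(self, o, frac, e, v):
        """One step from any valid state stays on the probability simplex."""
        params = ChannelParams()
        d = (1 - o) * frac
        state = ChannelState(O=o, D=d, t_light=0.0)
        out = step_channel(state, v, e, 1e-5, params, t=1e-3)
        assert -1e-9 <= out.O <= 1 + 1e-9
        assert -1e-9 <= out.D <= 1 + 1e-9
        assert out.O + out.D <= 1 + 1e-9


class TestConstantLightFixedPoint:
    def test_simulated_state_converges_to_analytic(self, params):
        # constant 5 mW/mm^2, V clamped at -70 mV, long integration
        protocol = StimulusProtocol(f=0.5, t_pulse=2.0, E_hat=5000.0)
        t, O, D, _ = simulate_channel(protocol, params, t_max=1.9, dt=1e-5)
        o_star, d_star = steady_state_open(5000.0, -70e-3, params)
        assert O[-1] == pytest.approx(o_star, rel=1e-3)
        assert D[-1] == pytest.approx(d_star, rel=1e-3)

    def test_monotone_saturation_in_intensity(self, params):
        """Steady-state O is nondecreasing in intensity and saturates."""
        intensities = np.array([500.0, 2000.0, 8000.0, 32000.0])
        o = np.array([steady_state_open(e, -70e-3, params)[0]
                      for e in intensities])
        assert np.all(np.diff(o) > 0)
        increments = np.diff(o)
        assert np.all(np.diff(increments) < 0)  # shrinking gains


class TestMeanOpeningRate:
    @pytest.mark.parametrize("e_mw, f, expected", [
        (4.0, 5.0, 6.03), (4.0, 30.0, 36.17), (4.0, 60.0, 72.33),
        (6.0, 5.0, 9.04), (6.0, 30.0, 54.25), (6.0, 60.0, 108.5),
        (8.0, 5.0, 12.06), (8.0, 30.0, 72.33), (8.0, 60.0, 144.66),
    ])
    def test_reference_table(self, params, e_mw, f, expected):
        rate = mean_opening_rate(e_mw * 1000.0, f, 4e-3, params)
        # agreement to one unit in the last printed digit
        digits = len(str(expected).split(".")[1])
        assert abs(rate - expected) <= 10 ** (-digits) + 1e-12

    def test_no_pulses(self, params):
        assert mean_opening_rate(4000.0, 0.0, 4e-3, params) == 0.0

    def test_overlapping_pulses_rejected(self, params):
        with pytest.raises(ValueError):
            mean_opening_rate(4000.0, 300.0, 4e-3, params)

    def test_consistent_with_numerical_average(self, params):
        """Time average of eps*p(t)*phi(t) over one period matches the formula."""
        f, t_pulse, e_hat = 20.0, 4e-3, 5000.0
        dt = 1e-5
        period = 1.0 / f
        t = np.arange(0.0, period, dt)
        drive = np.where(
            t < t_pulse,
            params.epsilon * photon_flux(e_hat, params)
            * -np.expm1(-t / params.tau_ChR2),
            0.0)
        numeric = np.trapezoid(drive, t) / period
        analytic = mean_opening_rate(e_hat, f, t_pulse, params)
        assert numeric == pytest.approx(analytic, rel=5e-3)


def test_params_validation():
    with pytest.raises(ValueError):
        ChannelParams(epsilon=1.5)
    with pytest.raises(ValueError):
        ChannelParams(tau_ChR2=-1.0)
    with pytest.raises(ValueError):
        ChannelState(O=0.7, D=0.5)
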