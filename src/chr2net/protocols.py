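"""Stimulus construction: rectangular pulse trains and spatial Gaussian light.

A protocol is a train of temporally rectangular light pulses of duration
``t_pulse`` delivered at frequency ``f`` with peak intensity ``E_hat``,
optionally modulated across a neuron grid by an isotropic Gaussian of
standard deviation ``sigma_light`` (in grid units) centered on the grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["StimulusProtocol", "signed_radius"]


@dataclass
class StimulusProtocol:
    """Pulsed light stimulus.

    Intensities are W/m^2 (1 mW/mm^2 = 1000 W/m^2), times in seconds,
    ``sigma_light`` in grid units.  ``spatial`` selects between a uniform
    intensity (single-neuron protocols) and the Gaussian profile (network
    protocols).  Pulse onsets sit at ``t_on + k/f``; the duty cycle
    ``f * t_pulse`` may not exceed 1 (at 250 Hz a 4 ms pulse train becomes
    continuous light).
    """

    f: float = 50.0  # pulse frequency, Hz
    t_pulse: float = 4e-3  # pulse duration, s
    E_hat: float = 0.0  # peak intensity, W/m^2
    sigma_light: float = 8.0  # spatial SD, grid units
    t_on: float = 0.0  # stimulation start, s
    t_off: float = math.inf  # stimulation end, s
    spatial: str = "uniform"  # "uniform" | "gaussian"

    def __post_init__(self) -> None:
        if self.E_hat < 0:
            raise ValueError("E_hat must be >= 0")
        if self.sigma_light <= 0:
            raise ValueError("sigma_light must be > 0")
        if self.t_pulse < 0 or self.f < 0:
            raise ValueError("f and t_pulse must be >= 0")
        if self.f * self.t_pulse > 1.0 + 1e-12:
            raise ValueError("duty cycle f * t_pulse exceeds 1 (pulses overlap)")
        if self.spatial not in ("uniform", "gaussian"):
            raise ValueError("spatial must be 'uniform' or 'gaussian'")
        if self.t_off <= self.t_on:
            raise ValueError("t_off must exceed t_on")

    @property
    def duty_cycle(self) -> float:
        return self.f * self.t_pulse

    def intensity_at(self, t: float) -> tuple[float, bool]:
        """Instantaneous intensity and whether ``t`` is a pulse onset.

        Returns ``(E_hat, onset)`` while inside a pulse and ``(0.0, False)``
        otherwise.  Onsets are the times ``t_on + k/f`` within
        ``[t_on, t_off)`` and trigger the channel's activation-clock reset.
        """
        if t < 0:
            raise ValueError("t must be >= 0")
        if not (self.t_on <= t < self.t_off) or self.E_hat == 0 or self.f == 0:
            return 0.0, False
        period = 1.0 / self.f
        phase = (t - self.t_on) % period
        # guard against phase == period from float round-off
        if phase >= period - 1e-15 * period:
            phase = 0.0
        if phase < self.t_pulse:
            return self.E_hat, math.isclose(phase, 0.0, abs_tol=1e-12)
        return 0.0, False

    def temporal_schedule(self, times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized intensity and onset-flag arrays on a time grid.

        ``times`` must be nondecreasing.  Onset flags mark the first grid
        point at or after each pulse onset, which with pulses aligned to
        the simulation clock is the onset itself.
        """
        times = np.asarray(times, dtype=float)
        E = np.zeros_like(times)
        onset = np.zeros(times.shape, dtype=bool)
        if self.E_hat == 0 or self.f == 0:
            return E, onset
        period = 1.0 / self.f
        active = (times >= self.t_on) & (times < self.t_off)
        phase = (times - self.t_on) % period
        phase = np.where(phase >= period * (1 - 1e-15), 0.0, phase)
        # snap float round-off at the trailing pulse edge
        in_pulse = active & (phase < self.t_pulse) & (
            self.t_pulse - phase > 1e-9 * period)
        E[in_pulse] = self.E_hat
        # onset = first sample of each pulse, detected as a phase reset
        phase_dropped = np.empty(times.shape, dtype=bool)
        phase_dropped[0] = phase[0] < 1e-12
        phase_dropped[1:] = (phase[1:] < phase[:-1]) | ~in_pulse[:-1]
        onset = in_pulse & phase_dropped
        return E, onset

    def spatial_profile(self, position, center) -> float | np.ndarray:
        """Gaussian intensity scale ``exp(-r^2 / (2 sigma_light^2))`` in (0, 1].

        ``position`` is one ``(x, y)`` pair or an ``(n, 2)`` array of grid
        coordinates; ``center`` the profile center.  The sign attached to
        ``r`` for plotting purposes is irrelevant here since the Gaussian
        is even.
        """
        pos = np.asarray(position, dtype=float)
        c = np.asarray(center, dtype=float)
        r2 = np.sum((pos - c) ** 2, axis=-1)
        out = np.exp(-r2 / (2.0 * self.sigma_light**2))
        return float(out) if out.ndim == 0 else out


def signed_radius(position, center) -> float | np.ndarray:
    """Distance to ``center`` signed by ``sgn(x - x_c)``, in grid units.

    The sign only serves one-dimensional visualization and fitting of the
    radially symmetric activity profile; positions exactly on the vertical
    center line take sign +1.
    """
    pos = np.asarray(position, dtype=float)
    c = np.asarray(center, dtype=float)
    d = pos - c
    r = np.sqrt(np.sum(d**2, axis=-1))
    sign = np.where(d[..., 0] < 0, -1.0, 1.0)
    out = sign * r
    return float(out) if out.ndim == 0 else out
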