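"""Three-state channelrhodopsin-2 (ChR2/H134R) kinetics.

The channel is modeled as a Markov scheme with three states: closed (C),
open (O) and desensitized (D).  Light drives the C -> O transition at the
effective opening rate ``epsilon * p(t) * phi(t)``, open channels
desensitize at the voltage-dependent rate ``Gamma_d(V)``, and desensitized
channels recover to the closed state at the fixed rate ``Gamma_r``.  Since
C + O + D = 1, the dynamics reduce to two ODEs for (O, D):

    dO/dt = eps * p(t) * phi(t) * (1 - O - D) - Gamma_d(V) * O
    dD/dt = Gamma_d(V) * O - Gamma_r * D

``phi`` is the photon flux hitting the retinal chromophore, ``p`` a
first-order activation factor that delays opening after each light-pulse
onset, and ``epsilon`` the quantum efficiency of channel opening.

All quantities are SI (volts, amperes, seconds, watts per square meter).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PLANCK_CONSTANT",
    "SPEED_OF_LIGHT",
    "ChannelParams",
    "ChannelState",
    "photon_flux",
    "activation",
    "desensitization_rate",
    "step_channel",
    "photocurrent",
    "mean_opening_rate",
    "steady_state_open",
    "simulate_channel",
]

PLANCK_CONSTANT = 6.62606957e-34  # J s
SPEED_OF_LIGHT = 299792458.0  # m / s

#: slope of the linear voltage dependence of the desensitization rate, 1/V
_GAMMA_D_SLOPE = 0.0056e3
#: reference potential of the desensitization rate, V
_GAMMA_D_VREF = -70e-3


@dataclass
class ChannelParams:
    """Parameters of the ChR2/H134R three-state model.

    Defaults are the tabulated values for the H134R variant; the channel
    count ``N_ChR2`` distinguishes the low (60,000) from the high
    (300,000) expression level regime.
    """

    lambda_max: float = 470e-9  # absorption-peak wavelength, m
    sigma_ret: float = 12e-20  # retinal absorption cross-section, m^2
    w_loss: float = 1.3  # loss factor for the channel environment
    g_ChR2: float = 100e-15  # single-channel conductance, S
    Gamma_d0: float = 126.74  # desensitization rate at -70 mV, 1/s
    Gamma_r: float = 8.38  # recovery rate, 1/s
    epsilon: float = 0.5  # quantum efficiency of opening
    tau_ChR2: float = 1.3e-3  # activation time constant, s
    E_ChR2: float = 0.0  # photocurrent reversal potential, V
    N_ChR2: int = 300_000  # channels per neuron

    def __post_init__(self) -> None:
        for name in ("lambda_max", "sigma_ret", "w_loss", "g_ChR2",
                     "Gamma_d0", "Gamma_r", "tau_ChR2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")
        if self.N_ChR2 < 0:
            raise ValueError("N_ChR2 must be >= 0")

    @property
    def flux_coefficient(self) -> float:
        """Photon flux per unit light intensity, (1/s) / (W/m^2)."""
        return self.sigma_ret * self.lambda_max / (
            PLANCK_CONSTANT * SPEED_OF_LIGHT * self.w_loss
        )


@dataclass
class ChannelState:
    """Open/desensitized probabilities plus the activation clock.

    The closed-state probability is implicit, ``C = 1 - O - D``.
    ``t_light`` is the onset time of the most recent light pulse and
    anchors the activation factor ``p``.
    """

    O: float = 0.0
    D: float = 0.0
    t_light: float = -np.inf

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0.0 <= self.O <= 1.0 and 0.0 <= self.D <= 1.0):
            raise ValueError("O and D must lie in [0, 1]")
        if self.O + self.D > 1.0 + 1e-12:
            raise ValueError("O + D must not exceed 1")

    @property
    def C(self) -> float:
        return 1.0 - self.O - self.D


def photon_flux(E, params: ChannelParams):
    """Photon flux (1/s) reaching the chromophore at light intensity ``E`` (W/m^2).

    Linear in ``E``: ``phi = sigma_ret * lambda_max / (h * c * w_loss) * E``.
    """
    E = np.asarray(E, dtype=float)
    if np.any(E < 0):
        raise ValueError("light intensity must be >= 0")
    out = params.flux_coefficient * E
    return float(out) if out.ndim == 0 else out


def activation(t, t_light, params: ChannelParams):
    """First-order activation factor ``p = 1 - exp(-(t - t_light)/tau_ChR2)``.

    ``t_light`` is the onset of the current light pulse; ``p`` rises from 0
    towards 1 with time constant ``tau_ChR2`` and models the
    non-instantaneous adaptation of the channel population to light.
    """
    dt = np.asarray(t, dtype=float) - t_light
    if np.any(dt < 0):
        raise ValueError("t must be >= t_light")
    out = -np.expm1(-dt / params.tau_ChR2)
    return float(out) if out.ndim == 0 else out


def desensitization_rate(V, params: ChannelParams):
    """Voltage-dependent desensitization rate Gamma_d(V) in 1/s.

    Linear in V with negative slope, anchored at ``Gamma_d0`` for
    V = -70 mV; clamped at zero (with a warning) should the linear form
    go negative, which cannot happen below roughly +108 mV.
    """
    V = np.asarray(V, dtype=float)
    rate = params.Gamma_d0 * (1.0 - _GAMMA_D_SLOPE * (V - _GAMMA_D_VREF))
    if np.any(rate < 0):
        warnings.warn("desensitization rate clamped at 0", RuntimeWarning)
        rate = np.maximum(rate, 0.0)
    return float(rate) if rate.ndim == 0 else rate


def photocurrent(state: ChannelState, V: float, params: ChannelParams) -> float:
    """Depolarizing photocurrent ``-(V - E_ChR2) * N_ChR2 * g_ChR2 * O`` in A."""
    return -(V - params.E_ChR2) * params.N_ChR2 * params.g_ChR2 * state.O


def step_channel(
    state: ChannelState,
    V: float,
    E: float,
    dt: float,
    params: ChannelParams,
    t: float | None = None,
) -> ChannelState:
    """Advance (O, D) by one explicit-Euler step.

    ``E`` is the instantaneous light intensity and ``V`` the membrane
    potential used for the desensitization rate.  The activation factor is
    evaluated at time ``t`` (defaults to ``state.t_light`` + elapsed
    handling by the caller; pass ``t`` explicitly for pulsed light).  If an
    Euler step overshoots the probability simplex the state is clipped
    back with a warning.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    state.validate()
    if E < 0:
        raise ValueError("light intensity must be >= 0")
    if E > 0:
        t_eval = state.t_light if t is None else t
        p = activation(t_eval, state.t_light, params) if np.isfinite(state.t_light) else 0.0
        drive = params.epsilon * p * photon_flux(E, params)
    else:
        drive = 0.0
    gamma_d = desensitization_rate(V, params)
    O, D = state.O, state.D
    dO = (drive * (1.0 - O - D) - gamma_d * O) * dt
    dD = (gamma_d * O - params.Gamma_r * D) * dt
    O_new, D_new = O + dO, D + dD
    if O_new < 0 or D_new < 0 or O_new + D_new > 1.0:
        warnings.warn("channel Euler step left the probability simplex; clipping",
                      RuntimeWarning)
        O_new = min(max(O_new, 0.0), 1.0)
        D_new = min(max(D_new, 0.0), 1.0)
        total = O_new + D_new
        if total > 1.0:
            O_new /= total
            D_new /= total
    return replace(state, O=O_new, D=D_new)


def mean_opening_rate(E_hat: float, f: float, t_pulse: float,
                      params: ChannelParams) -> float:
    """Time-averaged opening rate <Gamma_o> of a pulsed protocol, 1/s.

    Average of ``epsilon * p(t) * phi(t)`` over one stimulation period
    ``T = 1/f`` with rectangular pulses of duration ``t_pulse`` and peak
    intensity ``E_hat``, the activation clock resetting at each onset:

        <Gamma_o> = eps * phi_hat * f * (t_pulse + tau * (exp(-t_pulse/tau) - 1))

    Proportional to both ``E_hat`` and ``f``.
    """
    if f < 0 or t_pulse < 0:
        raise ValueError("f and t_pulse must be >= 0")
    if f * t_pulse > 1.0 + 1e-12:
        raise ValueError("pulses overlap: f * t_pulse must be <= 1")
    tau = params.tau_ChR2
    phi_hat = photon_flux(E_hat, params)
    return params.epsilon * phi_hat * f * (t_pulse + tau * math.expm1(-t_pulse / tau))


def steady_state_open(E: float, V: float, params: ChannelParams) -> tuple[float, float]:
    """Analytic fixed point (O*, D*) under constant light with full activation.

    Solves dO/dt = dD/dt = 0 with p = 1 and the membrane clamped at ``V``:
    ``O* = a / (a * (1 + Gd/Gr) + Gd)`` with ``a = eps * phi(E)`` and
    ``D* = Gd * O* / Gr``.
    """
    a = params.epsilon * photon_flux(E, params)
    gd = desensitization_rate(V, params)
    if a == 0.0:
        return 0.0, 0.0
    O = a / (a * (1.0 + gd / params.Gamma_r) + gd)
    return O, gd * O / params.Gamma_r


def simulate_channel(protocol, params: ChannelParams, t_max: float,
                     dt: float = 1e-5, V_clamp: float = -70e-3,
                     state: ChannelState | None = None):
    """Integrate the channel alone with the membrane clamped at ``V_clamp``.

    ``protocol`` is a :class:`~chr2net.protocols.StimulusProtocol`; only its
    temporal structure is used.  Returns ``(t, O, D, I_ChR2)`` arrays
    sampled at every step.  Meant for channel-level protocols and tests;
    network simulations integrate the same equations in the compiled
    kernels.
    """
    if dt <= 0 or t_max <= 0:
        raise ValueError("dt and t_max must be > 0")
    n = int(round(t_max / dt))
    t = np.arange(n + 1) * dt
    E_sched, onset = protocol.temporal_schedule(t[:-1])
    O = np.empty(n + 1)
    D = np.empty(n + 1)
    st = state if state is not None else ChannelState()
    O[0], D[0] = st.O, st.D
    o, d, t_light = st.O, st.D, st.t_light
    gamma_d = desensitization_rate(V_clamp, params)
    coef = params.epsilon * params.flux_coefficient
    tau = params.tau_ChR2
    gr = params.Gamma_r
    for k in range(n):
        tk = t[k]
        if onset[k]:
            t_light = tk
        drive = 0.0
        if E_sched[k] > 0 and np.isfinite(t_light):
            drive = coef * E_sched[k] * -math.expm1(-(tk - t_light) / tau)
        do = (drive * (1.0 - o - d) - gamma_d * o) * dt
        dd = (gamma_d * o - gr * d) * dt
        o += do
        d += dd
        O[k + 1], D[k + 1] = o, d
    current = -(V_clamp - params.E_ChR2) * params.N_ChR2 * params.g_ChR2 * O
    return t, O, D, current
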