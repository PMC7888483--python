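"""Leaky integrate-and-fire neuron with OU background input and ChR2 drive.

The membrane obeys ``C_m dV/dt = -g_m (V - V_rev) + I_syn + I_ChR2`` with
threshold/reset/refractory mechanics; the background synaptic bombardment
from outside the simulated circuit is an Ornstein-Uhlenbeck (colored
noise) current.  For an isolated neuron the synaptic input is just that
external current.

The batch driver simulates many independent trials at once through the
compiled kernel in :mod:`chr2net._kernels`; given identical seed and
configuration the spike times are bit-identical between runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .channel import ChannelParams, ChannelState, _GAMMA_D_SLOPE, _GAMMA_D_VREF
from .protocols import StimulusProtocol

__all__ = [
    "NeuronParams",
    "OUParams",
    "NeuronState",
    "SingleNeuronResult",
    "step_ou",
    "step_lif",
    "simulate_single_neuron",
    "unstimulated_rate",
    "calibrate_I0",
]

DEFAULT_CHUNK_STEPS = 50_000


@dataclass
class NeuronParams:
    """LIF membrane parameters (SI units).

    ``C_m`` defaults to ``tau_m * g_m`` (1 nF for the tabulated 10 ms and
    0.1 uS) and must stay consistent with that product.
    """

    tau_m: float = 10e-3
    g_m: float = 0.1e-6
    C_m: float | None = None
    V_rev: float = -65e-3
    V_reset: float = -70e-3
    V_th: float = -55e-3
    tau_ref: float = 3e-3

    def __post_init__(self) -> None:
        if self.C_m is None:
            self.C_m = self.tau_m * self.g_m
        if abs(self.C_m - self.tau_m * self.g_m) > 1e-9 * abs(self.C_m):
            raise ValueError("C_m must equal tau_m * g_m")
        if not self.V_reset <= self.V_rev < self.V_th:
            raise ValueError("require V_reset <= V_rev < V_th")
        if self.tau_ref < 0:
            raise ValueError("tau_ref must be >= 0")

    @property
    def rheobase(self) -> float:
        """Smallest constant current that can reach threshold, A."""
        return self.g_m * (self.V_th - self.V_rev)


@dataclass
class OUParams:
    """Ornstein-Uhlenbeck external current: tau_syn d(I)/dt = I_0 - I + sigma_wn * xi(t).

    ``sigma_wn`` is the amplitude of the unit-intensity white noise
    ``xi``; the stationary distribution is Gaussian with mean ``I_0`` and
    variance ``sigma_wn^2 / (2 tau_syn)``.
    """

    tau_syn: float = 5e-3
    I_0: float = 0.914576e-9
    sigma_wn: float = 0.01e-9

    def __post_init__(self) -> None:
        if self.tau_syn <= 0:
            raise ValueError("tau_syn must be > 0")
        if self.sigma_wn < 0:
            raise ValueError("sigma_wn must be >= 0")

    @property
    def stationary_sd(self) -> float:
        return self.sigma_wn / math.sqrt(2.0 * self.tau_syn)


@dataclass
class NeuronState:
    """Mutable single-neuron state for the scalar stepping operations."""

    V: float = -70e-3
    refractory_until: float = -math.inf
    I_ext: float = 0.0
    channel: ChannelState = field(default_factory=ChannelState)
    spike_times: list = field(default_factory=list)


def step_ou(I_ext: float, dt: float, ou: OUParams, rng: np.random.Generator) -> float:
    """One exact-discretization OU update.

    ``I' = I_0 + (I - I_0) e^{-dt/tau} + sigma_wn sqrt((1 - e^{-2dt/tau})/(2 tau)) z``
    with ``z`` standard normal; the update is distributionally exact for
    any dt, so the stationary statistics do not depend on the step size.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    alpha = math.exp(-dt / ou.tau_syn)
    sd = ou.sigma_wn * math.sqrt((1.0 - alpha * alpha) / (2.0 * ou.tau_syn))
    z = rng.standard_normal() if sd > 0 else 0.0
    return ou.I_0 + (I_ext - ou.I_0) * alpha + sd * z


def step_lif(state: NeuronState, I_syn: float, I_ChR2: float, t: float,
             dt: float, params: NeuronParams) -> NeuronState:
    """One explicit-Euler LIF step (in place; also returns the state).

    During the refractory period the membrane is clamped at ``V_reset``.
    A threshold crossing appends the post-step time ``t + dt`` to
    ``spike_times``, resets the membrane, and starts the refractory clock.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if t < state.refractory_until:
        state.V = params.V_reset
        return state
    dV = dt / params.C_m * (
        -params.g_m * (state.V - params.V_rev) + I_syn + I_ChR2
    )
    state.V += dV
    if state.V >= params.V_th:
        t_spike = t + dt
        state.V = params.V_reset
        state.refractory_until = t_spike + params.tau_ref
        state.spike_times.append(t_spike)
    return state


@dataclass
class SingleNeuronResult:
    """Output of the batch single-neuron simulation."""

    spike_trains: list  # one array of spike times (s) per trial
    mean_O: np.ndarray  # open-state probability averaged over trials, per step
    times: np.ndarray  # step-time grid matching mean_O
    dt: float
    t_max: float
    n_trials: int
    n_clip: int  # channel simplex clippings (should be 0 at sane dt)
    v_traces: np.ndarray | None = None  # (n_steps, n_trials) if recorded

    def mean_rate(self, t_start: float = 0.0) -> float:
        """Grand-mean firing rate over [t_start, t_max], Hz."""
        span = self.t_max - t_start
        count = sum(int(np.sum(tr >= t_start)) for tr in self.spike_trains)
        return count / (self.n_trials * span)


def opening_drive_schedule(protocol: StimulusProtocol, params: ChannelParams,
                           t_grid: np.ndarray) -> np.ndarray:
    """Per-step effective opening rate eps * p(t) * phi(E(t)), 1/s.

    The activation clock resets at every pulse onset; between pulses the
    drive is zero regardless of ``p``.  Spatial modulation is applied
    separately (the drive is linear in intensity).
    """
    E, onset = protocol.temporal_schedule(t_grid)
    onset_times = np.where(onset, t_grid, -np.inf)
    t_light = np.maximum.accumulate(onset_times)
    with np.errstate(invalid="ignore"):
        p = np.where(
            (E > 0) & np.isfinite(t_light),
            -np.expm1(-(t_grid - t_light) / params.tau_ChR2),
            0.0,
        )
    return params.epsilon * params.flux_coefficient * E * p


def _empty_coupling():
    return (np.zeros(1, dtype=np.int64), np.zeros(0, dtype=np.int64),
            np.zeros(0, dtype=np.float64))


def run_population(
    *,
    n: int,
    n_steps: int,
    dt: float,
    drive: np.ndarray,
    light_scale: np.ndarray,
    n_g: np.ndarray,
    neuron_params: NeuronParams,
    ou_params: OUParams,
    channel_params: ChannelParams,
    rng: np.random.Generator,
    coupling=None,
    tau_syn_rec: float | None = None,
    record_v: bool = False,
    chunk_steps: int = DEFAULT_CHUNK_STEPS,
):
    """Chunked driver around the compiled kernel; shared by both simulators.

    Returns ``(spike_neuron, spike_step, sum_O, v_traces, n_clip)``.
    """
    alpha = math.exp(-dt / ou_params.tau_syn)
    ou_sd = ou_params.sigma_wn * math.sqrt(
        (1.0 - alpha * alpha) / (2.0 * ou_params.tau_syn))
    ref_steps = int(round(neuron_params.tau_ref / dt))
    if coupling is None:
        indptr, indices, weights = _empty_coupling()
        syn_decay = 1.0
    else:
        indptr, indices, weights = coupling
        syn_decay = math.exp(-dt / tau_syn_rec)

    V = np.full(n, neuron_params.V_reset)
    O = np.zeros(n)
    D = np.zeros(n)
    Iext = np.full(n, ou_params.I_0)
    Isyn = np.zeros(n)
    ref_count = np.zeros(n, dtype=np.int64)

    sum_O = np.zeros(n_steps)
    v_traces = np.empty((n_steps, n)) if record_v else np.empty((0, 0))
    all_neuron = []
    all_step = []
    n_clip = 0
    step0 = 0
    while step0 < n_steps:
        m = min(chunk_steps, n_steps - step0)
        z = rng.standard_normal((m, n))
        cap = _kernels.spike_capacity(n, m, ref_steps)
        spike_neuron = np.empty(cap, dtype=np.int64)
        spike_step = np.empty(cap, dtype=np.int64)
        v_out = v_traces[step0:step0 + m] if record_v else np.empty((0, 0))
        ns, nc = _kernels.step_chunk(
            V, O, D, Iext, Isyn, ref_count,
            light_scale, n_g,
            drive[step0:step0 + m], z,
            indptr, indices, weights, syn_decay,
            step0, dt,
            alpha, ou_sd, ou_params.I_0,
            channel_params.Gamma_d0, _GAMMA_D_SLOPE, _GAMMA_D_VREF,
            channel_params.Gamma_r,
            channel_params.E_ChR2, neuron_params.g_m, neuron_params.V_rev,
            1.0 / neuron_params.C_m, neuron_params.V_th,
            neuron_params.V_reset, ref_steps,
            spike_neuron, spike_step, sum_O[step0:step0 + m],
            v_out, record_v,
        )
        n_clip += nc
        all_neuron.append(spike_neuron[:ns].copy())
        all_step.append(spike_step[:ns].copy())
        step0 += m
    spike_neuron = np.concatenate(all_neuron) if all_neuron else np.zeros(0, np.int64)
    spike_step = np.concatenate(all_step) if all_step else np.zeros(0, np.int64)
    return spike_neuron, spike_step, sum_O, (v_traces if record_v else None), n_clip


def simulate_single_neuron(
    protocol: StimulusProtocol,
    channel_params: ChannelParams,
    neuron_params: NeuronParams,
    ou_params: OUParams,
    t_max: float,
    dt: float = 1e-5,
    seed: int = 0,
    n_trials: int = 1,
    record_v: bool = False,
    chunk_steps: int = DEFAULT_CHUNK_STEPS,
) -> SingleNeuronResult:
    """Simulate ``n_trials`` independent stimulated neurons.

    Each trial is an isolated LIF neuron whose synaptic input equals its
    own OU external current, with ``N_ChR2`` channels driven by the
    (spatially uniform) protocol.  Trials share the stimulus but draw
    independent noise from the seeded generator; results are reproducible
    bit-for-bit for a given ``(seed, config)``.
    """
    if t_max <= 0 or dt <= 0:
        raise ValueError("t_max and dt must be > 0")
    if protocol.spatial != "uniform":
        raise ValueError("single-neuron protocols must be spatially uniform")
    n_steps = int(round(t_max / dt))
    t_grid = np.arange(n_steps) * dt
    drive = opening_drive_schedule(protocol, channel_params, t_grid)
    rng = np.random.default_rng(seed)
    light_scale = np.ones(n_trials)
    n_g = np.full(n_trials, channel_params.N_ChR2 * channel_params.g_ChR2)
    spike_neuron, spike_step, sum_O, v_traces, n_clip = run_population(
        n=n_trials, n_steps=n_steps, dt=dt, drive=drive,
        light_scale=light_scale, n_g=n_g,
        neuron_params=neuron_params, ou_params=ou_params,
        channel_params=channel_params, rng=rng,
        record_v=record_v, chunk_steps=chunk_steps,
    )
    spike_t = spike_step * dt
    order = np.argsort(spike_neuron, kind="stable")
    sorted_neuron = spike_neuron[order]
    sorted_t = spike_t[order]
    bounds = np.searchsorted(sorted_neuron, np.arange(n_trials + 1))
    trains = [np.sort(sorted_t[bounds[k]:bounds[k + 1]]) for k in range(n_trials)]
    return SingleNeuronResult(
        spike_trains=trains,
        mean_O=sum_O / n_trials,
        times=t_grid,
        dt=dt,
        t_max=t_max,
        n_trials=n_trials,
        n_clip=n_clip,
        v_traces=v_traces,
    )


def unstimulated_rate(
    I_0: float,
    neuron_params: NeuronParams | None = None,
    ou_params: OUParams | None = None,
    t_sim: float = 20.0,
    n_trials: int = 4,
    seed: int = 0,
    dt: float = 1e-5,
    t_skip: float = 0.1,
) -> float:
    """Mean firing rate (Hz) of an unstimulated neuron at mean current ``I_0``."""
    neuron_params = neuron_params or NeuronParams()
    base_ou = ou_params or OUParams()
    ou = OUParams(tau_syn=base_ou.tau_syn, I_0=I_0, sigma_wn=base_ou.sigma_wn)
    protocol = StimulusProtocol(E_hat=0.0)
    channel = ChannelParams(N_ChR2=0)
    res = simulate_single_neuron(protocol, channel, neuron_params, ou,
                                 t_max=t_sim, dt=dt, seed=seed,
                                 n_trials=n_trials)
    count = sum(int(np.sum(tr >= t_skip)) for tr in res.spike_trains)
    return count / (n_trials * (t_sim - t_skip))


def calibrate_I0(
    target_rate: float,
    rate_fn,
    tolerance: float = 0.1,
    bracket: tuple[float, float] = (0.5e-9, 1.5e-9),
    max_iter: int = 40,
) -> float:
    """Find the OU mean current giving a target baseline firing rate.

    Bisection over ``I_0`` on the empirically monotone rate function
    ``rate_fn(I_0) -> Hz`` (e.g. :func:`unstimulated_rate` with a fixed
    seed, or a network baseline).  Raises if the bracket does not
    straddle the target or the target is non-positive (a 0 Hz baseline is
    unreachable with noise).
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be > 0")
    lo, hi = bracket
    r_lo, r_hi = rate_fn(lo), rate_fn(hi)
    if not (r_lo < target_rate < r_hi):
        raise ValueError(
            f"bracket does not straddle target: rate({lo:.3e})={r_lo:.2f} Hz, "
            f"rate({hi:.3e})={r_hi:.2f} Hz, target={target_rate} Hz")
    mid = 0.5 * (lo + hi)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r = rate_fn(mid)
        if abs(r - target_rate) <= tolerance:
            return mid
        if r < target_rate:
            lo = mid
        else:
            hi = mid
    return mid
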