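"""Recurrent E/I network under spatially modulated optogenetic drive.

A square grid of excitatory neurons (60 x 60 by default) and an
inhibitory pool are randomly coupled: every ordered pair is connected
independently with probability ``p_c``, identically for E->E, E->I,
I->E and I->I.  A presynaptic spike deposits an exponentially decaying
postsynaptic current whose time integral equals the coupling charge
``J_ij`` (positive from E, negative from I).  Only excitatory neurons
carry ChR2 channels and see the light, whose peak intensity falls off as
a Gaussian of the distance to the grid center; inhibitory neurons have
no spatial position.  Every neuron receives its own OU background input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .channel import ChannelParams
from .neuron import (NeuronParams, OUParams, opening_drive_schedule,
                     run_population)
from .protocols import StimulusProtocol, signed_radius

__all__ = [
    "DEFAULT_COUPLING_PC",
    "NetworkConfig",
    "ConnectivityMatrix",
    "SynapticTrace",
    "NetworkResult",
    "grid_positions",
    "grid_center",
    "build_connectivity",
    "simulate_network",
    "network_baseline_rate",
]

#: coupling charges in pC, indexed [source_pop][target_pop] with 0 = E, 1 = I
DEFAULT_COUPLING_PC = ((0.110, 0.190), (-0.340, -0.540))


@dataclass
class NetworkConfig:
    """Geometry, connectivity and coupling of the recurrent network.

    ``J`` is the 2 x 2 coupling-charge matrix in coulombs, indexed
    ``[source][target]`` with population 0 = excitatory, 1 = inhibitory;
    rows sourced from E must be positive, from I negative.
    ``expression_E`` is the ChR2 channel count per excitatory neuron
    (inhibitory neurons express none).
    """

    N_E: int = 3600
    N_I: int = 900
    p_c: float = 0.01
    J: tuple = tuple(tuple(v * 1e-12 for v in row) for row in DEFAULT_COUPLING_PC)
    tau_syn: float = 5e-3
    expression_E: int = 60_000
    seed_connectivity: int = 0
    seed_noise: int = 0

    def __post_init__(self) -> None:
        side = int(round(math.sqrt(self.N_E)))
        if side * side != self.N_E:
            raise ValueError("N_E must be a perfect square")
        if not 0.0 <= self.p_c <= 1.0:
            raise ValueError("p_c must lie in [0, 1]")
        J = np.asarray(self.J, dtype=float)
        if J.shape != (2, 2):
            raise ValueError("J must be 2 x 2")
        if np.any(J[0] <= 0) or np.any(J[1] >= 0):
            raise ValueError("E-source couplings must be > 0, I-source < 0")
        if self.tau_syn <= 0:
            raise ValueError("tau_syn must be > 0")
        if self.expression_E < 0:
            raise ValueError("expression_E must be >= 0")

    @property
    def n_total(self) -> int:
        return self.N_E + self.N_I

    @property
    def side(self) -> int:
        return int(round(math.sqrt(self.N_E)))


@dataclass
class ConnectivityMatrix:
    """Binary directed adjacency, row = source neuron, column = target."""

    adjacency: sp.csr_matrix

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz)

    def density(self) -> float:
        n = self.adjacency.shape[0]
        return self.n_edges / (n * (n - 1))


class SynapticTrace:
    """Per-target exponentially decaying input currents.

    Reference implementation of the synapse model used by the compiled
    network kernel: a spike of charge ``J`` deposits an instantaneous
    current increment ``J / tau_syn`` which then decays with the exact
    per-step factor ``exp(-dt/tau_syn)``, so the integrated postsynaptic
    current equals ``J``.  Excitatory and inhibitory contributions are
    tracked separately (they share ``tau_syn``, so their sum follows the
    same recursion the kernel uses).
    """

    def __init__(self, n_targets: int, tau_syn: float):
        if tau_syn <= 0:
            raise ValueError("tau_syn must be > 0")
        self.tau_syn = tau_syn
        self.exc = np.zeros(n_targets)
        self.inh = np.zeros(n_targets)

    def deliver_spike(self, target: int, J_ij: float) -> None:
        if not 0 <= target < self.exc.size:
            raise KeyError(f"unknown target neuron {target}")
        if J_ij >= 0:
            self.exc[target] += J_ij / self.tau_syn
        else:
            self.inh[target] += J_ij / self.tau_syn

    def decay(self, dt: float) -> None:
        factor = math.exp(-dt / self.tau_syn)
        self.exc *= factor
        self.inh *= factor

    def current(self, target: int | None = None):
        total = self.exc + self.inh
        return total if target is None else float(total[target])


def grid_positions(N_E: int) -> np.ndarray:
    """Row-major (x, y) coordinates of the excitatory grid, shape (N_E, 2)."""
    side = int(round(math.sqrt(N_E)))
    if side * side != N_E:
        raise ValueError("N_E must be a perfect square")
    idx = np.arange(N_E)
    return np.column_stack((idx % side, idx // side)).astype(float)


def grid_center(N_E: int) -> tuple[float, float]:
    """Center of the grid, ((side-1)/2, (side-1)/2); (29.5, 29.5) for 60 x 60.

    With an even side the light peak sits symmetrically between the four
    central neurons.
    """
    side = int(round(math.sqrt(N_E)))
    if side * side != N_E:
        raise ValueError("N_E must be a perfect square")
    c = (side - 1) / 2.0
    return c, c


def build_connectivity(config: NetworkConfig,
                       rng: np.random.Generator) -> ConnectivityMatrix:
    """Draw the Bernoulli adjacency: each ordered pair (j != i) with prob p_c."""
    n = config.n_total
    mask = rng.random((n, n)) < config.p_c
    np.fill_diagonal(mask, False)
    return ConnectivityMatrix(sp.csr_matrix(mask))


def _coupling_csr(config: NetworkConfig, conn: ConnectivityMatrix):
    """Out-edge CSR with per-edge current increments J_ij / tau_syn."""
    adj = conn.adjacency
    n = config.n_total
    J = np.asarray(config.J, dtype=float)
    src_pop = (np.arange(n) >= config.N_E).astype(np.intp)
    tgt_pop = (adj.indices >= config.N_E).astype(np.intp)
    row_of_edge = np.repeat(np.arange(n), np.diff(adj.indptr))
    weights = J[src_pop[row_of_edge], tgt_pop] / config.tau_syn
    return (adj.indptr.astype(np.int64), adj.indices.astype(np.int64), weights)


@dataclass
class NetworkResult:
    """Spike trains and per-neuron time-averaged rates of a network run.

    ``spike_trains[trial][neuron]`` are sorted spike times in seconds;
    excitatory neurons come first (ids 0 .. N_E-1).  ``rates`` are
    trial-averaged mean rates over ``[t_skip, t_max]``.
    """

    spike_trains: list
    rates: np.ndarray  # (n_total,)
    positions: np.ndarray  # (N_E, 2)
    signed_r: np.ndarray  # (N_E,)
    config: NetworkConfig
    dt: float
    t_max: float
    t_skip: float
    n_trials: int
    n_clip: int

    @property
    def excitatory_rates(self) -> np.ndarray:
        return self.rates[:self.config.N_E]


def simulate_network(
    config: NetworkConfig,
    protocol: StimulusProtocol,
    channel_params: ChannelParams,
    neuron_params: NeuronParams,
    ou_params: OUParams,
    t_max: float,
    dt: float = 1e-4,
    n_trials: int = 1,
    t_skip: float = 0.1,
    record_spikes: bool = True,
    chunk_steps: int = 4000,
) -> NetworkResult:
    """Simulate the recurrent network under the given light protocol.

    Per trial, the connectivity is redrawn with seed
    ``seed_connectivity + trial`` and the noise stream uses
    ``seed_noise + trial``; trials are otherwise independent.  Only the
    excitatory grid carries channels (``config.expression_E`` each) and
    receives light, scaled per neuron by the protocol's spatial profile.
    """
    if t_max <= t_skip:
        raise ValueError("t_max must exceed t_skip")
    n = config.n_total
    n_steps = int(round(t_max / dt))
    t_grid = np.arange(n_steps) * dt
    channel = ChannelParams(**{**channel_params.__dict__,
                               "N_ChR2": config.expression_E})
    drive = opening_drive_schedule(protocol, channel, t_grid)

    positions = grid_positions(config.N_E)
    center = grid_center(config.N_E)
    light_scale = np.zeros(n)
    if protocol.spatial == "gaussian":
        light_scale[:config.N_E] = protocol.spatial_profile(positions, center)
    else:
        light_scale[:config.N_E] = 1.0
    n_g = np.zeros(n)
    n_g[:config.N_E] = channel.N_ChR2 * channel.g_ChR2

    rate_sum = np.zeros(n)
    all_trains = []
    n_clip = 0
    for trial in range(n_trials):
        conn = build_connectivity(
            config, np.random.default_rng(config.seed_connectivity + trial))
        coupling = _coupling_csr(config, conn)
        rng = np.random.default_rng(config.seed_noise + trial)
        spike_neuron, spike_step, _, _, nc = run_population(
            n=n, n_steps=n_steps, dt=dt, drive=drive,
            light_scale=light_scale, n_g=n_g,
            neuron_params=neuron_params, ou_params=ou_params,
            channel_params=channel, rng=rng,
            coupling=coupling, tau_syn_rec=config.tau_syn,
            chunk_steps=chunk_steps,
        )
        n_clip += nc
        spike_t = spike_step * dt
        in_window = spike_t >= t_skip
        rate_sum += np.bincount(spike_neuron[in_window], minlength=n) / (
            t_max - t_skip)
        if record_spikes:
            order = np.argsort(spike_neuron, kind="stable")
            sn, st = spike_neuron[order], spike_t[order]
            bounds = np.searchsorted(sn, np.arange(n + 1))
            all_trains.append(
                [np.sort(st[bounds[k]:bounds[k + 1]]) for k in range(n)])
    return NetworkResult(
        spike_trains=all_trains,
        rates=rate_sum / n_trials,
        positions=positions,
        signed_r=signed_radius(positions, center),
        config=config,
        dt=dt,
        t_max=t_max,
        t_skip=t_skip,
        n_trials=n_trials,
        n_clip=n_clip,
    )


def network_baseline_rate(
    I_0: float,
    config: NetworkConfig,
    neuron_params: NeuronParams | None = None,
    ou_params: OUParams | None = None,
    t_sim: float = 2.0,
    dt: float = 1e-4,
    seed: int = 0,
) -> float:
    """Mean excitatory rate (Hz) of the unstimulated network at mean current I_0.

    Used as the rate function for :func:`chr2net.neuron.calibrate_I0` in
    the network context, where recurrent input shifts the operating point
    away from the single-neuron value.
    """
    neuron_params = neuron_params or NeuronParams()
    base_ou = ou_params or OUParams()
    ou = OUParams(tau_syn=base_ou.tau_syn, I_0=I_0, sigma_wn=base_ou.sigma_wn)
    cfg = NetworkConfig(**{**config.__dict__,
                           "seed_connectivity": config.seed_connectivity + 90000 + seed,
                           "seed_noise": config.seed_noise + 90000 + seed})
    protocol = StimulusProtocol(E_hat=0.0, spatial="gaussian")
    res = simulate_network(cfg, protocol, ChannelParams(N_ChR2=0),
                           neuron_params, ou, t_max=t_sim, dt=dt,
                           record_spikes=False)
    return float(np.mean(res.excitatory_rates))
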