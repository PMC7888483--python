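"""Experiment drivers behind the command line interface.

Each driver takes a :class:`~chr2net.config.RunConfig`, runs the
corresponding simulation/analysis, writes its outputs (tagged with the
config hash and seeds) into ``cfg.outdir`` and returns the results so
they can also be used programmatically.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from pathlib import Path

import numpy as np

from . import analysis, io
from .channel import ChannelParams, mean_opening_rate, simulate_channel
from .config import RunConfig, config_hash
from .network import NetworkConfig, network_baseline_rate, simulate_network
from .neuron import calibrate_I0, simulate_single_neuron, unstimulated_rate
from .protocols import StimulusProtocol

__all__ = [
    "opening_rate_table",
    "single_sweep",
    "network_sweep",
    "calibrate",
    "analyze_spikes",
    "channel_trace",
]

log = logging.getLogger("chr2net")

MW_MM2 = 1e3  # W/m^2 per mW/mm^2


def _outdir(cfg: RunConfig) -> Path:
    path = Path(cfg.outdir)
    path.mkdir(parents=True, exist_ok=True)
    return path


def _meta(cfg: RunConfig, **extra) -> dict:
    return {"config_hash": config_hash(cfg), "seed": cfg.seed, **extra}


def opening_rate_table(cfg: RunConfig, intensities_mw_mm2, frequencies,
                       write: bool = True):
    """Analytic time-averaged opening rate over an intensity x frequency grid."""
    rows = {"e_hat_mw_mm2": [], "f_hz": [], "opening_rate_per_s": []}
    for E in intensities_mw_mm2:
        for f in frequencies:
            rate = mean_opening_rate(E * MW_MM2, f, cfg.protocol.t_pulse,
                                     cfg.channel)
            rows["e_hat_mw_mm2"].append(E)
            rows["f_hz"].append(f)
            rows["opening_rate_per_s"].append(rate)
    if write:
        io.write_csv(_outdir(cfg) / "opening_rates.csv", rows, **_meta(cfg))
    return rows


def _protocol_with(cfg: RunConfig, **overrides) -> StimulusProtocol:
    return dataclasses.replace(cfg.protocol, **overrides)


def single_sweep(cfg: RunConfig, frequencies=None, intensities_mw_mm2=None,
                 window: float = 1e-3, rate_grid_dt: float = 1e-4,
                 write: bool = True):
    """Steady-state pulse statistics over an f x E_hat grid, single neuron.

    For each grid point, ``cfg.n_trials`` trials are simulated; the
    boxcar firing rate and the trial-averaged open-state probability are
    folded into mean cycles and summarized as response min/max/FWHM.
    """
    frequencies = list(frequencies or [cfg.protocol.f])
    intensities = list(intensities_mw_mm2 or [cfg.protocol.E_hat / MW_MM2])
    records = []
    for E in intensities:
        for f in frequencies:
            t0 = time.perf_counter()
            protocol = _protocol_with(cfg, f=f, E_hat=E * MW_MM2,
                                      spatial="uniform")
            res = simulate_single_neuron(
                protocol, cfg.channel, cfg.neuron, cfg.ou,
                t_max=cfg.t_max, dt=cfg.dt, seed=cfg.seed,
                n_trials=cfg.n_trials)
            grid = np.arange(0.0, cfg.t_max, rate_grid_dt)
            rate = analysis.boxcar_rate(res.spike_trains, window, grid)
            stats = analysis.pulse_statistics(
                rate, f, onset_skip=cfg.onset_skip, t_align=protocol.t_on)
            o_stats = analysis.open_state_pulse_statistics(
                res.times, res.mean_O, f, onset_skip=cfg.onset_skip,
                t_align=protocol.t_on)
            if res.n_clip:
                log.warning("channel simplex clipped %d times", res.n_clip)
            records.append({
                "f_hz": f, "e_hat_mw_mm2": E,
                "n_trials": cfg.n_trials,
                "rate": dataclasses.asdict(stats),
                "open_state": dataclasses.asdict(o_stats),
            })
            log.info("single-sweep f=%g Hz E=%g mW/mm^2: %.1f s",
                     f, E, time.perf_counter() - t0)
    if write:
        out = _outdir(cfg)
        io.write_records_json(out / "single_sweep.json", records, **_meta(cfg))
        io.write_csv(out / "single_sweep.csv", {
            "f_hz": [r["f_hz"] for r in records],
            "e_hat_mw_mm2": [r["e_hat_mw_mm2"] for r in records],
            "resp_min_hz": [r["rate"]["resp_min"] for r in records],
            "resp_max_hz": [r["rate"]["resp_max"] for r in records],
            "fwhm_ms": [r["rate"]["fwhm"] * 1e3 for r in records],
            "o_min": [r["open_state"]["resp_min"] for r in records],
            "o_max": [r["open_state"]["resp_max"] for r in records],
            "o_fwhm_ms": [r["open_state"]["fwhm"] * 1e3 for r in records],
        }, **_meta(cfg))
    return records


def network_sweep(cfg: RunConfig, intensities_mw_mm2=None, p_cs=None,
                  write: bool = True):
    """Spatial Gaussian fits over an E_hat x p_c grid of network runs."""
    intensities = list(intensities_mw_mm2 or [cfg.protocol.E_hat / MW_MM2])
    p_cs = list(p_cs or [cfg.network.p_c])
    records = []
    for p_c in p_cs:
        for E in intensities:
            t0 = time.perf_counter()
            net = dataclasses.replace(cfg.network, p_c=p_c,
                                      seed_noise=cfg.network.seed_noise + cfg.seed,
                                      seed_connectivity=cfg.network.seed_connectivity + cfg.seed)
            protocol = _protocol_with(cfg, E_hat=E * MW_MM2, spatial="gaussian")
            res = simulate_network(net, protocol, cfg.channel, cfg.neuron,
                                   cfg.ou, t_max=cfg.t_max, dt=cfg.dt,
                                   n_trials=cfg.n_trials,
                                   t_skip=cfg.onset_skip)
            fit = analysis.spatial_gaussian_fit(
                res.signed_r, res.excitatory_rates,
                sigma0=protocol.sigma_light)
            if write:
                io.write_network_rates(
                    _outdir(cfg) / f"rates_pc{p_c:g}_E{E:g}.csv", res,
                    **_meta(cfg, p_c=p_c, e_hat_mw_mm2=E))
            if res.n_clip:
                log.warning("channel simplex clipped %d times", res.n_clip)
            records.append({
                "e_hat_mw_mm2": E, "p_c": p_c,
                "expression_e": net.expression_E,
                "sigma_light": protocol.sigma_light,
                "fit": dataclasses.asdict(fit),
            })
            log.info("network-sweep p_c=%g E=%g mW/mm^2: %.1f s "
                     "(sigma_FR=%.2f)", p_c, E,
                     time.perf_counter() - t0, fit.sigma_FR)
    if write:
        out = _outdir(cfg)
        io.write_records_json(out / "network_sweep.json", records, **_meta(cfg))
        io.write_csv(out / "network_sweep.csv", {
            "e_hat_mw_mm2": [r["e_hat_mw_mm2"] for r in records],
            "p_c": [r["p_c"] for r in records],
            "sigma_fr": [r["fit"]["sigma_FR"] for r in records],
            "nu_max_hz": [r["fit"]["nu_max"] for r in records],
            "nu_base_hz": [r["fit"]["nu_base"] for r in records],
            "pop_activity_hz": [r["fit"]["pop_activity"] for r in records],
            "r_squared": [r["fit"]["r_squared"] for r in records],
        }, **_meta(cfg))
    return records


def calibrate(cfg: RunConfig, target_rate: float = 5.0,
              context: str = "single", tolerance: float = 0.1,
              t_sim: float | None = None) -> float:
    """Calibrate the OU mean current I_0 to a target unstimulated rate."""
    if context == "single":
        def rate_fn(i0):
            return unstimulated_rate(i0, cfg.neuron, cfg.ou,
                                     t_sim=t_sim or 20.0, n_trials=4,
                                     seed=cfg.seed, dt=cfg.dt)
    elif context == "network":
        def rate_fn(i0):
            return network_baseline_rate(i0, cfg.network, cfg.neuron, cfg.ou,
                                         t_sim=t_sim or 2.0, dt=cfg.dt,
                                         seed=cfg.seed)
    else:
        raise ValueError("context must be 'single' or 'network'")
    i0 = calibrate_I0(target_rate, rate_fn, tolerance=tolerance)
    log.info("calibrated I_0 = %.6f nA (%s context)", i0 / 1e-9, context)
    return i0


def analyze_spikes(cfg: RunConfig, spike_path, f: float | None = None,
                   window: float = 1e-3, rate_grid_dt: float = 1e-4,
                   write: bool = True):
    """Recompute pulse statistics from a saved spike-train file."""
    trains = io.read_spike_trains(spike_path)
    if not trains:
        raise ValueError(f"no spike trains in {spike_path}")
    f = f or cfg.protocol.f
    t_end = max((tr[-1] for tr in trains if tr.size), default=0.0)
    grid = np.arange(0.0, t_end + window, rate_grid_dt)
    rate = analysis.boxcar_rate(trains, window, grid)
    stats = analysis.pulse_statistics(rate, f, onset_skip=cfg.onset_skip,
                                      t_align=cfg.protocol.t_on)
    record = {"f_hz": f, "source": str(spike_path),
              "rate": dataclasses.asdict(stats)}
    if write:
        io.write_records_json(_outdir(cfg) / "analyze.json", [record],
                              **_meta(cfg))
    return record


def intensity_map(cfg: RunConfig, write: bool = True):
    """Per-neuron peak light intensity of the configured protocol (mW/mm^2)."""
    from .network import grid_center, grid_positions
    positions = grid_positions(cfg.network.N_E)
    center = grid_center(cfg.network.N_E)
    if cfg.protocol.spatial == "gaussian":
        scale = cfg.protocol.spatial_profile(positions, center)
    else:
        scale = np.ones(cfg.network.N_E)
    peak = cfg.protocol.E_hat * scale / MW_MM2
    if write:
        io.write_csv(_outdir(cfg) / "intensity_map.csv", {
            "neuron_id": np.arange(cfg.network.N_E),
            "x": positions[:, 0].astype(int),
            "y": positions[:, 1].astype(int),
            "peak_intensity_mw_mm2": peak,
        }, **_meta(cfg))
    return positions, peak


def channel_trace(cfg: RunConfig, V_clamp: float = -70e-3,
                  write: bool = True):
    """Clamped-membrane channel protocol; writes (t, O, D, C, I_ChR2) CSV."""
    t, O, D, current = simulate_channel(cfg.protocol, cfg.channel,
                                        t_max=cfg.t_max, dt=cfg.dt,
                                        V_clamp=V_clamp)
    if write:
        io.write_csv(_outdir(cfg) / "channel_trace.csv", {
            "t_s": t, "O": O, "D": D, "C": 1.0 - O - D, "i_chr2_A": current,
        }, **_meta(cfg, v_clamp_mV=V_clamp / 1e-3))
    return t, O, D, current
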