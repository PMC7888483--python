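"""Run configuration: a single YAML file in the units of the experimental
literature (mW/mm^2, ms, nA, pC), converted to SI on load.

An empty file (or missing section) yields the tabulated default
parameters; unknown keys are rejected so silent typos cannot change a
simulation.  ``dump_config(load_config(path))`` is a normalizing
round-trip, and ``config_hash`` gives a short digest that output files
embed for provenance.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import yaml

from .channel import ChannelParams
from .network import NetworkConfig
from .neuron import NeuronParams, OUParams
from .protocols import StimulusProtocol

__all__ = ["RunConfig", "load_config", "loads_config", "dump_config",
           "config_hash"]

# (yaml key, dataclass field, scale yaml->SI) per section
_CHANNEL_KEYS = [
    ("lambda_max_nm", "lambda_max", 1e-9),
    ("sigma_ret_m2", "sigma_ret", 1.0),
    ("w_loss", "w_loss", 1.0),
    ("g_chr2_fS", "g_ChR2", 1e-15),
    ("gamma_d0_per_s", "Gamma_d0", 1.0),
    ("gamma_r_per_s", "Gamma_r", 1.0),
    ("epsilon", "epsilon", 1.0),
    ("tau_chr2_ms", "tau_ChR2", 1e-3),
    ("e_chr2_mV", "E_ChR2", 1e-3),
    ("n_chr2", "N_ChR2", None),  # integer, no scaling
]
_NEURON_KEYS = [
    ("tau_m_ms", "tau_m", 1e-3),
    ("g_m_uS", "g_m", 1e-6),
    ("v_rev_mV", "V_rev", 1e-3),
    ("v_reset_mV", "V_reset", 1e-3),
    ("v_th_mV", "V_th", 1e-3),
    ("tau_ref_ms", "tau_ref", 1e-3),
]
_OU_KEYS = [
    ("tau_syn_ms", "tau_syn", 1e-3),
    ("i0_nA", "I_0", 1e-9),
    ("sigma_wn_nA", "sigma_wn", 1e-9),
]
_PROTOCOL_KEYS = [
    ("f_hz", "f", 1.0),
    ("t_pulse_ms", "t_pulse", 1e-3),
    ("e_hat_mw_mm2", "E_hat", 1e3),  # 1 mW/mm^2 = 1000 W/m^2
    ("sigma_light", "sigma_light", 1.0),
    ("t_on_ms", "t_on", 1e-3),
    ("t_off_ms", "t_off", 1e-3),
    ("spatial", "spatial", None),
]
_NETWORK_KEYS = [
    ("n_e", "N_E", None),
    ("n_i", "N_I", None),
    ("p_c", "p_c", 1.0),
    ("j_ee_pC", ("J", 0, 0), 1e-12),
    ("j_ei_pC", ("J", 0, 1), 1e-12),
    ("j_ie_pC", ("J", 1, 0), 1e-12),
    ("j_ii_pC", ("J", 1, 1), 1e-12),
    ("tau_syn_ms", "tau_syn", 1e-3),
    ("expression_e", "expression_E", None),
    ("seed_connectivity", "seed_connectivity", None),
    ("seed_noise", "seed_noise", None),
]
_RUN_KEYS = ["dt_ms", "t_max_s", "n_trials", "seed", "onset_skip_ms", "outdir"]


@dataclass
class RunConfig:
    """Fully validated parameter set for one experiment."""

    channel: ChannelParams = field(default_factory=ChannelParams)
    neuron: NeuronParams = field(default_factory=NeuronParams)
    ou: OUParams = field(default_factory=OUParams)
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    dt: float = 1e-5  # s; 0.01 ms single neuron, use 0.1 ms for networks
    t_max: float = 20.0  # s
    n_trials: int = 1
    seed: int = 1
    onset_skip: float = 0.1  # s
    outdir: str = "out"

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.t_max <= 0:
            raise ValueError("dt and t_max must be > 0")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


def _build_section(cls, section: dict, keys, section_name: str):
    kwargs = {}
    j = None
    for key, value in section.items():
        spec = next((s for s in keys if s[0].lower() == key.lower()), None)
        if spec is None:
            raise ValueError(f"unknown key '{key}' in section '{section_name}'")
        _, target, scale = spec
        if isinstance(target, tuple):  # coupling-matrix entry
            if j is None:
                j = [list(r) for r in NetworkConfig().J]
            j[target[1]][target[2]] = float(value) * scale
        elif scale is None:
            kwargs[target] = value
        else:
            if key.lower() == "t_off_ms" and value is None:
                kwargs[target] = math.inf
            else:
                kwargs[target] = float(value) * scale
    if j is not None:
        kwargs["J"] = tuple(tuple(r) for r in j)
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as err:
        raise ValueError(f"invalid section '{section_name}': {err}") from err


def loads_config(text: str) -> RunConfig:
    """Parse a YAML configuration string into a validated :class:`RunConfig`."""
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    known = {"channel", "neuron", "ou", "protocol", "network", "run"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    cfg = {}
    cfg["channel"] = _build_section(ChannelParams, data.get("channel") or {},
                                    _CHANNEL_KEYS, "channel")
    cfg["neuron"] = _build_section(NeuronParams, data.get("neuron") or {},
                                   _NEURON_KEYS, "neuron")
    cfg["ou"] = _build_section(OUParams, data.get("ou") or {}, _OU_KEYS, "ou")
    cfg["protocol"] = _build_section(StimulusProtocol, data.get("protocol") or {},
                                     _PROTOCOL_KEYS, "protocol")
    cfg["network"] = _build_section(NetworkConfig, data.get("network") or {},
                                    _NETWORK_KEYS, "network")
    run = data.get("run") or {}
    unknown = set(k.lower() for k in run) - set(_RUN_KEYS)
    if unknown:
        raise ValueError(f"unknown keys in section 'run': {sorted(unknown)}")
    kw = {}
    if "dt_ms" in run:
        kw["dt"] = float(run["dt_ms"]) * 1e-3
    if "t_max_s" in run:
        kw["t_max"] = float(run["t_max_s"])
    if "onset_skip_ms" in run:
        kw["onset_skip"] = float(run["onset_skip_ms"]) * 1e-3
    for k in ("n_trials", "seed"):
        if k in run:
            kw[k] = int(run[k])
    if "outdir" in run:
        kw["outdir"] = str(run["outdir"])
    return RunConfig(**cfg, **kw)


def load_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        return loads_config(fh.read())


def dump_config(cfg: RunConfig) -> dict:
    """Normalized dictionary form (literature units), suitable for YAML."""
    j = [[v / 1e-12 for v in row] for row in cfg.network.J]
    t_off = cfg.protocol.t_off
    return {
        "channel": {
            "lambda_max_nm": cfg.channel.lambda_max / 1e-9,
            "sigma_ret_m2": cfg.channel.sigma_ret,
            "w_loss": cfg.channel.w_loss,
            "g_chr2_fS": cfg.channel.g_ChR2 / 1e-15,
            "gamma_d0_per_s": cfg.channel.Gamma_d0,
            "gamma_r_per_s": cfg.channel.Gamma_r,
            "epsilon": cfg.channel.epsilon,
            "tau_chr2_ms": cfg.channel.tau_ChR2 / 1e-3,
            "e_chr2_mV": cfg.channel.E_ChR2 / 1e-3,
            "n_chr2": cfg.channel.N_ChR2,
        },
        "neuron": {
            "tau_m_ms": cfg.neuron.tau_m / 1e-3,
            "g_m_uS": cfg.neuron.g_m / 1e-6,
            "v_rev_mV": cfg.neuron.V_rev / 1e-3,
            "v_reset_mV": cfg.neuron.V_reset / 1e-3,
            "v_th_mV": cfg.neuron.V_th / 1e-3,
            "tau_ref_ms": cfg.neuron.tau_ref / 1e-3,
        },
        "ou": {
            "tau_syn_ms": cfg.ou.tau_syn / 1e-3,
            "i0_nA": cfg.ou.I_0 / 1e-9,
            "sigma_wn_nA": cfg.ou.sigma_wn / 1e-9,
        },
        "protocol": {
            "f_hz": cfg.protocol.f,
            "t_pulse_ms": cfg.protocol.t_pulse / 1e-3,
            "e_hat_mw_mm2": cfg.protocol.E_hat / 1e3,
            "sigma_light": cfg.protocol.sigma_light,
            "t_on_ms": cfg.protocol.t_on / 1e-3,
            "t_off_ms": None if math.isinf(t_off) else t_off / 1e-3,
            "spatial": cfg.protocol.spatial,
        },
        "network": {
            "n_e": cfg.network.N_E,
            "n_i": cfg.network.N_I,
            "p_c": cfg.network.p_c,
            "j_ee_pC": j[0][0],
            "j_ei_pC": j[0][1],
            "j_ie_pC": j[1][0],
            "j_ii_pC": j[1][1],
            "tau_syn_ms": cfg.network.tau_syn / 1e-3,
            "expression_e": cfg.network.expression_E,
            "seed_connectivity": cfg.network.seed_connectivity,
            "seed_noise": cfg.network.seed_noise,
        },
        "run": {
            "dt_ms": cfg.dt / 1e-3,
            "t_max_s": cfg.t_max,
            "n_trials": cfg.n_trials,
            "seed": cfg.seed,
            "onset_skip_ms": cfg.onset_skip / 1e-3,
            "outdir": cfg.outdir,
        },
    }


def config_hash(cfg: RunConfig) -> str:
    """Short stable digest of the normalized configuration."""
    payload = json.dumps(dump_config(cfg), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
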