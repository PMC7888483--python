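"""Plain-text output formats.

Spike trains: one line per neuron, ``neuron_id<TAB>t1 t2 ...`` with times
in milliseconds.  Traces and sweep tables are CSV with a header row;
structured records are JSON.  Every file starts with ``#``-prefixed
metadata lines (config hash, seed, package version) so a run can be
reproduced exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = [
    "metadata_header",
    "write_spike_trains",
    "read_spike_trains",
    "write_csv",
    "write_network_rates",
    "write_records_json",
]


def metadata_header(**meta) -> str:
    from . import __version__
    lines = [f"# chr2net {__version__}"]
    lines += [f"# {k}: {v}" for k, v in meta.items()]
    return "\n".join(lines) + "\n"


def write_spike_trains(path, trains, **meta) -> None:
    """Write per-neuron spike times (seconds in, milliseconds on disk)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(metadata_header(**meta))
        for neuron_id, train in enumerate(trains):
            times = " ".join(f"{t * 1e3:.3f}" for t in np.asarray(train))
            fh.write(f"{neuron_id}\t{times}\n")


def read_spike_trains(path) -> list[np.ndarray]:
    """Read spike trains back as arrays of times in seconds."""
    trains = {}
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            head, _, rest = line.partition("\t")
            neuron_id = int(head)
            values = np.array([float(v) for v in rest.split()]) * 1e-3
            trains[neuron_id] = values
    return [trains[k] for k in sorted(trains)]


def write_csv(path, columns: dict, **meta) -> None:
    """Write named columns as CSV with a metadata preamble."""
    path = Path(path)
    names = list(columns)
    arrays = [np.asarray(columns[n]) for n in names]
    with path.open("w", encoding="utf-8") as fh:
        fh.write(metadata_header(**meta))
        fh.write(",".join(names) + "\n")
        for row in zip(*arrays):
            fh.write(",".join(_fmt(v) for v in row) + "\n")


def _fmt(v) -> str:
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    return f"{float(v):.10g}"


def write_network_rates(path, result, **meta) -> None:
    """Per-excitatory-neuron time-averaged rates with grid position and
    signed center distance, as CSV."""
    n_e = result.config.N_E
    write_csv(path, {
        "neuron_id": np.arange(n_e),
        "x": result.positions[:, 0].astype(int),
        "y": result.positions[:, 1].astype(int),
        "signed_r": result.signed_r,
        "rate_hz": result.rates[:n_e],
    }, **meta)


def write_records_json(path, records, **meta) -> None:
    """Write a list of dict records (PulseStats, SpatialFit, ...) as JSON."""
    payload = {"meta": meta, "records": records}
    Path(path).write_text(json.dumps(payload, indent=1, default=_jsonable),
                          encoding="utf-8")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dict__"):
        return obj.__dict__
    raise TypeError(f"not JSON-serializable: {type(obj)}")
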