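"""Snapshots, text output formats and run manifests.

Spike rasters and weight matrices are plain delimited text so that runs can
be inspected and parsed back with standard tools; the full-state snapshot is
a single binary container (versioned and checksummed) because it must round
trip bit-exactly, including RNG states.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SnapshotError",
    "save_snapshot",
    "load_snapshot",
    "write_raster",
    "read_raster",
    "write_weight_matrix",
    "read_weight_matrix",
    "write_synapse_trace",
    "RunManifest",
]

_MAGIC = b"STCNETSNAP\n"
_VERSION = 1


class SnapshotError(IOError):
    """Snapshot file is corrupted or of an unsupported version."""


def save_snapshot(path, state: dict, meta: dict | None = None) -> None:
    """Write a complete network state to a checksummed container file."""
    buf = _io.BytesIO()
    np.savez(buf, **state)
    payload = buf.getvalue()
    header = json.dumps({
        "version": _VERSION,
        "sha256": hashlib.sha256(payload).hexdigest(),
        "meta": meta or {},
    }).encode() + b"\n"
    Path(path).write_bytes(_MAGIC + header + payload)


def load_snapshot(path) -> tuple[dict, dict]:
    """Read a snapshot container; returns ``(state, meta)``.

    Raises :class:`SnapshotError` on a bad magic number, version mismatch or
    checksum failure.
    """
    raw = Path(path).read_bytes()
    if not raw.startswith(_MAGIC):
        raise SnapshotError("not a snapshot file")
    rest = raw[len(_MAGIC):]
    nl = rest.index(b"\n")
    try:
        header = json.loads(rest[:nl])
    except json.JSONDecodeError:
        raise SnapshotError("corrupted snapshot header") from None
    if header.get("version") != _VERSION:
        raise SnapshotError(f"unsupported snapshot version "
                            f"{header.get('version')}")
    payload = rest[nl + 1:]
    if hashlib.sha256(payload).hexdigest() != header["sha256"]:
        raise SnapshotError("snapshot checksum mismatch")
    with np.load(_io.BytesIO(payload)) as npz:
        state = {k: npz[k] for k in npz.files}
    return state, header.get("meta", {})


def write_raster(path, spike_log, header: dict | None = None) -> None:
    """Two-column tab-delimited raster: time (s, µs resolution), neuron id."""
    times, ids = spike_log
    with open(path, "w") as f:
        if header:
            f.write("# " + json.dumps(header) + "\n")
        f.write("# time_s\tneuron\n")
        for t, i in zip(times, ids):
            f.write(f"{t:.6f}\t{int(i)}\n")


def read_raster(path) -> tuple[np.ndarray, np.ndarray]:
    data = np.loadtxt(path, ndmin=2, comments="#")
    if data.size == 0:
        return np.empty(0), np.empty(0, np.int32)
    return data[:, 0], data[:, 1].astype(np.int32)


def write_weight_matrix(path, W: np.ndarray) -> None:
    """Dense weight matrix (rows presynaptic, nC); absent synapses as nan.

    Tab-delimited text with 9 significant digits by default; a ``.npz``
    suffix selects the compact binary container for large runs.
    """
    if str(path).endswith(".npz"):
        np.savez_compressed(path, W=W)
    else:
        np.savetxt(path, W, fmt="%.9g", delimiter="\t")


def read_weight_matrix(path) -> np.ndarray:
    if str(path).endswith(".npz"):
        with np.load(path) as npz:
            return npz["W"]
    return np.loadtxt(path, ndmin=2)


def write_synapse_trace(path, monitor: np.ndarray, h_0: float) -> None:
    """Delimited text trace of monitored synapses.

    ``monitor`` is the sample array returned by ``Network.advance`` /
    ``fast_forward`` monitoring: one row per sampling instant,
    ``[t, (h, z, c, p) ...]``.  Columns per synapse: h_nC, z, c, p_post and
    the total weight ``h + h_0 z``.
    """
    n_syn = (monitor.shape[1] - 1) // 4
    cols = [monitor[:, :1]]
    header = ["time_s"]
    for m in range(n_syn):
        h = monitor[:, 1 + 4 * m]
        z = monitor[:, 2 + 4 * m]
        cols.append(np.column_stack([h, z, monitor[:, 3 + 4 * m],
                                     monitor[:, 4 + 4 * m], h + h_0 * z]))
        header += [f"h{m}_nC", f"z{m}", f"c{m}", f"p{m}_post",
                   f"w{m}_total_nC"]
    np.savetxt(path, np.hstack(cols), fmt="%.9g", delimiter="\t",
               header="\t".join(header))


@dataclass
class RunManifest:
    """Provenance of one run: seeds, configuration digest, schedule."""

    master_seed: int
    config_digest: str
    command: str = ""
    schedule: list = field(default_factory=list)
    code_version: str = ""
    wall_time_s: float = 0.0
    created: str = field(
        default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")
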