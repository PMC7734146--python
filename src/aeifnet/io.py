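"""Plain-text I/O for spike trains, current series and configurations.

Spike files are two-column ASCII, ``neuron_id<TAB>spike_time_ms``,
sorted by time, with ``#`` header comments carrying provenance (config
hash, seed) and the neuron metadata needed to rebuild a
:class:`~aeifnet.diagnostics.SpikeData` (population split, autaptic
ids).  Neuron ids are 1-based in files.  Current files are
``time_ms<TAB>I_chem_pA``.
"""

from __future__ import annotations


import numpy as np
import yaml

from .diagnostics import SpikeData
from .network import NetworkConfig

__all__ = [
    "write_spikes",
    "read_spikes",
    "write_current",
    "read_current",
    "write_config",
    "read_config",
]


def write_spikes(path, spikes: SpikeData, meta: dict | None = None) -> None:
    ids = np.concatenate(
        [np.full(t.size, j + 1, dtype=np.int64) for j, t in enumerate(spikes.trains)]
        or [np.empty(0, np.int64)]
    )
    times = np.concatenate([t for t in spikes.trains] or [np.empty(0)])
    order = np.lexsort((ids, times))
    with open(path, "w") as fh:
        fh.write("# aeifnet spikes v1\n")
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        fh.write(f"# n_neurons: {spikes.n}\n")
        fh.write(f"# n_exc: {int(spikes.is_exc.sum())}\n")
        aut = ",".join(str(i + 1) for i in np.nonzero(spikes.autaptic)[0])
        fh.write(f"# autaptic: {aut}\n")
        fh.write("neuron_id\tspike_time_ms\n")
        for i in order:
            fh.write(f"{ids[i]}\t{times[i]:.6f}\n")


def read_spikes(path) -> tuple[SpikeData, dict]:
    meta: dict = {}
    ids, times = [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            if not line or line.startswith("neuron_id"):
                continue
            a, b = line.split("\t")
            ids.append(int(a) - 1)
            times.append(float(b))
    n = int(meta.get("n_neurons", (max(ids) + 1) if ids else 0))
    n_exc = int(meta.get("n_exc", n))
    is_exc = np.zeros(n, dtype=bool)
    is_exc[:n_exc] = True
    autaptic = np.zeros(n, dtype=bool)
    if meta.get("autaptic"):
        autaptic[[int(s) - 1 for s in meta["autaptic"].split(",") if s]] = True
    spikes = SpikeData.from_flat(ids, times, n=n, is_exc=is_exc, autaptic=autaptic)
    return spikes, meta


def write_current(path, t, I, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("# aeifnet mean synaptic current v1\n")
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        fh.write("time_ms\tI_chem_pA\n")
        for ti, Ii in zip(np.asarray(t), np.asarray(I)):
            fh.write(f"{ti:.6f}\t{Ii:.8g}\n")


def read_current(path) -> tuple[np.ndarray, np.ndarray, dict]:
    meta: dict = {}
    t, I = [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            if not line or line.startswith("time_ms"):
                continue
            a, b = line.split("\t")
            t.append(float(a))
            I.append(float(b))
    return np.asarray(t), np.asarray(I), meta


def write_config(path, config: NetworkConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def read_config(path) -> NetworkConfig:
    with open(path) as fh:
        return NetworkConfig.from_dict(yaml.safe_load(fh))
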