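"""Run containers (HDF5) and declarative configuration files (YAML).

A *run container* bundles everything one simulation produced: the LFP, the
spike raster, the JSON-serialized configuration, and the RNG provenance.
Schema (HDF5):

* ``/lfp`` — float64 vector, μV; attrs ``fs`` (Hz), ``t_start`` (ms)
* ``/spikes/cell_id``, ``/spikes/time_ms`` — parallel vectors (ragged raster
  flattened); ``/spikes`` attrs carry the role of every cell
* ``/config_json`` — the configuration as a JSON string
* ``/rng`` — attrs ``master_seed``, ``config_hash``
* root attrs: ``schema_version``, ``scaled`` (non-canonical fast-mode flag)
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import h5py
import numpy as np
import yaml

from .lfp import LFPSignal
from .network import NetworkConfig, SpikeRaster, SynapseParams

SCHEMA_VERSION = 1


def config_hash(config_json: str) -> str:
    """Short stable digest used for provenance."""
    return hashlib.sha256(config_json.encode()).hexdigest()[:16]


def save_run(
    path: str | Path,
    lfp: LFPSignal,
    raster: SpikeRaster | None = None,
    config_json: str = "{}",
    seed: int = 0,
    scaled: bool = False,
) -> None:
    """Write a simulation run container."""
    with h5py.File(path, "w") as fh:
        fh.attrs["schema_version"] = SCHEMA_VERSION
        fh.attrs["scaled"] = bool(scaled)
        d = fh.create_dataset("lfp", data=np.asarray(lfp.samples))
        d.attrs["fs"] = lfp.fs
        d.attrs["t_start"] = lfp.t_start
        grp = fh.create_group("spikes")
        if raster is not None:
            cell_ids = np.concatenate(
                [np.full(len(t), i, dtype=np.int32) for i, t in enumerate(raster.spike_times)]
            ) if raster.spike_times else np.empty(0, np.int32)
            times = (
                np.concatenate([np.asarray(t) for t in raster.spike_times])
                if raster.spike_times
                else np.empty(0)
            )
            grp.create_dataset("cell_id", data=cell_ids)
            grp.create_dataset("time_ms", data=times)
            grp.attrs["roles"] = json.dumps(list(raster.roles))
            grp.attrs["n_cells"] = len(raster.spike_times)
            grp.attrs["duration_ms"] = raster.duration_ms
        fh.create_dataset("config_json", data=config_json)
        rng = fh.create_group("rng")
        rng.attrs["master_seed"] = seed
        rng.attrs["config_hash"] = config_hash(config_json)


def load_run(path: str | Path) -> dict:
    """Read a run container back into plain objects."""
    out: dict = {}
    with h5py.File(path, "r") as fh:
        d = fh["lfp"]
        out["lfp"] = LFPSignal(d[()], float(d.attrs["fs"]), float(d.attrs["t_start"]))
        out["config_json"] = fh["config_json"][()].decode()
        out["seed"] = int(fh["rng"].attrs["master_seed"])
        out["config_hash"] = str(fh["rng"].attrs["config_hash"])
        out["scaled"] = bool(fh.attrs["scaled"])
        grp = fh["spikes"]
        if "cell_id" in grp:
            n = int(grp.attrs["n_cells"])
            roles = tuple(json.loads(grp.attrs["roles"]))
            ids = grp["cell_id"][()]
            times = grp["time_ms"][()]
            trains = tuple(np.sort(times[ids == i]) for i in range(n))
            out["raster"] = SpikeRaster(trains, roles, float(grp.attrs["duration_ms"]))
    return out


def save_raster_text(raster: SpikeRaster, path: str | Path) -> None:
    """Raster export: delimited text (cell_id, spike_time_ms, role)."""
    with open(path, "w") as fh:
        fh.write("# cell_id\tspike_time_ms\trole\n")
        for i, (train, role) in enumerate(zip(raster.spike_times, raster.roles)):
            for t in train:
                fh.write(f"{i}\t{t:.6g}\t{role}\n")


def _to_plain(obj):
    if is_dataclass(obj):
        return {k: _to_plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def save_network_config(cfg: NetworkConfig, path: str | Path) -> None:
    """Write a network configuration as a versioned YAML document."""
    doc = {"schema_version": SCHEMA_VERSION, "network": _to_plain(cfg)}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_network_config(path: str | Path) -> NetworkConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported config schema_version: {doc.get('schema_version')}")
    raw = dict(doc["network"])
    for key in ("gaba", "ampa_feedback", "ampa_noise", "ampa_noise_basket"):
        if key in raw and isinstance(raw[key], dict):
            raw[key] = SynapseParams(**raw[key])
    return NetworkConfig(**raw)


def save_psd_text(psd, path: str | Path) -> None:
    """PSD as two-column delimited text (freq_hz, power)."""
    np.savetxt(path, np.column_stack([psd.freqs, psd.power]),
               header=f"method={psd.method}\nfreq_hz\tpower", delimiter="\t", fmt="%.9g")


def save_spectrogram(spec, path: str | Path) -> None:
    """Spectrogram to an HDF5 file: /times, /freqs, /power."""
    with h5py.File(path, "w") as fh:
        fh.attrs["schema_version"] = SCHEMA_VERSION
        fh.attrs["window_sd_ms"] = spec.window_sd
        fh.create_dataset("times", data=spec.times)
        fh.create_dataset("freqs", data=spec.freqs)
        fh.create_dataset("power", data=spec.power)


def load_spectrogram(path: str | Path):
    from .spectral import Spectrogram

    with h5py.File(path, "r") as fh:
        return Spectrogram(
            times=fh["times"][()],
            freqs=fh["freqs"][()],
            power=fh["power"][()],
            window_sd=float(fh.attrs["window_sd_ms"]),
        )


def save_phase_histogram(hist, path: str | Path) -> None:
    """Phase histogram as delimited text (bin_center_rad, count)."""
    np.savetxt(
        path,
        np.column_stack([hist.bin_centers, hist.counts]),
        header=f"label={hist.label} n_episodes={hist.n_episodes}\nbin_center_rad\tcount",
        delimiter="\t",
        fmt="%.9g",
    )


def sweep_result_table(result) -> str:
    """Flatten a SweepResult into a delimited-text table (one row per
    grid point, columns = params then stat means and SEMs)."""
    rows = []
    param_keys = sorted({k for p in result.points for k in p["params"]})
    stat_keys = sorted({k for p in result.points for k in p["stats"]})
    header = param_keys + [f"{k}_mean" for k in stat_keys] + [f"{k}_sem" for k in stat_keys]
    rows.append("\t".join(header))
    for p in result.points:
        cells = [str(p["params"].get(k, "")) for k in param_keys]
        cells += [f"{p['stats'][k][0]:.9g}" if k in p["stats"] else "" for k in stat_keys]
        cells += [f"{p['stats'][k][1]:.9g}" if k in p["stats"] else "" for k in stat_keys]
        rows.append("\t".join(cells))
    return "\n".join(rows) + "\n"
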