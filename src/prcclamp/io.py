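"""Readers and writers for the package's interchange formats.

Small tables travel as CSV; sessions and estimates travel as HDF5 with a
``schema_version`` attribute and the full configuration snapshot (JSON) plus
package version embedded in every file, so any artifact records how it was
produced.

CSV schemas
-----------
* spike trains:  columns ``source_id, time_s``
* stimulus logs: columns ``t_pulse_s, amplitude_pA, duration_s``
* summary table: one row per PRC
  (cell_id, firing_rate_Hz, r, m_e, m_l, phi_peak, tau_peak_ms, n_trials)
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .clamp import SessionLog
from .direct import Perturbation, PRCSample, RawPRC
from .smoothing import SmoothedPRC
from .spikes import SpikeTrain

SCHEMA_VERSION = "1"

__all__ = [
    "read_spike_csv", "write_spike_csv",
    "read_stimulus_csv", "write_stimulus_csv",
    "save_session", "load_session",
    "save_raw_prc", "load_raw_prc",
    "save_smoothed_prc", "load_smoothed_prc",
    "save_spikes_h5", "load_spikes_h5",
    "save_trace_h5", "load_trace_h5",
    "save_stimulus_h5", "load_stimulus_h5",
]


def _pkg_version() -> str:
    from . import __version__

    return __version__


class FormatError(ValueError):
    """Malformed input file (message names the missing/bad field)."""


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

def write_spike_csv(path, train: SpikeTrain) -> None:
    pd.DataFrame({
        "source_id": train.source_id or "cell",
        "time_s": train.spike_times,
    }).to_csv(path, index=False)


def read_spike_csv(path, source_id: str | None = None) -> SpikeTrain:
    df = pd.read_csv(path)
    _require_columns(df, ["source_id", "time_s"], path)
    if source_id is not None:
        df = df[df["source_id"] == source_id]
        if df.empty:
            raise FormatError(f"{path}: no rows with source_id={source_id!r}")
    sid = str(df["source_id"].iloc[0]) if len(df) else ""
    return SpikeTrain(df["time_s"].to_numpy(dtype=float), source_id=sid)


def write_stimulus_csv(path, pulses) -> None:
    pd.DataFrame({
        "t_pulse_s": [p.t_pulse for p in pulses],
        "amplitude_pA": [p.amplitude for p in pulses],
        "duration_s": [p.duration for p in pulses],
    }).to_csv(path, index=False)


def read_stimulus_csv(path) -> list:
    df = pd.read_csv(path)
    _require_columns(df, ["t_pulse_s", "amplitude_pA", "duration_s"], path)
    return [
        Perturbation(float(r.t_pulse_s), float(r.amplitude_pA), float(r.duration_s))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# HDF5
# ---------------------------------------------------------------------------

def _stamp(group, config: dict | None = None) -> None:
    group.attrs["schema_version"] = SCHEMA_VERSION
    group.attrs["package_version"] = _pkg_version()
    if config is not None:
        group.attrs["config_json"] = json.dumps(config, default=str)


def save_session(path, log: SessionLog) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("session")
        _stamp(g, log.config)
        for name, df in (("spikes", log.spikes), ("pulses", log.pulses)):
            sub = g.create_group(name)
            for col in df.columns:
                sub.create_dataset(col, data=df[col].to_numpy())


def load_session(path) -> SessionLog:
    with h5py.File(path, "r") as f:
        if "session" not in f:
            raise FormatError(f"{path}: missing /session group")
        g = f["session"]
        frames = {}
        for name in ("spikes", "pulses"):
            if name not in g:
                raise FormatError(f"{path}: missing /session/{name}")
            sub = g[name]
            frames[name] = pd.DataFrame({c: sub[c][...] for c in sub})
        config = json.loads(g.attrs.get("config_json", "{}"))
    return SessionLog(spikes=frames["spikes"], pulses=frames["pulses"], config=config)


def save_raw_prc(path, raw: RawPRC, config: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("raw_prc")
        _stamp(g, config)
        g.attrs["mean_isi"] = raw.mean_isi
        g.attrs["charge"] = raw.charge
        g.attrs["n_trials"] = raw.n_trials
        g.attrs["skip_log_json"] = json.dumps(dict(raw.skip_log))
        g.create_dataset("phi", data=raw.phi)
        g.create_dataset("z", data=raw.z)
        g.create_dataset("order", data=raw.order)
        g.create_dataset("trial_id",
                         data=np.array([s.trial_id for s in raw.samples]))


def load_raw_prc(path) -> RawPRC:
    from collections import Counter

    with h5py.File(path, "r") as f:
        if "raw_prc" not in f:
            raise FormatError(f"{path}: missing /raw_prc group")
        g = f["raw_prc"]
        phi = g["phi"][...]
        z = g["z"][...]
        order = g["order"][...]
        tid = g["trial_id"][...]
        samples = [
            PRCSample(phi=float(p), z=float(zz), order=int(o), trial_id=int(t))
            for p, zz, o, t in zip(phi, z, order, tid)
        ]
        return RawPRC(
            samples=samples,
            mean_isi=float(g.attrs["mean_isi"]),
            charge=float(g.attrs["charge"]),
            n_trials=int(g.attrs["n_trials"]),
            skip_log=Counter(json.loads(g.attrs.get("skip_log_json", "{}"))),
        )


def save_smoothed_prc(path, curve: SmoothedPRC, config: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("smoothed_prc")
        _stamp(g, config)
        g.attrs["bandwidth"] = curve.bandwidth
        g.attrs["n_samples"] = curve.n_samples
        g.create_dataset("phi_grid", data=curve.phi_grid)
        g.create_dataset("z_smooth", data=curve.z_smooth)
        if curve.ci68_lo is not None:
            g.create_dataset("ci68_lo", data=curve.ci68_lo)
            g.create_dataset("ci68_hi", data=curve.ci68_hi)


def load_smoothed_prc(path) -> SmoothedPRC:
    with h5py.File(path, "r") as f:
        if "smoothed_prc" not in f:
            raise FormatError(f"{path}: missing /smoothed_prc group")
        g = f["smoothed_prc"]
        return SmoothedPRC(
            phi_grid=g["phi_grid"][...],
            z_smooth=g["z_smooth"][...],
            bandwidth=float(g.attrs["bandwidth"]),
            ci68_lo=g["ci68_lo"][...] if "ci68_lo" in g else None,
            ci68_hi=g["ci68_hi"][...] if "ci68_hi" in g else None,
            n_samples=int(g.attrs["n_samples"]),
        )


def save_spikes_h5(path, train: SpikeTrain, mode: str = "a") -> None:
    """Store a spike train at /spikes/<source_id>."""
    with h5py.File(path, mode) as f:
        g = f.require_group("spikes")
        name = train.source_id or "cell"
        if name in g:
            del g[name]
        d = g.create_dataset(name, data=train.spike_times)
        d.attrs["units"] = "s"
        _stamp(g)


def load_spikes_h5(path, source_id: str = "cell") -> SpikeTrain:
    with h5py.File(path, "r") as f:
        key = f"spikes/{source_id}"
        if key not in f:
            raise FormatError(f"{path}: missing /{key}")
        return SpikeTrain(f[key][...], source_id=source_id)


def save_trace_h5(path, trace, trace_id: str = "trace", mode: str = "a") -> None:
    """Store a voltage trace at /traces/<id> with sample_rate and units attrs."""
    with h5py.File(path, mode) as f:
        g = f.require_group("traces")
        if trace_id in g:
            del g[trace_id]
        d = g.create_dataset(trace_id, data=trace.values)
        d.attrs["sample_rate"] = trace.sample_rate
        d.attrs["t0"] = trace.t0
        d.attrs["units"] = "mV"
        _stamp(g)


def load_trace_h5(path, trace_id: str = "trace"):
    from .spikes import VoltageTrace

    with h5py.File(path, "r") as f:
        key = f"traces/{trace_id}"
        if key not in f:
            raise FormatError(f"{path}: missing /{key}")
        d = f[key]
        return VoltageTrace(d[...], float(d.attrs["sample_rate"]),
                            t0=float(d.attrs.get("t0", 0.0)))


def save_stimulus_h5(path, stim, stim_id: str = "ou", mode: str = "a") -> None:
    """Store an OU stimulus trace with its (dt, s, tau_i, offset, seed) attrs."""
    with h5py.File(path, mode) as f:
        g = f.require_group("stimuli")
        if stim_id in g:
            del g[stim_id]
        d = g.create_dataset(stim_id, data=stim.values)
        for k in ("dt", "s", "tau_i", "offset", "seed"):
            d.attrs[k] = getattr(stim, k)
        d.attrs["units"] = "pA"
        _stamp(g)


def load_stimulus_h5(path, stim_id: str = "ou"):
    from .wsta import OUStimulus

    with h5py.File(path, "r") as f:
        key = f"stimuli/{stim_id}"
        if key not in f:
            raise FormatError(f"{path}: missing /{key}")
        d = f[key]
        return OUStimulus(d[...], float(d.attrs["dt"]), float(d.attrs["s"]),
                          float(d.attrs["tau_i"]), float(d.attrs["offset"]),
                          int(d.attrs["seed"]))
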