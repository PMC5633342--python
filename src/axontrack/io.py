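"""HDF5 recording container, footprint storage, tables and run configuration.

Container layout (schema ``axontrack-recording`` version 1)::

    /traces        float32/float64, (electrodes, samples), microvolts
    /electrodes    datasets id, x, y (micrometers)
    /stim          optional: trial, time_s, voltage_mv, episode, pulse_index
    attrs          fs (Hz), schema, schema_version, metadata (JSON)

All tabular outputs (ground truth, events, kinetics) are plain CSV.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd
import yaml

from .footprint import Footprint, Template
from .recording import Recording

SCHEMA = "axontrack-recording"
SCHEMA_VERSION = 1

_STIM_COLUMNS = ["trial", "time_s", "voltage_mv", "episode", "pulse_index"]


class SchemaError(ValueError):
    """The file does not follow the documented container layout."""


def write_recording(recording: Recording, path) -> str:
    path = str(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = SCHEMA
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["fs"] = float(recording.fs)
        f.attrs["metadata"] = json.dumps(recording.metadata, default=str)
        f.create_dataset("traces", data=recording.traces)
        grp = f.create_group("electrodes")
        n = recording.n_electrodes
        grp.create_dataset("id", data=np.arange(n))
        if recording.positions is None:
            raise SchemaError("recording has no electrode table; cannot serialize")
        grp.create_dataset("x", data=recording.positions[:, 0])
        grp.create_dataset("y", data=recording.positions[:, 1])
        if recording.stim is not None:
            sg = f.create_group("stim")
            for col in _STIM_COLUMNS:
                sg.create_dataset(col, data=recording.stim[col].to_numpy(dtype=float))
    return path


def read_recording(path) -> Recording:
    with h5py.File(str(path), "r") as f:
        schema = f.attrs.get("schema")
        if schema != SCHEMA:
            raise SchemaError(f"not an {SCHEMA} file (schema attribute: {schema!r})")
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise SchemaError(f"unsupported schema version {version}")
        for required in ("traces", "electrodes"):
            if required not in f:
                raise SchemaError(f"missing dataset {required!r}")
        for axis in ("x", "y"):
            if axis not in f["electrodes"]:
                raise SchemaError(f"electrode table lacks field {axis!r}")
        traces = f["traces"][...]
        positions = np.column_stack([f["electrodes"]["x"][...], f["electrodes"]["y"][...]])
        stim = None
        if "stim" in f:
            stim = pd.DataFrame({col: f["stim"][col][...] for col in _STIM_COLUMNS})
        metadata = json.loads(f.attrs.get("metadata", "{}"))
        fs = float(f.attrs["fs"])
    return Recording(traces=traces, fs=fs, positions=positions, stim=stim, metadata=metadata)


def write_footprint(footprint: Footprint, path) -> str:
    path = str(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = "axontrack-footprint"
        f.attrs["schema_version"] = 1
        if footprint.ais_electrode is not None:
            f.attrs["ais_electrode"] = int(footprint.ais_electrode)
        electrodes = sorted(footprint.templates)
        first = footprint.templates[electrodes[0]]
        f.attrs["fs"] = first.fs
        f.attrs["t0_offset_s"] = first.t0_offset_s
        f.create_dataset("electrode", data=np.asarray(electrodes))
        f.create_dataset("n_trials", data=np.asarray(
            [footprint.templates[e].n_trials for e in electrodes]))
        f.create_dataset("waveforms", data=np.stack(
            [footprint.templates[e].waveform for e in electrodes]))
    return path


def read_footprint(path) -> Footprint:
    with h5py.File(str(path), "r") as f:
        if f.attrs.get("schema") != "axontrack-footprint":
            raise SchemaError("not an axontrack-footprint file")
        electrodes = f["electrode"][...]
        n_trials = f["n_trials"][...]
        waveforms = f["waveforms"][...]
        fs = float(f.attrs["fs"])
        t0 = float(f.attrs["t0_offset_s"])
        ais = int(f.attrs["ais_electrode"]) if "ais_electrode" in f.attrs else None
    templates = {
        int(e): Template(waveform=w, fs=fs, n_trials=int(n), t0_offset_s=t0)
        for e, n, w in zip(electrodes, n_trials, waveforms)
    }
    return Footprint(templates=templates, ais_electrode=ais)


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with its default.

    Round-trips losslessly through YAML; the defaults reproduce the
    standard benchmark protocol without overrides.
    """

    seed: int = 0
    fs: float = 20_000.0
    pitch_um: float = 17.8
    trial_window_s: float = 0.010
    trial_t0_s: float = 0.003
    waveform_ms: float = 2.0
    # footprint
    ais_threshold_sigmas: float = 5.0
    trigger_dead_time_s: float = 0.002
    trigger_align: str = "peak"
    sta_pre_s: float = 0.003
    sta_window_s: float = 0.010
    n_training_trials: int = 40
    # matched filter
    group_floor_sigmas: float = 2.0
    filter_min_ms: float = 1.0
    filter_max_ms: float = 3.0
    filter_support_sigmas: float = 0.5
    whitening: str = "full"  # or "spatial"
    ridge: float = 1e-3
    prior_ratio: float = 1.0
    detect_dead_time_s: float = 0.001
    upsample_factor: int = 10
    refine_half_window_s: float = 0.0005
    eval_tolerance_s: float = 0.001
    # kinetics
    jitter_mode: str = "std"  # or "variance"
    path_max_offset_pitches: float = 1.0

    def to_yaml(self, path) -> str:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
        return str(path)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        import hashlib

        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
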