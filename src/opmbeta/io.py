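"""On-disk containers: HDF5 recordings with a JSON sidecar for the
paradigm and planted ground truth, CSV exports for tables."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import ChannelGeometry, Paradigm, Recording

#: fixed float format so repeated runs produce byte-identical CSVs
CSV_FLOAT_FORMAT = "%.10g"


def save_recording(path: str | Path, recording: Recording, ground_truth: dict | None = None) -> None:
    """Write /data, /positions, /orientations plus fs/age/subject_id
    attributes; the paradigm (and any ground truth) goes to a JSON sidecar."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=recording.data)
        f.create_dataset("positions", data=recording.geometry.positions)
        f.create_dataset("orientations", data=recording.geometry.orientations)
        f.create_dataset(
            "labels", data=np.array(recording.geometry.labels, dtype="S")
        )
        f.attrs["fs"] = recording.fs
        f.attrs["age"] = recording.age
        f.attrs["subject_id"] = recording.subject_id
    sidecar = {
        "paradigm": {
            "n_trials_per_finger": recording.paradigm.n_trials_per_finger,
            "stim_duration": recording.paradigm.stim_duration,
            "rest_duration": recording.paradigm.rest_duration,
            "fingers": list(recording.paradigm.fingers),
            "lead_in": recording.paradigm.lead_in,
            "onsets": recording.paradigm.onsets.tolist(),
            "trial_fingers": recording.paradigm.trial_fingers,
        },
    }
    if ground_truth is not None:
        sidecar["ground_truth"] = _jsonable(ground_truth)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def load_recording(path: str | Path) -> tuple[Recording, dict]:
    path = Path(path)
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        geom = ChannelGeometry(
            positions=f["positions"][()],
            orientations=f["orientations"][()],
            labels=[s.decode() for s in f["labels"][()]],
        )
        fs = float(f.attrs["fs"])
        age = float(f.attrs["age"])
        subject_id = str(f.attrs["subject_id"])
    sidecar = json.loads(path.with_suffix(".json").read_text())
    p = sidecar["paradigm"]
    paradigm = Paradigm(
        n_trials_per_finger=p["n_trials_per_finger"],
        stim_duration=p["stim_duration"],
        rest_duration=p["rest_duration"],
        fingers=tuple(p["fingers"]),
        lead_in=p["lead_in"],
    )
    rec = Recording(
        data=data, fs=fs, geometry=geom, paradigm=paradigm,
        subject_id=subject_id, age=age,
    )
    return rec, sidecar


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def write_csv(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, float_format=CSV_FLOAT_FORMAT, index=index)
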