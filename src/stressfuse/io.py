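"""Reading and writing recordings, schedules and feature tables.

Recordings are stored as delimited text: one CSV per sampling-rate group
(``<subject>_256Hz.csv`` with FP1, FP2, T3, T4, Pz and RESP;
``<subject>_2048Hz.csv`` with BVP and SC), a schedule CSV, and a JSON
sidecar with channel metadata. Feature tables and decision tables are plain
CSV; models are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Channel, Recording, StimulusSchedule


def write_recording(recording: Recording, directory: str | Path) -> list[Path]:
    """Write a recording to delimited text; returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sid = recording.subject_id
    by_fs: dict[float, dict[str, np.ndarray]] = {}
    meta = {"subject_id": sid, "channels": {}}
    for name, ch in recording.channels.items():
        by_fs.setdefault(ch.fs, {})[name] = ch.samples
        meta["channels"][name] = {"fs": ch.fs, "modality": ch.modality}
    paths = []
    for fs, chans in sorted(by_fs.items()):
        p = directory / f"{sid}_{int(fs)}Hz.csv"
        pd.DataFrame(chans).to_csv(p, index=False, float_format="%.6g")
        paths.append(p)
    sched_path = directory / f"{sid}_schedule.csv"
    recording.schedule.to_frame().to_csv(sched_path, index=False)
    paths.append(sched_path)
    meta_path = directory / f"{sid}_meta.json"
    meta_path.write_text(json.dumps(meta, indent=1))
    paths.append(meta_path)
    return paths


def read_recording(directory: str | Path, subject_id: str) -> Recording:
    """Read a recording previously written by :func:`write_recording`."""
    directory = Path(directory)
    meta = json.loads((directory / f"{subject_id}_meta.json").read_text())
    frames: dict[int, pd.DataFrame] = {}
    channels = {}
    for name, info in meta["channels"].items():
        fs = float(info["fs"])
        if int(fs) not in frames:
            frames[int(fs)] = pd.read_csv(
                directory / f"{subject_id}_{int(fs)}Hz.csv")
        channels[name] = Channel(frames[int(fs)][name].to_numpy(),
                                 fs, info["modality"])
    schedule = StimulusSchedule.from_frame(
        pd.read_csv(directory / f"{subject_id}_schedule.csv"))
    return Recording(channels=channels, schedule=schedule,
                     subject_id=meta["subject_id"])
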