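"""Study directory layout: plain-CSV interchange for session recordings.

Layout::

    <root>/P01/in_person/free_talk/ecg.csv
                                   respiration.csv
                                   pupil.csv
                                   gaze.csv
                                   imu.csv
                                   hand.csv
                                   ground_truth.json   (optional sidecar)

Each modality CSV has a ``timestamp_s`` column plus one column per channel.
The native sampling rate is recovered from the median timestamp spacing.
An XDF-to-layout converter is a documented extension point and is not
implemented here.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .streams import Condition, Modality, SessionRecording, SignalStream, Task

MODALITY_FILES = {
    "ecg": Modality.ECG,
    "respiration": Modality.RESPIRATION,
    "pupil": Modality.PUPIL,
    "gaze": Modality.GAZE,
    "imu": Modality.IMU,
    "hand": Modality.HAND,
}


def session_dir(root: Path, participant_id: str, condition, task) -> Path:
    return Path(root) / participant_id / Condition(condition).value / Task(task).value


def write_session(rec: SessionRecording, root: Path) -> Path:
    """Write one session's streams (and ground-truth sidecar) as CSVs."""
    d = session_dir(root, rec.participant_id, rec.condition, rec.task)
    d.mkdir(parents=True, exist_ok=True)
    for name, s in rec.streams.items():
        df = pd.DataFrame({"timestamp_s": s.timestamps})
        for c, ch in enumerate(s.channel_labels):
            df[ch] = s.samples[:, c]
        df.to_csv(d / f"{name}.csv", index=False, float_format="%.6f")
    if rec.ground_truth:
        meta = {k: v for k, v in rec.ground_truth.items()}
        (d / "ground_truth.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    return d


def write_study(sessions: list[SessionRecording], root: Path) -> Path:
    root = Path(root)
    for rec in sessions:
        write_session(rec, root)
    return root


def read_stream(path: Path, modality: Modality) -> SignalStream:
    df = pd.read_csv(path)
    if "timestamp_s" not in df.columns:
        raise ValueError(f"{path} lacks a timestamp_s column")
    t = df["timestamp_s"].to_numpy(dtype=float)
    chans = [c for c in df.columns if c != "timestamp_s"]
    if len(t) > 1:
        fs = 1.0 / float(np.median(np.diff(t)))
    else:
        fs = 1.0
    return SignalStream(
        name=path.stem,
        modality=modality,
        channel_labels=chans,
        fs_native=fs,
        timestamps=t,
        samples=df[chans].to_numpy(dtype=float),
    )


def read_session(d: Path, participant_id: str, condition, task) -> SessionRecording:
    d = Path(d)
    streams = {}
    for name, modality in MODALITY_FILES.items():
        f = d / f"{name}.csv"
        if f.exists():
            streams[name] = read_stream(f, modality)
    if not streams:
        raise FileNotFoundError(f"no modality CSVs found in {d}")
    gt_file = d / "ground_truth.json"
    gt = json.loads(gt_file.read_text()) if gt_file.exists() else {}
    return SessionRecording(
        participant_id=participant_id,
        condition=condition,
        task=task,
        streams=streams,
        ground_truth=gt,
    )


def read_study(root: Path) -> list[SessionRecording]:
    """Read every session under a study root, sorted for determinism."""
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"study root {root} does not exist")
    sessions = []
    for pdir in sorted(p for p in root.iterdir() if p.is_dir()):
        for cond in Condition:
            for task in Task:
                d = pdir / cond.value / task.value
                if d.is_dir():
                    sessions.append(read_session(d, pdir.name, cond, task))
    if not sessions:
        raise FileNotFoundError(f"no sessions found under {root}")
    return sessions
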