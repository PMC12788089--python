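"""Core in-memory containers for multimodal session recordings.

A :class:`SignalStream` holds one modality at its native sampling rate on the
shared session clock (all devices are assumed to have been timestamped by a
common lab-streaming clock, possibly with small per-device offsets).  A
:class:`SessionRecording` bundles every stream recorded for one participant in
one condition and task.  :class:`AlignedSession` is the product of
preprocessing: every channel interpolated onto one uniform common-rate grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np


class Modality(str, Enum):
    ECG = "ecg"
    RESPIRATION = "respiration"
    PUPIL = "pupil"
    GAZE = "gaze"
    IMU = "imu"
    HAND = "hand"


class Condition(str, Enum):
    IN_PERSON = "in_person"
    VIRTUAL = "virtual"


class Task(str, Enum):
    READING = "reading"
    FREE_TALK = "free_talk"


#: Canonical channel labels for the six head-movement IMU axes.
IMU_AXES = ("acc_x", "acc_y", "acc_z", "gyro_roll", "gyro_pitch", "gyro_yaw")


class AlignmentError(ValueError):
    """Raised when an operation requires streams on an identical time grid."""


@dataclass
class SignalStream:
    """One timestamped multichannel recording of a single modality.

    Parameters
    ----------
    name : str
        Human-readable stream identifier (e.g. ``"ecg"``).
    modality : Modality
        Which kind of signal the samples represent.
    channel_labels : list of str
        One label per column of ``samples``.
    fs_native : float
        Nominal sampling rate in Hz.
    timestamps : ndarray, shape (n,)
        Sample times in seconds on the shared session clock; strictly
        increasing.
    samples : ndarray, shape (n, c)
        Signal values; NaN marks invalid samples (e.g. blink gaps).
    meta : dict
        Free-form ground-truth / provenance annotations (R-peak times,
        derivation notes, ...).
    """

    name: str
    modality: Modality
    channel_labels: list[str]
    fs_native: float
    timestamps: np.ndarray
    samples: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.modality = Modality(self.modality)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim == 1:
            self.samples = self.samples[:, None]
        if self.fs_native <= 0:
            raise ValueError(f"fs_native must be positive, got {self.fs_native}")
        if len(self.timestamps) != self.samples.shape[0]:
            raise ValueError("timestamps and samples disagree in length")
        if self.samples.shape[1] != len(self.channel_labels):
            raise ValueError("channel_labels and samples disagree in width")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Extent of the recording in seconds (first to last timestamp)."""
        if self.n_samples < 2:
            return 0.0
        return float(self.timestamps[-1] - self.timestamps[0])

    def channel(self, label: str) -> np.ndarray:
        """Return the 1-D sample vector for one channel label."""
        idx = self.channel_labels.index(label)
        return self.samples[:, idx]

    def with_samples(self, samples: np.ndarray, **meta) -> "SignalStream":
        """Copy of this stream with replaced sample values (same grid)."""
        return SignalStream(
            name=self.name,
            modality=self.modality,
            channel_labels=list(self.channel_labels),
            fs_native=self.fs_native,
            timestamps=self.timestamps.copy(),
            samples=np.asarray(samples, dtype=float),
            meta={**self.meta, **meta},
        )


@dataclass
class SessionRecording:
    """All streams for one participant x condition x task, plus metadata."""

    participant_id: str
    condition: Condition
    task: Task
    streams: dict[str, SignalStream]
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.condition = Condition(self.condition)
        self.task = Task(self.task)


@dataclass
class AlignedSession:
    """Every channel of a session interpolated onto one uniform grid.

    ``data`` is samples x channels on a grid starting at ``t0`` with spacing
    ``1/fs``.  ``invalid`` flags samples that were reconstructed across a gap
    longer than the configured maximum (these are filled numerically so the
    matrix holds no NaN, but features treat them as missing).  ``edge`` flags
    the filter-transient region at either end of the session.
    """

    participant_id: str
    condition: Condition
    task: Task
    fs: float
    t0: float
    data: np.ndarray
    channel_labels: list[str]
    provenance: dict[str, str]
    invalid: np.ndarray  # bool, same shape as data
    edge: np.ndarray  # bool, (n_samples,)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channel(self, label: str) -> np.ndarray:
        return self.data[:, self.channel_labels.index(label)]

    def channel_invalid(self, label: str) -> np.ndarray:
        return self.invalid[:, self.channel_labels.index(label)]
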