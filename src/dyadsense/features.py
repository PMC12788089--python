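"""Per-window feature extractors.

Seven features are computed per 30 s window: heart rate and an HRV
dispersion ratio from the derived ECG, respiratory rate from the band-passed
respiration belt, mean pupil size (zeroed to the first window), horizontal
and vertical gaze-position variance, the percentage of time the hands were
moving, and per-axis Welch power spectral densities of the six head-IMU
channels at 1 Hz resolution.

Conventions used throughout: "normalized" means z-scored within the window;
sample statistics use the n-1 denominator; an extractor that cannot produce
a defensible number returns NaN (missing), never a fabricated value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .config import AnalysisConfig
from .preprocess import Window
from .streams import IMU_AXES

#: Feature units, fixed per feature.
FEATURE_UNITS = {
    "heart_rate": "beats/min",
    "hrv": "dimensionless",
    "respiratory_rate": "breaths/min",
    "pupil_mean": "a.u. (relative to first window)",
    "gaze_variance_h": "units^2",
    "gaze_variance_v": "units^2",
    "hand_fraction": "% of window",
}


@dataclass
class WindowedFeature:
    """Participants x windows matrix of one scalar feature for one
    condition and task.  NaN marks missing windows."""

    feature_name: str
    units: str
    condition: str
    task: str
    participants: list[str]
    values: np.ndarray  # (n_participants, n_windows)
    window_end_times: np.ndarray  # (n_windows,)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.window_end_times = np.asarray(self.window_end_times, dtype=float)
        if self.values.shape != (len(self.participants), len(self.window_end_times)):
            raise ValueError("values shape disagrees with participants/windows")

    def participant_means(self) -> np.ndarray:
        """Per-participant average over windows (task-level summary)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.values, axis=1)


@dataclass
class PsdSet:
    """Per-participant Welch PSDs of one IMU axis, window-averaged."""

    signal_axis: str
    frequencies: np.ndarray  # (n_bins,) at psd_bin_width spacing
    power: np.ndarray  # (n_participants, n_bins)
    participants: list[str] = field(default_factory=list)
    condition: str = ""
    task: str = ""

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.atleast_2d(np.asarray(self.power, dtype=float))
        if np.nanmin(self.power) < 0:
            raise ValueError("PSD power must be non-negative")


def _z(x: np.ndarray) -> np.ndarray | None:
    sd = np.std(x)
    if sd == 0 or not np.isfinite(sd):
        return None
    return (x - np.mean(x)) / sd


def _detect_ecg_peaks(x: np.ndarray, fs: float, cfg: AnalysisConfig) -> np.ndarray:
    """R-event detection on the z-normalized negative first difference.

    Returns peak times in seconds relative to window start.  The sharp
    downslope after each R apex gives the dominant extremum of -diff, one
    per beat under the 0.25 s refractory constraint.
    """
    d = _z(-np.diff(x))
    if d is None:
        return np.array([])
    peaks, _ = sps.find_peaks(
        d,
        distance=max(1, int(round(cfg.ecg_refractory_s * fs))),
        prominence=cfg.peak_prominence,
    )
    return peaks / fs


def heart_rate(x: np.ndarray, fs: float, cfg: AnalysisConfig | None = None) -> float:
    """Window heart rate in beats/min: 60 * n_intervals / total interval
    duration over detected R events.  NaN when fewer than two events."""
    cfg = cfg or AnalysisConfig()
    pk = _detect_ecg_peaks(np.asarray(x, dtype=float), fs, cfg)
    if len(pk) < 2:
        return float("nan")
    return 60.0 * (len(pk) - 1) / (pk[-1] - pk[0])


def hrv(x: np.ndarray, fs: float, cfg: AnalysisConfig | None = None) -> float:
    """Dimensionless beat-interval dispersion: SD of peak-to-peak intervals
    (n-1 denominator) divided by their root-mean-square.  NaN when fewer
    than two intervals."""
    cfg = cfg or AnalysisConfig()
    pk = _detect_ecg_peaks(np.asarray(x, dtype=float), fs, cfg)
    intervals = np.diff(pk)
    return hrv_from_intervals(intervals)


def hrv_from_intervals(intervals: np.ndarray) -> float:
    """SD/RMS of a vector of beat-to-beat intervals (scale-free)."""
    intervals = np.asarray(intervals, dtype=float)
    if len(intervals) < 2:
        return float("nan")
    rms = float(np.sqrt(np.mean(intervals**2)))
    if rms == 0:
        return float("nan")
    return float(np.std(intervals, ddof=1) / rms)


def respiratory_rate(x: np.ndarray, fs: float, cfg: AnalysisConfig | None = None) -> float:
    """Window respiratory rate in breaths/min from peaks of the z-normalized
    respiration signal (2 s refractory).  NaN when fewer than two peaks."""
    cfg = cfg or AnalysisConfig()
    z = _z(np.asarray(x, dtype=float))
    if z is None:
        return float("nan")
    peaks, _ = sps.find_peaks(
        z,
        distance=max(1, int(round(cfg.resp_refractory_s * fs))),
        prominence=cfg.peak_prominence,
    )
    if len(peaks) < 2:
        return float("nan")
    span = (peaks[-1] - peaks[0]) / fs
    return 60.0 * (len(peaks) - 1) / span


def pupil_mean(
    trace: np.ndarray,
    windows: list[Window],
    invalid: np.ndarray | None = None,
    invalid_window_fraction: float = 0.5,
) -> tuple[np.ndarray, dict]:
    """Per-window mean pupil size after zeroing to the first window.

    The mean of the first (valid) window is subtracted from the whole trace
    so absolute camera-to-eye geometry differences between conditions cancel
    out; the first window's feature is ~0 by construction.  Windows whose
    invalid fraction exceeds the threshold are NaN.  Returns the feature
    vector and an info dict noting any baseline-window fallback.
    """
    trace = np.asarray(trace, dtype=float)
    if invalid is None:
        invalid = np.zeros(len(trace), dtype=bool)
    window_valid = np.array(
        [np.mean(invalid[w.slice()]) <= invalid_window_fraction for w in windows]
    )
    info: dict = {"baseline_window": None}
    base = None
    for k, w in enumerate(windows):
        if window_valid[k]:
            seg = trace[w.slice()]
            good = ~invalid[w.slice()]
            base = float(np.mean(seg[good]))
            info["baseline_window"] = k
            info["baseline_fallback"] = k != 0
            break
    out = np.full(len(windows), np.nan)
    if base is None:
        return out, info
    for k, w in enumerate(windows):
        if not window_valid[k]:
            continue
        seg = trace[w.slice()]
        good = ~invalid[w.slice()]
        out[k] = float(np.mean(seg[good])) - base
    return out, info


def gaze_variance(
    x: np.ndarray,
    invalid: np.ndarray | None = None,
    invalid_window_fraction: float = 0.5,
) -> float:
    """Sample variance (n-1) of one gaze axis within a window; NaN when more
    than the allowed fraction of samples is invalid."""
    x = np.asarray(x, dtype=float)
    if invalid is not None:
        if np.mean(invalid) > invalid_window_fraction:
            return float("nan")
        x = x[~invalid]
    if len(x) < 2:
        return float("nan")
    return float(np.var(x, ddof=1))


def hand_fraction(x: np.ndarray) -> float:
    """Percentage of the window during which the hands were moving.

    Input is the binary annotation carried sample-and-hold on the common
    grid, so the mean of the flags is the moving-time fraction."""
    x = np.asarray(x, dtype=float)
    if len(x) == 0:
        return 0.0
    return float(100.0 * np.mean(x > 0.5))


def welch_psd(
    x: np.ndarray, fs: float, bin_width: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD with Hann-tapered segments of ``1/bin_width`` seconds and
    50% overlap, giving frequency bins at ``bin_width`` Hz spacing."""
    nperseg = int(round(fs / bin_width))
    if len(x) < nperseg:
        raise ValueError("signal shorter than one Welch segment")
    f, p = sps.welch(x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2)
    return f, p


def head_psd(
    x: np.ndarray,
    fs: float,
    windows: list[Window],
    bin_width: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Session-level PSD of one IMU channel: Welch per 30 s window, then
    averaged over windows.  Returns (frequencies, mean power)."""
    if not windows:
        raise ValueError("no windows to analyse")
    psds = []
    f = None
    for w in windows:
        f, p = welch_psd(np.asarray(x, dtype=float)[w.slice()], fs, bin_width)
        psds.append(p)
    return f, np.mean(psds, axis=0)


def extract_session_features(
    aligned,
    windows: list[Window],
    cfg: AnalysisConfig,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], dict]:
    """All configured features for one aligned session.

    Returns ``(features, psds, info)`` where ``features`` maps feature name
    to a per-window vector, ``psds`` maps IMU axis to its window-averaged
    PSD row, and ``info`` carries extraction notes.  Task-exclusion rules
    come from ``cfg.task_features``.
    """
    wanted = set(cfg.features_for_task(aligned.task))
    feats: dict[str, np.ndarray] = {}
    psds: dict[str, np.ndarray] = {}
    info: dict = {}

    def col(label: str) -> np.ndarray:
        return aligned.channel(label)

    def inv(label: str) -> np.ndarray:
        return aligned.channel_invalid(label)

    def fully_edge(w: Window) -> bool:
        return bool(np.all(aligned.edge[w.slice()]))

    if "heart_rate" in wanted or "hrv" in wanted:
        x = col("ecg_diff")
        if "heart_rate" in wanted:
            feats["heart_rate"] = np.array(
                [
                    np.nan if fully_edge(w) else heart_rate(x[w.slice()], aligned.fs, cfg)
                    for w in windows
                ]
            )
        if "hrv" in wanted:
            feats["hrv"] = np.array(
                [np.nan if fully_edge(w) else hrv(x[w.slice()], aligned.fs, cfg) for w in windows]
            )
    if "respiratory_rate" in wanted:
        x = col("resp")
        feats["respiratory_rate"] = np.array(
            [
                np.nan if fully_edge(w) else respiratory_rate(x[w.slice()], aligned.fs, cfg)
                for w in windows
            ]
        )
    if "pupil_mean" in wanted:
        vals, pinfo = pupil_mean(
            col("pupil"), windows, inv("pupil"), cfg.invalid_window_fraction
        )
        feats["pupil_mean"] = vals
        info["pupil"] = pinfo
    for fname, label in (("gaze_variance_h", "gaze_h"), ("gaze_variance_v", "gaze_v")):
        if fname in wanted:
            x, m = col(label), inv(label)
            feats[fname] = np.array(
                [
                    gaze_variance(x[w.slice()], m[w.slice()], cfg.invalid_window_fraction)
                    for w in windows
                ]
            )
    if "hand_fraction" in wanted:
        x = col("moving")
        feats["hand_fraction"] = np.array([hand_fraction(x[w.slice()]) for w in windows])
    if "head_psd" in wanted:
        for ax in IMU_AXES:
            f, p = head_psd(col(ax), aligned.fs, windows, cfg.psd_bin_width)
            psds[ax] = p
            info["psd_frequencies"] = f
    # Window-average gaze position, used for the gaze-dispersion ellipse.
    if "gaze_variance_h" in wanted:
        gh, gv = col("gaze_h"), col("gaze_v")
        info["gaze_mean_h"] = np.array([np.mean(gh[w.slice()]) for w in windows])
        info["gaze_mean_v"] = np.array([np.mean(gv[w.slice()]) for w in windows])
    return feats, psds, info
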