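"""Preprocessing: lead derivation, zero-phase filtering, common-grid
alignment and sliding-window segmentation.

All filters are Butterworth designs applied forward-backward
(``sosfiltfilt``) so the net phase response is zero and event timing is
preserved.  Streams are brought onto one uniform common-rate grid by linear
interpolation of their native timestamps; the grid spans the intersection of
all stream extents.  Binary annotations are carried as sample-and-hold
rather than interpolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .config import AnalysisConfig
from .streams import (
    AlignedSession,
    AlignmentError,
    Modality,
    SessionRecording,
    SignalStream,
)


def derive_ecg(lead_a: SignalStream, lead_b: SignalStream | None = None) -> SignalStream:
    """Derived single-lead ECG: samplewise difference of the two electrodes.

    Accepts either one two-channel ECG stream or two single-channel streams
    on identical time grids.
    """
    if lead_b is None:
        if lead_a.n_channels != 2:
            raise ValueError("derive_ecg needs two channels or two streams")
        diff = lead_a.samples[:, 0] - lead_a.samples[:, 1]
        src = lead_a
        derivation = f"{lead_a.channel_labels[0]} - {lead_a.channel_labels[1]}"
    else:
        if lead_a.n_samples != lead_b.n_samples or not np.array_equal(
            lead_a.timestamps, lead_b.timestamps
        ):
            raise AlignmentError("ECG leads are not on an identical time grid")
        diff = lead_a.samples[:, 0] - lead_b.samples[:, 0]
        src = lead_a
        derivation = f"{lead_a.name} - {lead_b.name}"
    return SignalStream(
        name="ecg_diff",
        modality=Modality.ECG,
        channel_labels=["ecg_diff"],
        fs_native=src.fs_native,
        timestamps=src.timestamps.copy(),
        samples=diff,
        meta={**src.meta, "derivation": derivation},
    )


def _design_sos(fs: float, low: float | None, high: float | None, order: int):
    nyq = fs / 2.0
    if low is not None and high is not None:
        if not 0.0 < low < high < nyq:
            raise ValueError(f"band ({low}, {high}) Hz outside (0, {nyq}) Hz")
        return sps.butter(order, [low, high], btype="band", fs=fs, output="sos")
    cutoff = high if high is not None else low
    if not 0.0 < cutoff < nyq:
        raise ValueError(f"cutoff {cutoff} Hz outside (0, {nyq}) Hz")
    return sps.butter(order, cutoff, btype="low", fs=fs, output="sos")


def _filtfilt_stream(s: SignalStream, sos, description: str) -> SignalStream:
    # NaN spans would poison filtfilt over the whole record; bridge them for
    # filtering, then restore so downstream gap policy still sees them.
    x = s.samples
    nan_mask = np.isnan(x)
    if nan_mask.any():
        x = x.copy()
        idx = np.arange(x.shape[0])
        for c in range(x.shape[1]):
            m = nan_mask[:, c]
            if m.all():
                raise ValueError(f"channel {s.channel_labels[c]} is entirely invalid")
            x[m, c] = np.interp(idx[m], idx[~m], x[~m, c])
    y = sps.sosfiltfilt(sos, x, axis=0)
    y = np.asarray(y)
    y[nan_mask] = np.nan
    return s.with_samples(y, filtered=description)


def zero_phase_bandpass(
    s: SignalStream, low: float, high: float, order: int = 4
) -> SignalStream:
    """Forward-backward Butterworth band-pass (net zero phase)."""
    sos = _design_sos(s.fs_native, low, high, order)
    return _filtfilt_stream(s, sos, f"bandpass {low}-{high} Hz (zero-phase)")


def zero_phase_lowpass(s: SignalStream, cutoff: float, order: int = 4) -> SignalStream:
    """Forward-backward Butterworth low-pass (net zero phase)."""
    sos = _design_sos(s.fs_native, None, cutoff, order)
    return _filtfilt_stream(s, sos, f"lowpass {cutoff} Hz (zero-phase)")


def preprocess_streams(rec: SessionRecording, cfg: AnalysisConfig) -> list[SignalStream]:
    """Apply the per-modality filtering policy to a raw session.

    ECG: lead difference, band-passed (default 2-30 Hz).  Respiration:
    band-passed (default 0.1-0.5 Hz).  Pupil, gaze, IMU: anti-alias low-pass
    (default 50 Hz) ahead of resampling to the common rate.  Hand
    annotations pass through untouched.
    """
    out: list[SignalStream] = []
    for name, s in rec.streams.items():
        if s.modality == Modality.ECG:
            d = derive_ecg(s) if s.n_channels == 2 else s
            out.append(zero_phase_bandpass(d, *cfg.ecg_band, order=cfg.filter_order))
        elif s.modality == Modality.RESPIRATION:
            out.append(zero_phase_bandpass(s, *cfg.resp_band, order=cfg.filter_order))
        elif s.modality in (Modality.PUPIL, Modality.GAZE, Modality.IMU):
            cutoff = min(cfg.antialias_cutoff, 0.98 * s.fs_native / 2)
            out.append(zero_phase_lowpass(s, cutoff, order=cfg.filter_order))
        elif s.modality == Modality.HAND:
            out.append(s)
        else:  # pragma: no cover - enum is closed
            out.append(s)
    return out


def _fill_gaps(t: np.ndarray, x: np.ndarray, grid: np.ndarray, max_gap_s: float):
    """Interpolate one channel onto ``grid``; flag samples spanned by gaps
    (NaN runs or missing coverage) longer than ``max_gap_s``."""
    good = ~np.isnan(x)
    if not good.any():
        raise ValueError("channel has no valid samples")
    tg, xg = t[good], x[good]
    y = np.interp(grid, tg, xg)
    invalid = np.zeros(len(grid), dtype=bool)
    # Any grid point falling between valid samples further apart than
    # max_gap_s was reconstructed across a dropout.
    if len(tg) > 1:
        gaps = np.diff(tg)
        big = np.nonzero(gaps > max_gap_s)[0]
        for i in big:
            invalid |= (grid > tg[i]) & (grid < tg[i + 1])
    return y, invalid


def resample_align(
    streams: list[SignalStream],
    cfg: AnalysisConfig,
    participant_id: str = "",
    condition="virtual",
    task="free_talk",
) -> AlignedSession:
    """Interpolate every channel onto one uniform common-rate grid.

    The grid spans the intersection of all stream extents, anchored at the
    latest stream start.  Continuous channels are linearly interpolated on
    their timestamps; hand annotations are carried sample-and-hold.  Gaps
    longer than ``cfg.max_gap_s`` are filled numerically but flagged invalid.
    """
    if not streams:
        raise ValueError("no streams to align")
    t_start = max(s.timestamps[0] for s in streams)
    t_end = min(s.timestamps[-1] for s in streams)
    if t_end <= t_start:
        raise AlignmentError("streams have no common time interval")
    n = int(np.floor((t_end - t_start) * cfg.fs_common)) + 1
    grid = t_start + np.arange(n) / cfg.fs_common

    cols, labels, prov, invalid_cols = [], [], {}, []
    for s in streams:
        for c, ch in enumerate(s.channel_labels):
            x = s.samples[:, c]
            if s.modality == Modality.HAND:
                idx = np.clip(
                    np.searchsorted(s.timestamps, grid, side="right") - 1, 0, s.n_samples - 1
                )
                y = x[idx]
                inv = np.zeros(n, dtype=bool)
            else:
                y, inv = _fill_gaps(s.timestamps, x, grid, cfg.max_gap_s)
            label = ch if ch not in labels else f"{s.name}:{ch}"
            labels.append(label)
            prov[label] = f"{s.name}/{s.modality.value}"
            cols.append(y)
            invalid_cols.append(inv)

    edge = np.zeros(n, dtype=bool)
    k = int(round(cfg.edge_seconds * cfg.fs_common))
    if k > 0:
        edge[:k] = True
        edge[-k:] = True

    return AlignedSession(
        participant_id=participant_id,
        condition=condition,
        task=task,
        fs=cfg.fs_common,
        t0=float(t_start),
        data=np.column_stack(cols),
        channel_labels=labels,
        provenance=prov,
        invalid=np.column_stack(invalid_cols),
        edge=edge,
    )


@dataclass
class Window:
    """One sliding-window view: sample slice plus its end-time label.

    Windows are labelled by their END time relative to session start, so the
    first 30 s window is labelled 30 s.
    """

    index: int
    start_idx: int
    stop_idx: int
    end_time: float

    def slice(self) -> slice:
        return slice(self.start_idx, self.stop_idx)


def n_windows(T: float, L: float, S: float) -> int:
    """Closed-form window count: floor((T - L)/S) + 1, or 0 when T < L."""
    if T < L:
        return 0
    return int(np.floor((T - L) / S + 1e-9)) + 1


def segment(a: AlignedSession, cfg: AnalysisConfig) -> list[Window]:
    """Sliding windows of ``window_length`` s advanced by ``window_step`` s.

    A 300 s session with 30 s windows and a 5 s step yields 55 windows.
    Sessions shorter than one window yield an empty list with a warning.
    """
    L = int(round(cfg.window_length * a.fs))
    S = int(round(cfg.window_step * a.fs))
    T = a.n_samples
    if T < L:
        warnings.warn(
            f"session shorter than one window ({T / a.fs:.1f} s < {cfg.window_length} s)",
            stacklevel=2,
        )
        return []
    K = (T - L) // S + 1
    return [
        Window(
            index=k,
            start_idx=k * S,
            stop_idx=k * S + L,
            end_time=(k * S + L) / a.fs,
        )
        for k in range(K)
    ]
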