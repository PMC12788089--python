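"""Synthetic dyad-study generator with known ground truth.

Generates paired in-person / virtual conversation sessions whose signal
streams statistically emulate a multimodal recording rig: two-lead ECG and a
respiration belt at 500 Hz, pupil size and 2-D gaze at 200 Hz, a 6-axis head
IMU at 110 Hz, and a 1 Hz binary hand-movement annotation.  Every generator
is seeded and keeps its ground truth (R-peak times, breath times, target
variances, spectral profiles) alongside the samples so downstream stages can
be tested for parameter recovery without any real recordings.

The generator does **not** model interpersonal coupling between the two
interlocutors; each participant's signals are independent draws around their
own baseline, with the condition contrast injected as a known effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

from .streams import (
    IMU_AXES,
    Condition,
    Modality,
    SessionRecording,
    SignalStream,
    Task,
)

# Stable per-modality entropy so streams of one session are decorrelated
# while remaining reproducible from a single session seed.
_MODALITY_KEY = {"ecg": 11, "respiration": 23, "pupil": 37, "gaze": 41, "imu": 53, "hand": 67}

#: Default per-device start offsets (s) on the shared session clock, to
#: exercise timestamp-based alignment.  Magnitudes are typical of
#: consumer-device stream startup skew.
DEFAULT_DEVICE_OFFSETS = {
    "ecg": 0.0,
    "respiration": 0.004,
    "pupil": 0.013,
    "gaze": 0.013,
    "imu": 0.027,
    "hand": 0.0,
}

#: Physiological truncation bounds for beat-to-beat intervals (s);
#: 0.25 s ~ 240 bpm, 2.5 s ~ 24 bpm.
RR_BOUNDS = (0.25, 2.5)


def _default_imu_profile() -> dict:
    """Head-movement spectral profile: energy concentrated below ~5 Hz
    (nodding, postural sway) with a weaker mid-band component."""
    acc = [(0.8, 0.5), (3.0, 0.2)]
    gyro = [(0.6, 0.4), (2.5, 0.15)]
    return {
        "acc_x": list(acc),
        "acc_y": list(acc),
        "acc_z": list(acc),
        "gyro_roll": list(gyro),
        "gyro_pitch": list(gyro),
        "gyro_yaw": list(gyro),
    }


@dataclass
class GroundTruth:
    """True parameters of one synthetic session.

    Units: ``mean_hr`` and ``hr_sd`` in beats/min (``hr_sd`` expresses
    beat-interval jitter on the rate scale), ``resp_rate`` in breaths/min,
    pupil quantities in arbitrary units, gaze variances in deg**2,
    ``hand_move_prob`` as probability of movement per second,
    ``duration`` in seconds.
    """

    mean_hr: float = 72.0
    hr_sd: float = 3.0
    resp_rate: float = 15.0
    pupil_baseline: float = 3.5
    pupil_offset: float = 0.0
    gaze_var_h: float = 4.0
    gaze_var_v: float = 2.0
    imu_spectral_profile: dict = field(default_factory=_default_imu_profile)
    hand_move_prob: float = 0.25
    duration: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.mean_hr <= 300.0:
            raise ValueError(f"mean_hr must lie in (0, 300], got {self.mean_hr}")
        if not 0.0 < self.resp_rate < 60.0:
            raise ValueError(f"resp_rate must lie in (0, 60), got {self.resp_rate}")
        if self.hr_sd < 0 or self.gaze_var_h < 0 or self.gaze_var_v < 0:
            raise ValueError("spread parameters must be non-negative")
        if not 0.0 <= self.hand_move_prob <= 1.0:
            raise ValueError("hand_move_prob must lie in [0, 1]")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        for axis, comps in self.axis_profiles().items():
            for f0, power in comps:
                if f0 <= 0 or power < 0:
                    raise ValueError(f"invalid IMU component ({f0}, {power}) on {axis}")

    def axis_profiles(self) -> dict:
        """Per-axis component lists; a bare list applies to all six axes."""
        prof = self.imu_spectral_profile
        if isinstance(prof, dict):
            return {ax: list(prof.get(ax, [])) for ax in IMU_AXES}
        return {ax: list(prof) for ax in IMU_AXES}

    def replace(self, **kw) -> "GroundTruth":
        d = asdict(self)
        d.update(kw)
        return GroundTruth(**d)


@dataclass
class EffectConfig:
    """Condition contrast applied to the in-person session of each pair.

    Defaults encode the qualitative between-condition pattern this pipeline
    is designed to detect: larger pupils, higher horizontal gaze variance,
    more low-frequency head movement, somewhat higher heart rate, and more
    frequent hand movement during in-person conversation.  Magnitudes are
    simulation conventions (the contrast directions are the constraint, not
    any particular effect size).
    """

    pupil_shift: float = 0.3
    gaze_var_h_ratio: float = 2.0
    hr_shift: float = 2.0
    low_freq_imu_power_ratio: float = 2.0
    low_freq_cutoff_hz: float = 5.0
    hand_prob_ratio: float = 1.5
    n_participants: int = 18

    def __post_init__(self) -> None:
        for name in ("gaze_var_h_ratio", "low_freq_imu_power_ratio", "hand_prob_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_participants < 2:
            raise ValueError("n_participants must be at least 2")

    @classmethod
    def null(cls, n_participants: int = 18) -> "EffectConfig":
        """No condition effect: both sessions drawn from the same truth."""
        return cls(
            pupil_shift=0.0,
            gaze_var_h_ratio=1.0,
            hr_shift=0.0,
            low_freq_imu_power_ratio=1.0,
            hand_prob_ratio=1.0,
            n_participants=n_participants,
        )


def _rng(gt: GroundTruth, modality: str) -> np.random.Generator:
    return np.random.default_rng([int(gt.seed), _MODALITY_KEY[modality]])


def _grid(fs: float, duration: float, start: float) -> np.ndarray:
    n = int(round(duration * fs)) + 1
    return start + np.arange(n) / fs


def _trunc_normal(rng, mean, sd, low, high, size):
    """Truncated-normal draws; degenerates to the mean when sd == 0."""
    if sd == 0:
        return np.full(size, float(mean))
    a, b = (low - mean) / sd, (high - mean) / sd
    return spstats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _qrs_template(fs: float, width_s: float = 0.012, amplitude: float = 1.0):
    """Smooth biphasic QRS-like pulse (Mexican-hat shape).

    The only contract on the shape is that the negative derivative of the
    lead difference shows one dominant extremum per beat, which any sharp
    unimodal pulse satisfies.
    """
    half = int(round(4 * width_s * fs))
    t = np.arange(-half, half + 1) / fs
    u = t / width_s
    tpl = amplitude * (1.0 - u**2) * np.exp(-(u**2) / 2.0)
    return tpl, half


def generate_ecg(
    gt: GroundTruth,
    fs: float = 500.0,
    noise_sd: float = 0.02,
    baseline_amp: float = 0.1,
    start: float = 0.0,
    pad: float = 0.0,
) -> SignalStream:
    """Two-lead ECG whose lead difference carries a QRS-like pulse train.

    Beat-to-beat intervals are i.i.d. truncated-normal with mean
    ``60/mean_hr`` s and an SD obtained by propagating ``hr_sd`` from the
    rate scale (``60*hr_sd/mean_hr**2`` s), truncated to the physiological
    range 0.25-2.5 s intersected with mean +/- 4 SD.  True R-peak times are
    stored in ``meta['r_peak_times']``.
    """
    rng = _rng(gt, "ecg")
    duration = gt.duration + pad
    mean_rr = 60.0 / gt.mean_hr
    sd_rr = 60.0 * gt.hr_sd / gt.mean_hr**2
    low = max(RR_BOUNDS[0], mean_rr - 4 * sd_rr)
    high = min(RR_BOUNDS[1], mean_rr + 4 * sd_rr)

    n_beats = int(math.ceil(duration / mean_rr)) + 8
    intervals = _trunc_normal(rng, mean_rr, sd_rr, low, high, n_beats)
    beat_times = 0.5 * mean_rr + np.cumsum(np.concatenate([[0.0], intervals]))
    beat_times = beat_times[beat_times < duration]

    t = _grid(fs, duration, start)
    n = len(t)
    tpl, half = _qrs_template(fs)
    qrs = np.zeros(n + 2 * half)
    # Snap each beat to the sample grid so stored truth matches the samples.
    beat_idx = np.round((beat_times) * fs).astype(int)
    for bi in beat_idx:
        qrs[bi : bi + 2 * half + 1] += tpl
    qrs = qrs[half : half + n]

    wander = baseline_amp * np.sin(2 * np.pi * 0.12 * (t - start) + rng.uniform(0, 2 * np.pi))
    lead_b = wander + noise_sd * rng.standard_normal(n)
    lead_a = wander + qrs + noise_sd * rng.standard_normal(n)

    return SignalStream(
        name="ecg",
        modality=Modality.ECG,
        channel_labels=["lead_a", "lead_b"],
        fs_native=fs,
        timestamps=t,
        samples=np.column_stack([lead_a, lead_b]),
        meta={
            "r_peak_times": (start + beat_idx / fs).tolist(),
            "rr_mean_s": mean_rr,
            "rr_sd_s": sd_rr,
            "rr_bounds_s": [low, high],
        },
    )


def generate_respiration(
    gt: GroundTruth,
    fs: float = 500.0,
    amplitude: float = 1.0,
    cycle_jitter_sd: float = 0.2,
    amp_jitter_sd: float = 0.05,
    noise_sd: float = 0.02,
    start: float = 0.0,
    pad: float = 0.0,
) -> SignalStream:
    """Quasi-sinusoidal respiration at ``resp_rate/60`` Hz.

    Cycle durations are truncated-normal around ``60/resp_rate`` s with SD
    ``cycle_jitter_sd``; per-cycle amplitude jitters around ``amplitude``.
    True inhalation-peak times are stored in ``meta['cycle_times']``.
    """
    rng = _rng(gt, "respiration")
    duration = gt.duration + pad
    period = 60.0 / gt.resp_rate
    n_cyc = int(math.ceil(duration / period)) + 8
    durations = _trunc_normal(
        rng, period, cycle_jitter_sd, max(0.3 * period, period - 3 * cycle_jitter_sd),
        period + 3 * cycle_jitter_sd, n_cyc
    )
    boundaries = np.concatenate([[0.0], np.cumsum(durations)])

    t = _grid(fs, duration, start)
    rel = t - start
    # Continuous phase: one full cycle (2*pi) between successive boundaries.
    phase = 2 * np.pi * np.interp(rel, boundaries, np.arange(len(boundaries)))
    amps = amplitude * (1.0 + amp_jitter_sd * rng.standard_normal(n_cyc))
    cyc_of_sample = np.clip(np.searchsorted(boundaries, rel, side="right") - 1, 0, n_cyc - 1)
    x = amps[cyc_of_sample] * np.cos(phase)
    if noise_sd:
        x = x + noise_sd * rng.standard_normal(len(t))

    peaks = boundaries[boundaries < duration]
    return SignalStream(
        name="respiration",
        modality=Modality.RESPIRATION,
        channel_labels=["resp"],
        fs_native=fs,
        timestamps=t,
        samples=x,
        meta={"cycle_times": (start + peaks).tolist(), "period_s": period},
    )


def _ou_process(rng, n: int, fs: float, variance: float, tau: float) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck path via its exact AR(1) discretisation."""
    if variance == 0:
        return np.zeros(n)
    rho = math.exp(-1.0 / (fs * tau))
    eps = math.sqrt(variance * (1 - rho**2)) * rng.standard_normal(n)
    x0 = math.sqrt(variance) * rng.standard_normal()
    y, _ = sps.lfilter([1.0], [1.0, -rho], eps, zi=[rho * x0])
    return y


def _insert_blinks(rng, x: np.ndarray, fs: float, rate_per_min: float, dur_s: float):
    """NaN out Poisson-timed spans, emulating blink dropouts."""
    if rate_per_min <= 0:
        return x
    n = len(x)
    n_blinks = rng.poisson(rate_per_min * n / fs / 60.0)
    starts = rng.integers(0, n, size=n_blinks)
    w = max(1, int(round(dur_s * fs)))
    for s0 in starts:
        x[s0 : s0 + w] = np.nan
    return x


def generate_pupil(
    gt: GroundTruth,
    fs: float = 200.0,
    drift_sd: float = 0.08,
    drift_tau: float = 30.0,
    noise_sd: float = 0.02,
    blink_rate_per_min: float = 0.0,
    blink_duration_s: float = 0.25,
    onset_delay_s: float = 30.0,
    onset_rise_s: float = 30.0,
    start: float = 0.0,
    pad: float = 0.0,
) -> SignalStream:
    """Pupil size: baseline + arousal-driven condition offset + slow OU
    drift + noise.

    The condition offset is absent at session start and ramps in linearly
    between ``onset_delay_s`` and ``onset_delay_s + onset_rise_s`` — the
    arousal contrast develops once the conversation is underway.  This
    matters because downstream feature extraction re-zeroes each trace to
    its first window: a constant offset would cancel there, while this
    onset profile survives as a between-condition difference of ~the full
    offset for windows past the ramp.

    Optional blink dropouts appear as NaN spans (the alignment stage's gap
    policy is responsible for them).
    """
    rng = _rng(gt, "pupil")
    t = _grid(fs, gt.duration + pad, start)
    n = len(t)
    rel = t - start
    ramp = np.clip((rel - onset_delay_s) / max(onset_rise_s, 1e-9), 0.0, 1.0)
    x = gt.pupil_baseline + gt.pupil_offset * ramp
    x = x + _ou_process(rng, n, fs, drift_sd**2, drift_tau)
    if noise_sd:
        x = x + noise_sd * rng.standard_normal(n)
    x = _insert_blinks(rng, x, fs, blink_rate_per_min, blink_duration_s)
    return SignalStream(
        name="pupil",
        modality=Modality.PUPIL,
        channel_labels=["pupil"],
        fs_native=fs,
        timestamps=t,
        samples=x,
        meta={
            "pupil_baseline": gt.pupil_baseline,
            "pupil_offset": gt.pupil_offset,
            "onset_delay_s": onset_delay_s,
            "onset_rise_s": onset_rise_s,
        },
    )


def _jump_process(rng, n: int, fs: float, variance: float, rate_hz: float) -> np.ndarray:
    """Piecewise-constant saccade-target process with N(0, variance) levels."""
    if variance == 0:
        return np.zeros(n)
    duration = n / fs
    n_jumps = rng.poisson(rate_hz * duration)
    times = np.sort(rng.uniform(0, duration, size=n_jumps))
    levels = math.sqrt(variance) * rng.standard_normal(n_jumps + 1)
    idx = np.searchsorted(times, np.arange(n) / fs, side="right")
    return levels[idx]


def generate_gaze(
    gt: GroundTruth,
    fs: float = 200.0,
    saccade_rate_hz: float = 1.0,
    fixation_tau: float = 0.3,
    start: float = 0.0,
    pad: float = 0.0,
) -> SignalStream:
    """2-D gaze: saccadic jump process plus within-fixation OU drift.

    Per axis, the stationary variance is split 65% between-fixation (jump
    levels), 30% within-fixation drift and 5% measurement noise, so the
    total stationary variance equals the configured ``gaze_var_h`` /
    ``gaze_var_v`` exactly.
    """
    rng = _rng(gt, "gaze")
    t = _grid(fs, gt.duration + pad, start)
    n = len(t)
    chans = []
    for target in (gt.gaze_var_h, gt.gaze_var_v):
        x = _jump_process(rng, n, fs, 0.65 * target, saccade_rate_hz)
        x = x + _ou_process(rng, n, fs, 0.30 * target, fixation_tau)
        if target > 0:
            x = x + math.sqrt(0.05 * target) * rng.standard_normal(n)
        chans.append(x)
    return SignalStream(
        name="gaze",
        modality=Modality.GAZE,
        channel_labels=["gaze_h", "gaze_v"],
        fs_native=fs,
        timestamps=t,
        samples=np.column_stack(chans),
        meta={"gaze_var_true": [gt.gaze_var_h, gt.gaze_var_v]},
    )


def _narrowband(rng, n: int, fs: float, f0: float, power: float, bw: float = 1.0):
    """Band-limited Gaussian noise centred at f0, scaled to sample variance
    ``power``."""
    low = max(0.05, f0 - bw / 2)
    high = min(0.98 * fs / 2, f0 + bw / 2)
    if low >= high:
        raise ValueError(f"IMU component frequency {f0} Hz outside (0, {fs / 2}) Hz")
    sos = sps.butter(2, [low, high], btype="band", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    sd = x.std()
    if sd > 0 and power > 0:
        x = x * (math.sqrt(power) / sd)
    else:
        x = np.zeros(n)
    return x


def generate_imu(
    gt: GroundTruth,
    fs: float = 110.0,
    noise_sd: float = 0.05,
    start: float = 0.0,
    pad: float = 0.0,
) -> SignalStream:
    """6-axis head IMU: per-axis sums of narrowband components plus white
    noise, per the ground-truth spectral profile."""
    rng = _rng(gt, "imu")
    t = _grid(fs, gt.duration + pad, start)
    n = len(t)
    profiles = gt.axis_profiles()
    chans = []
    for ax in IMU_AXES:
        x = noise_sd * rng.standard_normal(n)
        for f0, power in profiles[ax]:
            x = x + _narrowband(rng, n, fs, f0, power)
        chans.append(x)
    return SignalStream(
        name="imu",
        modality=Modality.IMU,
        channel_labels=list(IMU_AXES),
        fs_native=fs,
        timestamps=t,
        samples=np.column_stack(chans),
        meta={"spectral_profile": profiles},
    )


def generate_hand(
    gt: GroundTruth,
    fs: float = 1.0,
    start: float = 0.0,
    pad: float = 0.0,
) -> SignalStream:
    """Binary hand-movement annotation, i.i.d. Bernoulli per second."""
    rng = _rng(gt, "hand")
    t = _grid(fs, gt.duration + pad, start)
    x = (rng.uniform(size=len(t)) < gt.hand_move_prob).astype(float)
    return SignalStream(
        name="hand",
        modality=Modality.HAND,
        channel_labels=["moving"],
        fs_native=fs,
        timestamps=t,
        samples=x,
        meta={"hand_move_prob": gt.hand_move_prob},
    )


def generate_session(
    gt: GroundTruth,
    participant_id: str,
    condition: Condition | str,
    task: Task | str,
    device_offsets: dict | None = None,
    pad: float = 1.0,
) -> SessionRecording:
    """All six streams of one session on a shared clock.

    Each device starts with its own small offset; streams are generated with
    ``pad`` extra seconds so that after intersection-based alignment the
    session still covers the nominal duration.
    """
    offsets = dict(DEFAULT_DEVICE_OFFSETS)
    if device_offsets:
        offsets.update(device_offsets)
    streams = {
        "ecg": generate_ecg(gt, start=offsets["ecg"], pad=pad),
        "respiration": generate_respiration(gt, start=offsets["respiration"], pad=pad),
        "pupil": generate_pupil(gt, start=offsets["pupil"], pad=pad),
        "gaze": generate_gaze(gt, start=offsets["gaze"], pad=pad),
        "imu": generate_imu(gt, start=offsets["imu"], pad=pad),
        "hand": generate_hand(gt, start=offsets["hand"], pad=pad),
    }
    return SessionRecording(
        participant_id=participant_id,
        condition=Condition(condition),
        task=Task(task),
        streams=streams,
        ground_truth=asdict(gt),
    )


def _apply_effects(gt: GroundTruth, effects: EffectConfig) -> GroundTruth:
    """Ground truth for the in-person member of a pair."""
    profiles = gt.axis_profiles()
    boosted = {
        ax: [
            (f0, power * effects.low_freq_imu_power_ratio)
            if f0 <= effects.low_freq_cutoff_hz
            else (f0, power)
            for f0, power in comps
        ]
        for ax, comps in profiles.items()
    }
    return gt.replace(
        mean_hr=gt.mean_hr + effects.hr_shift,
        pupil_offset=gt.pupil_offset + effects.pupil_shift,
        gaze_var_h=gt.gaze_var_h * effects.gaze_var_h_ratio,
        imu_spectral_profile=boosted,
        hand_move_prob=min(1.0, gt.hand_move_prob * effects.hand_prob_ratio),
    )


def participant_truths(
    effects: EffectConfig, base: GroundTruth
) -> list[dict[str, GroundTruth]]:
    """Per-participant ground truths for both conditions.

    Each participant draws a random baseline around ``base`` (between-subject
    variation), then the in-person condition applies the configured contrast
    on top of that shared baseline (within-pair design).
    """
    rng = np.random.default_rng([int(base.seed), 97])
    out = []
    for _ in range(effects.n_participants):
        virt = base.replace(
            mean_hr=float(np.clip(base.mean_hr + 6.0 * rng.standard_normal(), 45, 110)),
            resp_rate=float(np.clip(base.resp_rate + 1.5 * rng.standard_normal(), 6, 30)),
            pupil_baseline=base.pupil_baseline + 0.25 * rng.standard_normal(),
            gaze_var_h=base.gaze_var_h * math.exp(0.15 * rng.standard_normal()),
            gaze_var_v=base.gaze_var_v * math.exp(0.15 * rng.standard_normal()),
            hand_move_prob=float(np.clip(base.hand_move_prob + 0.05 * rng.standard_normal(), 0.02, 0.95)),
            seed=int(rng.integers(2**31)),
        )
        inp = _apply_effects(virt, effects).replace(seed=int(rng.integers(2**31)))
        out.append({"virtual": virt, "in_person": inp})
    return out


def generate_dyad_study(
    effects: EffectConfig,
    base: GroundTruth,
    tasks: tuple[str, ...] = ("reading", "free_talk"),
) -> list[SessionRecording]:
    """Full paired study: each participant gets one session per condition per
    task.  Sessions of one participant share the participant baseline; the
    in-person sessions additionally carry the configured condition effects.
    Fixing ``base.seed`` makes the whole study reproducible."""
    truths = participant_truths(effects, base)
    rng = np.random.default_rng([int(base.seed), 101])
    sessions = []
    for i, pair in enumerate(truths):
        pid = f"P{i + 1:02d}"
        for cond in ("in_person", "virtual"):
            for task in tasks:
                gt = pair[cond].replace(seed=int(rng.integers(2**31)))
                sessions.append(generate_session(gt, pid, cond, task))
    return sessions
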