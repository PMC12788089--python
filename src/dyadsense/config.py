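"""Analysis configuration: every numeric parameter of the pipeline.

The defaults encode the study protocol this package implements: a common
100 Hz analysis grid, 30 s sliding windows advanced in 5 s steps, a 2-30 Hz
ECG band (the range carrying most QRS energy), a 0.1-0.5 Hz respiration band
(6-30 breaths/min, generous around the 12-20 breaths/min adult resting
range), and a 50 Hz anti-alias low-pass for signals without a defined band.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from .streams import Task

#: Features computed for each task.  Movement-related measures (hand, gaze,
#: head movement) and pupil size are excluded from the reading task because
#: alternating between reading a phone and eye contact drives those signals
#: for task-extrinsic reasons.
DEFAULT_TASK_FEATURES: dict[str, tuple[str, ...]] = {
    Task.READING.value: ("heart_rate", "hrv", "respiratory_rate"),
    Task.FREE_TALK.value: (
        "heart_rate",
        "hrv",
        "respiratory_rate",
        "pupil_mean",
        "gaze_variance_h",
        "gaze_variance_v",
        "hand_fraction",
        "head_psd",
    ),
}


@dataclass
class AnalysisConfig:
    """Tunable parameters of preprocessing, feature extraction and stats.

    Attributes
    ----------
    fs_common : float
        Common analysis rate all streams are resampled to (Hz).
    window_length : float
        Sliding-window length in seconds.
    window_step : float
        Step between successive window starts in seconds.
    ecg_band : (float, float)
        Zero-phase band-pass corner frequencies for the derived ECG lead (Hz).
    resp_band : (float, float)
        Band-pass for the respiratory signal (Hz); 0.1-0.5 Hz corresponds to
        6-30 breaths per minute.
    antialias_cutoff : float
        Low-pass cutoff applied to signals without a defined band (Hz).
    alpha : float
        Significance level for all paired tests.
    ellipse_level : float
        Probability mass of the gaze concentration ellipse.
    psd_bin_width : float
        Welch frequency resolution (Hz); fixes the segment length to
        ``1/psd_bin_width`` seconds.
    max_gap_s : float
        Gaps (NaN runs) up to this length are linearly interpolated during
        alignment; samples bridging longer gaps are flagged invalid.
    edge_seconds : float
        Length of the filter-transient region flagged at either end.
    ecg_refractory_s, resp_refractory_s : float
        Minimum spacing between detected beats / breaths, bounded by
        physiology (~240 bpm, ~30 breaths per minute).
    peak_prominence : float
        Peak prominence threshold in z-score units for both detectors.
    invalid_window_fraction : float
        A window whose invalid-sample fraction exceeds this is missing.
    task_features : dict
        Which features are computed for each task.
    """

    fs_common: float = 100.0
    window_length: float = 30.0
    window_step: float = 5.0
    ecg_band: tuple[float, float] = (2.0, 30.0)
    resp_band: tuple[float, float] = (0.1, 0.5)
    antialias_cutoff: float = 50.0
    alpha: float = 0.05
    ellipse_level: float = 0.95
    psd_bin_width: float = 1.0
    max_gap_s: float = 0.5
    edge_seconds: float = 2.0
    ecg_refractory_s: float = 0.25
    resp_refractory_s: float = 2.0
    peak_prominence: float = 0.5
    invalid_window_fraction: float = 0.5
    filter_order: int = 4
    task_features: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_TASK_FEATURES.items()}
    )

    def __post_init__(self) -> None:
        nyq = self.fs_common / 2.0
        for low, high in (self.ecg_band, self.resp_band):
            if not (0.0 < low < high < nyq):
                raise ValueError(f"band ({low}, {high}) must satisfy 0 < low < high < {nyq}")
        if self.window_step > self.window_length:
            raise ValueError("window_step must not exceed window_length")
        if self.window_length <= 0 or self.window_step <= 0:
            raise ValueError("window_length and window_step must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.ellipse_level < 1.0:
            raise ValueError("ellipse_level must lie in (0, 1)")
        if self.psd_bin_width <= 0:
            raise ValueError("psd_bin_width must be positive")
        if self.fs_common <= 0:
            raise ValueError("fs_common must be positive")

    def features_for_task(self, task) -> tuple[str, ...]:
        key = Task(task).value
        return tuple(self.task_features.get(key, ()))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ecg_band"] = list(self.ecg_band)
        d["resp_band"] = list(self.resp_band)
        d["task_features"] = {k: list(v) for k, v in self.task_features.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "ecg_band" in d:
            d["ecg_band"] = tuple(d["ecg_band"])
        if "resp_band" in d:
            d["resp_band"] = tuple(d["resp_band"])
        if "task_features" in d:
            d["task_features"] = {k: tuple(v) for k, v in d["task_features"].items()}
        return cls(**d)
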