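"""Study-scale Monte-Carlo validation of the inference layer.

These suites replay the paired study design (18 pairs, 55 windows, 51
spectral bins per IMU axis) many times at the *feature level*: per-window
feature values and per-participant PSDs are drawn directly from the
documented within-pair noise model rather than re-synthesising and
re-filtering raw signals for every replicate.  What they measure — type-I
error and power of the window-wise / spectral Wilcoxon + BH layer at the
study's sample size and multiplicity — depends only on that feature-level
geometry; full-signal fidelity is exercised separately by the end-to-end
pipeline tests.

Conventions: "within-pair noise SD" is the standard deviation of the paired
(in-person minus virtual) difference of the quantity entering the test
under the null; injected effects are expressed as multiples of it.
"""

from __future__ import annotations

import numpy as np

from .config import AnalysisConfig
from .features import PsdSet, WindowedFeature, heart_rate, respiratory_rate
from .preprocess import derive_ecg, resample_align, zero_phase_bandpass
from .stats import spectral_compare, wilcoxon_signed_rank, windowwise_compare
from .synth import GroundTruth, generate_ecg, generate_gaze, generate_respiration


def _feature_pair(values_a, values_b, name="sim", task="free_talk"):
    n_win = values_a.shape[1]
    ends = 30.0 + 5.0 * np.arange(n_win)
    mk = lambda v, c: WindowedFeature(  # noqa: E731
        feature_name=name,
        units="a.u.",
        condition=c,
        task=task,
        participants=[f"P{i:02d}" for i in range(values_a.shape[0])],
        values=v,
        window_end_times=ends,
    )
    return mk(values_a, "in_person"), mk(values_b, "virtual")


def null_windowwise_rejection_rate(
    n_pairs: int = 18,
    n_windows: int = 55,
    n_replicates: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, int]:
    """Uncorrected per-window rejection rate on null studies.

    Window values are i.i.d. normal in both conditions, so every per-window
    paired test is an independent draw from its null and the pooled
    rejection count is binomial.  Returns (rate, number of window tests).
    """
    rng = np.random.default_rng(seed)
    cfg = AnalysisConfig(alpha=alpha)
    rejected = 0
    total = 0
    for _ in range(n_replicates):
        a = rng.standard_normal((n_pairs, n_windows))
        b = rng.standard_normal((n_pairs, n_windows))
        fa, fb = _feature_pair(a, b)
        rep = windowwise_compare(fa, fb, cfg)
        ok = ~np.isnan(rep.p_values)
        rejected += int(np.sum(rep.significant[ok]))
        total += int(ok.sum())
    return rejected / total, total


def null_spectral_zero_rejection_fraction(
    n_pairs: int = 18,
    n_bins: int = 51,
    n_axes: int = 6,
    n_replicates: int = 200,
    alpha: float = 0.05,
    log_sd: float = 0.3,
    seed: int = 0,
) -> tuple[float, int]:
    """Fraction of null BH families (one IMU axis of one replicate study)
    with zero spectral rejections.

    Per-participant PSDs are log-normal around a common spectral shape;
    both conditions draw from the same law, so every axis family is a
    complete null and BH controls P(any rejection) at ``alpha`` per family.
    Returns (fraction, number of families).
    """
    rng = np.random.default_rng(seed)
    cfg = AnalysisConfig(alpha=alpha)
    freqs = np.arange(n_bins, dtype=float)
    shape = 1.0 / (1.0 + freqs)  # generic low-frequency-dominant spectrum
    zero_families = 0
    families = 0
    for _ in range(n_replicates):
        for _ax in range(n_axes):
            a = shape * np.exp(log_sd * rng.standard_normal((n_pairs, n_bins)))
            b = shape * np.exp(log_sd * rng.standard_normal((n_pairs, n_bins)))
            sa = PsdSet("sim", freqs, a)
            sb = PsdSet("sim", freqs, b)
            sc = spectral_compare(sa, sb, cfg)
            families += 1
            zero_families += int(sc.rejected.sum() == 0)
    return zero_families / families, families


def hr_recovery_errors(n_draws: int = 100, seed: int = 0) -> np.ndarray:
    """Per-window heart-rate error (bpm) on clean (noise-free) synthetic ECG
    across random (mean rate, beat jitter) draws.

    The reference is the windowed rate computed from the generator's true
    R-peak times over the same 30 s window the extractor sees.
    """
    rng = np.random.default_rng(seed)
    cfg = AnalysisConfig()
    errors = []
    for _ in range(n_draws):
        gt = GroundTruth(
            mean_hr=float(rng.uniform(50.0, 100.0)),
            hr_sd=float(rng.uniform(0.0, 4.0)),
            duration=40.0,
            seed=int(rng.integers(2**31)),
        )
        raw = generate_ecg(gt, noise_sd=0.0)
        filt = zero_phase_bandpass(derive_ecg(raw), *cfg.ecg_band)
        a = resample_align([filt], cfg)
        x = a.channel("ecg_diff")[: int(30 * cfg.fs_common)]
        est = heart_rate(x, cfg.fs_common, cfg)
        peaks = np.array(raw.meta["r_peak_times"])
        tw = peaks[(peaks >= a.t0) & (peaks < a.t0 + 30.0)]
        true = 60.0 * (len(tw) - 1) / (tw[-1] - tw[0])
        errors.append(est - true)
    return np.array(errors)


def resp_recovery_errors(n_draws: int = 100, seed: int = 0) -> np.ndarray:
    """Per-window respiratory-rate error (breaths/min) on clean synthetic
    respiration across random rate draws."""
    rng = np.random.default_rng(seed)
    cfg = AnalysisConfig()
    errors = []
    for _ in range(n_draws):
        rate = float(rng.uniform(8.0, 25.0))
        gt = GroundTruth(resp_rate=rate, duration=40.0, seed=int(rng.integers(2**31)))
        raw = generate_respiration(gt, cycle_jitter_sd=0.0, amp_jitter_sd=0.0, noise_sd=0.0)
        filt = zero_phase_bandpass(raw, *cfg.resp_band)
        a = resample_align([filt], cfg)
        x = a.channel("resp")[: int(30 * cfg.fs_common)]
        est = respiratory_rate(x, cfg.fs_common, cfg)
        errors.append(est - rate)
    return np.array(errors)


def gaze_variance_recovery(
    n_draws: int = 100, duration: float = 300.0, seed: int = 0
) -> tuple[np.ndarray, float]:
    """Relative error of the recovered gaze variance across random draws,
    plus the simulation-derived tolerance (4 x the relative sampling SE of
    the variance estimator under the saccade/fixation model, estimated from
    an independent pilot run at the same record length)."""
    rng = np.random.default_rng(seed)
    pilot = []
    for _ in range(40):
        gt = GroundTruth(gaze_var_h=4.0, gaze_var_v=2.0, duration=duration,
                         seed=int(rng.integers(2**31)))
        s = generate_gaze(gt)
        pilot.append(np.var(s.channel("gaze_h"), ddof=1) / 4.0)
    tol = 4.0 * float(np.std(pilot, ddof=1))
    rel_errors = []
    for _ in range(n_draws):
        target = float(rng.uniform(1.0, 6.0))
        gt = GroundTruth(gaze_var_h=target, gaze_var_v=target, duration=duration,
                         seed=int(rng.integers(2**31)))
        s = generate_gaze(gt)
        v = float(np.var(s.channel("gaze_h"), ddof=1))
        rel_errors.append(v / target - 1.0)
    return np.array(rel_errors), tol


def summary_power(
    effect_multiple: float = 3.0,
    n_pairs: int = 18,
    n_replicates: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Power of the task-summary paired test for an additive shift of
    ``effect_multiple`` x the within-pair noise SD of the participant means
    (the pupil-offset / heart-rate style contrast)."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_replicates):
        d = effect_multiple + rng.standard_normal(n_pairs)
        if wilcoxon_signed_rank(d).pvalue < alpha:
            hits += 1
    return hits / n_replicates


def variance_ratio_power(
    ratio: float = 2.0,
    effect_multiple: float = 3.0,
    n_pairs: int = 18,
    n_replicates: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Power of the summary test for a multiplicative variance contrast
    (the horizontal gaze-variance finding).

    Per-participant mean window variances are log-normal around a shared
    participant baseline; the within-pair log-scale noise SD is set to
    ``log(ratio)/effect_multiple`` so the injected effect is
    ``effect_multiple`` x the within-pair noise SD.
    """
    rng = np.random.default_rng(seed)
    log_noise = np.log(ratio) / effect_multiple
    hits = 0
    for _ in range(n_replicates):
        base = np.exp(0.3 * rng.standard_normal(n_pairs))  # between-subject
        a = base * ratio * np.exp(log_noise * rng.standard_normal(n_pairs))
        b = base * np.exp(log_noise * rng.standard_normal(n_pairs))
        if wilcoxon_signed_rank(a, b).pvalue < alpha:
            hits += 1
    return hits / n_replicates


def spectral_low_freq_power(
    ratio: float = 2.0,
    effect_multiple: float = 3.0,
    cutoff_hz: float = 5.0,
    n_pairs: int = 18,
    n_bins: int = 51,
    n_replicates: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Detection of an in-person low-frequency head-movement power boost.

    Bins at or below ``cutoff_hz`` carry ``ratio`` x power in the in-person
    condition; the within-pair log-scale noise SD is ``log(ratio) /
    effect_multiple``.  Returns (fraction of replicates with at least one
    BH-significant bin <= cutoff, fraction of all rejections that fall at or
    below the cutoff).
    """
    rng = np.random.default_rng(seed)
    cfg = AnalysisConfig(alpha=alpha)
    log_noise = np.log(ratio) / effect_multiple
    freqs = np.arange(n_bins, dtype=float)
    shape = 1.0 / (1.0 + freqs)
    boost = np.where(freqs <= cutoff_hz, ratio, 1.0)
    hits = 0
    low_rej = 0
    all_rej = 0
    for _ in range(n_replicates):
        base = shape * np.exp(0.3 * rng.standard_normal((n_pairs, 1)))
        a = base * boost * np.exp(log_noise * rng.standard_normal((n_pairs, n_bins)))
        b = base * np.exp(log_noise * rng.standard_normal((n_pairs, n_bins)))
        sc = spectral_compare(PsdSet("sim", freqs, a), PsdSet("sim", freqs, b), cfg)
        rej_low = sc.rejected & (freqs <= cutoff_hz)
        hits += int(rej_low.any())
        low_rej += int(rej_low.sum())
        all_rej += int(sc.rejected.sum())
    frac_low = low_rej / all_rej if all_rej else float("nan")
    return hits / n_replicates, frac_low
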