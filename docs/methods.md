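# Methods

This note documents the models, conventions and numerical choices behind
`dyadsense`, in the order the pipeline runs them.

## Study design being analyzed

The pipeline targets a within-subject paired design: each participant holds
one conversation per condition (in-person, virtual) per task (reading aloud
from a shared dialogue, unscripted free talk), nominally 300 s each, while
multiple devices record on a shared session clock: two-lead ECG and a
respiration belt at 500 Hz, pupil size and 2-D gaze at 200 Hz, a 6-axis head
IMU at 110 Hz, and a binary hand-movement annotation at 1 Hz. Analyses are
paired across participants within a task. Movement-linked features (hand,
gaze, head movement) and pupil size are analyzed only for free talk, because
the reading task forces alternation between a phone and the interlocutor's
face; cardiorespiratory features are analyzed for both tasks. These
exclusions live in `AnalysisConfig.task_features`, not in code paths, so a
different protocol can re-enable them; requesting an excluded combination
raises an explicit `TaskExclusionError` rather than returning silent output.

## Synthetic dyad-study generator

The generator exists so that every downstream stage can be validated against
known ground truth. It emulates the *marginal statistics and spectral
content* of each stream, and the paired structure of the design. It does
**not** model interpersonal synchrony between interlocutors, conversational
turn-taking structure, posture shifts, electrode artifacts, or nonstationary
arousal beyond the pupil onset ramp described below — so passing recovery
and power tests demonstrates correctness of the pipeline's arithmetic and
calibration of its inference under the stated noise model, not robustness to
every artifact of real recordings.

Per modality (defaults in parentheses, all seeded via per-modality
`numpy` generators spawned from one session seed):

- **ECG.** Beat-to-beat intervals are i.i.d. truncated normal with mean
  `60/mean_hr` s and SD `60*hr_sd/mean_hr²` s (jitter specified on the
  rate scale, propagated to the interval scale), truncated to 0.25–2.5 s
  intersected with mean ± 4 SD. Each beat places a Mexican-hat-shaped
  biphasic pulse (σ = 12 ms) on the lead-difference; both leads share a
  0.12 Hz baseline wander that cancels on subtraction, plus independent
  white noise (SD 0.02 of the unit pulse amplitude). True R-peak times are
  snapped to the sample grid and stored.
- **Respiration.** Cosine with one cycle per truncated-normal cycle
  duration (mean `60/resp_rate` s, SD 0.2 s), per-cycle amplitude jitter
  (5%), white noise (SD 0.02). Cycle-peak times stored.
- **Pupil.** Baseline (3.5 a.u.) plus a slow Ornstein–Uhlenbeck drift
  (SD 0.08 a.u., τ = 30 s) plus white noise (SD 0.02). The condition
  offset ramps in linearly between 30 s and 60 s: the arousal contrast
  develops once the conversation is underway. This matters because feature
  extraction re-zeroes each trace to its first window; a constant offset
  would cancel there by construction, whereas the ramped offset survives as
  ≈ the full offset for windows past the ramp. Optional blink dropouts
  (NaN spans) exercise the gap policy.
- **Gaze.** Per axis, a saccade process (Poisson jumps at 1 Hz to new
  normal targets) plus within-fixation OU drift (τ = 0.3 s) plus
  measurement noise, with the stationary variance split 65/30/5% so the
  total equals the configured `gaze_var_h` / `gaze_var_v` exactly
  (defaults 4 and 2 units², horizontal wider, as free conversation gaze
  wanders laterally between face and surroundings).
- **Head IMU.** Per axis, a sum of narrowband components (band-limited
  Gaussian noise, 1 Hz bandwidth, scaled to the component's target
  variance) plus a white floor (SD 0.05). The default profile concentrates
  power below ~5 Hz (nodding, sway): acceleration axes
  (0.8 Hz, 0.5) + (3 Hz, 0.2); gyro axes (0.6 Hz, 0.4) + (2.5 Hz, 0.15).
- **Hand.** I.i.d. Bernoulli flags per second (p = 0.25).

Each device starts with a small fixed offset (0–27 ms) on the shared clock
and generates one padded second beyond the nominal duration, so
intersection-based alignment still covers the full task.

**Paired study construction.** Each participant draws a between-subject
baseline around the study-level ground truth (heart rate SD 6 bpm,
respiratory rate SD 1.5 breaths/min, pupil baseline SD 0.25 a.u., log-normal
scale 0.15 on gaze variances, hand probability SD 0.05), shared by that
participant's sessions. The in-person sessions then apply the configured
condition contrast on top: pupil offset +0.3 a.u., horizontal gaze variance
×2, heart rate +2 bpm, IMU components at ≤5 Hz ×2, hand probability ×1.5
(`EffectConfig` defaults; `EffectConfig.null()` removes all of them). The
directions encode the qualitative between-condition pattern this pipeline is
designed to detect; the magnitudes are simulation conventions chosen once to
sit near 2.5–4× the within-pair noise of the corresponding summary
statistic, the regime where a paired design with 18 participants has high
but not trivial power. No effect is configured for HRV, respiratory rate or
vertical gaze variance, which serve as built-in negative controls.

## Preprocessing

- **Filters.** The protocol fixes bands but not a filter family; we use
  4th-order Butterworth (monotone passband) applied forward–backward
  (`sosfiltfilt`), so the net phase is zero and event timing is preserved;
  the effective magnitude response is the design's squared. NaN spans are
  bridged by linear interpolation before filtering and restored after, so a
  blink cannot poison the whole record.
- **Alignment.** All channels are linearly interpolated on their native
  timestamps onto one uniform grid at `fs_common` (100 Hz), spanning the
  intersection of stream extents and anchored at the latest stream start.
  Whether the original analysis interpolated or binned is unstated; linear
  interpolation on timestamps is this package's convention (robust to
  irregular sampling, exact for affine signals). The binary hand channel is
  carried sample-and-hold. Gaps (NaN runs or missing coverage) up to 500 ms
  are filled by the interpolation; grid samples bridging longer gaps are
  filled numerically but flagged invalid — a conventional pupillometry
  compromise — and features treat windows with > 50% invalid samples as
  missing. The first/last 2 s are flagged as filter-transient edges;
  features skip only windows that lie entirely inside the flagged region.
- **Segmentation.** Windows of L = 30 s advance by S = 5 s;
  K = ⌊(T−L)/S⌋ + 1, so a 300 s task yields 55 windows. Windows are
  labelled by their **end** time (the first window is "30 s"), matching the
  30–300 s axis convention of windowed trace plots. Sessions shorter than
  one window produce an empty list with a warning, not an exception.

## Feature extraction

"Normalized" always means z-scored within the window; sample statistics use
the n−1 denominator; an extractor that cannot produce a defensible value
returns NaN, which propagates as pairwise deletion in the tests.

- **Heart rate** detects peaks of the z-normalized *negative first
  difference* of the derived ECG (the R downslope), with a 0.25 s
  refractory period (~240 bpm ceiling) and prominence ≥ 0.5 z-units, then
  reports 60·(n−1)/(span of detected peaks). Count-over-total-duration is
  adopted over mean instantaneous rate and documented as a convention; the
  two differ by O(jitter²).
- **HRV** is SD(beat intervals, n−1)/RMS(beat intervals): a dimensionless
  dispersion ratio (scale-free; distinct from SDNN or RMSSD alone).
- **Respiratory rate** applies the same peak logic to the z-normalized
  band-passed respiration signal with a 2 s refractory period
  (~30 breaths/min ceiling).
- **Pupil** subtracts the first *valid* window's mean from the whole trace
  (falling back to the first valid window when the first is blink-ruined,
  with the fallback recorded), then takes per-window means. Zeroing removes
  between-condition differences in camera-to-eye geometry; pupil units are
  therefore arbitrary and relative.
- **Gaze variance** is the per-axis within-window sample variance; window
  mean positions are also retained for the gaze dispersion ellipse.
- **Hand fraction** is 100 × the mean of the sample-and-hold binary flags.
- **Head-movement PSD** uses Welch's method with 1 s Hann segments and 50%
  overlap — the 1 Hz bin-width requirement fixes the segment length; taper
  and overlap are standard practice — computed per 30 s window, then
  averaged over windows, giving one 0–50 Hz row per participant per axis.

## Inference

- **Wilcoxon signed-rank** (two-sided, paired). Zero differences are
  dropped (classic convention; Pratt available via `zero_method`). The
  null distribution of W⁺ is enumerated exactly by subset-sum convolution
  over the observed (mid)ranks — valid under ties — for up to 25 effective
  pairs, which covers study-scale tests exactly; beyond that the normal
  approximation with the standard tie correction (−Σ(t³−t)/48) is used,
  without continuity correction.
- **Window-wise traces** are tested per window with pairwise deletion of
  missing values (≥ 2 complete pairs required) and masked at uncorrected
  α = 0.05 — time-resolved maps are exploratory by design — with a
  BH-adjusted mask reported alongside as a labelled extra.
- **Task summaries** average each participant over windows, then run one
  paired test on the means. This per-participant-mean construction is an
  interpretation of "feature averaged over the task with a p-value" and is
  documented as such.
- **Spectral comparison** tests each 1 Hz bin with the paired Wilcoxon on
  per-participant window-averaged PSDs (consistent with a paired test at
  study n), corrected per **axis** (6 families of 51 bins, matching the
  per-axis presentation of spectral panels) by Benjamini–Hochberg
  (implemented via `statsmodels.multipletests`, verified against the
  definitional step-up rule). The per-bin effect measure is the symmetric
  ratio (ā−b̄)/(ā+b̄), bounded in [−1, 1]; bins where both means are zero
  report 0 with a flag. The exact normalization used in prior presentations
  of "normalized PSD differences" is unstated; the symmetric ratio is this
  package's convention.
- **Gaze ellipse** is a *concentration* (covariance) ellipse of the
  window-average gaze positions — semi-axes √(λᵢ·χ²₂(0.95)) along the
  covariance eigenvectors — not a standard-error-of-mean ellipse; collinear
  inputs yield a degenerate flagged ellipse.

## Validation suites and problem sizes

The Monte-Carlo suites in `dyadsense.simulate` (used by the test suite and
`scripts/acceptance.py`) replay the study geometry — 18 pairs, 55 windows,
51 bins per axis — at the feature level: window values and per-participant
PSDs are drawn directly from the documented within-pair noise model
(log-normal for power quantities), rather than re-synthesizing and
re-filtering raw signals per replicate. Type-I error and power of the
inference layer depend only on this geometry; full-signal fidelity is
covered separately by end-to-end tests that run generation → preprocessing →
features → stats once at 18 participants with 120 s sessions. Null
calibration uses 200 replicate studies (11,000 window tests; 1,200 BH axis
families); power uses 100 replicates with effects set to 3× the within-pair
noise SD. Because BH's false-discovery guarantee is per family, the "zero
spectral rejections under the null" rate is evaluated per (replicate, axis)
family, where its expected value is ≥ 1−α. Parameter recovery uses 100
random draws on clean (noise-free) streams; the gaze-variance tolerance is
simulation-derived (4× the empirical relative SE of the variance estimator
from an independent 40-run pilot at the same record length, a max-over-100
bound).

## Known limitations

- The generator's noise model is stationary and Gaussian per modality; real
  ECG has morphology variation, real gaze has smooth pursuit, real IMU
  spectra are nonstationary. Recovery tolerances here do not transfer to
  arbitrary real data.
- HR estimation under additive noise can admit an occasional spurious peak
  (the prominence threshold is fixed at 0.5 z-units by contract), which
  inflates single-window HRV; recovery guarantees are stated for clean
  streams.
- Between-interlocutor coupling, EEG, electrodermal activity, audio and
  video are out of scope.
- XDF ingestion is an extension point: the CSV layout is the interchange
  format; a converter would populate it without touching the pipeline.
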