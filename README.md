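# dyadsense

Multimodal biosignal analysis comparing **in-person** and **video-mediated
(virtual)** dyadic conversation.

Psychophysiology studies of co-presence record many signals at once while two
people talk — ECG, a respiration belt, an eye tracker with pupillometry, a
head-worn IMU, and behavioral annotations — and ask which physiological and
behavioral measures differ between talking to someone in the room and talking
to them over a video call. `dyadsense` implements that analysis as a tested,
reusable pipeline for researchers in human–computer interaction and
psychophysiology:

- **Synthetic dyad-study generator** with known ground truth (heart rate and
  beat jitter, respiratory rate, pupil baseline/offset, gaze variance, IMU
  spectral profiles, hand-movement probability), so the whole pipeline is
  testable without human recordings.
- **Preprocessing**: two-electrode ECG lead derivation, zero-phase Butterworth
  filtering (ECG 2–30 Hz, respiration 0.1–0.5 Hz, 50 Hz anti-alias low-pass
  elsewhere), timestamp-based alignment of all streams onto a common 100 Hz
  grid, and segmentation into 30 s windows with a 5 s step (a 300 s task gives
  55 windows).
- **Per-window features**: heart rate and an HRV dispersion ratio from R-peak
  intervals, respiratory rate, mean pupil size zeroed to the first window,
  horizontal/vertical gaze-position variance, percentage of time the hands
  move, and Welch PSDs of the six head-IMU axes at 1 Hz resolution.
- **Paired nonparametric inference**: window-wise Wilcoxon signed-rank traces
  with significance masks, task-summary tests on per-participant means,
  per-frequency-bin spectral tests corrected with Benjamini–Hochberg per axis,
  symmetric normalized PSD differences, and 95% gaze concentration ellipses.

## The statistics in brief

For feature $x$ observed in $n$ pairs (one in-person and one virtual session
per participant), each window $w$ is tested with the two-sided Wilcoxon
signed-rank test on the paired differences $d_i = x^{\mathrm{in}}_{i,w} -
x^{\mathrm{virt}}_{i,w}$; zero differences are dropped and the null
distribution of $W^+$ is enumerated exactly (valid under ties) up to 25
effective pairs. Task summaries test per-participant window means. For head
movement, per-participant window-averaged Welch PSDs $P_i(f)$ are compared
bin-by-bin; the $m = 51$ p-values of one axis form one
Benjamini–Hochberg family (reject $p_{(i)}$ for $i \le \max\{k : p_{(k)} \le
k\alpha/m\}$), and the effect size per bin is
$(\bar P^{\mathrm{in}} - \bar P^{\mathrm{virt}}) / (\bar P^{\mathrm{in}} +
\bar P^{\mathrm{virt}}) \in [-1, 1]$. Gaze dispersion is summarized by the
covariance ellipse with semi-axes $\sqrt{\lambda_i\,\chi^2_{2,0.95}}$.

Hand, gaze, head-movement and pupil features are analyzed in the free-talk
task only; the reading task alternates phone-reading with eye contact, which
drives those signals for task-extrinsic reasons. Heart rate, HRV and
respiratory rate are analyzed in both tasks.

## Worked example

Simulate a small paired study (8 participants, 150 s free-talk sessions, with
the default in-person condition effects) and analyze it:

```sh
dyadsense simulate --out demo --seed 42 --participants 8 --duration 150 --tasks free_talk
dyadsense run --layout demo --out demo_out --tasks free_talk
```

`demo_out/summary_comparisons.csv` then reads:

```
task,feature,summary_p,mean_in_person,mean_virtual
free_talk,heart_rate,0.0078125,71.963964,70.082399
free_talk,hrv,0.109375,0.060132129,0.073290671
free_talk,respiratory_rate,0.4609375,15.17064,15.239805
free_talk,pupil_mean,0.0078125,0.24809836,-0.0019448305
free_talk,gaze_variance_h,0.0078125,6.9371808,3.5391058
free_talk,gaze_variance_v,0.84375,1.8580076,1.8216197
free_talk,hand_fraction,0.0078125,45.548333,30.050667
```

The generator injected in-person effects on pupil size, horizontal gaze
variance, heart rate, hand movement and low-frequency head movement — and
exactly those summaries are significant (p = 0.0078 is the smallest two-sided
exact p attainable with 8 pairs, i.e. all 8 paired differences share one
sign), while the unaffected measures (HRV, respiratory rate, vertical gaze
variance) are not. `spectral_comparisons.csv` shows the spectral fingerprint:
positive normalized PSD differences around 0.32–0.38 at low frequencies,
decaying toward zero with BH-significant bins concentrated below ~16 Hz, and
noise-level differences above. `gaze_ellipses.json` contains the 95%
concentration ellipses of window-average gaze positions; with a 2× horizontal
variance boost the in-person major semi-axis (1.33) exceeds the virtual one
(1.22).

Every run writes a `manifest.json` (config snapshot, seed, input hash,
produced files); re-running with the same layout and config reproduces
byte-identical tables. The same analysis is available as a library:

```python
from dyadsense.pipeline import simulate_study, analyze_sessions
result = analyze_sessions(simulate_study(seed=42, n_participants=8))
result.reports[("free_talk", "pupil_mean")].summary_p
```

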