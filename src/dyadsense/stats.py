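"""Paired nonparametric inference layer.

Window-wise traces are compared with a paired two-sided Wilcoxon
signed-rank test across participants (uncorrected, as an exploratory
time-resolved map; a Benjamini-Hochberg-adjusted mask is reported alongside
as a labelled extra).  Task-level summaries take each participant's mean
over windows and run one paired test.  Head-movement spectra are compared
bin-by-bin with the same test, corrected per signal axis with the
Benjamini-Hochberg step-up rule, and summarised by the symmetric normalized
difference (a-b)/(a+b) of the condition-mean PSDs.  Gaze dispersion is
summarised by a covariance concentration ellipse at a chi-squared quantile.

The Wilcoxon p-value is exact (full enumeration of sign assignments over
the observed ranks, valid under ties) for up to ``EXACT_MAX_N`` effective
pairs and uses the tie-corrected normal approximation beyond that.  The
subset-sum convolution makes enumeration cheap well past the study's 18
pairs, so paired tests at study scale are exact.  Zero
differences are dropped (classic Wilcoxon convention; Pratt's method is
available via ``zero_method="pratt"``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as spstats
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig
from .features import PsdSet, WindowedFeature

#: Largest effective n for which the exact null distribution is enumerated.
EXACT_MAX_N = 25


@dataclass
class WilcoxonResult:
    statistic: float  # W+ = sum of ranks of positive differences
    pvalue: float
    n_effective: int
    method: str  # "exact" | "approx" | "degenerate"

    def __iter__(self):
        return iter((self.statistic, self.pvalue))


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p by enumerating all 2^n sign assignments.

    Uses a subset-sum convolution over the (mid)ranks, doubled to make
    half-integer midranks integral, so ties are handled exactly.
    """
    r2 = np.round(ranks * 2).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: len(counts) - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(w_plus * 2))
    p_low = counts[: w2 + 1].sum()
    p_high = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def wilcoxon_signed_rank(
    x,
    y=None,
    zero_method: str = "wilcox",
    exact_max_n: int = EXACT_MAX_N,
) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Parameters
    ----------
    x, y : array-like
        Paired observations; ``y=None`` treats ``x`` as differences.
        NaN pairs are dropped (pairwise deletion).
    zero_method : str
        ``"wilcox"`` drops zero differences; ``"pratt"`` ranks them but
        excludes them from the statistic.
    """
    x = np.asarray(x, dtype=float)
    d = x if y is None else x - np.asarray(y, dtype=float)
    d = d[~np.isnan(d)]
    if len(d) < 2:
        return WilcoxonResult(float("nan"), float("nan"), len(d), "degenerate")

    if zero_method == "pratt":
        ranks_all = spstats.rankdata(np.abs(d))
        nz = d != 0
        ranks = ranks_all[nz]
        d_nz = d[nz]
    elif zero_method == "wilcox":
        d_nz = d[d != 0]
        ranks = spstats.rankdata(np.abs(d_nz))
    else:
        raise ValueError(f"unknown zero_method {zero_method!r}")

    n = len(d_nz)
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return WilcoxonResult(0.0, 1.0, 0, "degenerate")

    w_plus = float(ranks[d_nz > 0].sum())
    if n <= exact_max_n:
        p = _exact_signed_rank_p(ranks, w_plus)
        return WilcoxonResult(w_plus, p, n, "exact")

    mu = ranks.sum() / 2.0
    # Tie correction: subtract sum(t^3 - t)/48 from the null variance.
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts.astype(float) ** 3 - tie_counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return WilcoxonResult(w_plus, 1.0, n, "approx")
    z = (w_plus - mu) / np.sqrt(var)
    p = float(min(1.0, 2.0 * spstats.norm.sf(abs(z))))
    return WilcoxonResult(w_plus, p, n, "approx")


def bh_adjust(p, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up decisions and adjusted p-values.

    NaN entries are excluded from the family and stay NaN / non-rejected.
    """
    p = np.asarray(p, dtype=float)
    reject = np.zeros(p.shape, dtype=bool)
    p_adj = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.sum() == 0:
        return reject, p_adj
    rej, adj, _, _ = multipletests(p[ok], alpha=alpha, method="fdr_bh")
    reject[ok] = rej
    p_adj[ok] = adj
    return reject, p_adj


@dataclass
class ComparisonReport:
    """Window-wise and summary comparison of one feature between conditions."""

    feature_name: str
    task: str
    window_end_times: np.ndarray
    p_values: np.ndarray  # per window
    significant: np.ndarray  # p < alpha, uncorrected
    significant_bh: np.ndarray  # labelled extra: BH-adjusted across windows
    n_pairs: np.ndarray
    summary_p: float
    summary_means: dict = field(default_factory=dict)  # condition -> per-participant means
    alpha: float = 0.05


def windowwise_compare(
    fa: WindowedFeature, fb: WindowedFeature, cfg: AnalysisConfig | None = None
) -> ComparisonReport:
    """Per-window paired Wilcoxon between two conditions of one feature.

    Missing values are deleted pairwise per window; windows with fewer than
    two complete pairs get a missing p.  The task summary averages each
    participant over windows and runs one paired test on those means.
    """
    cfg = cfg or AnalysisConfig()
    if fa.values.shape != fb.values.shape:
        raise ValueError("conditions disagree in participants x windows shape")
    if not np.allclose(fa.window_end_times, fb.window_end_times):
        raise ValueError("conditions are not on the same window grid")
    n_win = fa.values.shape[1]
    pvals = np.full(n_win, np.nan)
    n_pairs = np.zeros(n_win, dtype=int)
    for w in range(n_win):
        xa, xb = fa.values[:, w], fb.values[:, w]
        ok = ~np.isnan(xa) & ~np.isnan(xb)
        n_pairs[w] = int(ok.sum())
        if n_pairs[w] >= 2:
            pvals[w] = wilcoxon_signed_rank(xa[ok], xb[ok]).pvalue

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ma, mb = fa.participant_means(), fb.participant_means()
    ok = ~np.isnan(ma) & ~np.isnan(mb)
    summary_p = (
        wilcoxon_signed_rank(ma[ok], mb[ok]).pvalue if ok.sum() >= 2 else float("nan")
    )

    with np.errstate(invalid="ignore"):
        significant = pvals < cfg.alpha
    bh_mask, _ = bh_adjust(pvals, cfg.alpha)
    return ComparisonReport(
        feature_name=fa.feature_name,
        task=fa.task,
        window_end_times=fa.window_end_times.copy(),
        p_values=pvals,
        significant=significant,
        significant_bh=bh_mask,
        n_pairs=n_pairs,
        summary_p=float(summary_p),
        summary_means={fa.condition: ma, fb.condition: mb},
        alpha=cfg.alpha,
    )


def normalized_psd_difference(a: PsdSet, b: PsdSet) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric normalized difference of condition-mean PSDs per bin:
    (mean_a - mean_b) / (mean_a + mean_b), bounded in [-1, 1].

    Returns (values, zero_flags); bins where both means are zero get value 0
    and a flag.
    """
    if a.power.shape[1] != b.power.shape[1] or not np.allclose(
        a.frequencies, b.frequencies
    ):
        raise ValueError("PSD sets disagree in frequency bins")
    ma = np.nanmean(a.power, axis=0)
    mb = np.nanmean(b.power, axis=0)
    denom = ma + mb
    zero = denom == 0
    out = np.zeros_like(denom)
    out[~zero] = (ma[~zero] - mb[~zero]) / denom[~zero]
    return out, zero


@dataclass
class SpectralComparison:
    """Per-bin comparison of one IMU axis between conditions."""

    signal_axis: str
    frequencies: np.ndarray
    normalized_difference: np.ndarray
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    rejected: np.ndarray  # BH decisions at alpha, family = this axis's bins
    alpha: float = 0.05


def spectral_compare(
    a: PsdSet, b: PsdSet, cfg: AnalysisConfig | None = None
) -> SpectralComparison:
    """Bin-wise paired Wilcoxon on per-participant PSDs, BH-corrected.

    The correction family is all frequency bins of this one signal axis.
    """
    cfg = cfg or AnalysisConfig()
    if a.signal_axis != b.signal_axis:
        raise ValueError(f"axis mismatch: {a.signal_axis} vs {b.signal_axis}")
    nd, _ = normalized_psd_difference(a, b)
    n_bins = a.power.shape[1]
    pvals = np.full(n_bins, np.nan)
    for i in range(n_bins):
        xa, xb = a.power[:, i], b.power[:, i]
        ok = ~np.isnan(xa) & ~np.isnan(xb)
        if ok.sum() >= 2:
            pvals[i] = wilcoxon_signed_rank(xa[ok], xb[ok]).pvalue
    rejected, p_adj = bh_adjust(pvals, cfg.alpha)
    return SpectralComparison(
        signal_axis=a.signal_axis,
        frequencies=a.frequencies.copy(),
        normalized_difference=nd,
        p_raw=pvals,
        p_adjusted=p_adj,
        rejected=rejected,
        alpha=cfg.alpha,
    )


@dataclass
class GazeEllipse:
    """Covariance concentration ellipse of 2-D gaze points."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]  # major, minor
    angle_rad: float  # orientation of the major axis
    level: float
    degenerate: bool = False


def confidence_ellipse(points: np.ndarray, level: float = 0.95) -> GazeEllipse:
    """Concentration ellipse containing ``level`` probability mass under a
    bivariate normal fitted by sample mean and covariance.

    Semi-axes are ``sqrt(lambda_i * q)`` with ``lambda_i`` the covariance
    eigenvalues and ``q`` the chi-squared(2 df) quantile at ``level``; the
    orientation follows the leading eigenvector.  Collinear inputs yield a
    degenerate (zero minor axis) ellipse with a flag.
    """
    points = np.asarray(points, dtype=float)
    points = points[~np.isnan(points).any(axis=1)]
    if points.ndim != 2 or points.shape[1] != 2 or points.shape[0] < 3:
        raise ValueError("need at least 3 (h, v) points")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    center = points.mean(axis=0)
    cov = np.cov(points, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.0, None)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    q = spstats.chi2.ppf(level, df=2)
    semi = np.sqrt(evals * q)
    angle = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
    degenerate = bool(evals[1] <= 1e-12 * max(evals[0], 1.0))
    if degenerate:
        semi[1] = 0.0
    return GazeEllipse(
        center=(float(center[0]), float(center[1])),
        semi_axes=(float(semi[0]), float(semi[1])),
        angle_rad=angle,
        level=level,
        degenerate=degenerate,
    )
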