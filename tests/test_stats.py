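"""Inference layer vs independent oracles (brute-force enumeration,
definitional step-up rule, chi-squared closed forms, scipy cross-checks)."""

import itertools

import numpy as np
import pytest
from scipy import stats as spstats

from dyadsense.config import AnalysisConfig
from dyadsense.features import PsdSet, WindowedFeature
from dyadsense.stats import (
    bh_adjust,
    confidence_ellipse,
    normalized_psd_difference,
    spectral_compare,
    wilcoxon_signed_rank,
    windowwise_compare,
)


def brute_force_signed_rank_p(d: np.ndarray) -> float:
    """Independent oracle: enumerate all 2^n sign assignments directly."""
    d = d[d != 0]
    n = len(d)
    ranks = spstats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array(
        [np.sum(ranks[list(signs)]) for signs in
         (np.array(c, dtype=bool) for c in itertools.product([0, 1], repeat=n))]
    )
    p_low = np.mean(ws <= w_obs + 1e-12)
    p_high = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(p_low, p_high))


def step_up_oracle(p: np.ndarray, alpha: float) -> np.ndarray:
    """Definitional BH: reject p(i) for i <= max{k : p(k) <= k*alpha/m}."""
    m = len(p)
    order = np.argsort(p)
    ks = np.nonzero(p[order] <= (np.arange(1, m + 1) * alpha / m))[0]
    reject = np.zeros(m, dtype=bool)
    if len(ks):
        reject[order[: ks[-1] + 1]] = True
    return reject


class TestWilcoxon:
    def test_identical_pairs_give_p_one(self):
        x = np.arange(8.0)
        with pytest.warns(UserWarning):
            r = wilcoxon_signed_rank(x, x)
        assert r.pvalue == 1.0

    def test_five_positive_distinct_pairs(self):
        r = wilcoxon_signed_rank(np.array([0.3, 1.0, 2.0, 0.7, 1.5]))
        assert r.pvalue == pytest.approx(0.0625)
        assert r.method == "exact"

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(60):
            n = int(rng.integers(3, 11))
            d = np.round(rng.normal(size=n), 1)  # rounding induces ties/zeros
            if np.all(d == 0):
                continue
            got = wilcoxon_signed_rank(d).pvalue
            want = brute_force_signed_rank_p(d)
            assert got == pytest.approx(want, abs=1e-12)

    def test_matches_scipy_exact_without_ties(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 13))
            x, y = rng.normal(size=n), rng.normal(size=n)
            got = wilcoxon_signed_rank(x, y).pvalue
            want = spstats.wilcoxon(x, y, method="exact").pvalue
            assert got == pytest.approx(want, abs=1e-12)

    def test_matches_scipy_normal_approximation(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        got = wilcoxon_signed_rank(x, y).pvalue
        want = spstats.wilcoxon(x, y, method="approx", correction=False).pvalue
        assert got == pytest.approx(want, rel=1e-9)

    def test_nan_pairs_deleted(self):
        x = np.array([1.0, 2.0, np.nan, 3.0, 4.0, 5.0])
        y = np.zeros(6)
        r = wilcoxon_signed_rank(x, y)
        assert r.n_effective == 5
        assert r.pvalue == pytest.approx(0.0625)

    def test_single_pair_missing(self):
        r = wilcoxon_signed_rank(np.array([1.0]))
        assert np.isnan(r.pvalue)

    def test_pratt_handles_zeros(self):
        d = np.array([0.0, 1.0, 2.0, -0.5, 3.0])
        r = wilcoxon_signed_rank(d, zero_method="pratt")
        assert 0.0 < r.pvalue <= 1.0


class TestBhAdjust:
    def test_all_four_rejected_at_boundary(self):
        rej, adj = bh_adjust(np.array([0.01, 0.02, 0.04, 0.05]), alpha=0.05)
        assert rej.all()
        assert adj[-1] == pytest.approx(0.05)

    def test_single_p(self):
        assert bh_adjust(np.array([0.04]), 0.05)[0][0]
        assert not bh_adjust(np.array([0.06]), 0.05)[0][0]

    def test_all_ones_none_rejected(self):
        rej, _ = bh_adjust(np.ones(10), 0.05)
        assert not rej.any()

    def test_empty_input(self):
        rej, adj = bh_adjust(np.array([]), 0.05)
        assert rej.size == 0 and adj.size == 0

    def test_matches_step_up_oracle(self, rng):
        for _ in range(200):
            m = int(rng.integers(1, 60))
            p = rng.uniform(size=m) ** rng.uniform(0.5, 3.0)
            rej, _ = bh_adjust(p, 0.05)
            np.testing.assert_array_equal(rej, step_up_oracle(p, 0.05))

    def test_rejections_monotone_in_alpha(self, rng):
        p = rng.uniform(size=40)
        counts = [bh_adjust(p, a)[0].sum() for a in (0.01, 0.05, 0.1, 0.2, 0.5)]
        assert all(c2 >= c1 for c1, c2 in zip(counts, counts[1:]))


def _wf(values, condition, name="f", task="free_talk"):
    values = np.asarray(values, dtype=float)
    return WindowedFeature(
        feature_name=name,
        units="a.u.",
        condition=condition,
        task=task,
        participants=[f"P{i}" for i in range(values.shape[0])],
        values=values,
        window_end_times=30.0 + 5.0 * np.arange(values.shape[1]),
    )


class TestWindowwiseCompare:
    def test_identical_matrices_all_p_one(self, rng):
        v = rng.normal(size=(10, 12))
        with pytest.warns(UserWarning):
            rep = windowwise_compare(_wf(v, "in_person"), _wf(v, "virtual"))
        np.testing.assert_allclose(rep.p_values, 1.0)
        assert not rep.significant.any()

    def test_large_shift_all_significant_with_minimal_exact_p(self, rng):
        n = 18
        a = rng.normal(size=(n, 10)) + 10.0
        b = rng.normal(size=(n, 10))
        rep = windowwise_compare(_wf(a, "in_person"), _wf(b, "virtual"))
        assert rep.significant.all()
        # all-positive differences at n=18: two-sided p = 2 * 2^-18
        assert rep.summary_p == pytest.approx(2.0 * 2.0**-18, rel=1e-9)

    def test_missing_values_deleted_pairwise(self, rng):
        a = rng.normal(size=(6, 4))
        b = rng.normal(size=(6, 4))
        a[0, 2] = np.nan
        rep = windowwise_compare(_wf(a, "in_person"), _wf(b, "virtual"))
        assert rep.n_pairs[2] == 5
        assert rep.n_pairs[0] == 6

    def test_too_few_pairs_gives_missing_p(self):
        a = np.full((4, 3), np.nan)
        a[0] = 1.0
        b = np.zeros((4, 3))
        rep = windowwise_compare(_wf(a, "in_person"), _wf(b, "virtual"))
        assert np.isnan(rep.p_values).all()


class TestSpectral:
    def test_normalized_difference_definitional(self):
        f = np.arange(3.0)
        a = PsdSet("acc_x", f, np.full((4, 3), 3.0))
        b = PsdSet("acc_x", f, np.full((4, 3), 1.0))
        nd, flags = normalized_psd_difference(a, b)
        np.testing.assert_allclose(nd, 0.5)
        assert not flags.any()
        nd_rev, _ = normalized_psd_difference(b, a)
        np.testing.assert_allclose(nd_rev, -0.5)

    def test_equal_sets_zero_difference_no_rejections(self, rng):
        f = np.arange(51.0)
        power = rng.uniform(0.5, 2.0, size=(8, 51))
        a = PsdSet("acc_x", f, power)
        b = PsdSet("acc_x", f, power.copy())
        nd, _ = normalized_psd_difference(a, b)
        np.testing.assert_allclose(nd, 0.0)
        with pytest.warns(UserWarning):
            sc = spectral_compare(a, b)
        assert not sc.rejected.any()

    def test_both_zero_bin_flagged(self):
        f = np.arange(2.0)
        a = PsdSet("acc_x", f, np.array([[0.0, 1.0]]))
        b = PsdSet("acc_x", f, np.array([[0.0, 3.0]]))
        nd, flags = normalized_psd_difference(a, b)
        assert nd[0] == 0.0 and flags[0]

    def test_bounded_in_unit_interval(self, rng):
        f = np.arange(20.0)
        a = PsdSet("acc_x", f, rng.uniform(0, 5, size=(6, 20)))
        b = PsdSet("acc_x", f, rng.uniform(0, 5, size=(6, 20)))
        nd, _ = normalized_psd_difference(a, b)
        assert np.all(np.abs(nd) <= 1.0)


class TestConfidenceEllipse:
    def test_isotropic_gaussian_axes_match_chi2_quantile(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(100000, 2))
        e = confidence_ellipse(pts, level=0.95)
        expected = np.sqrt(spstats.chi2.ppf(0.95, df=2))
        assert e.semi_axes[0] == pytest.approx(expected, rel=0.02)
        assert e.semi_axes[1] == pytest.approx(expected, rel=0.02)

    def test_collinear_points_degenerate(self):
        t = np.linspace(0, 1, 50)
        pts = np.column_stack([t, 2 * t + 1])
        e = confidence_ellipse(pts)
        assert e.degenerate and e.semi_axes[1] == 0.0

    def test_rotation_equivariance(self, rng):
        pts = rng.normal(size=(500, 2)) @ np.diag([3.0, 1.0])
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        e1 = confidence_ellipse(pts)
        e2 = confidence_ellipse(pts @ R.T)
        assert e2.semi_axes == pytest.approx(e1.semi_axes, rel=1e-9)
        d = (e2.angle_rad - e1.angle_rad - theta) % np.pi
        assert min(d, np.pi - d) < 1e-9

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            confidence_ellipse(np.zeros((2, 2)))
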