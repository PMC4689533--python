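"""Aggregation, bootstrap box plots, and the domain-of-attraction verdict."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tailverdict import (
    AlphaCurve,
    StableParams,
    StudentParams,
    TemperedStableParams,
    aggregate,
    alpha_curve,
    bootstrap_curves,
    boxplot_stats,
    classify,
    stable_rvs,
    student_rvs,
    tempered_rvs,
    verdicts_differ,
)


class TestAggregate:
    def test_block_sums_drop_remainder(self):
        assert aggregate([1, 2, 3, 4, 5], 2).tolist() == [3.0, 7.0]

    def test_k_one_is_identity(self):
        x = np.arange(7.0)
        assert np.array_equal(aggregate(x, 1), x)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        data=st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=200),
        K=st.integers(1, 20),
    )
    def test_conservation_and_length(self, data, K):
        x = np.asarray(data)
        if K > x.size:
            with pytest.raises(ValueError):
                aggregate(x, K)
            return
        out = aggregate(x, K)
        m = x.size // K
        assert out.size == m
        assert out.sum() == pytest.approx(x[: m * K].sum(), rel=1e-9, abs=1e-6)

    def test_invalid_K(self):
        with pytest.raises(ValueError):
            aggregate([1.0, 2.0], 0)


class TestBoxplotStats:
    def test_printed_example_outlier(self):
        s = boxplot_stats([1, 2, 3, 4, 5, 6, 7, 8, 9, 100])
        assert s.outliers.tolist() == [100.0]
        assert s.whisker_high == 9.0
        assert s.whisker_low == 1.0

    def test_constant_batch(self):
        s = boxplot_stats([3.0] * 12)
        assert s.Q1 == s.median == s.Q3 == s.whisker_low == s.whisker_high == 3.0
        assert s.outliers.size == 0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=100))
    def test_against_bruteforce_rule(self, data):
        v = np.asarray(data)
        s = boxplot_stats(v)
        # independent brute force of the fence rule with interpolated quartiles
        srt = np.sort(v)

        def quantile(q):
            pos = (srt.size - 1) * q
            lo = int(np.floor(pos))
            hi = int(np.ceil(pos))
            return srt[lo] + (pos - lo) * (srt[hi] - srt[lo])

        q1, q3 = quantile(0.25), quantile(0.75)
        fence_lo, fence_hi = q1 - 1.5 * (q3 - q1), q3 + 1.5 * (q3 - q1)
        out = np.sort(v[(v < fence_lo) | (v > fence_hi)])
        assert s.Q1 <= s.median <= s.Q3
        assert np.array_equal(s.outliers, out)
        # partition: outliers plus in-fence values restore the multiset
        inl = v[(v >= fence_lo) & (v <= fence_hi)]
        assert np.array_equal(np.sort(np.concatenate([inl, out])), srt)
        if inl.size:
            assert s.whisker_low == inl.min() and s.whisker_high == inl.max()


class TestAlphaCurve:
    def test_stable_curve_is_flat(self):
        # aggregation does not change the index of an exact stable sample
        x = stable_rvs(StableParams(1.9), 2000, seed=1)
        c = alpha_curve(x, 10)
        assert c.alpha_hats.max() - c.alpha_hats.min() < 0.15
        assert np.all((c.alpha_hats > 0) & (c.alpha_hats <= 2))
        assert c.K_levels.tolist() == list(range(1, 11))

    def test_stable_curves_statistically_flat_across_seeds(self):
        """Least-squares slope of the alpha curve over K is indistinguishable
        from 0 (3 sigma) for exact stable data, for several indices."""
        K = np.arange(1, 11)
        for alpha in [1.85, 1.9, 1.95]:
            slopes = [
                np.polyfit(K, alpha_curve(stable_rvs(StableParams(alpha), 2000, s), 10).alpha_hats, 1)[0]
                for s in range(100)
            ]
            mean, se = np.mean(slopes), np.std(slopes, ddof=1) / 10.0
            assert abs(mean) < 3 * se, (alpha, mean, se)

    def test_tempered_curve_drifts_upward(self):
        # finite-variance data drift toward alpha=2 under aggregation
        up = 0
        for s in range(15):
            c = alpha_curve(tempered_rvs(TemperedStableParams(1.9, 0.1), 2000, s), 10)
            up += c.alpha_hats[9] > c.alpha_hats[0]
        assert up > 7

    def test_error_annotated_with_level(self):
        from tailverdict import EstimationError

        with pytest.raises(EstimationError, match="K=1"):
            alpha_curve(np.ones(300), 4)  # degenerate sample fails at the first level


class TestBootstrap:
    def test_deterministic_given_seed(self):
        x = stable_rvs(StableParams(1.9), 500, seed=2)
        r1 = bootstrap_curves(x, B=8, K_max=5, seed=77)
        r2 = bootstrap_curves(x, B=8, K_max=5, seed=77)
        assert np.array_equal(r1.estimates, r2.estimates)

    def test_single_replicate_degenerate_boxstats(self):
        x = stable_rvs(StableParams(1.9), 500, seed=3)
        r = bootstrap_curves(x, B=1, K_max=3, seed=5)
        assert r.estimates.shape == (1, 3)
        for s in r.per_K_boxstats:
            assert s.Q1 == s.median == s.Q3 == s.whisker_low == s.whisker_high

    def test_boxes_widen_with_aggregation(self):
        # higher K means shorter aggregated samples, hence noisier estimates
        x = stable_rvs(StableParams(1.85), 2000, seed=4)
        r = bootstrap_curves(x, B=100, K_max=10, seed=6)
        iqr = np.array([s.Q3 - s.Q1 for s in r.per_K_boxstats])
        assert np.mean(iqr[5:]) > np.mean(iqr[:5])


class TestClassify:
    def _curve(self, alphas):
        a = np.asarray(alphas, dtype=float)
        return AlphaCurve(np.arange(1, a.size + 1), a, 2000)

    def test_all_two_is_light(self):
        v = classify(self._curve([2.0] * 10))
        assert v.domain_label == "light"
        assert v.limiting_alpha == pytest.approx(2.0)

    def test_flat_below_two_is_heavy(self):
        v = classify(self._curve([1.90] * 10))
        assert v.domain_label == "heavy"
        assert v.limiting_alpha == pytest.approx(1.90)

    def test_rising_to_two_is_light(self):
        rising = np.linspace(1.85, 1.99, 10)
        assert classify(self._curve(rising), delta=0.02).domain_label == "light"

    def test_rising_but_still_low_is_inconclusive(self):
        rising = np.linspace(1.5, 1.8, 10)
        assert classify(self._curve(rising), delta=0.02).domain_label == "inconclusive"

    def test_too_few_levels(self):
        with pytest.raises(ValueError):
            classify(self._curve([2.0, 2.0]))

    def test_verdicts_differ_rules(self):
        light = classify(self._curve([2.0] * 10))
        heavy_190 = classify(self._curve([1.90] * 10))
        heavy_185 = classify(self._curve([1.85] * 10))
        assert verdicts_differ(light, heavy_190)
        assert verdicts_differ(heavy_185, heavy_190)
        assert not verdicts_differ(heavy_190, heavy_190)
        assert not verdicts_differ(light, light)
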