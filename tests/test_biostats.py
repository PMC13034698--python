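"""Normalization, t-tests, BH adjustment, effect sizes, power."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cometdr.biostats import (
    bh_adjust,
    calibrator_scale,
    cohens_d_from_summary,
    de_table,
    median_normalize,
    power_two_sample_t,
    report_d,
    sample_size_for_power,
    t_test_two_sample,
)


def bh_reference(p):
    """Independent step-up implementation of Benjamini-Hochberg."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p[idx] * m / rank)
        adjusted[idx] = running_min
    return np.minimum(adjusted, 1.0)


class TestCalibratorScale:
    def _matrix(self):
        values = pd.DataFrame(
            {"A": [10.0, 20.0, 30.0], "B": [5.0, 6.0, 7.0]},
            index=["s1", "s2", "s3"],
        )
        batches = pd.Series(["B1", "B2", "B2"], index=values.index, name="batch")
        calibrators = pd.DataFrame(
            {"A": [100.0, 200.0], "B": [50.0, 50.0]}, index=["B1", "B2"]
        )
        return values, batches, calibrators

    def test_single_batch_identity(self):
        values, _, _ = self._matrix()
        batches = pd.Series(["B1"] * 3, index=values.index)
        calibrators = pd.DataFrame({"A": [100.0], "B": [50.0]}, index=["B1"])
        out = calibrator_scale(values, batches, calibrators)
        assert np.allclose(out, values)

    def test_doubled_calibrator_halves_values(self):
        values, batches, calibrators = self._matrix()
        out = calibrator_scale(values, batches, calibrators)
        # batch B2 protein A calibrator is 2x reference -> values halved
        assert out.loc["s2", "A"] == pytest.approx(10.0)
        assert out.loc["s3", "A"] == pytest.approx(15.0)
        # protein B calibrators equal -> unchanged
        assert out.loc["s2", "B"] == pytest.approx(6.0)
        # reference batch unchanged
        assert out.loc["s1", "A"] == pytest.approx(10.0)

    def test_zero_calibrator_rejected(self):
        values, batches, calibrators = self._matrix()
        calibrators.loc["B2", "A"] = 0.0
        with pytest.raises(ValueError, match="nonzero"):
            calibrator_scale(values, batches, calibrators)


class TestMedianNormalize:
    def test_equal_medians_fixed_point(self):
        arr = np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        assert np.allclose(median_normalize(arr), arr)

    def test_all_medians_equal_after(self):
        rng = np.random.default_rng(0)
        arr = rng.lognormal(size=(6, 11))
        out = median_normalize(arr)
        medians = np.median(out, axis=1)
        assert np.ptp(medians) < 1e-12

    def test_known_scale_factors(self):
        """Sample medians {10, 20, 40} scale by {2, 1, 0.5} to grand 20."""
        arr = np.array([[10.0] * 3, [20.0] * 3, [40.0] * 3])
        out = median_normalize(arr)
        assert np.allclose(out, 20.0)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        arr = rng.lognormal(size=(5, 9))
        once = median_normalize(arr)
        assert np.allclose(median_normalize(once), once)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            median_normalize(np.array([[1.0, -2.0]]))


class TestTTest:
    def test_identical_groups_null(self):
        t, p, fc = t_test_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0) and fc == 0.0

    def test_antisymmetry(self):
        a, b = [1.0, 2.0, 4.0], [3.0, 5.0, 6.0]
        t1, p1, fc1 = t_test_two_sample(a, b)
        t2, p2, fc2 = t_test_two_sample(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)
        assert fc1 == pytest.approx(-fc2)

    def test_textbook_pooled_formula(self):
        """2x5 fixture against the hand-applied pooled-variance formula."""
        a = np.array([5.1, 4.9, 5.6, 4.8, 5.3])
        b = np.array([4.2, 4.4, 4.0, 4.5, 4.1])
        t, p, fc = t_test_two_sample(a, b)
        sp2 = (a.var(ddof=1) * 4 + b.var(ddof=1) * 4) / 8
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 5 + 1 / 5))
        p_hand = 2 * stats.t.sf(abs(t_hand), df=8)
        assert t == pytest.approx(t_hand) and p == pytest.approx(p_hand)
        assert fc == pytest.approx(a.mean() - b.mean())

    def test_degenerate_zero_variance(self):
        assert t_test_two_sample([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0, 0.0)
        with pytest.raises(ValueError, match="degenerate"):
            t_test_two_sample([2.0, 2.0], [3.0, 3.0])

    def test_group_size_minimum(self):
        with pytest.raises(ValueError, match="at least 2"):
            t_test_two_sample([1.0], [2.0, 3.0])


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_all_equal_stay_equal(self):
        out = bh_adjust([0.2] * 7)
        assert np.allclose(out, 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.0])
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=1000, deadline=None)
    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=10))
    def test_matches_independent_step_up(self, pvals):
        assert np.allclose(bh_adjust(pvals), bh_reference(pvals))

    def test_monotone_in_ranks(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestEffectSizeAndPower:
    def test_summary_d_reported_value(self):
        assert cohens_d_from_summary(2.6, 1.9) == pytest.approx(1.368421, abs=1e-6)
        assert report_d(2.6, 1.9) == 1.4

    def test_d_identity_and_null(self):
        assert cohens_d_from_summary(1.9, 1.9) == 1.0
        assert cohens_d_from_summary(0.0, 1.9) == 0.0
        with pytest.raises(ValueError):
            cohens_d_from_summary(1.0, 0.0)

    def test_null_effect_power_equals_alpha(self):
        assert power_two_sample_t(0.0, 20, 20, alpha=0.05) == pytest.approx(0.05)

    def test_posthoc_power_of_study_design(self):
        power = power_two_sample_t(2.6 / 1.9, 87, 14, alpha=0.05)
        assert power == pytest.approx(0.997, abs=0.001)

    def test_power_matches_monte_carlo(self):
        """d=0.8, n=25/25 against a simulated rejection rate."""
        d, n = 0.8, 25
        rng = np.random.default_rng(42)
        reps = 200_000
        a = rng.standard_normal((reps, n)) + d
        b = rng.standard_normal((reps, n))
        tstat, p = stats.ttest_ind(a, b, axis=1)
        mc = (p < 0.05).mean()
        exact = power_two_sample_t(d, n, n)
        assert exact == pytest.approx(mc, abs=2 * np.sqrt(mc * (1 - mc) / reps))

    def test_power_monotone_in_d_and_n(self):
        assert power_two_sample_t(1.0, 20, 20) > power_two_sample_t(0.5, 20, 20)
        assert power_two_sample_t(0.5, 40, 40) > power_two_sample_t(0.5, 20, 20)


class TestSampleSize:
    def test_minimality_contract(self):
        n1, n2 = sample_size_for_power(1.4, power=0.9, ratio=1.0)
        assert power_two_sample_t(1.4, n1, n2) >= 0.9
        if n2 > 2:
            assert power_two_sample_t(1.4, n1 - 1, n2 - 1) < 0.9

    def test_matches_brute_force_scan(self):
        n1, n2 = sample_size_for_power(1.4, power=0.9, ratio=1.0)
        for n in range(2, n2):
            assert power_two_sample_t(1.4, n, n) < 0.9

    def test_doubling_d_shrinks_n(self):
        small = sum(sample_size_for_power(1.0, power=0.9, ratio=1.0))
        large = sum(sample_size_for_power(2.0, power=0.9, ratio=1.0))
        assert large <= small

    def test_fixed_n2_allocation(self):
        n1, n2 = sample_size_for_power(2.6 / 1.9, power=0.9, n2=7)
        assert n2 == 7 and power_two_sample_t(2.6 / 1.9, n1, 7) >= 0.9

    def test_unreachable_power_with_fixed_n2(self):
        with pytest.raises(ValueError, match="unreachable"):
            sample_size_for_power(0.1, power=0.99, n2=3)


class TestDETable:
    def _cohort(self, n_cases=14, n_controls=87, d=1.4, sd=1.9, seed=0):
        rng = np.random.default_rng(seed)
        n = n_cases + n_controls
        labels = np.r_[np.ones(n_cases), np.zeros(n_controls)]
        log2 = rng.normal(10.0, sd, size=(n, 4))
        log2[labels == 1, 0] += d * sd  # plant one real effect
        values = pd.DataFrame(2.0**log2, columns=["hit", "null1", "null2", "null3"])
        return values, labels

    def test_planted_effect_detected_at_power_rate(self):
        """A d=1.4 protein at n=87/14 is significant in ~99.7% of runs."""
        hits = 0
        reps = 300
        for seed in range(reps):
            values, labels = self._cohort(seed=seed)
            res = de_table(values, labels, ["hit"])
            hits += bool(res.table.loc["hit", "significant"])
        rate = hits / reps
        assert rate == pytest.approx(0.997, abs=3 * np.sqrt(0.997 * 0.003 / reps) + 0.005)

    def test_null_protein_alpha_calibrated(self):
        hits = 0
        reps = 400
        for seed in range(reps):
            values, labels = self._cohort(seed=seed)
            res = de_table(values, labels, ["null1"])
            hits += bool(res.table.loc["null1", "significant"])
        rate = hits / reps
        assert rate == pytest.approx(0.05, abs=3 * np.sqrt(0.05 * 0.95 / reps))

    def test_subset_of_one_padj_equals_p(self):
        values, labels = self._cohort()
        res = de_table(values, labels, ["hit"])
        assert res.table.loc["hit", "p_adj"] == res.table.loc["hit", "p"]

    def test_missing_protein_rejected(self):
        values, labels = self._cohort()
        with pytest.raises(ValueError, match="absent"):
            de_table(values, labels, ["nope"])

    def test_padj_at_least_p(self):
        values, labels = self._cohort()
        res = de_table(values, labels)
        assert (res.table["p_adj"] >= res.table["p"] - 1e-15).all()
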