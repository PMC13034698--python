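"""Splits, grid search, Monte Carlo CV, ranking metrics, bootstrap CIs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cometdr.evaluation import (
    auprc,
    auroc,
    bootstrap_ci,
    grid_search,
    make_split,
    monte_carlo_cv,
)


def brute_force_auroc(predictions, labels):
    """Concordant-pair fraction with ties counted 1/2."""
    pos = predictions[labels == 1]
    neg = predictions[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def brute_force_auprc(predictions, labels):
    """Average precision by explicit threshold sweep.

    Tied scores enter together at their common threshold (one
    precision/recall point per unique score), matching the step
    interpolation AP = sum_i (R_i - R_{i-1}) P_i.
    """
    total_pos = labels.sum()
    ap = 0.0
    prev_recall = 0.0
    for threshold in sorted(set(predictions), reverse=True):
        at_or_above = predictions >= threshold
        tp = int(labels[at_or_above].sum())
        precision = tp / at_or_above.sum()
        recall = tp / total_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


class TestSplits:
    def test_partition_is_exhaustive_and_disjoint(self):
        labels = np.r_[np.ones(14), np.zeros(87)]
        plan = make_split(labels, seed=0)
        all_idx = np.sort(np.concatenate([plan.train, plan.test, plan.validation]))
        assert np.array_equal(all_idx, np.arange(101))

    def test_stratification_keeps_cases_in_every_split(self):
        labels = np.r_[np.ones(14), np.zeros(87)]
        for seed in range(10):
            plan = make_split(labels, seed=seed)
            for part in (plan.train, plan.test, plan.validation):
                assert labels[part].sum() >= 1

    def test_proportions_near_70_15_15(self):
        labels = np.r_[np.ones(30), np.zeros(170)]
        plan = make_split(labels, seed=1)
        assert len(plan.test) == pytest.approx(30, abs=3)
        assert len(plan.validation) == pytest.approx(30, abs=3)
        assert len(plan.train) == 200 - len(plan.test) - len(plan.validation)


class TestGridSearch:
    def test_singleton_grid(self):
        labels = np.r_[np.ones(12), np.zeros(24)]
        best = grid_search(labels, ["only"], lambda *_: 1.0, seed=0)
        assert best == "only"

    def test_lower_loss_config_wins(self):
        labels = np.r_[np.ones(12), np.zeros(24)]
        losses = {"bad": 0.9, "good": 0.1}

        def evaluate(config, *_):
            return losses[config]

        assert grid_search(labels, ["bad", "good"], evaluate, seed=0) == "good"

    def test_tie_goes_to_first_declared(self):
        labels = np.r_[np.ones(12), np.zeros(24)]
        assert grid_search(labels, ["a", "b"], lambda *_: 0.5, seed=0) == "a"

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            grid_search(np.r_[np.ones(5), np.zeros(5)], [], lambda *_: 0.0)

    def test_stratification_failure(self):
        labels = np.r_[np.ones(2), np.zeros(30)]  # fewer cases than folds
        with pytest.raises(ValueError, match="stratification"):
            grid_search(labels, ["a"], lambda *_: 0.0, folds=3)


class TestMonteCarloCV:
    @staticmethod
    def _stub_fit_predict(labels, noise_sd, rng):
        def fit_predict(train_idx, stop_idx, val_idx, seed):
            return np.clip(
                labels[val_idx] + rng.normal(0, noise_sd, len(val_idx)), 0, 1
            )

        return fit_predict

    def test_single_iteration_equals_single_split(self):
        labels = np.r_[np.ones(10), np.zeros(40)]
        rng = np.random.default_rng(0)
        preds = rng.random(50)

        def fit_predict(train_idx, stop_idx, val_idx, seed):
            return preds[val_idx]

        res = monte_carlo_cv(labels, fit_predict, iterations=1, seed=4, n_bootstrap=50)
        plan = make_split(labels, seed=int(np.random.SeedSequence(4).generate_state(1)[0] % 2**31))
        assert res.auroc == pytest.approx(
            auroc(preds[plan.validation], labels[plan.validation])
        )

    def test_predictions_averaged_per_patient(self):
        labels = np.r_[np.ones(10), np.zeros(40)]
        calls = {"n": 0}

        def fit_predict(train_idx, stop_idx, val_idx, seed):
            calls["n"] += 1
            return np.full(len(val_idx), 0.2 if calls["n"] % 2 else 0.6)

        res = monte_carlo_cv(labels, fit_predict, iterations=30, seed=0, n_bootstrap=50)
        seen_twice = res.predictions[(res.predictions > 0.25) & (res.predictions < 0.55)]
        assert len(seen_twice) > 0  # patients hit in both odd and even iterations

    def test_stub_model_auroc_matches_analytic(self):
        """Label + Gaussian noise stub: AUROC ~= Phi(1/(sd*sqrt(2)))."""
        from scipy.stats import norm

        labels = np.r_[np.ones(60), np.zeros(140)]
        rng = np.random.default_rng(5)
        sd = 0.5
        res = monte_carlo_cv(
            labels, self._stub_fit_predict(labels, sd, rng),
            iterations=25, seed=2, n_bootstrap=50,
        )
        # clipping to [0,1] raises AUC slightly above the unclipped form;
        # wide MC tolerance around the analytic unclipped value
        analytic = norm.cdf(1.0 / (sd * np.sqrt(2)))
        assert res.auroc == pytest.approx(analytic, abs=0.08)

    def test_reproducible_bit_for_bit(self):
        labels = np.r_[np.ones(10), np.zeros(40)]
        rngs = [np.random.default_rng(1), np.random.default_rng(1)]
        results = [
            monte_carlo_cv(
                labels, self._stub_fit_predict(labels, 0.4, rng),
                iterations=5, seed=9, n_bootstrap=20,
            )
            for rng in rngs
        ]
        assert results[0].predictions.equals(results[1].predictions)
        assert results[0].auroc_ci == results[1].auroc_ci


class TestAUROC:
    def test_perfect_and_inverted_ranking(self):
        y = np.array([0, 0, 1, 1])
        assert auroc(np.array([0.1, 0.2, 0.8, 0.9]), y) == 1.0
        assert auroc(np.array([0.9, 0.8, 0.2, 0.1]), y) == 0.0

    def test_tie_counts_half(self):
        """6-point set with one tie matches exhaustive pair enumeration."""
        y = np.array([1, 1, 1, 0, 0, 0])
        p = np.array([0.9, 0.5, 0.3, 0.5, 0.2, 0.1])
        assert auroc(p, y) == pytest.approx(brute_force_auroc(p, y))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both"):
            auroc(np.array([0.1, 0.2]), np.array([1, 1]))

    def test_matches_sklearn_on_random_instances(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(6, 40))
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            preds = rng.choice(np.linspace(0, 1, 9), size=n)
            assert auroc(preds, labels) == pytest.approx(
                roc_auc_score(labels, preds)
            )

    @settings(max_examples=200, deadline=None)
    @given(st.data())
    def test_matches_brute_force_on_small_instances(self, data):
        n = data.draw(st.integers(4, 12))
        labels = np.array(data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n)
            .filter(lambda xs: 0 < sum(xs) < len(xs))
        ))
        preds = np.array(data.draw(
            st.lists(st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0]), min_size=n, max_size=n)
        ))
        assert auroc(preds, labels) == pytest.approx(brute_force_auroc(preds, labels))


class TestAUPRC:
    def test_perfect_ranking(self):
        y = np.array([0, 0, 1, 1])
        assert auprc(np.array([0.1, 0.2, 0.8, 0.9]), y) == 1.0

    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5])
    def test_single_positive_ranked_kth(self, k):
        """One positive at rank k of n distinct scores -> AP = 1/k."""
        n = 6
        preds = np.linspace(1.0, 0.0, n)
        labels = np.zeros(n, dtype=int)
        labels[k - 1] = 1
        assert auprc(preds, labels) == pytest.approx(1.0 / k)

    def test_worked_five_point_ladder(self):
        """Hand enumeration: positives at ranks 1 and 4 of 5."""
        preds = np.array([0.9, 0.7, 0.5, 0.3, 0.1])
        labels = np.array([1, 0, 0, 1, 0])
        # precision at rank 1 = 1/1; at rank 4 = 2/4; AP = (1 + 0.5)/2
        assert auprc(preds, labels) == pytest.approx(0.75)

    @settings(max_examples=150, deadline=None)
    @given(st.data())
    def test_matches_brute_force_on_small_instances(self, data):
        n = data.draw(st.integers(4, 12))
        labels = np.array(data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n)
            .filter(lambda xs: 0 < sum(xs) < len(xs))
        ))
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        preds = rng.random(n)  # distinct with probability 1
        assert auprc(preds, labels) == pytest.approx(brute_force_auprc(preds, labels))


class TestBootstrapCI:
    def test_constant_metric_zero_width(self):
        preds = np.array([1.0, 1.0, 0.0, 0.0, 0.0, 1.0] * 5)
        labels = np.array([1, 1, 0, 0, 0, 1] * 5)
        low, high = bootstrap_ci(preds, labels, metric=auroc, B=100, seed=0)
        assert (low, high) == (1.0, 1.0)

    def test_bounds_bracket_point_estimate(self):
        rng = np.random.default_rng(3)
        labels = np.r_[np.ones(30), np.zeros(70)]
        preds = np.clip(labels * 0.4 + rng.random(100) * 0.6, 0, 1)
        point = auroc(preds, labels)
        low, high = bootstrap_ci(preds, labels, metric=auroc, B=2000, seed=1)
        assert low <= point <= high

    def test_invalid_b_rejected(self):
        with pytest.raises(ValueError, match="B"):
            bootstrap_ci(np.array([0.1, 0.9]), np.array([0, 1]), B=0)
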