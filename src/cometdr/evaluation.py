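"""Hyperparameter selection, Monte Carlo cross-validation, and metrics.

The evaluation protocol: hyperparameters are chosen once by grid search
under threefold cross-validation (each fold's training portion donates
20% for early stopping), then the chosen configuration is run through 25
Monte Carlo iterations of stratified 70/15/15 train/test/validation
splits.  Training early-stops on the 15% test split; predictions are
collected on the 15% validation split; each patient's final prediction is
the mean over the iterations in which they landed in validation.  AUROC
and AUPRC are computed on these averaged predictions with 95% percentile
bootstrap confidence intervals over 1,000 patient-level resamples.

Splits are stratified by outcome label: at ~14% prevalence, unstratified
15% splits would frequently contain no cases at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score

log = logging.getLogger(__name__)

__all__ = [
    "SplitPlan",
    "EvalResult",
    "make_split",
    "grid_search",
    "monte_carlo_cv",
    "auroc",
    "auprc",
    "bootstrap_ci",
    "results_table",
]

DEFAULT_ITERATIONS = 25
DEFAULT_BOOTSTRAP = 1000


@dataclass
class SplitPlan:
    """One 70/15/15 stratified partition of patient indices."""

    iteration: int
    train: np.ndarray
    test: np.ndarray  # early-stopping split
    validation: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        parts = np.concatenate([self.train, self.test, self.validation])
        if len(np.unique(parts)) != len(parts):
            raise ValueError("split partitions overlap")


@dataclass
class EvalResult:
    auroc: float
    auprc: float
    auroc_ci: tuple[float, float]
    auprc_ci: tuple[float, float]
    n_bootstrap: int
    predictions: pd.Series  # per-patient averaged prediction (index: patient idx)
    labels: pd.Series
    n_never_validated: int = 0


def make_split(
    labels: np.ndarray,
    seed: int,
    iteration: int = 0,
    fractions: tuple[float, float] = (0.15, 0.15),
) -> SplitPlan:
    """Stratified 70/15/15 split: per class, floor(0.15 n) to test and to
    validation (at least one each when the class allows), remainder to
    train."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, test, val = [], [], []
    for cls in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == cls))
        n = len(idx)
        n_test = max(1, int(np.floor(fractions[0] * n))) if n >= 3 else 0
        n_val = max(1, int(np.floor(fractions[1] * n))) if n >= 3 else 0
        test.append(idx[:n_test])
        val.append(idx[n_test : n_test + n_val])
        train.append(idx[n_test + n_val :])
    return SplitPlan(
        iteration=iteration,
        train=np.sort(np.concatenate(train)),
        test=np.sort(np.concatenate(test)),
        validation=np.sort(np.concatenate(val)),
        seed=seed,
    )


def grid_search(
    labels: np.ndarray,
    grid: Sequence,
    evaluate: Callable[[object, np.ndarray, np.ndarray, np.ndarray, int], float],
    folds: int = 3,
    seed: int = 0,
    holdout_frac: float = 0.2,
):
    """Pick the grid point with the lowest mean validation loss over
    ``folds`` stratified folds.

    ``evaluate(config, train_idx, stop_idx, val_idx, seed) -> loss`` trains
    with early stopping on ``stop_idx`` and scores ``val_idx``.  Ties go to
    the earlier config in declared grid order (strict improvement only).
    """
    if len(grid) == 0:
        raise ValueError("empty hyperparameter grid")
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2 or counts.min() < folds:
        raise ValueError(
            f"stratification failure: need >= {folds} patients per class, got {counts}"
        )
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    rng = np.random.default_rng(seed)
    fold_plans = []  # identical folds and early-stop splits for every config
    for train_idx, val_idx in skf.split(np.zeros(len(labels)), labels):
        stop_local = _stratified_pick(labels[train_idx], holdout_frac, rng)
        stop_idx = train_idx[stop_local]
        inner_train = np.setdiff1d(train_idx, stop_idx)
        fold_plans.append((inner_train, stop_idx, val_idx))
    best_config, best_loss = None, np.inf
    mean_losses = []
    for config in grid:
        losses = []
        for k, (inner_train, stop_idx, val_idx) in enumerate(fold_plans):
            losses.append(evaluate(config, inner_train, stop_idx, val_idx, seed + k))
        mean_loss = float(np.mean(losses))
        mean_losses.append(mean_loss)
        if mean_loss < best_loss:
            best_loss, best_config = mean_loss, config
    log.info("grid search losses: %s", mean_losses)
    return best_config


def _stratified_pick(labels: np.ndarray, frac: float, rng: np.random.Generator) -> np.ndarray:
    picked = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        k = max(1, int(round(frac * len(idx))))
        picked.append(rng.choice(idx, size=k, replace=False))
    return np.sort(np.concatenate(picked))


def monte_carlo_cv(
    labels: np.ndarray,
    fit_predict: Callable[[np.ndarray, np.ndarray, np.ndarray, int], np.ndarray],
    iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
    n_bootstrap: int = DEFAULT_BOOTSTRAP,
) -> EvalResult:
    """Monte Carlo cross-validation with per-patient prediction averaging.

    ``fit_predict(train_idx, stop_idx, val_idx, seed)`` returns the
    predicted probabilities for ``val_idx``.  Patients that never land in
    any validation split are excluded from the final metrics (with a
    logged count).
    """
    labels = np.asarray(labels)
    n = len(labels)
    sums = np.zeros(n)
    counts = np.zeros(n, dtype=int)
    seeds = np.random.SeedSequence(seed).generate_state(iterations) % (2**31)
    for it in range(iterations):
        plan = make_split(labels, seed=int(seeds[it]), iteration=it + 1)
        preds = np.asarray(
            fit_predict(plan.train, plan.test, plan.validation, int(seeds[it]))
        )
        sums[plan.validation] += preds
        counts[plan.validation] += 1
    covered = counts > 0
    n_missed = int(n - covered.sum())
    if n_missed:
        log.warning("%d patients never appeared in a validation split; excluded", n_missed)
    avg = sums[covered] / counts[covered]
    y = labels[covered]
    point_auroc = auroc(avg, y)
    point_auprc = auprc(avg, y)
    ci_roc = bootstrap_ci(avg, y, metric=auroc, B=n_bootstrap, seed=seed)
    ci_prc = bootstrap_ci(avg, y, metric=auprc, B=n_bootstrap, seed=seed + 1)
    return EvalResult(
        auroc=point_auroc,
        auprc=point_auprc,
        auroc_ci=ci_roc,
        auprc_ci=ci_prc,
        n_bootstrap=n_bootstrap,
        predictions=pd.Series(avg, index=np.flatnonzero(covered)),
        labels=pd.Series(y, index=np.flatnonzero(covered)),
        n_never_validated=n_missed,
    )


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both outcome classes must be present")


def auroc(predictions, labels) -> float:
    """Probability a random positive outranks a random negative (ties 1/2).

    Computed as the Mann-Whitney U statistic over average ranks, which is
    algebraically identical to the trapezoidal ROC area.
    """
    labels = np.asarray(labels)
    _check_two_classes(labels)
    predictions = np.asarray(predictions)
    from scipy.stats import rankdata

    ranks = rankdata(predictions)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auprc(predictions, labels) -> float:
    """Average precision: step-interpolated area under precision-recall."""
    labels = np.asarray(labels)
    _check_two_classes(labels)
    return float(average_precision_score(labels, np.asarray(predictions)))


def bootstrap_ci(
    predictions,
    labels,
    metric: Callable = auroc,
    B: int = DEFAULT_BOOTSTRAP,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap interval over patient-level resamples.

    Resamples that lack one of the classes are redrawn (logged), so the
    full ``B`` replicates are always used.
    """
    if B <= 0:
        raise ValueError("B must be positive")
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    rng = np.random.default_rng(seed)
    n = len(labels)
    stats = np.empty(B)
    redraws = 0
    for b in range(B):
        while True:
            idx = rng.integers(0, n, size=n)
            if len(np.unique(labels[idx])) == 2:
                break
            redraws += 1
        stats[b] = metric(predictions[idx], labels[idx])
    if redraws:
        log.info("bootstrap: redrew %d degenerate resamples", redraws)
    alpha = (1.0 - level) / 2.0
    return (float(np.quantile(stats, alpha)), float(np.quantile(stats, 1.0 - alpha)))


MODEL_FEATURES = {
    "ehr_only": "EHR only",
    "omics_only": "Proteomics only",
    "joint": "EHR and proteomics, no pretraining",
    "comet": "COMET (EHR and proteomics with pretraining)",
}


def results_table(results: dict[str, EvalResult], sample_sizes: dict[str, str]) -> pd.DataFrame:
    """Discrimination-metrics table, one row per model variant."""
    rows = []
    for i, (mode, res) in enumerate(results.items(), start=1):
        rows.append(
            {
                "model": i,
                "features": MODEL_FEATURES.get(mode, mode),
                "sample_size": sample_sizes.get(mode, ""),
                "auroc": round(res.auroc, 2),
                "auroc_ci_low": round(res.auroc_ci[0], 2),
                "auroc_ci_high": round(res.auroc_ci[1], 2),
                "auprc": round(res.auprc, 2),
                "auprc_ci_low": round(res.auprc_ci[0], 2),
                "auprc_ci_high": round(res.auprc_ci[1], 2),
            }
        )
    return pd.DataFrame(rows)
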