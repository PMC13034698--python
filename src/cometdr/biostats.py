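"""Normalization, differential expression, and power calculations.

The post hoc statistics of the two-stage workflow: aptamer intensities
are scaled across experimental batches with external calibrators and
median-normalized within sample type; candidate proteins are compared
between groups by unpaired t-tests on log2 intensities with
Benjamini-Hochberg correction (adjusted p < 0.05 significant); and
standardized effect sizes (Cohen's d = mean log2 fold change / common SD)
feed exact noncentral-t power and sample-size calculations.

Differential expression uses plain pooled-variance (optionally Welch)
linear-model t-tests rather than empirical-Bayes variance moderation:
with group sizes in the tens and a candidate set of ~15 proteins the
moderation correction is immaterial, and the reported quantities
(t, p, log2 fold change, adjusted p) are exactly the ones computed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEResult",
    "PowerSpec",
    "calibrator_scale",
    "median_normalize",
    "t_test_two_sample",
    "bh_adjust",
    "cohens_d_from_summary",
    "power_two_sample_t",
    "sample_size_for_power",
    "de_table",
]

ALPHA = 0.05


@dataclass
class PowerSpec:
    """A two-sample t-test power scenario."""

    d: float
    n1: int
    n2: int
    alpha: float = ALPHA
    sides: int = 2
    power: float | None = None

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError("d uses the non-negative convention")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.sides not in (1, 2):
            raise ValueError("sides must be 1 or 2")


@dataclass
class DEResult:
    """Per-protein differential-expression table.

    ``table`` columns: log2_fc, t, p, p_adj, significant (adjusted
    p < 0.05).
    """

    table: pd.DataFrame
    alpha: float = ALPHA


def calibrator_scale(
    values: pd.DataFrame, batches: pd.Series, calibrators: pd.DataFrame
) -> pd.DataFrame:
    """Scale each batch onto the first batch using external calibrators.

    Every value in batch b for protein p is multiplied by
    ``calibrator[reference, p] / calibrator[b, p]`` where the reference is
    the first row of ``calibrators``.  A single-batch matrix is returned
    unchanged.
    """
    if (calibrators.to_numpy() == 0).any():
        raise ValueError("calibrator values must be nonzero")
    missing = set(batches.unique()) - set(calibrators.index)
    if missing:
        raise ValueError(f"batches without calibrator measurements: {sorted(missing)}")
    reference = calibrators.iloc[0]
    scaled = values.copy()
    for batch in batches.unique():
        factor = reference / calibrators.loc[batch]
        rows = batches[batches == batch].index
        scaled.loc[rows] = scaled.loc[rows] * factor[values.columns].to_numpy()
    return scaled


def median_normalize(values):
    """Scale each sample (row) so all sample medians equal the grand
    median of the sample medians.  Idempotent; requires positive values."""
    frame = isinstance(values, pd.DataFrame)
    arr = values.to_numpy(dtype=np.float64) if frame else np.asarray(values, dtype=np.float64)
    if np.any(arr <= 0):
        raise ValueError("median normalization requires strictly positive values")
    medians = np.median(arr, axis=1)
    grand = np.median(medians)
    scaled = arr * (grand / medians)[:, None]
    if frame:
        return pd.DataFrame(scaled, index=values.index, columns=values.columns)
    return scaled


def t_test_two_sample(a, b, pooled: bool = True) -> tuple[float, float, float]:
    """Unpaired two-sample t-test on log2 values.

    Pooled-variance Student's test by default (Welch with
    ``pooled=False``).  Returns (t, two-sided p, log2 fold change =
    mean(a) - mean(b)).  Zero variance with equal means degenerates to
    (0, 1); with unequal means it is an error.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    log2_fc = float(a.mean() - b.mean())
    var_a, var_b = a.var(ddof=1), b.var(ddof=1)
    if var_a == 0 and var_b == 0:
        if log2_fc == 0:
            return 0.0, 1.0, 0.0
        raise ValueError("degenerate test: zero variance with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=pooled)
    return float(t), float(p), log2_fc


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order restored."""
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cohens_d_from_summary(median_log_fc: float, sd: float) -> float:
    """Standardized effect size from a summary fold change: d = |FC| / SD."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    return abs(median_log_fc) / sd


def report_d(median_log_fc: float, sd: float) -> float:
    """The effect size rounded to one decimal, as conventionally reported."""
    return round(cohens_d_from_summary(median_log_fc, sd), 1)


def power_two_sample_t(
    d: float, n1: int, n2: int, alpha: float = ALPHA, sides: int = 2
) -> float:
    """Exact noncentral-t power of the two-sample t-test.

    Noncentrality ``d * sqrt(n1 n2 / (n1 + n2))`` with ``n1 + n2 - 2``
    degrees of freedom.  At d = 0 the two-sided power equals alpha.
    """
    spec = PowerSpec(d=d, n1=n1, n2=n2, alpha=alpha, sides=sides)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    df = n1 + n2 - 2
    nc = d * np.sqrt(n1 * n2 / (n1 + n2))
    if sides == 2:
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
        power = stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
    else:
        tcrit = stats.t.ppf(1.0 - alpha, df)
        power = stats.nct.sf(tcrit, df, nc)
    return float(power)


def sample_size_for_power(
    d: float,
    power: float = 0.9,
    alpha: float = ALPHA,
    ratio: float | None = 1.0,
    n2: int | None = None,
    sides: int = 2,
    max_n: int = 1_000_000,
) -> tuple[int, int]:
    """Smallest integer group sizes reaching the target power.

    Allocation is either a fixed ``ratio = n1/n2`` (scanning n2 upward) or
    a fixed smaller group ``n2`` (scanning n1 upward).  With n2 fixed the
    power is bounded as n1 grows; an unreachable target raises.
    """
    if not 0 < power < 1:
        raise ValueError("power must be in (0, 1)")
    if d <= 0:
        raise ValueError("d must be positive for a sample-size calculation")
    if n2 is not None:
        # asymptotic bound: limit of noncentrality as n1 -> inf is d*sqrt(n2)
        limit = stats.norm.sf(stats.norm.ppf(1 - alpha / sides) - d * np.sqrt(n2))
        if limit < power:
            raise ValueError(
                f"power {power} unreachable with n2={n2} at d={d} "
                f"(asymptotic power {limit:.3f})"
            )
        for n1 in range(2, max_n):
            if power_two_sample_t(d, n1, n2, alpha, sides) >= power:
                return n1, n2
        raise ValueError("sample size scan exceeded max_n")
    if ratio is None or ratio <= 0:
        raise ValueError("provide a positive ratio or a fixed n2")
    for n2_try in range(2, max_n):
        n1_try = max(2, int(np.ceil(ratio * n2_try)))
        if power_two_sample_t(d, n1_try, n2_try, alpha, sides) >= power:
            return n1_try, n2_try
    raise ValueError("sample size scan exceeded max_n")


def de_table(
    proteins: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    subset: list[str] | None = None,
    alpha: float = ALPHA,
    pooled: bool = True,
    already_log2: bool = False,
    check_normality: bool = False,
) -> DEResult:
    """Differential expression of ``subset`` proteins, cases vs controls.

    Intensities are log2-transformed (unless ``already_log2``), each
    protein tested with :func:`t_test_two_sample` (log2_fc = case mean -
    control mean), and p-values BH-adjusted *across the subset*.  With
    ``check_normality`` a Shapiro-Wilk advisory warning (never a gate) is
    emitted for clearly non-normal groups.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    subset = list(proteins.columns) if subset is None else list(subset)
    missing = [p for p in subset if p not in proteins.columns]
    if missing:
        raise ValueError(f"proteins absent from matrix: {missing}")
    values = proteins[subset].to_numpy(dtype=np.float64)
    if not already_log2:
        if np.any(values <= 0):
            raise ValueError("intensities must be positive for log2 transform")
        values = np.log2(values)
    cases = values[labels == 1]
    controls = values[labels == 0]
    rows = []
    for j, name in enumerate(subset):
        if check_normality:
            for group, tag in ((cases[:, j], "cases"), (controls[:, j], "controls")):
                if len(group) >= 3 and stats.shapiro(group).pvalue < 0.01:
                    warnings.warn(
                        f"{name}: {tag} deviate from normality (Shapiro-Wilk p < 0.01)",
                        stacklevel=2,
                    )
        t, p, fc = t_test_two_sample(cases[:, j], controls[:, j])
        rows.append({"protein": name, "log2_fc": fc, "t": t, "p": p})
    table = pd.DataFrame(rows).set_index("protein")
    # extreme t statistics can underflow p to exactly 0; keep it in (0, 1]
    table["p"] = table["p"].clip(lower=np.nextafter(0.0, 1.0))
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    table["significant"] = table["p_adj"] < alpha
    return DEResult(table=table, alpha=alpha)
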