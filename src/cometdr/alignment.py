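"""Cross-modal alignment: correlation-matrix t-SNE and latent-protein
correlation statistics.

Two complementary views of how well the EHR and proteomics modalities
align.  First, the Pearson correlation matrix over *all* variables
(dichotomous EHR features enter as 0/1, so their correlations with
proteins are point-biserial) is embedded into two dimensions with t-SNE,
treating each variable's row of correlations as its feature vector —
variables that correlate similarly with everything land near each other.
Second, every (EHR latent dimension, protein) pair is tested for Pearson
correlation; the number of significant pairs and the mean absolute R
quantify how strongly a model's learned EHR representation is coupled to
the molecular data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "CorrelationResult",
    "feature_correlation_matrix",
    "tsne_embed",
    "latent_protein_correlations",
    "protein_latent_coverage",
    "compare_mean_abs_r",
]

DEFAULT_ALPHA = 0.05


@dataclass
class CorrelationResult:
    """All (latent dimension, protein) Pearson correlations.

    ``r`` and ``p`` are latent-dim x protein frames; pairs with undefined
    correlation (a constant column on either side) hold NaN and are
    excluded from ``mean_abs_r`` and significance counts.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    alpha: float
    n_significant: int
    mean_abs_r: float
    n_excluded: int = 0

    @property
    def significant(self) -> pd.DataFrame:
        return (self.p < self.alpha) & self.r.notna()


def feature_correlation_matrix(
    ehr_features: pd.DataFrame, proteins: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation of every variable pair across both blocks.

    Zero-variance variables are dropped (Pearson undefined) with a log
    message.  Requires matched patient rows and at least 3 patients.
    """
    if len(ehr_features) != len(proteins):
        raise ValueError("EHR and protein blocks have different patient counts")
    if len(ehr_features) < 3:
        raise ValueError("need at least 3 patients for a correlation matrix")
    combined = pd.concat(
        [ehr_features.reset_index(drop=True), proteins.reset_index(drop=True)], axis=1
    )
    variances = combined.var(axis=0, ddof=0)
    constant = variances[variances == 0].index
    if len(constant):
        log.info("dropping %d zero-variance variables before correlation", len(constant))
        combined = combined.drop(columns=constant)
    corr = np.corrcoef(combined.to_numpy(dtype=np.float64), rowvar=False)
    corr = (corr + corr.T) / 2.0  # enforce exact symmetry against fp drift
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=combined.columns, columns=combined.columns)


def tsne_embed(
    corr_matrix: pd.DataFrame, perplexity: float = 30.0, seed: int = 0,
    max_iter: int = 1000,
) -> pd.DataFrame:
    """2-D t-SNE of the correlation matrix rows (one point per variable)."""
    n = len(corr_matrix)
    if corr_matrix.shape[0] != corr_matrix.shape[1]:
        raise ValueError("correlation matrix must be square")
    if n < 3 * perplexity:
        raise ValueError(f"perplexity {perplexity} too large for {n} variables")
    from sklearn.manifold import TSNE

    coords = TSNE(
        n_components=2,
        perplexity=perplexity,
        init="pca",
        random_state=seed,
        max_iter=max_iter,
    ).fit_transform(corr_matrix.to_numpy(dtype=np.float64))
    return pd.DataFrame(coords, index=corr_matrix.index, columns=["x", "y"])


def latent_protein_correlations(
    latents: np.ndarray,
    proteins: pd.DataFrame | np.ndarray,
    alpha: float = DEFAULT_ALPHA,
) -> CorrelationResult:
    """Pearson R and two-sided p for every (latent dim, protein) pair.

    p-values come from the exact t-transform ``t = R sqrt((n-2)/(1-R^2))``
    with n-2 degrees of freedom.  Significance counting uses unadjusted
    p < alpha; apply a BH correction to ``p`` beforehand if desired.
    """
    latents = np.asarray(latents, dtype=np.float64)
    if isinstance(proteins, pd.DataFrame):
        protein_names = list(proteins.columns)
        prot = proteins.to_numpy(dtype=np.float64)
    else:
        prot = np.asarray(proteins, dtype=np.float64)
        protein_names = [f"p{j}" for j in range(prot.shape[1])]
    n = latents.shape[0]
    if prot.shape[0] != n:
        raise ValueError("latent and protein matrices have different patient counts")
    if n < 4:
        raise ValueError("need at least 4 patients")
    lat_sd = latents.std(axis=0, ddof=0)
    prot_sd = prot.std(axis=0, ddof=0)
    lat_c = (latents - latents.mean(axis=0))
    prot_c = (prot - prot.mean(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (lat_c.T @ prot_c) / n / np.outer(lat_sd, prot_sd)
    r = np.clip(r, -1.0, 1.0)
    undefined = (lat_sd == 0)[:, None] | (prot_sd == 0)[None, :]
    r[undefined] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isnan(r)] = np.nan
    p[np.abs(r) == 1.0] = 0.0
    n_excluded = int(undefined.sum())
    if n_excluded:
        log.info("%d latent-protein pairs undefined (constant column); excluded", n_excluded)
    dims = [f"d{i}" for i in range(latents.shape[1])]
    r_df = pd.DataFrame(r, index=dims, columns=protein_names)
    p_df = pd.DataFrame(p, index=dims, columns=protein_names)
    valid = ~np.isnan(r)
    return CorrelationResult(
        r=r_df,
        p=p_df,
        alpha=alpha,
        n_significant=int((p[valid] < alpha).sum()),
        mean_abs_r=float(np.abs(r[valid]).mean()) if valid.any() else float("nan"),
        n_excluded=n_excluded,
    )


def protein_latent_coverage(result: CorrelationResult) -> pd.Series:
    """Per protein: percent of latent dimensions significantly correlated
    with it, sorted descending (the per-protein view of alignment)."""
    d = result.r.shape[0]
    counts = result.significant.sum(axis=0)
    coverage = 100.0 * counts / d
    return coverage.sort_values(ascending=False)


def compare_mean_abs_r(result_a: CorrelationResult, result_b: CorrelationResult):
    """Two-sided Mann-Whitney test on the |R| distributions of two models'
    latent-protein pairs (undefined pairs excluded)."""
    a = np.abs(result_a.r.to_numpy()).ravel()
    b = np.abs(result_b.r.to_numpy()).ravel()
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(stat), float(p)
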