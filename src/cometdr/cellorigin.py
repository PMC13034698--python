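"""Cell-type-of-origin assignment by an expression z-score rule.

Candidate aqueous-humor proteins are traced back to ocular cell types
using single-cell mean expression: a cell type is called an origin of a
protein's gene when its expression is at least ``k_sd`` standard
deviations above that gene's mean across all cell types (inclusive
threshold, default k_sd = 2).  Constant rows have zero deviation and
yield no origins.  The resulting (protein, cell type) links feed a
Sankey-style diagram of cellular origins.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["assign_origins", "sankey_links"]


def assign_origins(
    expression: pd.DataFrame,
    k_sd: float = 2.0,
    gene_map: dict[str, str] | None = None,
    population_sd: bool = True,
) -> dict[str, set[str]]:
    """Map each protein to the cell types passing the z-score threshold.

    ``expression`` is genes x cell types (non-negative mean expression);
    ``gene_map`` maps protein codes to gene rows (identity by default).
    The mean and SD are taken across cell types within each gene row;
    ``population_sd`` selects the n-denominator convention.
    """
    if expression.shape[1] < 2:
        raise ValueError("need at least 2 cell types to define an SD")
    if (expression.to_numpy() < 0).any():
        raise ValueError("expression values must be non-negative")
    gene_map = gene_map or {g: g for g in expression.index}
    values = expression.to_numpy(dtype=np.float64)
    means = values.mean(axis=1)
    sds = values.std(axis=1, ddof=0 if population_sd else 1)
    thresholds = means + k_sd * sds
    origins: dict[str, set[str]] = {}
    cell_types = list(expression.columns)
    row_of = {g: i for i, g in enumerate(expression.index)}
    for protein, gene in gene_map.items():
        if gene not in row_of:
            raise ValueError(f"gene {gene!r} (protein {protein}) absent from matrix")
        i = row_of[gene]
        if sds[i] == 0:
            log.info("%s: constant expression across cell types, no origin", protein)
            origins[protein] = set()
            continue
        passing = values[i] >= thresholds[i]  # inclusive: "at least" k SDs
        origins[protein] = {cell_types[j] for j in np.flatnonzero(passing)}
    return origins


def sankey_links(origins: dict[str, set[str]]) -> pd.DataFrame:
    """One row per (protein, cell type) edge, sorted for stable output."""
    rows = [
        {"protein": protein, "cell_type": cell_type}
        for protein in sorted(origins)
        for cell_type in sorted(origins[protein])
    ]
    return pd.DataFrame(rows, columns=["protein", "cell_type"])
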