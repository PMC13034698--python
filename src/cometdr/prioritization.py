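"""Integrated-gradients attribution and cross-model importance ranking.

Per-protein importance is defined as the cohort mean of the absolute
integrated-gradients attribution of the model's pre-sigmoid combined
logit with respect to the standardized protein inputs, normalized to sum
to one across proteins ("relative feature importance").  Ranking proteins
by the fold change of this importance between the pretrained transfer
model and a non-pretrained baseline surfaces the proteins whose
contribution is rooted in the EHR signal rather than in their marginal
association alone.

Integrated gradients for input x, baseline b, and scalar output F:

    attr_i = (x_i - b_i) * (1/m) * sum_{k=1..m} dF/dx_i |_{b + (k/m)(x-b)}

The attribution target F is the combined logit, not the probability:
differentiating through the sigmoid flattens attributions for confident
predictions.  The baseline is the zero vector in standardized protein
space (i.e. the cohort mean profile) together with a zero-content EHR
sequence under the patient's own padding mask — the continuous analog of
an all-padding sequence, which keeps the interpolation path differentiable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .model import CometModel, MultimodalData

log = logging.getLogger(__name__)

__all__ = [
    "integrated_gradients",
    "cohort_importance",
    "importance_fold_change",
    "CohortImportance",
]

DEFAULT_STEPS = 128
MIN_BASELINE_IMPORTANCE = 1e-12


def integrated_gradients(
    model: CometModel,
    sequence: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    omics: np.ndarray | None = None,
    baseline_sequence: np.ndarray | None = None,
    baseline_omics: np.ndarray | None = None,
    steps: int = DEFAULT_STEPS,
) -> dict[str, np.ndarray]:
    """Attribution of the combined logit for one patient.

    Returns a dict with keys among {"sequence", "omics"} holding
    attributions of the same shape as the corresponding input.  Baselines
    default to zeros.  A right-rule Riemann grid with ``steps`` points is
    used; attributions satisfy the completeness property
    ``sum(attr) -> F(x) - F(baseline)`` as ``steps`` grows.
    """
    if steps < 1:
        raise ValueError(f"steps must be >= 1, got {steps}")
    inputs: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if model.uses_ehr:
        if sequence is None or mask is None:
            raise ValueError("EHR modes require sequence and mask")
        sequence = np.asarray(sequence, dtype=np.float64)
        b_seq = np.zeros_like(sequence) if baseline_sequence is None else np.asarray(baseline_sequence, dtype=np.float64)
        if b_seq.shape != sequence.shape:
            raise ValueError(f"baseline sequence shape {b_seq.shape} != input {sequence.shape}")
        inputs["sequence"] = (sequence, b_seq)
    if model.uses_omics:
        if omics is None:
            raise ValueError("omics modes require an omics vector")
        omics = np.asarray(omics, dtype=np.float64)
        b_om = np.zeros_like(omics) if baseline_omics is None else np.asarray(baseline_omics, dtype=np.float64)
        if b_om.shape != omics.shape:
            raise ValueError(f"baseline omics shape {b_om.shape} != input {omics.shape}")
        inputs["omics"] = (omics, b_om)

    alphas = (np.arange(1, steps + 1) / steps).reshape(-1, 1)
    seq_t = om_t = None
    masks = None
    if "sequence" in inputs:
        x, b = inputs["sequence"]
        path = b[None] + alphas[:, :, None] * (x - b)[None]
        seq_t = Tensor(path, requires_grad=True)
        masks = np.broadcast_to(np.asarray(mask, dtype=bool), (steps,) + x.shape[:1])
    if "omics" in inputs:
        x, b = inputs["omics"]
        om_t = Tensor(b[None] + alphas * (x - b)[None], requires_grad=True)

    combined, _, _ = model.combined_logit(seq_t, masks, om_t, train=False)
    combined.sum().backward()

    attributions: dict[str, np.ndarray] = {}
    if seq_t is not None:
        x, b = inputs["sequence"]
        attributions["sequence"] = (x - b) * seq_t.grad.mean(axis=0)
    if om_t is not None:
        x, b = inputs["omics"]
        attributions["omics"] = (x - b) * om_t.grad.mean(axis=0)
    return attributions


@dataclass
class CohortImportance:
    """Normalized per-protein relative importance over a cohort."""

    values: pd.Series  # sums to 1 unless degenerate
    degenerate: bool = False


def cohort_importance(
    model: CometModel,
    data: MultimodalData,
    protein_names: list[str] | None = None,
    steps: int = DEFAULT_STEPS,
) -> CohortImportance:
    """Mean |attribution| per protein across patients, normalized to sum
    to one.  A model with no dependence on the proteins (all-zero
    attributions) is flagged degenerate and reported as zeros."""
    if data.n == 0:
        raise ValueError("cohort_importance of an empty dataset")
    if not model.uses_omics:
        raise ValueError(f"mode {model.mode} has no protein inputs")
    totals = np.zeros(data.omics.shape[1])
    # batch several patients' interpolation paths into one graph: the
    # per-coordinate gradients are independent across rows, so stacking
    # (patient, step) pairs changes nothing but the wall time
    alphas = np.arange(1, steps + 1) / steps
    chunk = max(1, 256 // steps)
    for start in range(0, data.n, chunk):
        idx = np.arange(start, min(start + chunk, data.n))
        k = len(idx)
        om = data.omics[idx]  # (k, P)
        om_path = (alphas[None, :, None] * om[:, None, :]).reshape(k * steps, -1)
        om_t = Tensor(om_path, requires_grad=True)
        seq_t = masks = None
        if model.uses_ehr:
            seq = data.sequences[idx]  # (k, T, D)
            seq_path = (alphas[None, :, None, None] * seq[:, None]).reshape(
                (k * steps,) + seq.shape[1:]
            )
            seq_t = Tensor(seq_path, requires_grad=True)
            masks = np.repeat(data.masks[idx], steps, axis=0)
        combined, _, _ = model.combined_logit(seq_t, masks, om_t, train=False)
        combined.sum().backward()
        grads = om_t.grad.reshape(k, steps, -1).mean(axis=1)
        totals += np.abs(om * grads).sum(axis=0)
    mean_abs = totals / data.n
    total = mean_abs.sum()
    names = protein_names if protein_names is not None else list(range(len(mean_abs)))
    if total == 0.0:
        log.warning("cohort importance is identically zero (degenerate model)")
        return CohortImportance(pd.Series(mean_abs, index=names), degenerate=True)
    return CohortImportance(pd.Series(mean_abs / total, index=names), degenerate=False)


def importance_fold_change(
    comet_importance: pd.Series,
    baseline_importance: pd.Series,
    min_baseline: float = MIN_BASELINE_IMPORTANCE,
) -> pd.DataFrame:
    """Per-protein importance fold change, ranked descending.

    ``fold_change = importance_comet / importance_baseline``; proteins
    whose baseline importance is below ``min_baseline`` have an undefined
    ratio and are excluded (logged).  Rank 1 is the largest fold change.
    """
    if set(comet_importance.index) != set(baseline_importance.index):
        raise ValueError("protein universes differ between the two importance vectors")
    baseline_importance = baseline_importance.reindex(comet_importance.index)
    defined = baseline_importance >= min_baseline
    n_dropped = int((~defined).sum())
    if n_dropped:
        log.info("excluding %d proteins with baseline importance < %g", n_dropped, min_baseline)
    table = pd.DataFrame(
        {
            "importance_comet": comet_importance[defined],
            "importance_baseline": baseline_importance[defined],
        }
    )
    table["fold_change"] = table["importance_comet"] / table["importance_baseline"]
    table = table.sort_values("fold_change", ascending=False, kind="stable")
    table["rank"] = np.arange(1, len(table) + 1)
    table.index.name = "protein"
    return table


def top_candidates(table: pd.DataFrame, k: int = 5) -> list[str]:
    """The k proteins with the largest importance fold change."""
    return list(table.index[:k])
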