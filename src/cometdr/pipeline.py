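"""End-to-end two-stage workflow: discovery prioritization, then validation.

Stage one (discovery): synthetic or provided cohorts are embedded, the
recurrent encoder is pretrained on the EHR-only cohort, the four model
variants are tuned by grid search and scored by Monte Carlo
cross-validation, and integrated-gradients importance fold changes
between the pretrained and non-pretrained multimodal models produce the
candidate protein list, together with cross-modal alignment statistics.

Stage two (validation): the independent validation cohort never touches
model training; its proteomics matrix is calibrator-scaled and
median-normalized, candidates are tested for differential expression with
BH correction, cases are substratified by disease stage, and
discovery/validation log2-fold-change sign concordance is summarized.

Every output file is recorded in a manifest with a SHA-256 content hash;
rerunning a stage with unchanged inputs and seeds reproduces the hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import alignment as align_mod
from . import biostats
from .embedding import SkipGramParams, build_daily_sentences, cohort_sequences, train_embeddings, truncate_at_index
from .evaluation import (
    EvalResult,
    grid_search,
    monte_carlo_cv,
    results_table,
)
from .model import (
    CometModel,
    ModelConfig,
    MultimodalData,
    evaluate_loss,
    prepare_omics,
    pretrain,
    train_model,
    transfer_and_finetune,
)
from .prioritization import cohort_importance, importance_fold_change, top_candidates
from .synthetic import SyntheticCohort, SyntheticConfig, generate_cohorts, read_cohort

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_discovery", "run_validation", "DiscoveryReport"]


@dataclass
class RunConfig:
    """Configuration of a full run; defaults follow the evaluation
    protocol (25 MC iterations, 1,000 bootstraps, 3 folds, patience 5,
    70/15/15 splits) at desk-scale model sizes."""

    seed: int = 0
    out_dir: str = "comet_out"
    cohort_dir: str | None = None  # read cohorts instead of simulating
    synthetic: dict = field(default_factory=dict)
    # embedding
    embed_dim: int = 32
    window: int = 32
    skipgram_epochs: int = 3
    embedding_source: str = "shared"  # or "separate"
    # model geometry (scaled; the original protocol used hidden 400/800, 2-4 layers)
    hidden_dim: int = 32
    layers: int = 1
    dropout: float = 0.1
    max_epochs: int = 60
    patience: int = 5
    pretrain_learning_rate: float = 0.2
    pretrain_lr_decay: float = 1e-2
    pretrain_batch_size: int = 32  # scaled with the desk-size pretraining cohort
    pretrain_max_epochs: int = 80
    # grid over (learning_rate, lr_decay) for fine-tuning
    grid_learning_rates: tuple = (1e-1, 1e-2)
    grid_lr_decays: tuple = (1e-2,)
    folds: int = 3
    # evaluation protocol
    iterations: int = 25
    n_bootstrap: int = 1000
    # prioritization / alignment
    ig_steps: int = 32
    n_candidates: int = 15
    n_table: int = 5
    alpha: float = 0.05
    include_tsne: bool = True
    tsne_perplexity: float = 30.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("grid_learning_rates", "grid_lr_decays"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class DiscoveryReport:
    metrics: pd.DataFrame
    importance_table: pd.DataFrame
    candidates: list[str]
    alignment_summary: dict
    eval_results: dict[str, EvalResult]
    discovery_de: pd.DataFrame
    out_dir: Path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out_dir: Path, paths: list[Path], name: str = "manifest.json") -> None:
    manifest = {p.name: _sha256(p) for p in sorted(set(paths))}
    (out_dir / name).write_text(json.dumps(manifest, indent=1, sort_keys=True))


class _StageLogger:
    """Line-oriented JSON stage log."""

    def __init__(self, path: Path, seed: int):
        self.path = path
        self.seed = seed
        self.path.write_text("")

    def stage(self, name: str):
        logger = self

        class _Ctx:
            def __enter__(ctx):
                ctx.start = time.monotonic()
                return ctx

            def __exit__(ctx, exc_type, exc, tb):
                record = {
                    "stage": name,
                    "seed": logger.seed,
                    "duration_s": round(time.monotonic() - ctx.start, 3),
                    "ok": exc_type is None,
                }
                with logger.path.open("a") as fh:
                    fh.write(json.dumps(record) + "\n")
                if exc_type is not None:
                    raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

        return _Ctx()


def _load_cohorts(cfg: RunConfig) -> tuple[SyntheticCohort, SyntheticCohort, SyntheticCohort]:
    if cfg.cohort_dir is not None:
        base = Path(cfg.cohort_dir)
        return (
            read_cohort(base / "pretrain"),
            read_cohort(base / "discovery"),
            read_cohort(base / "validation"),
        )
    syn = dict(cfg.synthetic)
    syn.setdefault("seed", cfg.seed)
    return generate_cohorts(SyntheticConfig(**syn))


def _cohort_corpus(cohort: SyntheticCohort, seed: int) -> list[list[int]]:
    corpus = []
    for i, tl in enumerate(cohort.timelines):
        corpus.extend(build_daily_sentences(truncate_at_index(tl), seed + i))
    return corpus


class SequenceScaler:
    """Per-dimension standardization of daily-summary rows.

    Fitted on the unmasked rows of the pretraining cohort and applied to
    every cohort, so transferred encoders see inputs on the scale they
    were trained on.  Padded rows stay exactly zero.
    """

    def __init__(self, sequences: np.ndarray, masks: np.ndarray):
        rows = sequences[masks]
        self.mean = rows.mean(axis=0) if len(rows) else np.zeros(sequences.shape[-1])
        sd = rows.std(axis=0) if len(rows) else np.ones(sequences.shape[-1])
        sd[sd == 0] = 1.0
        self.sd = sd

    def transform(self, sequences: np.ndarray, masks: np.ndarray) -> np.ndarray:
        out = (sequences - self.mean) / self.sd
        return np.where(masks[..., None], out, 0.0)


def build_features(cfg: RunConfig, pretrain_cohort, multimodal_cohort):
    """Embed concepts, build standardized sequences, standardize omics."""
    corpus_pre = _cohort_corpus(pretrain_cohort, cfg.seed)
    params = SkipGramParams(epochs=cfg.skipgram_epochs, seed=cfg.seed)
    emb_pre = train_embeddings(corpus_pre, dimension=cfg.embed_dim, params=params,
                               training_corpus_tag="pretrain")
    if cfg.embedding_source == "separate":
        corpus_mm = _cohort_corpus(multimodal_cohort, cfg.seed + 1)
        emb_mm = train_embeddings(corpus_mm, dimension=cfg.embed_dim, params=params,
                                  training_corpus_tag="multimodal")
    else:
        emb_mm = emb_pre
    pre_tl = [truncate_at_index(tl) for tl in pretrain_cohort.timelines]
    mm_tl = [truncate_at_index(tl) for tl in multimodal_cohort.timelines]
    seq_pre, mask_pre = cohort_sequences(pre_tl, emb_pre, cfg.window)
    seq_mm, mask_mm = cohort_sequences(mm_tl, emb_mm, cfg.window)
    fit_seq, fit_mask = (seq_pre, mask_pre) if len(seq_pre) else (seq_mm, mask_mm)
    scaler = SequenceScaler(fit_seq, fit_mask)
    seq_pre = scaler.transform(seq_pre, mask_pre)
    seq_mm = scaler.transform(seq_mm, mask_mm)
    omics = prepare_omics(multimodal_cohort.proteomics.values)
    data_pre = MultimodalData(
        sequences=seq_pre, masks=mask_pre, omics=None,
        labels=pretrain_cohort.labels["label"].to_numpy(),
    )
    data_mm = MultimodalData(
        sequences=seq_mm, masks=mask_mm, omics=omics,
        labels=multimodal_cohort.labels["label"].to_numpy(),
    )
    return data_pre, data_mm, (emb_pre, emb_mm, scaler)


def _variant_config(cfg: RunConfig, mode: str, lr: float, lr_decay: float,
                    batch_size: int = 16) -> ModelConfig:
    return ModelConfig(
        mode=mode, layers=cfg.layers, hidden_dim=cfg.hidden_dim, dropout=cfg.dropout,
        learning_rate=lr, lr_decay=lr_decay, batch_size=batch_size,
        max_epochs=cfg.max_epochs, patience=cfg.patience, seed=cfg.seed,
    )


def _mode_data(mode: str, data_mm: MultimodalData) -> MultimodalData:
    if mode == "ehr_only":
        return MultimodalData(data_mm.sequences, data_mm.masks, None, data_mm.labels)
    if mode == "omics_only":
        return MultimodalData(None, None, data_mm.omics, data_mm.labels)
    return data_mm


def _fit_variant(mode, config, data, pretrained, train_idx, stop_idx, seed):
    config = dataclasses.replace(config, seed=seed)
    if mode == "comet":
        model, _ = transfer_and_finetune(pretrained, data, config, train_idx, stop_idx)
        return model
    if train_idx is None or stop_idx is None:
        from .model import _stratified_fraction

        rng = np.random.default_rng(config.seed)
        stop_idx = _stratified_fraction(data.labels, 0.2, rng)
        train_idx = np.setdiff1d(np.arange(data.n), stop_idx)
    model = CometModel(
        config,
        input_dim=None if data.sequences is None else data.sequences.shape[2],
        n_proteins=None if data.omics is None else data.omics.shape[1],
    )
    train_model(model, data, train_idx, stop_idx, config)
    return model


def tune_and_evaluate(cfg: RunConfig, mode: str, data_mm: MultimodalData,
                      pretrained: CometModel | None) -> tuple[ModelConfig, EvalResult]:
    """Grid-search lr/lr_decay for one variant, then Monte Carlo CV."""
    data = _mode_data(mode, data_mm)
    grid = [
        _variant_config(cfg, mode, lr, dec)
        for lr in cfg.grid_learning_rates
        for dec in cfg.grid_lr_decays
    ]

    def evaluate(config, train_idx, stop_idx, val_idx, seed):
        model = _fit_variant(mode, config, data, pretrained, train_idx, stop_idx, seed)
        return evaluate_loss(model, data, val_idx)

    best = grid_search(data.labels, grid, evaluate, folds=cfg.folds, seed=cfg.seed)

    def fit_predict(train_idx, stop_idx, val_idx, seed):
        model = _fit_variant(mode, best, data, pretrained, train_idx, stop_idx, seed)
        return model.predict_proba(data.subset(val_idx))

    result = monte_carlo_cv(
        data.labels, fit_predict, iterations=cfg.iterations, seed=cfg.seed,
        n_bootstrap=cfg.n_bootstrap,
    )
    return best, result


def run_discovery(cfg: RunConfig) -> DiscoveryReport:
    """Execute the full discovery stage; writes a report bundle."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage_log = _StageLogger(out_dir / "run.log", cfg.seed)
    written: list[Path] = []

    with stage_log.stage("cohorts"):
        pretrain_cohort, discovery_cohort, _ = _load_cohorts(cfg)
    with stage_log.stage("embed"):
        data_pre, data_mm, _ = build_features(cfg, pretrain_cohort, discovery_cohort)
    with stage_log.stage("pretrain"):
        pre_config = ModelConfig(
            mode="ehr_only", layers=cfg.layers, hidden_dim=cfg.hidden_dim,
            dropout=cfg.dropout, learning_rate=cfg.pretrain_learning_rate,
            lr_decay=cfg.pretrain_lr_decay, batch_size=cfg.pretrain_batch_size,
            max_epochs=cfg.pretrain_max_epochs, patience=cfg.patience, seed=cfg.seed,
        )
        pretrained, _ = pretrain(
            pre_config, data_pre.sequences, data_pre.masks, data_pre.labels
        )

    eval_results: dict[str, EvalResult] = {}
    best_configs: dict[str, ModelConfig] = {}
    for mode in ("ehr_only", "omics_only", "joint", "comet"):
        with stage_log.stage(f"evaluate:{mode}"):
            best, result = tune_and_evaluate(cfg, mode, data_mm, pretrained)
            best_configs[mode] = best
            eval_results[mode] = result

    n_mm = data_mm.n
    n_pre = data_pre.n
    sizes = {
        "ehr_only": str(n_mm),
        "omics_only": str(n_mm),
        "joint": str(n_mm),
        "comet": f"{n_pre} for pretraining, {n_mm} for fine tuning and evaluation",
    }
    metrics = results_table(eval_results, sizes)
    path = out_dir / "metrics.tsv"
    metrics.to_csv(path, sep="\t", index=False)
    written.append(path)

    protein_names = list(discovery_cohort.proteomics.values.columns)
    with stage_log.stage("prioritize"):
        comet_full, _ = transfer_and_finetune(pretrained, data_mm, best_configs["comet"])
        joint_full = _fit_variant("joint", best_configs["joint"], data_mm, None, None, None, cfg.seed)
        if joint_full is None:  # pragma: no cover - defensive
            raise RuntimeError("joint model fit failed")
        imp_comet = cohort_importance(comet_full, data_mm, protein_names, steps=cfg.ig_steps)
        imp_joint = cohort_importance(joint_full, data_mm, protein_names, steps=cfg.ig_steps)
        table = importance_fold_change(imp_comet.values, imp_joint.values)
        candidates = top_candidates(table, cfg.n_candidates)
    path = out_dir / "importance.tsv"
    table.to_csv(path, sep="\t")
    written.append(path)
    path = out_dir / "top_proteins.tsv"
    table.head(cfg.n_table).to_csv(path, sep="\t")
    written.append(path)
    path = out_dir / "candidates.txt"
    path.write_text("\n".join(candidates) + "\n")
    written.append(path)

    with stage_log.stage("align"):
        from .model import extract_latent

        lat_comet = extract_latent(comet_full, data_mm.sequences, data_mm.masks)
        lat_joint = extract_latent(joint_full, data_mm.sequences, data_mm.masks)
        prot_df = pd.DataFrame(data_mm.omics, columns=protein_names)
        corr_comet = align_mod.latent_protein_correlations(lat_comet, prot_df, cfg.alpha)
        corr_joint = align_mod.latent_protein_correlations(lat_joint, prot_df, cfg.alpha)
        _, p_compare = align_mod.compare_mean_abs_r(corr_comet, corr_joint)
        alignment_summary = {
            "comet": {
                "n_significant": corr_comet.n_significant,
                "mean_abs_r": round(corr_comet.mean_abs_r, 4),
            },
            "baseline": {
                "n_significant": corr_joint.n_significant,
                "mean_abs_r": round(corr_joint.mean_abs_r, 4),
            },
            "mann_whitney_p": p_compare,
        }
        coverage = align_mod.protein_latent_coverage(corr_comet)
    path = out_dir / "alignment_summary.json"
    path.write_text(json.dumps(alignment_summary, indent=1))
    written.append(path)
    path = out_dir / "latent_coverage.tsv"
    coverage.rename("pct_latent_dims_significant").to_csv(path, sep="\t")
    written.append(path)

    if cfg.include_tsne:
        with stage_log.stage("tsne"):
            ever = _binary_features(discovery_cohort)
            raw_prot = np.log2(discovery_cohort.proteomics.values)
            corr = align_mod.feature_correlation_matrix(ever, raw_prot)
            perplexity = min(cfg.tsne_perplexity, max(2.0, (len(corr) - 1) / 3.0 - 1))
            coords = align_mod.tsne_embed(corr, perplexity=perplexity, seed=cfg.seed)
            coords["type"] = [
                "ehr" if str(v).startswith("c") else "protein" for v in coords.index
            ]
        path = out_dir / "tsne.tsv"
        coords.to_csv(path, sep="\t")
        written.append(path)

    with stage_log.stage("discovery_de"):
        values = biostats.calibrator_scale(
            discovery_cohort.proteomics.values,
            discovery_cohort.proteomics.batches,
            discovery_cohort.proteomics.calibrators,
        )
        values = biostats.median_normalize(values)
        de = biostats.de_table(
            values, discovery_cohort.labels["label"].to_numpy(), candidates, cfg.alpha
        )
    path = out_dir / "discovery_de.tsv"
    de.table.to_csv(path, sep="\t")
    written.append(path)

    _write_manifest(out_dir, written)
    return DiscoveryReport(
        metrics=metrics,
        importance_table=table,
        candidates=candidates,
        alignment_summary=alignment_summary,
        eval_results=eval_results,
        discovery_de=de.table,
        out_dir=out_dir,
    )


def _binary_features(cohort: SyntheticCohort) -> pd.DataFrame:
    """Patients x concepts ever-occurred indicator block."""
    concepts = sorted(cohort.concept_domains)
    index = {c: j for j, c in enumerate(concepts)}
    matrix = np.zeros((len(cohort.timelines), len(concepts)))
    for i, tl in enumerate(cohort.timelines):
        for _, day_concepts in tl.days:
            for c in day_concepts:
                matrix[i, index[c]] = 1.0
    return pd.DataFrame(matrix, columns=[f"c{c}" for c in concepts])


def run_validation(cfg: RunConfig, candidates: list[str],
                   discovery_de: pd.DataFrame | None = None) -> dict:
    """Statistics-only validation stage on the independent cohort."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage_log = _StageLogger(out_dir / "validation.log", cfg.seed)
    written: list[Path] = []

    with stage_log.stage("cohorts"):
        _, discovery_cohort, validation_cohort = _load_cohorts(cfg)
    prot = validation_cohort.proteomics
    present = [c for c in candidates if c in prot.values.columns]
    missing = [c for c in candidates if c not in prot.values.columns]

    with stage_log.stage("normalize"):
        values = biostats.calibrator_scale(prot.values, prot.batches, prot.calibrators)
        values = biostats.median_normalize(values)

    labels = validation_cohort.labels["label"].to_numpy()
    de_report: dict = {}
    with stage_log.stage("de"):
        if present:
            de = biostats.de_table(values, labels, present, cfg.alpha)
            de_table_out = de.table
        else:
            de_table_out = pd.DataFrame(
                columns=["log2_fc", "t", "p", "p_adj", "significant"]
            )
    path = out_dir / "validation_de.tsv"
    de_table_out.to_csv(path, sep="\t")
    written.append(path)

    with stage_log.stage("stage_substratification"):
        stages = validation_cohort.labels["stage"].to_numpy()
        rows = []
        cases = labels == 1
        log2_values = np.log2(values.to_numpy())
        col_of = {c: j for j, c in enumerate(values.columns)}
        if (stages == "PDR").sum() >= 2 and (stages == "NPDR").sum() >= 2:
            for name in present:
                j = col_of[name]
                pdr = log2_values[cases & (stages == "PDR"), j]
                npdr = log2_values[cases & (stages == "NPDR"), j]
                t, p, fc = biostats.t_test_two_sample(pdr, npdr)
                rows.append({"protein": name, "log2_fc_pdr_vs_npdr": fc, "t": t, "p": p})
        stage_table = pd.DataFrame(rows, columns=["protein", "log2_fc_pdr_vs_npdr", "t", "p"])
    path = out_dir / "stage_comparison.tsv"
    stage_table.to_csv(path, sep="\t", index=False)
    written.append(path)

    concordance = None
    if discovery_de is not None and present and len(de_table_out):
        shared = [c for c in present if c in discovery_de.index]
        if shared:
            signs_d = np.sign(discovery_de.loc[shared, "log2_fc"])
            signs_v = np.sign(de_table_out.loc[shared, "log2_fc"])
            concordance = float((signs_d == signs_v).mean())

    report = {
        "cohort_sizes": {
            "discovery": int(discovery_cohort.n_patients),
            "validation": int(validation_cohort.n_patients),
        },
        "n_candidates": len(candidates),
        "candidates_missing": missing,
        "n_significant": int(de_table_out["significant"].sum()) if len(de_table_out) else 0,
        "sign_concordance": concordance,
    }
    path = out_dir / "validation_report.json"
    path.write_text(json.dumps(report, indent=1))
    written.append(path)
    _write_manifest(out_dir, written, name="validation_manifest.json")
    return report
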