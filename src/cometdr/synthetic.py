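"""Synthetic cohort generator with planted cross-modal structure.

Emulates the three-cohort study design behind the two-stage biomarker
workflow: a large EHR-only pretraining cohort, a small multimodal
discovery cohort (aqueous-humor proteomics + longitudinal EHR), and an
independent proteomics validation cohort.  Real patient data cannot be
shared, so every downstream stage is exercised on cohorts drawn from an
explicit generative model:

* each patient carries latent factors ``z ~ N(0, I)`` with distinct
  cross-modal footprints: ``z0`` is a systemic *confounder* (expressed in
  concept occurrences and contaminating the EHR-rooted proteins, but not
  itself part of the outcome), ``z1`` is clinical severity (documented in
  the record and driving the outcome), and ``z2`` is molecular severity
  (carried by the rooted proteins and driving the outcome, invisible to
  the record) — so neither modality alone determines the outcome, and a
  model that understands the EHR can *de-confound* the rooted proteins;
* the multimodal cohorts' outcome score is ``(z1+z2)/sqrt(2)`` at the
  default ``latent_dim_true=3`` (``z0`` alone with one factor,
  ``(z0+z1)/sqrt(2)`` with two); the EHR-only pretraining cohort is
  labeled by an EHR-defined phenotype scoring ``(z0+z1)/sqrt(2)`` —
  diagnosis-code labels reflect what the record can see, so pretraining
  teaches the encoder both clinical factors;
* "effect" concepts split into two halves whose occurrence
  log-odds are raised by ``concept_effect * z0`` and ``concept_effect *
  z1`` respectively (logistic link), so timelines encode both the
  confounder and the clinical severity;
* the binary outcome is assigned by quota: the ``n_cases`` patients with
  the largest score are cases, guaranteeing the exact prevalences of the
  emulated study (14/101 discovery, 17/164 validation);
* "effect" proteins are mean-shifted in cases by ``protein_d * noise_sd``
  on the log2 scale (population Cohen's d = ``protein_d``);
* "EHR-rooted" proteins load on the cross-modal mix
  ``(z0+z2)/sqrt(2)`` at correlation ``cross_modal_rho`` and carry a
  weaker marginal case shift (``rooted_protein_d``): they blend an
  EHR-documented systemic process with molecular outcome signal the
  record lacks — the signature the pretrained multimodal model is
  designed to surface by explaining the confounded share away;
* the validation proteomics matrix is split into batches with a known
  per-batch, per-protein multiplicative scale plus calibrator rows, so
  calibrator-based batch scaling is exercised.

Cases are substratified by severity: the top half of cases by ``z`` are
tagged "PDR", the rest "NPDR" (proliferative vs non-proliferative
retinopathy analogs), enabling stage comparisons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .embedding import PatientTimeline

__all__ = [
    "SyntheticConfig",
    "SyntheticCohort",
    "ProteomicsMatrix",
    "DOMAINS",
    "generate_cohorts",
    "write_cohort",
    "read_cohort",
]

DOMAINS = ("measurement", "observation", "drug", "condition", "procedure")


@dataclass
class SyntheticConfig:
    """Generative parameters for the three synthetic cohorts.

    Discovery and validation sizes default to the emulated study design
    (101 with 14 cases; 164 with 17 cases).  The pretraining cohort and
    vocabulary are scaled down from the original study (319,896 patients,
    2,531 features) to desk size; see the methods note.
    """

    seed: int
    n_pretrain: int = 2000
    n_discovery: int = 101
    n_discovery_cases: int = 14
    n_validation: int = 164
    n_validation_cases: int = 17
    n_concepts: int = 300
    n_proteins: int = 200
    n_days: int = 64
    latent_dim_true: int = 3
    concept_effect: float = 1.0
    protein_d: float = 1.4
    rooted_protein_d: float = 0.4
    cross_modal_rho: float = 0.8
    noise_sd: float = 1.9
    n_effect_concepts: int = 20
    n_effect_proteins: int = 15
    n_rooted_proteins: int = 5
    n_validation_batches: int = 2
    batch_scale_sd: float = 0.3  # log2-scale SD of per-batch calibrator drift
    pretrain_case_frac: float = 0.15
    # co-regulation: effect proteins share a latent noise factor (pairwise
    # correlation protein_cor), emulating pathway co-expression
    protein_cor: float = 0.5

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is required: all generation must be reproducible")
        counts = {
            "n_pretrain": self.n_pretrain,
            "n_discovery": self.n_discovery,
            "n_validation": self.n_validation,
            "n_concepts": self.n_concepts,
            "n_proteins": self.n_proteins,
            "n_days": self.n_days,
            "latent_dim_true": self.latent_dim_true,
        }
        for name, value in counts.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if self.n_discovery_cases > self.n_discovery:
            raise ValueError(
                f"n_discovery_cases ({self.n_discovery_cases}) exceeds cohort size "
                f"({self.n_discovery})"
            )
        if self.n_validation_cases > self.n_validation:
            raise ValueError(
                f"n_validation_cases ({self.n_validation_cases}) exceeds cohort size "
                f"({self.n_validation})"
            )
        if not 0.0 <= self.cross_modal_rho <= 1.0:
            raise ValueError("cross_modal_rho must be in [0, 1]")
        if not 0.0 <= self.protein_cor < 1.0:
            raise ValueError("protein_cor must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_effect_proteins + self.n_rooted_proteins > self.n_proteins:
            raise ValueError("more planted proteins than proteins")
        if self.n_effect_concepts > self.n_concepts:
            raise ValueError("more effect concepts than concepts")


@dataclass
class ProteomicsMatrix:
    """Samples x proteins positive intensity matrix with batch annotations.

    ``values`` has sample IDs as the index and protein codes as columns
    (RFU-like, strictly positive).  ``calibrators`` holds one reference
    measurement per (batch, protein); for single-batch matrices it is a
    one-row frame.
    """

    values: pd.DataFrame
    batches: pd.Series
    calibrators: pd.DataFrame

    def __eq__(self, other) -> bool:  # round-trip identity support
        if not isinstance(other, ProteomicsMatrix):
            return NotImplemented
        return (
            self.values.equals(other.values)
            and self.batches.equals(other.batches)
            and self.calibrators.equals(other.calibrators)
        )


@dataclass
class SyntheticCohort:
    """One generated cohort: timelines, optional proteomics, labels, truth."""

    timelines: list[PatientTimeline]
    proteomics: ProteomicsMatrix | None
    labels: pd.DataFrame  # columns: person_id, label, stage
    truth: dict[str, list]
    concept_domains: dict[int, str] = field(default_factory=dict)

    @property
    def person_ids(self) -> list[int]:
        return list(self.labels["person_id"])

    @property
    def n_patients(self) -> int:
        return len(self.labels)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SyntheticCohort):
            return NotImplemented
        return (
            self.timelines == other.timelines
            and self.proteomics == other.proteomics
            and self.labels.equals(other.labels)
            and self.truth == other.truth
            and self.concept_domains == other.concept_domains
        )


def _concept_ids(config: SyntheticConfig) -> np.ndarray:
    return np.arange(1000, 1000 + config.n_concepts)


def _protein_codes(config: SyntheticConfig) -> list[str]:
    return [f"P{i:04d}" for i in range(config.n_proteins)]


def _plant_truth(config: SyntheticConfig, rng: np.random.Generator) -> dict[str, list]:
    concepts = _concept_ids(config)
    effect_concepts = rng.choice(concepts, size=config.n_effect_concepts, replace=False)
    proteins = _protein_codes(config)
    order = rng.permutation(config.n_proteins)
    effect = [proteins[i] for i in order[: config.n_effect_proteins]]
    rooted = [
        proteins[i]
        for i in order[
            config.n_effect_proteins : config.n_effect_proteins + config.n_rooted_proteins
        ]
    ]
    return {
        "effect_concepts": sorted(int(c) for c in effect_concepts),
        "effect_proteins": sorted(effect),
        "rooted_proteins": sorted(rooted),
    }


def _shared_generative_frame(config: SyntheticConfig, rng: np.random.Generator):
    """Draw the population-level quantities shared by all three cohorts."""
    # concept base rates, log-uniform in [0.001, 0.05] -> realistic sparsity
    log_lo, log_hi = np.log(0.001), np.log(0.05)
    base_rates = np.exp(rng.uniform(log_lo, log_hi, size=config.n_concepts))
    base_logits = np.log(base_rates / (1.0 - base_rates))
    # nuisance latent factors (beyond the three outcome-linked ones) load
    # sparsely on concepts to give timelines realistic correlation structure
    loadings = np.zeros((config.latent_dim_true, config.n_concepts))
    for k in range(3, config.latent_dim_true):
        idx = rng.choice(
            config.n_concepts, size=max(1, config.n_concepts // 10), replace=False
        )
        loadings[k, idx] = 0.5
    protein_baseline = rng.uniform(6.0, 14.0, size=config.n_proteins)
    calibrator_reference = rng.uniform(100.0, 1000.0, size=config.n_proteins)
    truth = _plant_truth(config, rng)
    return base_logits, loadings, protein_baseline, calibrator_reference, truth


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _generate_timelines(
    config: SyntheticConfig,
    person_ids: np.ndarray,
    z: np.ndarray,
    base_logits: np.ndarray,
    loadings: np.ndarray,
    effect_mask: np.ndarray,
    rng: np.random.Generator,
) -> list[PatientTimeline]:
    n = len(person_ids)
    concepts = _concept_ids(config)
    # per-patient, per-concept occurrence probability (constant across days)
    logits = np.broadcast_to(base_logits, (n, config.n_concepts)).copy()
    effect_idx = np.flatnonzero(effect_mask)
    if z.shape[1] >= 2 and len(effect_idx) >= 2:
        # first half of the effect concepts expresses systemic severity,
        # second half clinical-only severity
        half = len(effect_idx) // 2
        logits[:, effect_idx[:half]] += config.concept_effect * z[:, 0:1]
        logits[:, effect_idx[half:]] += config.concept_effect * z[:, 1:2]
    else:
        logits[:, effect_idx] += config.concept_effect * z[:, 0:1]
    if z.shape[1] > 3:
        logits += z[:, 3:] @ loadings[3:]
    probs = _sigmoid(logits)
    events: list[list[tuple[int, list[int]]]] = [[] for _ in range(n)]
    for day in range(config.n_days):
        hits = rng.random((n, config.n_concepts)) < probs
        rows, cols = np.nonzero(hits)
        if rows.size == 0:
            continue
        boundaries = np.searchsorted(rows, np.arange(n + 1))
        for i in range(n):
            lo, hi = boundaries[i], boundaries[i + 1]
            if lo < hi:
                events[i].append((day, [int(concepts[c]) for c in cols[lo:hi]]))
    timelines = []
    for i in range(n):
        if not events[i]:
            # guarantee a non-empty timeline for every labeled patient
            events[i].append((0, [int(rng.choice(concepts))]))
        index_date = events[i][-1][0]  # end of record analog of biopsy/onset
        timelines.append(
            PatientTimeline(
                person_id=int(person_ids[i]), days=events[i], index_date=index_date
            )
        )
    return timelines


def _generate_proteomics(
    config: SyntheticConfig,
    person_ids: np.ndarray,
    z: np.ndarray,
    labels: np.ndarray,
    protein_baseline: np.ndarray,
    calibrator_reference: np.ndarray,
    truth: dict[str, list],
    n_batches: int,
    rng: np.random.Generator,
) -> ProteomicsMatrix:
    n = len(person_ids)
    codes = _protein_codes(config)
    code_index = {c: j for j, c in enumerate(codes)}
    effect_idx = np.array([code_index[c] for c in truth["effect_proteins"]], dtype=int)
    rooted_idx = np.array([code_index[c] for c in truth["rooted_proteins"]], dtype=int)

    eps = rng.standard_normal((n, config.n_proteins))
    if effect_idx.size and config.protein_cor > 0:
        # shared factor induces pairwise correlation protein_cor among the
        # effect proteins while keeping each marginal SD at 1
        shared = rng.standard_normal((n, 1))
        c = config.protein_cor
        eps[:, effect_idx] = np.sqrt(c) * shared + np.sqrt(1.0 - c) * eps[:, effect_idx]
    log2 = protein_baseline + config.noise_sd * eps
    if effect_idx.size:
        log2[:, effect_idx] += (
            config.protein_d * config.noise_sd * labels[:, None]
        )
    if rooted_idx.size:
        rho = config.cross_modal_rho
        # cross-modal severity mix: systemic (EHR-expressed) + molecular-only
        if z.shape[1] >= 3:
            z_mix = (z[:, 0:1] + z[:, 2:3]) / np.sqrt(2.0)
        else:
            z_mix = z[:, 0:1]
        correlated = rho * z_mix + np.sqrt(1.0 - rho**2) * eps[:, rooted_idx]
        log2[:, rooted_idx] = (
            protein_baseline[rooted_idx]
            + config.noise_sd * correlated
            + config.rooted_protein_d * config.noise_sd * labels[:, None]
        )
    intensities = np.power(2.0, log2)

    batch_names = [f"B{b + 1}" for b in range(n_batches)]
    batch_assign = np.array(batch_names)[rng.integers(0, n_batches, size=n)]
    scales = np.ones((n_batches, config.n_proteins))
    if n_batches > 1:
        scales[1:] = np.power(
            2.0, rng.normal(0.0, config.batch_scale_sd, size=(n_batches - 1, config.n_proteins))
        )
    for b, name in enumerate(batch_names):
        intensities[batch_assign == name] *= scales[b]
    calibrators = pd.DataFrame(
        calibrator_reference * scales, index=batch_names, columns=codes
    )
    values = pd.DataFrame(intensities, index=[int(p) for p in person_ids], columns=codes)
    batches = pd.Series(batch_assign, index=values.index, name="batch")
    return ProteomicsMatrix(values=values, batches=batches, calibrators=calibrators)


def _make_cohort(
    config: SyntheticConfig,
    person_ids: np.ndarray,
    n_cases: int,
    frame,
    with_proteomics: bool,
    n_batches: int,
    rng: np.random.Generator,
    ehr_defined_outcome: bool = False,
) -> SyntheticCohort:
    base_logits, loadings, protein_baseline, calibrator_reference, truth = frame
    n = len(person_ids)
    concepts = _concept_ids(config)
    domains = {int(c): DOMAINS[i % len(DOMAINS)] for i, c in enumerate(concepts)}
    if n == 0:
        labels = pd.DataFrame(columns=["person_id", "label", "stage"]).astype(
            {"person_id": int, "label": int, "stage": str}
        )
        return SyntheticCohort(
            timelines=[], proteomics=None, labels=labels, truth=truth,
            concept_domains=domains,
        )
    z = rng.standard_normal((n, max(1, config.latent_dim_true)))
    # outcome by quota on the severity score: exact case count.  The
    # multimodal cohorts' outcome is the clean clinical+molecular
    # phenotype (z1+z2); the pretraining cohort's outcome is an
    # EHR-defined label (diagnosis-code style) reflecting the factors the
    # record can see, systemic+clinical (z0+z1).
    if z.shape[1] >= 3:
        if ehr_defined_outcome:
            score = (z[:, 0] + z[:, 1]) / np.sqrt(2.0)
        else:
            score = (z[:, 1] + z[:, 2]) / np.sqrt(2.0)
    elif z.shape[1] == 2:
        score = (z[:, 0] + z[:, 1]) / np.sqrt(2.0)
    else:
        score = z[:, 0]
    order = np.argsort(-score, kind="stable")
    labels_vec = np.zeros(n, dtype=int)
    labels_vec[order[:n_cases]] = 1
    stage = np.array(["none"] * n, dtype=object)
    if n_cases > 0:
        case_order = order[:n_cases]  # already sorted by decreasing severity
        half = (n_cases + 1) // 2
        stage[case_order[:half]] = "PDR"
        stage[case_order[half:]] = "NPDR"
    effect_mask = np.isin(concepts, truth["effect_concepts"])
    timelines = _generate_timelines(
        config, person_ids, z, base_logits, loadings, effect_mask, rng
    )
    proteomics = None
    if with_proteomics:
        proteomics = _generate_proteomics(
            config, person_ids, z, labels_vec, protein_baseline,
            calibrator_reference, truth, n_batches, rng,
        )
    labels = pd.DataFrame(
        {"person_id": person_ids.astype(int), "label": labels_vec, "stage": stage}
    )
    return SyntheticCohort(
        timelines=timelines, proteomics=proteomics, labels=labels, truth=truth,
        concept_domains=domains,
    )


def generate_cohorts(
    config: SyntheticConfig,
) -> tuple[SyntheticCohort, SyntheticCohort, SyntheticCohort]:
    """Generate (pretrain, discovery, validation) cohorts.

    Discovery and validation are independent draws from the identical
    generative law; the pretraining cohort has timelines and labels but no
    proteomics.  Two calls with the same config are byte-identical.
    """
    rng = np.random.default_rng(config.seed)
    frame = _shared_generative_frame(config, rng)
    ids_pre = np.arange(1, config.n_pretrain + 1)
    ids_disc = np.arange(100001, 100001 + config.n_discovery)
    ids_val = np.arange(200001, 200001 + config.n_validation)
    n_pre_cases = int(round(config.pretrain_case_frac * config.n_pretrain))
    pretrain = _make_cohort(
        config, ids_pre, n_pre_cases, frame, with_proteomics=False, n_batches=1,
        rng=np.random.default_rng(rng.integers(2**31)), ehr_defined_outcome=True,
    )
    discovery = _make_cohort(
        config, ids_disc, config.n_discovery_cases, frame, with_proteomics=True,
        n_batches=1, rng=np.random.default_rng(rng.integers(2**31)),
    )
    validation = _make_cohort(
        config, ids_val, config.n_validation_cases, frame, with_proteomics=True,
        n_batches=config.n_validation_batches,
        rng=np.random.default_rng(rng.integers(2**31)),
    )
    return pretrain, discovery, validation


def generate_discovery_replicate(
    config: SyntheticConfig, replicate_seed: int
) -> SyntheticCohort:
    """An independent multimodal cohort from the *same* generative law.

    Rebuilds the population frame (base rates, planted truth, loadings)
    deterministically from ``config.seed`` — identical to the frame used
    by :func:`generate_cohorts` — and draws a fresh set of patients with
    ``replicate_seed``.  Used by repeated-cohort experiments.
    """
    rng = np.random.default_rng(config.seed)
    frame = _shared_generative_frame(config, rng)
    ids = np.arange(100001, 100001 + config.n_discovery)
    return _make_cohort(
        config, ids, config.n_discovery_cases, frame, with_proteomics=True,
        n_batches=1, rng=np.random.default_rng(replicate_seed),
    )


# ---------------------------------------------------------------------------
# Delimited-text round trip
# ---------------------------------------------------------------------------


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> list[Path]:
    """Write a cohort as delimited text files; returns the paths written.

    Layout: ``events.tsv`` (person_id, day, concept_id, domain),
    ``labels.tsv`` (person_id, label, stage), ``proteins.csv`` (samples x
    proteins), ``batches.tsv``, ``calibrators.csv``, ``truth.tsv``, and a
    JSON manifest with index dates.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []

    rows = []
    for tl in cohort.timelines:
        for day, concepts in tl.days:
            for c in concepts:
                rows.append((tl.person_id, day, c, cohort.concept_domains.get(c, "observation")))
    events = pd.DataFrame(rows, columns=["person_id", "day", "concept_id", "domain"])
    path = directory / "events.tsv"
    events.to_csv(path, sep="\t", index=False)
    written.append(path)

    path = directory / "labels.tsv"
    cohort.labels.to_csv(path, sep="\t", index=False)
    written.append(path)

    if cohort.proteomics is not None:
        path = directory / "proteins.csv"
        cohort.proteomics.values.to_csv(path, index_label="sample_id", float_format="%.17g")
        written.append(path)
        path = directory / "batches.tsv"
        cohort.proteomics.batches.rename_axis("sample_id").to_csv(path, sep="\t")
        written.append(path)
        path = directory / "calibrators.csv"
        cohort.proteomics.calibrators.to_csv(path, index_label="batch", float_format="%.17g")
        written.append(path)

    truth_rows = [
        (kind, item) for kind, items in sorted(cohort.truth.items()) for item in items
    ]
    path = directory / "truth.tsv"
    pd.DataFrame(truth_rows, columns=["kind", "identifier"]).to_csv(
        path, sep="\t", index=False
    )
    written.append(path)

    manifest = {
        "index_dates": {str(tl.person_id): tl.index_date for tl in cohort.timelines},
        "has_proteomics": cohort.proteomics is not None,
        # full vocabulary (events cover only concepts that occurred)
        "concept_domains": {str(c): d for c, d in cohort.concept_domains.items()},
    }
    path = directory / "cohort.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    written.append(path)
    return written


def _parse_events(path: Path) -> pd.DataFrame:
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty event file")
    header = lines[0].split("\t")
    expected = ["person_id", "day", "concept_id", "domain"]
    if header != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {header}")
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ValueError(f"{path}: line {lineno}: expected 4 fields, got {len(parts)}")
        person, day, concept, domain = parts
        try:
            person_i, day_i, concept_i = int(person), int(day), int(concept)
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: non-integer field ({exc})") from None
        if domain not in DOMAINS:
            raise ValueError(
                f"{path}: line {lineno}: unknown domain {domain!r} (expected one of {DOMAINS})"
            )
        rows.append((person_i, day_i, concept_i, domain))
    return pd.DataFrame(rows, columns=["person_id", "day", "concept_id", "domain"])


def read_cohort(directory: str | Path) -> SyntheticCohort:
    """Read a cohort written by :func:`write_cohort` (round-trip identity)."""
    directory = Path(directory)
    events = _parse_events(directory / "events.tsv")
    labels = pd.read_csv(directory / "labels.tsv", sep="\t")
    labels["stage"] = labels["stage"].astype(object)
    manifest = json.loads((directory / "cohort.json").read_text())
    index_dates = {int(k): v for k, v in manifest["index_dates"].items()}

    domains = {
        int(c): d
        for c, d in events[["concept_id", "domain"]].drop_duplicates().itertuples(
            index=False
        )
    }
    for c, d in manifest.get("concept_domains", {}).items():
        domains.setdefault(int(c), d)
    timelines = []
    for person_id in labels["person_id"]:
        sub = events[events["person_id"] == person_id]
        days = []
        for day in sorted(sub["day"].unique()):
            concepts = [int(c) for c in sub.loc[sub["day"] == day, "concept_id"]]
            days.append((int(day), concepts))
        timelines.append(
            PatientTimeline(
                person_id=int(person_id), days=days,
                index_date=index_dates.get(int(person_id)),
            )
        )

    proteomics = None
    if manifest.get("has_proteomics"):
        values = pd.read_csv(
            directory / "proteins.csv", index_col="sample_id", float_precision="round_trip"
        )
        batches = pd.read_csv(directory / "batches.tsv", sep="\t", index_col="sample_id")[
            "batch"
        ]
        calibrators = pd.read_csv(
            directory / "calibrators.csv", index_col="batch", float_precision="round_trip"
        )
        proteomics = ProteomicsMatrix(values=values, batches=batches, calibrators=calibrators)

    truth_df = pd.read_csv(directory / "truth.tsv", sep="\t")
    truth: dict[str, list] = {}
    for kind, group in truth_df.groupby("kind"):
        items = list(group["identifier"])
        if kind == "effect_concepts":
            items = [int(i) for i in items]
        truth[str(kind)] = sorted(items)
    return SyntheticCohort(
        timelines=timelines, proteomics=proteomics, labels=labels, truth=truth,
        concept_domains=domains,
    )
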