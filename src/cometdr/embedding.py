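"""Concept embeddings and fixed-length patient sequences from EHR timelines.

Longitudinal concept-occurrence records are organized chronologically by
patient and day.  Same-day events have no reliable within-day ordering, so
each day's events are shuffled once into a "sentence"; a skip-gram
word-embedding model (negative sampling, trained here directly on numpy)
maps every concept code to a dense vector (default dimension 400).  A
patient's day is summarized by the arithmetic mean of that day's concept
vectors, and the model consumes the most recent 32 of these daily
summaries as a left-padded ``window x dimension`` matrix with a padding
mask.

"Most recent 32 days" means the last 32 *event-days* (days with at least
one recorded code), since daily summaries only exist for such days.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PatientTimeline",
    "ConceptEmbedding",
    "PatientSequence",
    "find_index_date",
    "truncate_at_index",
    "build_daily_sentences",
    "train_embeddings",
    "daily_average",
    "build_sequence",
    "cohort_sequences",
]

DEFAULT_DIMENSION = 400
DEFAULT_WINDOW_DAYS = 32


@dataclass
class PatientTimeline:
    """Ordered per-patient daily concept records with an index date.

    ``days`` is a list of ``(day, concepts)`` with strictly increasing
    integer days and non-empty concept lists (multisets: repeats allowed).
    """

    person_id: int
    days: list[tuple[int, list[int]]]
    index_date: int | None = None

    def __post_init__(self) -> None:
        day_numbers = [d for d, _ in self.days]
        if any(b <= a for a, b in zip(day_numbers, day_numbers[1:])):
            raise ValueError(f"person {self.person_id}: days must be strictly increasing")
        if any(len(concepts) == 0 for _, concepts in self.days):
            raise ValueError(f"person {self.person_id}: empty concept list on a day")


@dataclass
class ConceptEmbedding:
    """Concept code -> vector lookup with a fixed dimension."""

    dimension: int
    vectors: dict[int, np.ndarray]
    training_corpus_tag: str = "pretrain"

    def __post_init__(self) -> None:
        for code, vec in self.vectors.items():
            if vec.shape != (self.dimension,):
                raise ValueError(
                    f"vector for concept {code} has shape {vec.shape}, "
                    f"expected ({self.dimension},)"
                )


@dataclass
class PatientSequence:
    """Fixed-length matrix of daily-average vectors, oldest to newest.

    Rows where ``mask`` is False are zero padding (or days whose concepts
    were all absent from the embedding vocabulary).
    """

    matrix: np.ndarray  # (window, dimension)
    mask: np.ndarray  # (window,) bool

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != self.mask.shape[0]:
            raise ValueError("matrix and mask lengths differ")


def find_index_date(timeline: PatientTimeline, onset_concepts: set[int]) -> int | None:
    """Earliest day on which any onset concept occurs; None if none do.

    Used for EHR-only patients, whose record is truncated at disease
    onset.  Multimodal patients instead use their externally supplied
    biopsy date.
    """
    if not timeline.days:
        raise ValueError(f"person {timeline.person_id}: empty timeline")
    for day, concepts in timeline.days:
        if any(c in onset_concepts for c in concepts):
            return day
    return None


def truncate_at_index(timeline: PatientTimeline, inclusive: bool = True) -> PatientTimeline:
    """Drop events after the index date (inclusive keeps the index day)."""
    if timeline.index_date is None:
        return timeline
    if inclusive:
        days = [(d, c) for d, c in timeline.days if d <= timeline.index_date]
    else:
        days = [(d, c) for d, c in timeline.days if d < timeline.index_date]
    return PatientTimeline(
        person_id=timeline.person_id, days=days, index_date=timeline.index_date
    )


def build_daily_sentences(timeline: PatientTimeline, seed: int) -> list[list[int]]:
    """One sentence per event-day: a seeded random permutation of that
    day's concept multiset (within-day order is unreliable in the source
    records, so it is randomized once)."""
    rng = np.random.default_rng(seed)
    sentences = []
    for _, concepts in timeline.days:
        perm = rng.permutation(len(concepts))
        sentences.append([concepts[i] for i in perm])
    return sentences


# ---------------------------------------------------------------------------
# Skip-gram with negative sampling
# ---------------------------------------------------------------------------


@dataclass
class SkipGramParams:
    window: int = 25
    negative: int = 5
    epochs: int = 10
    min_count: int = 1
    initial_lr: float = 0.025
    min_lr: float = 1e-4
    batch_pairs: int = 1024
    seed: int = 0


def _collect_pairs(
    sentences: list[list[int]], index: dict[int, int], window: int
) -> tuple[np.ndarray, np.ndarray]:
    centers, contexts = [], []
    for sentence in sentences:
        ids = [index[c] for c in sentence if c in index]
        n = len(ids)
        for i in range(n):
            lo, hi = max(0, i - window), min(n, i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    centers.append(ids[i])
                    contexts.append(ids[j])
    return np.asarray(centers, dtype=np.int64), np.asarray(contexts, dtype=np.int64)


def train_embeddings(
    sentences: list[list[int]],
    dimension: int = DEFAULT_DIMENSION,
    params: SkipGramParams | None = None,
    training_corpus_tag: str = "pretrain",
) -> ConceptEmbedding:
    """Train skip-gram concept embeddings with negative sampling.

    Deterministic for a fixed ``params.seed`` (single worker).  Every
    concept meeting ``min_count`` receives a ``dimension``-length vector;
    no other keys appear.
    """
    if dimension <= 0:
        raise ValueError(f"dimension must be positive, got {dimension}")
    params = params or SkipGramParams()
    counts: dict[int, int] = {}
    for sentence in sentences:
        for c in sentence:
            counts[c] = counts.get(c, 0) + 1
    vocab = sorted(c for c, n in counts.items() if n >= params.min_count)
    if not vocab:
        raise ValueError("empty corpus: no concepts meet min_count")
    index = {c: i for i, c in enumerate(vocab)}
    V = len(vocab)
    rng = np.random.default_rng(params.seed)

    centers, contexts = _collect_pairs(sentences, index, params.window)
    n_pairs = len(centers)
    if n_pairs == 0:
        # degenerate corpus of singleton sentences: random but valid vectors
        w_in = (rng.random((V, dimension)) - 0.5) / dimension
        return ConceptEmbedding(
            dimension=dimension,
            vectors={c: w_in[i].copy() for c, i in index.items()},
            training_corpus_tag=training_corpus_tag,
        )

    freq = np.array([counts[c] for c in vocab], dtype=np.float64) ** 0.75
    noise_cdf = np.cumsum(freq / freq.sum())

    w_in = (rng.random((V, dimension)) - 0.5) / dimension
    w_out = np.zeros((V, dimension))

    total_updates = params.epochs * n_pairs
    done = 0
    for _ in range(params.epochs):
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, params.batch_pairs):
            batch = order[start : start + params.batch_pairs]
            ci, oi = centers[batch], contexts[batch]
            lr = max(
                params.min_lr,
                params.initial_lr * (1.0 - done / total_updates),
            )
            c_vec = w_in[ci]  # (B, D)
            # positive pair (scores clipped to +-6, the classic sigmoid range)
            o_vec = w_out[oi]
            s_pos = 1.0 / (1.0 + np.exp(-np.clip(np.sum(c_vec * o_vec, axis=1), -6, 6)))
            g_pos = s_pos - 1.0  # (B,)
            grad_c = g_pos[:, None] * o_vec
            # negative samples
            negs = np.searchsorted(
                noise_cdf, rng.random((len(batch), params.negative))
            )
            n_vec = w_out[negs]  # (B, K, D)
            s_neg = 1.0 / (
                1.0 + np.exp(-np.clip(np.einsum("bd,bkd->bk", c_vec, n_vec), -6, 6))
            )
            grad_c += np.einsum("bk,bkd->bd", s_neg, n_vec)
            # accumulate per-row gradients, then average over each row's
            # update count so the step size is independent of how often a
            # word appears in the batch (keeps aggregated SGD stable)
            flat = negs.reshape(-1)
            out_rows = np.concatenate([oi, flat])
            out_grads = np.concatenate(
                [
                    g_pos[:, None] * c_vec,
                    (s_neg[..., None] * c_vec[:, None, :]).reshape(len(flat), -1),
                ]
            )
            acc_out = np.zeros_like(w_out)
            np.add.at(acc_out, out_rows, out_grads)
            cnt_out = np.bincount(out_rows, minlength=V)[:, None]
            w_out -= lr * acc_out / np.maximum(cnt_out, 1)
            acc_in = np.zeros_like(w_in)
            np.add.at(acc_in, ci, grad_c)
            cnt_in = np.bincount(ci, minlength=V)[:, None]
            w_in -= lr * acc_in / np.maximum(cnt_in, 1)
            done += len(batch)

    return ConceptEmbedding(
        dimension=dimension,
        vectors={c: w_in[i].copy() for c, i in index.items()},
        training_corpus_tag=training_corpus_tag,
    )


def daily_average(concepts: list[int], embedding: ConceptEmbedding) -> np.ndarray | None:
    """Arithmetic mean of the concepts' vectors (multiplicity respected).

    Concepts absent from the embedding vocabulary are skipped; returns
    None when no concept is known (the caller pads such days).
    """
    if len(concepts) == 0:
        raise ValueError("daily_average of an empty concept multiset")
    known = [embedding.vectors[c] for c in concepts if c in embedding.vectors]
    if not known:
        return None
    return np.mean(known, axis=0)


def build_sequence(
    timeline: PatientTimeline,
    embedding: ConceptEmbedding,
    window: int = DEFAULT_WINDOW_DAYS,
) -> PatientSequence:
    """Last ``window`` event-day summaries, left-padded with zero rows.

    The timeline is expected to be truncated at its index date.  Rows are
    oldest to newest so a recurrent encoder's final state reflects the
    most recent day.
    """
    summaries: list[np.ndarray | None] = [
        daily_average(concepts, embedding) for _, concepts in timeline.days
    ]
    recent = summaries[-window:]
    matrix = np.zeros((window, embedding.dimension))
    mask = np.zeros(window, dtype=bool)
    offset = window - len(recent)
    for i, vec in enumerate(recent):
        if vec is not None:
            matrix[offset + i] = vec
            mask[offset + i] = True
    return PatientSequence(matrix=matrix, mask=mask)


def cohort_sequences(
    timelines: list[PatientTimeline],
    embedding: ConceptEmbedding,
    window: int = DEFAULT_WINDOW_DAYS,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-patient sequences into (N, window, dim) + (N, window) mask."""
    seqs = [build_sequence(tl, embedding, window) for tl in timelines]
    matrix = np.stack([s.matrix for s in seqs]) if seqs else np.zeros((0, window, embedding.dimension))
    mask = np.stack([s.mask for s in seqs]) if seqs else np.zeros((0, window), dtype=bool)
    return matrix, mask
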