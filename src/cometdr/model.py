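"""Multimodal EHR + proteomics classifier with frozen-encoder transfer.

Four model variants share one architecture with three components:

* an **EHR component**: a stacked gated-recurrent-unit (GRU) encoder over
  the patient's sequence of daily concept-embedding averages, whose final
  hidden state (the EHR latent representation) feeds a linear logit head;
* an **omics component**: a single linear layer over the standardized
  protein vector;
* a **joint component**: a linear layer over the concatenation of the EHR
  latent and the protein vector, capturing cross-modal interactions.

A bias-free linear combiner weighs the active component logits and a
sigmoid yields the outcome probability; training minimizes binary cross
entropy.  The variants are ``ehr_only``, ``omics_only``, ``joint`` (all
three components, trained from scratch), and ``comet`` (same as joint but
the GRU weights are copied from an encoder pretrained on the large
EHR-only cohort and *frozen* during fine-tuning).

Training is plain SGD with a multiplicative per-epoch learning-rate decay
``lr *= (1 - lr_decay)`` and early stopping (patience 5) on a held-out
split, returning the weights at the best held-out loss.  Everything is
float64 numpy and bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .autodiff import Tensor, bce_with_logits, concat

__all__ = [
    "ModelConfig",
    "MultimodalData",
    "GRUEncoder",
    "Linear",
    "CometModel",
    "pretrain",
    "train_model",
    "transfer_and_finetune",
    "extract_latent",
    "parameter_checksum",
    "prepare_omics",
    "save_checkpoint",
    "load_checkpoint",
]

MODES = ("ehr_only", "omics_only", "joint", "comet")

# hyperparameter grids of the original tuning protocol
LEARNING_RATE_GRID = (1e-1, 1e-2, 1e-3, 1e-4)
DROPOUT_GRID = (0.1, 0.2, 0.3, 0.4, 0.5)
LR_DECAY_GRID = (1e-1, 1e-2, 1e-3, 1e-4)
LAYERS_GRID = (2, 4)
HIDDEN_DIM_GRID = (400, 800)
BATCH_SIZE_PRETRAIN = 512
BATCH_SIZE_OMICS = 16


@dataclass
class ModelConfig:
    mode: str
    layers: int = 2
    hidden_dim: int = 400
    dropout: float = 0.1
    learning_rate: float = 1e-2
    lr_decay: float = 1e-2
    batch_size: int = BATCH_SIZE_OMICS
    max_epochs: int = 100
    patience: int = 5
    weight_decay: float = 0.0  # L2 penalty on trainable parameters
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.batch_size <= 0:
            raise ValueError("batch_size must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.layers < 1 or self.hidden_dim < 1:
            raise ValueError("layers and hidden_dim must be >= 1")


@dataclass
class MultimodalData:
    """Aligned per-patient arrays consumed by the trainer.

    ``omics`` is the standardized (log2, median-normalized, per-protein
    z-scored) protein matrix; either block may be None for single-modality
    variants.
    """

    sequences: np.ndarray | None  # (N, T, D)
    masks: np.ndarray | None  # (N, T) bool
    omics: np.ndarray | None  # (N, P)
    labels: np.ndarray  # (N,) in {0, 1}

    @property
    def n(self) -> int:
        return len(self.labels)

    def subset(self, idx) -> "MultimodalData":
        return MultimodalData(
            sequences=None if self.sequences is None else self.sequences[idx],
            masks=None if self.masks is None else self.masks[idx],
            omics=None if self.omics is None else self.omics[idx],
            labels=self.labels[idx],
        )


class Linear:
    """Affine map with parameters registered under a name prefix."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        k = 1.0 / np.sqrt(in_dim)
        self.weight = Tensor(rng.uniform(-k, k, size=(in_dim, out_dim)), requires_grad=True)
        self.bias = Tensor(rng.uniform(-k, k, size=(out_dim,)), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out

    def parameters(self, prefix: str) -> dict[str, Tensor]:
        params = {f"{prefix}.weight": self.weight}
        if self.bias is not None:
            params[f"{prefix}.bias"] = self.bias
        return params


class GRUEncoder:
    """Stacked GRU over (batch, time, dim) with a boolean validity mask.

    Gate order follows the common (reset, update, candidate) convention.
    Padded timesteps carry the previous hidden state through unchanged, so
    with left-sided padding the final state is the state after the most
    recent real day.  Dropout (training only) is applied to the outputs of
    every layer except the last, with one mask per layer per forward pass.
    """

    def __init__(self, input_dim: int, hidden_dim: int, layers: int, dropout: float,
                 rng: np.random.Generator):
        self.input_dim = input_dim
        self.hidden_dim = hidden_dim
        self.layers = layers
        self.dropout = dropout
        k = 1.0 / np.sqrt(hidden_dim)
        self.w_ih, self.w_hh, self.b_ih, self.b_hh = [], [], [], []
        for layer in range(layers):
            d_in = input_dim if layer == 0 else hidden_dim
            self.w_ih.append(Tensor(rng.uniform(-k, k, (d_in, 3 * hidden_dim)), requires_grad=True))
            self.w_hh.append(Tensor(rng.uniform(-k, k, (hidden_dim, 3 * hidden_dim)), requires_grad=True))
            self.b_ih.append(Tensor(rng.uniform(-k, k, (3 * hidden_dim,)), requires_grad=True))
            self.b_hh.append(Tensor(rng.uniform(-k, k, (3 * hidden_dim,)), requires_grad=True))

    def parameters(self, prefix: str = "encoder") -> dict[str, Tensor]:
        params = {}
        for layer in range(self.layers):
            params[f"{prefix}.l{layer}.w_ih"] = self.w_ih[layer]
            params[f"{prefix}.l{layer}.w_hh"] = self.w_hh[layer]
            params[f"{prefix}.l{layer}.b_ih"] = self.b_ih[layer]
            params[f"{prefix}.l{layer}.b_hh"] = self.b_hh[layer]
        return params

    def forward(self, x, mask: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        B, T, _ = x.data.shape
        H = self.hidden_dim
        mask = np.asarray(mask, dtype=np.float64).reshape(B, T, 1)
        drop_masks = []
        if train and self.dropout > 0 and self.layers > 1:
            if rng is None:
                raise ValueError("training forward with dropout requires an rng")
            keep = 1.0 - self.dropout
            drop_masks = [
                (rng.random((B, H)) < keep).astype(np.float64) / keep
                for _ in range(self.layers - 1)
            ]
        layer_input_rows = None  # list of (B, d_in) tensors after first layer
        h = None
        for layer in range(self.layers):
            h = Tensor(np.zeros((B, H)))
            outputs = []
            for t in range(T):
                x_t = x[:, t, :] if layer == 0 else layer_input_rows[t]
                gi = x_t @ self.w_ih[layer] + self.b_ih[layer]
                gh = h @ self.w_hh[layer] + self.b_hh[layer]
                r = (gi[:, :H] + gh[:, :H]).sigmoid()
                z = (gi[:, H : 2 * H] + gh[:, H : 2 * H]).sigmoid()
                n = (gi[:, 2 * H :] + r * gh[:, 2 * H :]).tanh()
                h_new = (1.0 - z) * n + z * h
                m_t = mask[:, t]
                h = m_t * h_new + (1.0 - m_t) * h
                if layer < self.layers - 1:
                    out_t = h
                    if drop_masks:
                        out_t = out_t * drop_masks[layer]
                    outputs.append(out_t)
            layer_input_rows = outputs
        return h


class CometModel:
    """The four-variant multimodal classifier.

    ``frozen`` names parameter groups excluded from gradient updates; in
    ``comet`` mode the encoder group is frozen after transfer.
    """

    def __init__(self, config: ModelConfig, input_dim: int | None, n_proteins: int | None):
        self.config = config
        self.mode = config.mode
        rng = np.random.default_rng(config.seed)
        self.uses_ehr = self.mode in ("ehr_only", "joint", "comet")
        self.uses_omics = self.mode in ("omics_only", "joint", "comet")
        self.n_proteins = n_proteins
        self.encoder = None
        self.ehr_head = None
        self.omics_head = None
        self.joint_head = None
        if self.uses_ehr:
            if input_dim is None:
                raise ValueError("EHR modes require input_dim")
            self.encoder = GRUEncoder(
                input_dim, config.hidden_dim, config.layers, config.dropout, rng
            )
            self.ehr_head = Linear(config.hidden_dim, 1, rng)
        if self.uses_omics:
            if n_proteins is None:
                raise ValueError("omics modes require n_proteins")
            self.omics_head = Linear(n_proteins, 1, rng)
        if self.uses_ehr and self.uses_omics:
            self.joint_head = Linear(config.hidden_dim + n_proteins, 1, rng)
        n_components = (1 if self.uses_ehr else 0) + (1 if self.uses_omics else 0)
        if n_components == 2:
            n_components = 3  # ehr, omics, joint
        # bias-free combiner: exactly one weight per active component
        k = 1.0 / np.sqrt(n_components)
        self.combiner = Tensor(rng.uniform(-k, k, size=(n_components, 1)), requires_grad=True)
        self.frozen: set[str] = set()

    # -- parameter registry ---------------------------------------------

    def parameters(self) -> dict[str, Tensor]:
        params: dict[str, Tensor] = {"combiner.weight": self.combiner}
        if self.encoder is not None:
            params.update(self.encoder.parameters("encoder"))
        if self.ehr_head is not None:
            params.update(self.ehr_head.parameters("ehr_head"))
        if self.omics_head is not None:
            params.update(self.omics_head.parameters("omics_head"))
        if self.joint_head is not None:
            params.update(self.joint_head.parameters("joint_head"))
        return params

    def trainable_parameters(self) -> dict[str, Tensor]:
        return {
            name: p
            for name, p in self.parameters().items()
            if not any(name.startswith(group) for group in self.frozen)
        }

    # -- forward ---------------------------------------------------------

    def combined_logit(self, sequences=None, masks=None, omics=None,
                       train: bool = False, rng: np.random.Generator | None = None):
        """Graph-building forward pass; returns (logit Tensor, parts, latent)."""
        logits: list[Tensor] = []
        parts: dict[str, Tensor] = {}
        latent = None
        if self.uses_ehr:
            if sequences is None or masks is None:
                raise ValueError(f"mode {self.mode} requires a sequence input")
            latent = self.encoder.forward(sequences, masks, train=train, rng=rng)
            parts["ehr"] = self.ehr_head(latent)
            logits.append(parts["ehr"])
        if self.uses_omics:
            if omics is None:
                raise ValueError(f"mode {self.mode} requires an omics input")
            om = omics if isinstance(omics, Tensor) else Tensor(omics)
            if om.data.ndim != 2 or om.data.shape[1] != self.n_proteins:
                raise ValueError(
                    f"omics input has shape {om.data.shape}, expected (*, {self.n_proteins})"
                )
            parts["omics"] = self.omics_head(om)
            logits.append(parts["omics"])
            if self.uses_ehr:
                parts["joint"] = self.joint_head(concat([latent, om], axis=1))
                logits.append(parts["joint"])
        combined = concat(logits, axis=1) @ self.combiner
        return combined, parts, latent

    def forward(self, sequences=None, masks=None, omics=None):
        """Evaluation-mode forward: (probabilities, component logits, latents)."""
        combined, parts, latent = self.combined_logit(sequences, masks, omics, train=False)
        prob = 1.0 / (1.0 + np.exp(-combined.data[:, 0]))
        part_values = {k: v.data[:, 0].copy() for k, v in parts.items()}
        return prob, part_values, None if latent is None else latent.data.copy()

    def predict_proba(self, data: MultimodalData) -> np.ndarray:
        prob, _, _ = self.forward(data.sequences, data.masks, data.omics)
        return prob

    # -- state -----------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if set(state) != set(params):
            missing = set(params) ^ set(state)
            raise ValueError(f"state dict mismatch: {sorted(missing)}")
        for name, value in state.items():
            if params[name].data.shape != value.shape:
                raise ValueError(
                    f"shape mismatch for {name}: {value.shape} vs {params[name].data.shape}"
                )
            params[name].data = value.copy()


def parameter_checksum(model: CometModel, group: str | None = None) -> str:
    """SHA-256 over the named parameter group (or all parameters)."""
    digest = hashlib.sha256()
    for name in sorted(model.parameters()):
        if group is not None and not name.startswith(group):
            continue
        digest.update(name.encode())
        digest.update(np.ascontiguousarray(model.parameters()[name].data).tobytes())
    return digest.hexdigest()


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _batch_loss(model: CometModel, data: MultimodalData, idx: np.ndarray,
                train: bool, rng: np.random.Generator | None):
    sub = data.subset(idx)
    combined, _, _ = model.combined_logit(
        sub.sequences, sub.masks, sub.omics, train=train, rng=rng
    )
    return bce_with_logits(combined, sub.labels.reshape(-1, 1))


def evaluate_loss(model: CometModel, data: MultimodalData, idx: np.ndarray | None = None) -> float:
    idx = np.arange(data.n) if idx is None else np.asarray(idx)
    return float(_batch_loss(model, data, idx, train=False, rng=None).data)


def train_model(
    model: CometModel,
    data: MultimodalData,
    train_idx: np.ndarray,
    stop_idx: np.ndarray,
    config: ModelConfig | None = None,
) -> list[dict]:
    """SGD with per-epoch multiplicative lr decay and patience-5 early stop.

    ``stop_idx`` is the held-out split monitored for early stopping; the
    weights at the best held-out loss are restored before returning.
    Returns the per-epoch history (train loss, held-out loss, stop reason).
    """
    config = config or model.config
    if len(np.unique(data.labels[train_idx])) < 2:
        raise ValueError("training labels contain a single class")
    rng = np.random.default_rng(config.seed)
    lr = config.learning_rate
    best_loss = np.inf
    best_state = model.state_dict()
    best_epoch = -1
    history: list[dict] = []
    trainable = model.trainable_parameters()
    train_idx = np.asarray(train_idx)
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train_idx))
        epoch_losses = []
        for start in range(0, len(train_idx), config.batch_size):
            batch = train_idx[order[start : start + config.batch_size]]
            loss = _batch_loss(model, data, batch, train=True, rng=rng)
            loss.backward()
            for p in trainable.values():
                if p.grad is not None:
                    step = p.grad
                    if config.weight_decay:
                        step = step + config.weight_decay * p.data
                    p.data = p.data - lr * step
                    p.grad = None
            for p in model.parameters().values():
                p.grad = None
            epoch_losses.append(float(loss.data))
        held_loss = evaluate_loss(model, data, stop_idx)
        record = {
            "epoch": epoch,
            "train_loss": float(np.mean(epoch_losses)),
            "held_out_loss": held_loss,
            "stop": "",
        }
        history.append(record)
        if held_loss < best_loss:
            best_loss = held_loss
            best_state = model.state_dict()
            best_epoch = epoch
        elif epoch - best_epoch >= config.patience:
            record["stop"] = f"early stop: no improvement for {config.patience} epochs"
            break
        lr *= 1.0 - config.lr_decay
    model.load_state_dict(best_state)
    return history


def pretrain(
    config: ModelConfig,
    sequences: np.ndarray,
    masks: np.ndarray,
    labels: np.ndarray,
    holdout_frac: float = 0.2,
) -> tuple[CometModel, list[dict]]:
    """Train the EHR-only model on the large pretraining cohort.

    A ``holdout_frac`` stratified split is reserved for early stopping.
    """
    if config.mode != "ehr_only":
        raise ValueError("pretraining uses mode='ehr_only'")
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("pretraining labels contain a single class")
    data = MultimodalData(sequences=sequences, masks=masks, omics=None, labels=labels)
    rng = np.random.default_rng(config.seed)
    holdout = _stratified_fraction(labels, holdout_frac, rng)
    train_idx = np.setdiff1d(np.arange(data.n), holdout)
    model = CometModel(config, input_dim=sequences.shape[2], n_proteins=None)
    history = train_model(model, data, train_idx, holdout, config)
    return model, history


def _stratified_fraction(labels: np.ndarray, frac: float, rng: np.random.Generator) -> np.ndarray:
    picked = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        k = max(1, int(round(frac * len(idx))))
        picked.append(rng.choice(idx, size=k, replace=False))
    return np.sort(np.concatenate(picked))


def transfer_and_finetune(
    pretrained: CometModel,
    data: MultimodalData,
    config: ModelConfig,
    train_idx: np.ndarray | None = None,
    stop_idx: np.ndarray | None = None,
) -> tuple[CometModel, list[dict]]:
    """Build the transfer-learning variant: frozen pretrained encoder.

    Layers, hidden dimension, and dropout are fixed to the pretraining
    optima; learning rate and decay come from ``config`` (re-optimized by
    the caller's grid search).  The encoder weights are copied and frozen;
    all heads and the combiner are trained on the multimodal cohort.
    """
    if pretrained.encoder is None:
        raise ValueError("pretrained model has no encoder to transfer")
    if config.mode != "comet":
        raise ValueError("transfer_and_finetune builds mode='comet'")
    pre_cfg = pretrained.config
    if (config.hidden_dim, config.layers) != (pre_cfg.hidden_dim, pre_cfg.layers):
        raise ValueError(
            f"encoder geometry mismatch: pretrained (hidden={pre_cfg.hidden_dim}, "
            f"layers={pre_cfg.layers}) vs config (hidden={config.hidden_dim}, "
            f"layers={config.layers})"
        )
    if data.sequences is None or data.sequences.shape[2] != pretrained.encoder.input_dim:
        raise ValueError("sequence input dimension does not match pretrained encoder")
    config = replace(config, dropout=pre_cfg.dropout)
    model = CometModel(config, input_dim=pretrained.encoder.input_dim,
                       n_proteins=data.omics.shape[1])
    # copy encoder weights, then freeze the group
    pre_params = pretrained.encoder.parameters("encoder")
    own_params = model.encoder.parameters("encoder")
    for name, p in own_params.items():
        p.data = pre_params[name].data.copy()
    model.frozen.add("encoder")
    if train_idx is None or stop_idx is None:
        rng = np.random.default_rng(config.seed)
        stop_idx = _stratified_fraction(data.labels, 0.2, rng)
        train_idx = np.setdiff1d(np.arange(data.n), stop_idx)
    history = train_model(model, data, train_idx, stop_idx, config)
    return model, history


def extract_latent(model: CometModel, sequences: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """The EHR latent representation (encoder final state) per patient."""
    if model.encoder is None:
        raise ValueError(f"mode {model.mode} has no EHR encoder")
    return model.encoder.forward(sequences, masks, train=False).data.copy()


# ---------------------------------------------------------------------------
# Omics preprocessing and checkpoints
# ---------------------------------------------------------------------------


def prepare_omics(values, log2: bool = True) -> np.ndarray:
    """Standardize a positive intensity matrix for the network:
    log2 transform, median normalization across samples, per-protein
    z-score.  Constant proteins standardize to zero."""
    from .biostats import median_normalize  # local import to avoid cycle

    arr = np.asarray(values, dtype=np.float64)
    if np.any(arr <= 0):
        raise ValueError("omics intensities must be strictly positive")
    arr = median_normalize(arr)
    if log2:
        arr = np.log2(arr)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (arr - mean) / sd


def save_checkpoint(model: CometModel, path: str | Path) -> None:
    """Serialized weights plus a JSON sidecar (config, frozen groups,
    per-group checksums)."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.state_dict())
    sidecar = {
        "config": {k: getattr(model.config, k) for k in (
            "mode", "layers", "hidden_dim", "dropout", "learning_rate",
            "lr_decay", "batch_size", "max_epochs", "patience",
            "weight_decay", "seed")},
        "input_dim": None if model.encoder is None else model.encoder.input_dim,
        "n_proteins": model.n_proteins,
        "frozen": sorted(model.frozen),
        "checksums": {
            "all": parameter_checksum(model),
            "encoder": parameter_checksum(model, "encoder") if model.encoder else None,
        },
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_checkpoint(path: str | Path) -> CometModel:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    config = ModelConfig(**sidecar["config"])
    model = CometModel(config, input_dim=sidecar["input_dim"], n_proteins=sidecar["n_proteins"])
    with np.load(path.with_suffix(".npz")) as archive:
        model.load_state_dict({k: archive[k] for k in archive.files})
    model.frozen = set(sidecar["frozen"])
    if parameter_checksum(model) != sidecar["checksums"]["all"]:
        raise ValueError(f"checkpoint {path}: checksum mismatch after load")
    return model
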