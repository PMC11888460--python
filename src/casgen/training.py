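"""Seeded end-to-end training of the autoencoder and classifier.

The optimizer is Adam with global gradient-norm clipping (default 1.0, which
also counters the unbounded inter-class term of the margin loss).  Batches
are stratified by default so every batch contains both classes whenever the
margin weight gamma is positive — the intra/inter distance terms are
degenerate on single-class batches.  The train/validation split is 80/20,
stratified, and derived from the training seed, so two runs with identical
seeds and configs produce bit-identical histories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import silhouette_score

from .autodiff import Tensor, softmax
from .losses import (
    LossBreakdown,
    LossWeights,
    MarginWeights,
    class_weights_from_counts,
    classification_loss,
    inter_class_distance,
    intra_class_distance,
    margin_loss,
    reconstruction_loss,
    total_loss,
)
from .model_core import CasGenModel, ModelConfig
from .sequence_io import ProteinRecord, tokenize_records

__all__ = [
    "TrainingConfig",
    "EpochRecord",
    "TrainingHistory",
    "LatentSeparation",
    "train_model",
    "evaluate_latent_separation",
]


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    gradient_clip_norm: float = 1.0
    stratified_batching: bool = True
    validation_fraction: float = 0.2
    class_weighting: bool = True
    loss_weights: LossWeights = field(default_factory=LossWeights)
    margin_weights: MarginWeights = field(default_factory=MarginWeights)
    early_stopping_patience: int | None = None  # None: run all epochs (deterministic)
    rng_seed: int = 0

    def __post_init__(self):
        if self.loss_weights.gamma > 0 and self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 when the margin weight gamma > 0")


@dataclass(frozen=True)
class EpochRecord:
    train: LossBreakdown
    validation: LossBreakdown
    val_accuracy: float
    val_silhouette: float


@dataclass
class TrainingHistory:
    epochs: list[EpochRecord] = field(default_factory=list)

    def to_rows(self) -> list[dict]:
        rows = []
        for i, e in enumerate(self.epochs):
            rows.append(
                {
                    "epoch": i,
                    "train_recon": e.train.recon,
                    "train_ce": e.train.classification,
                    "train_margin": e.train.margin,
                    "train_total": e.train.total,
                    "val_recon": e.validation.recon,
                    "val_ce": e.validation.classification,
                    "val_margin": e.validation.margin,
                    "val_total": e.validation.total,
                    "val_accuracy": e.val_accuracy,
                    "val_silhouette": e.val_silhouette,
                }
            )
        return rows


@dataclass(frozen=True)
class LatentSeparation:
    silhouette: float
    d_cas: float
    d_noncas: float
    d_inter: float


def evaluate_latent_separation(latents, labels) -> LatentSeparation:
    """Silhouette score (Euclidean) plus the three margin-loss distance terms."""
    latents = np.asarray(latents, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    cas, non = latents[labels == 1], latents[labels == 0]
    if len(cas) < 2 or len(non) < 2:
        raise ValueError("need at least 2 samples of each class")
    return LatentSeparation(
        silhouette=float(silhouette_score(latents, labels, metric="euclidean")),
        d_cas=intra_class_distance(cas),
        d_noncas=intra_class_distance(non),
        d_inter=inter_class_distance(cas, non),
    )


class _Adam:
    def __init__(self, params: dict[str, Tensor], lr: float, clip_norm: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.clip = lr, clip_norm
        self.b1, self.b2, self.eps = betas[0], betas[1], eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        grads = {k: (p.grad if p.grad is not None else np.zeros_like(p.data))
                 for k, p in self.params.items()}
        norm = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
        scale = min(1.0, self.clip / norm) if norm > 0 else 1.0
        self.t += 1
        for k, p in self.params.items():
            g = grads[k] * scale
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            p.grad = None


def _stratified_split(labels: np.ndarray, frac: float, rng: np.random.Generator):
    if frac == 0.0:
        # no holdout: validation metrics are computed on the training split
        idx = np.arange(len(labels))
        return idx, idx
    train_idx, val_idx = [], []
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(len(idx))]
        n_val = max(1, int(round(frac * len(idx))))
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.sort(np.array(train_idx)), np.sort(np.array(val_idx))


def _stratified_batches(labels: np.ndarray, batch_size: int, rng: np.random.Generator):
    """Yield index batches, each containing at least one sample per class.

    Class positions are shuffled, then interleaved in proportion to class
    frequency so consecutive windows mix classes.
    """
    order = []
    per_class = {}
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        per_class[cls] = list(idx[rng.permutation(len(idx))])
    n = len(labels)
    counts = {cls: len(per_class[cls]) for cls in per_class}
    # proportional interleave by largest-remainder scheduling
    taken = {cls: 0 for cls in per_class}
    for i in range(n):
        best = max(per_class, key=lambda c: counts[c] * (i + 1) / n - taken[c]
                   if per_class[c] else -np.inf)
        order.append(per_class[best].pop(0))
        taken[best] += 1
    batches = [np.array(order[i : i + batch_size]) for i in range(0, n, batch_size)]
    # fold a trailing single-class remainder into the previous batch
    if len(batches) > 1 and len(set(labels[batches[-1]])) < 2:
        batches[-2] = np.concatenate([batches[-2], batches[-1]])
        batches.pop()
    return batches


def _batch_losses(model: CasGenModel, tokens: np.ndarray, labels: np.ndarray,
                  config: TrainingConfig, class_weights, train: bool):
    """Forward pass returning (total Tensor, LossBreakdown)."""
    latents = model._encode_tensor(tokens, train=train)
    probs = softmax(model._classify_tensor(latents), axis=-1)
    logits = model._decode_tensor(latents, train=train)
    l_recon = reconstruction_loss(tokens, logits, mask_padding=True)
    l_ce = classification_loss(probs, labels, class_weights=class_weights)
    if config.loss_weights.gamma > 0:
        l_margin = margin_loss(latents, labels, config.margin_weights)
    else:
        l_margin = Tensor(0.0)
    total = total_loss(l_recon, l_ce, l_margin, config.loss_weights)
    breakdown = total_loss(float(l_recon.data), float(l_ce.data), float(l_margin.data),
                           config.loss_weights)
    return total, breakdown


def _mean_breakdown(parts: list[LossBreakdown], sizes: list[int]) -> LossBreakdown:
    w = np.array(sizes, dtype=np.float64)
    w /= w.sum()
    return LossBreakdown(
        recon=float(sum(p.recon * wi for p, wi in zip(parts, w))),
        classification=float(sum(p.classification * wi for p, wi in zip(parts, w))),
        margin=float(sum(p.margin * wi for p, wi in zip(parts, w))),
        total=float(sum(p.total * wi for p, wi in zip(parts, w))),
    )


def train_model(
    records: list[ProteinRecord],
    labels: dict[str, int] | np.ndarray,
    model_config: ModelConfig,
    training_config: TrainingConfig = TrainingConfig(),
) -> tuple[CasGenModel, TrainingHistory]:
    """Train encoder, decoder, and classifier jointly under the total loss.

    ``labels`` maps record ids to classes (1 = Cas, 0 = non-Cas) or is an
    aligned integer array.  Returns the trained model and a per-epoch history
    of train/validation loss breakdowns, validation classifier accuracy, and
    validation latent silhouette.
    """
    if isinstance(labels, dict):
        y = np.array([labels[r.id] for r in records], dtype=np.int64)
    else:
        y = np.asarray(labels, dtype=np.int64)
    if len(y) != len(records):
        raise ValueError("labels must cover every record")
    if len(np.unique(y)) < 2 and training_config.loss_weights.gamma > 0:
        raise ValueError("margin loss requires both classes in the dataset")

    tokens = tokenize_records(records, model_config.max_len)
    rng = np.random.default_rng(training_config.rng_seed)
    train_idx, val_idx = _stratified_split(y, training_config.validation_fraction, rng)

    class_weights = None
    if training_config.class_weighting:
        counts = (int((y[train_idx] == 0).sum()), int((y[train_idx] == 1).sum()))
        class_weights = class_weights_from_counts(counts)

    model = CasGenModel(model_config)
    opt = _Adam(model.params, training_config.learning_rate, training_config.gradient_clip_norm)
    history = TrainingHistory()
    best_val, patience_left = np.inf, training_config.early_stopping_patience

    for epoch in range(training_config.epochs):
        epoch_rng = np.random.default_rng(
            (training_config.rng_seed * 100003 + epoch) % (2**31)
        )
        if training_config.stratified_batching:
            batches = _stratified_batches(y[train_idx], training_config.batch_size, epoch_rng)
            batches = [train_idx[b] for b in batches]
        else:
            perm = train_idx[epoch_rng.permutation(len(train_idx))]
            batches = [perm[i : i + training_config.batch_size]
                       for i in range(0, len(perm), training_config.batch_size)]

        train_parts, train_sizes = [], []
        for batch in batches:
            total, breakdown = _batch_losses(
                model, tokens[batch], y[batch], training_config, class_weights, train=True
            )
            total.backward()
            opt.step()
            train_parts.append(breakdown)
            train_sizes.append(len(batch))

        # validation diagnostics in eval mode
        _, val_breakdown = _batch_losses(
            model, tokens[val_idx], y[val_idx], training_config, class_weights, train=False
        )
        val_latents = model.encode_to_latent(tokens[val_idx])
        val_probs = model.classify_latent(val_latents)
        val_acc = float(np.mean((val_probs[:, 1] >= 0.5) == (y[val_idx] == 1)))
        if len(val_idx) >= 3 and len(np.unique(y[val_idx])) == 2:
            val_sil = float(silhouette_score(val_latents, y[val_idx], metric="euclidean"))
        else:  # silhouette undefined for fewer samples than labels + 1
            val_sil = float("nan")
        history.epochs.append(
            EpochRecord(
                train=_mean_breakdown(train_parts, train_sizes),
                validation=val_breakdown,
                val_accuracy=val_acc,
                val_silhouette=val_sil,
            )
        )
        if patience_left is not None:
            if val_breakdown.total < best_val - 1e-12:
                best_val, patience_left = val_breakdown.total, training_config.early_stopping_patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break
    return model, history
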