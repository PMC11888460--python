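"""Training objectives: classification, margin, reconstruction, and total loss.

The latent space is shaped by three terms.  A class-weighted cross-entropy on
the classifier output separates Cas from non-Cas embeddings; a margin loss

    L_margin = w_cas * d_cas + w_noncas * d_noncas - w_inter * d_inter

rewards intra-class compactness (mean squared distance over unordered
same-class pairs) and penalizes inter-class proximity (mean squared distance
over cross-class pairs); and a per-position cross-entropy on decoder output
drives sequence reconstruction.  The total objective is the weighted sum

    L_total = alpha * L_recon + beta * L_ce + gamma * L_margin.

All functions accept either plain NumPy arrays (returning a float) or
:class:`~casgen.autodiff.Tensor` inputs (returning a Tensor on the tape), so
the training loop differentiates the same code these public wrappers expose.

Pairwise-distance sums use the identity
``sum_ij ||x_i - y_j||^2 = m2 * sum_i ||x_i||^2 + m1 * sum_j ||y_j||^2
- 2 <sum_i x_i, sum_j y_j>``, which avoids materializing the pair grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, softmax

logger = logging.getLogger(__name__)

PROB_FLOOR = 1e-12  # clamp for log arguments


@dataclass(frozen=True)
class MarginWeights:
    """Weights of the margin-loss terms: Cas compactness, non-Cas compactness,
    inter-class separation."""

    w_cas: float = 1.0
    w_noncas: float = 1.0
    w_inter: float = 1.0

    def __post_init__(self):
        if min(self.w_cas, self.w_noncas, self.w_inter) < 0:
            raise ValueError("margin weights must be nonnegative")


@dataclass(frozen=True)
class LossWeights:
    """Coefficients of the total loss: alpha (reconstruction), beta
    (classification), gamma (margin)."""

    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0

    def __post_init__(self):
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("loss weights must be nonnegative")


@dataclass(frozen=True)
class LossBreakdown:
    """The three loss components and their weighted total for one batch."""

    recon: float
    classification: float
    margin: float
    total: float


def _maybe_float(x: Tensor, tensor_in: bool):
    return x if tensor_in else float(x.data)


def classification_loss(probabilities, labels, class_weights=None):
    """Mean negative log-probability of the true class.

    ``probabilities`` is ``(n, 2)`` with columns ordered (non-Cas, Cas) so the
    column index equals the class label.  With ``class_weights = (w0, w1)``
    each sample's term is multiplied by the weight of its true class and the
    sum is normalized by the total applied weight, so balanced weights reduce
    to the plain mean.
    """
    tensor_in = isinstance(probabilities, Tensor)
    probs = as_tensor(probabilities)
    labels = np.asarray(labels, dtype=np.int64)
    n = labels.shape[0]
    if n < 1:
        raise ValueError("need at least one sample")
    true_p = probs[np.arange(n), labels]
    if np.any(true_p.data <= PROB_FLOOR):
        logger.warning("true-class probability at or below %.0e clamped", PROB_FLOOR)
    neg_log = -(true_p.clip_min(PROB_FLOOR).log())
    if class_weights is None:
        loss = neg_log.mean()
    else:
        w = np.asarray(class_weights, dtype=np.float64)[labels]
        loss = (neg_log * Tensor(w)).sum() / float(w.sum())
    return _maybe_float(loss, tensor_in)


def class_weights_from_counts(counts) -> tuple[float, ...]:
    """Inverse-class-frequency weights: ``w_j = n_total / (K * n_j)``.

    Balanced counts give unit weights; the weights are invariant to scaling
    all counts by a constant.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if np.any(counts < 1):
        raise ValueError("all class counts must be >= 1")
    weights = counts.sum() / (len(counts) * counts)
    return tuple(float(w) for w in weights)


def intra_class_distance(latents):
    """Mean squared Euclidean distance over unordered same-class pairs.

    Defined as 0 for fewer than two points (no pairs exist).
    """
    tensor_in = isinstance(latents, Tensor)
    x = as_tensor(latents)
    m = x.shape[0]
    if m < 2:
        return Tensor(0.0) if tensor_in else 0.0
    sq = (x * x).sum()  # sum_i ||x_i||^2
    s = x.sum(axis=0)  # sum_i x_i
    # sum over ordered pairs = 2*m*sq - 2*||s||^2; mean over the m(m-1)/2
    # unordered pairs is that divided by m(m-1)
    loss = (m * sq - (s * s).sum()) * (2.0 / (m * (m - 1)))
    return _maybe_float(loss, tensor_in)


def inter_class_distance(cas_latents, noncas_latents):
    """Mean squared Euclidean distance over all cross-class pairs."""
    tensor_in = isinstance(cas_latents, Tensor) or isinstance(noncas_latents, Tensor)
    a, b = as_tensor(cas_latents), as_tensor(noncas_latents)
    m1, m2 = a.shape[0], b.shape[0]
    if m1 < 1 or m2 < 1:
        raise ValueError("both classes must be nonempty")
    if a.shape[1] != b.shape[1]:
        raise ValueError("latent dimensions differ between classes")
    qa, qb = (a * a).sum(), (b * b).sum()
    sa, sb = a.sum(axis=0), b.sum(axis=0)
    total = m2 * qa + m1 * qb - 2.0 * (sa * sb).sum()
    return _maybe_float(total / (m1 * m2), tensor_in)


def margin_loss(latents, labels, weights: MarginWeights = MarginWeights()):
    """Weighted margin loss over a labeled batch of latent vectors.

    If either class is absent from the batch the inter-class term is 0 and a
    warning is logged; the present class still contributes its compactness
    term.  Note the loss is unbounded below through the ``-w_inter * d_inter``
    term; training relies on gradient clipping (see
    :class:`casgen.training.TrainingConfig`).
    """
    tensor_in = isinstance(latents, Tensor)
    x = as_tensor(latents)
    labels = np.asarray(labels, dtype=np.int64)
    if labels.shape[0] == 0:
        raise ValueError("batch must be nonempty")
    cas_idx = np.flatnonzero(labels == 1)
    non_idx = np.flatnonzero(labels == 0)
    d_cas = intra_class_distance(x[cas_idx]) if cas_idx.size else Tensor(0.0)
    d_non = intra_class_distance(x[non_idx]) if non_idx.size else Tensor(0.0)
    if cas_idx.size and non_idx.size:
        d_inter = inter_class_distance(x[cas_idx], x[non_idx])
    else:
        logger.warning("single-class batch: inter-class term set to 0")
        d_inter = Tensor(0.0)
    loss = (
        weights.w_cas * as_tensor(d_cas)
        + weights.w_noncas * as_tensor(d_non)
        - weights.w_inter * as_tensor(d_inter)
    )
    return _maybe_float(loss, tensor_in)


def reconstruction_loss(token_targets, token_predictions, mask_padding: bool = True,
                        from_logits: bool = True):
    """Mean per-position negative log-probability of the true token.

    ``token_targets`` is ``(n, T)`` integer codes and ``token_predictions`` is
    ``(n, T, 24)``.  With ``from_logits`` (the default) prediction rows are
    softmax-normalized before the log; pass ``False`` when rows already are
    probabilities.  With ``mask_padding`` on, positions after the end token
    are excluded from the mean, so the decoder is not rewarded for predicting
    padding; switch it off to average over all ``n * T`` positions.
    """
    tensor_in = isinstance(token_predictions, Tensor)
    targets = np.asarray(token_targets, dtype=np.int64)
    preds = as_tensor(token_predictions)
    if targets.ndim == 1:
        targets = targets[None, :]
    if preds.ndim == 2:
        preds = preds.reshape(1, *preds.shape)
    n, t = targets.shape
    probs = softmax(preds, axis=-1) if from_logits else preds
    ii, tt = np.meshgrid(np.arange(n), np.arange(t), indexing="ij")
    true_p = probs[ii, tt, targets]
    if np.any(true_p.data <= PROB_FLOOR):
        logger.warning("true-token probability at or below %.0e clamped", PROB_FLOOR)
    neg_log = -(true_p.clip_min(PROB_FLOOR).log())
    if mask_padding:
        # count start..end inclusive; pads (code 0 after the end token) excluded
        from .sequence_io import PAD

        counted = targets != PAD
        loss = (neg_log * Tensor(counted.astype(np.float64))).sum() / float(counted.sum())
    else:
        loss = neg_log.mean()
    return _maybe_float(loss, tensor_in)


def total_loss(recon, classification, margin, weights: LossWeights = LossWeights()):
    """Combine the three components into the weighted total.

    Returns a :class:`LossBreakdown` when given floats; a Tensor (the total
    only) when any component is on the autodiff tape.
    """
    if any(isinstance(c, Tensor) for c in (recon, classification, margin)):
        return (
            weights.alpha * as_tensor(recon)
            + weights.beta * as_tensor(classification)
            + weights.gamma * as_tensor(margin)
        )
    total = weights.alpha * recon + weights.beta * classification + weights.gamma * margin
    return LossBreakdown(recon=float(recon), classification=float(classification),
                         margin=float(margin), total=float(total))
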