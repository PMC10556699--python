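"""Supervised and contrastive loss functions.

The training objective has two parts:

* the supervised branch minimises pixel-wise cross-entropy between predicted
  class probabilities and ground-truth masks;
* the unsupervised branch minimises ``L_cl = L_ce + lambda * L_dc`` on two
  augmented views of the same unlabeled image, where ``L_ce`` is a
  confidence-gated cross-view pseudo-label cross-entropy and ``L_dc`` is the
  pixel-wise *directional contrastive* (DC) loss.

The DC loss is an InfoNCE-style objective over per-pixel embeddings on the
overlap region of the two views. For an anchor embedding ``phi1`` and its
positive counterpart ``phi2`` (the same source pixel seen in the other view),
with a pool of negatives ``phi_n``::

    l = -(1/N) * sum_hw M_dpf * log[ r(phi1, phi2) /
                                     (r(phi1, phi2) + sum_n r(phi1, phi_n)) ]

where ``r(a, b) = exp(cos(a, b) / tau)`` and ``N`` is the number of overlap
grid locations. The loss is *directional*: the binary mask ``M_d`` selects
only pixels where the anchor view is less confident than the other view
(strict inequality), so the uncertain view is pulled toward the confident
one and never the reverse; ``M_dpf`` additionally zeroes pixels where the
confident view's probability does not exceed the threshold ``gamma``. The
full batch loss symmetrises over both directions and averages over the batch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .nn.tensor import Tensor, as_tensor

logger = logging.getLogger(__name__)

LOG_EPS = 1e-12


class ValidationError(ValueError):
    pass


@dataclass
class DCLossConfig:
    lambda_weight: float = 0.1
    temperature: float = 0.1
    confidence_threshold: float = 0.75
    negatives_per_anchor: int = 64

    def __post_init__(self):
        if not 0.0 <= self.lambda_weight <= 1.0:
            raise ValidationError("lambda_weight must be in [0, 1]")
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive")
        if not 0.0 <= self.confidence_threshold <= 1.0:
            raise ValidationError("confidence_threshold must be in [0, 1]")
        if self.negatives_per_anchor < 0:
            raise ValidationError("negatives_per_anchor must be >= 0")


@dataclass
class MaskPair:
    """Directional mask M_d and its confidence-filtered form M_dpf."""
    directional: np.ndarray
    filtered: np.ndarray

    def __post_init__(self):
        self.directional = np.asarray(self.directional)
        self.filtered = np.asarray(self.filtered)
        if np.any(self.filtered > self.directional):
            raise ValidationError("filtered mask must be <= directional mask")


def _prob_array(p) -> np.ndarray:
    """Accept ProbabilityMap, Tensor or ndarray; return (K, h, w) ndarray."""
    if hasattr(p, "values"):
        p = p.values
    if isinstance(p, Tensor):
        p = p.data
    return np.asarray(p)


# ---------------------------------------------------------------------------
def cross_entropy(prob, target, valid_mask=None) -> Tensor:
    """Mean pixel-wise cross-entropy of probabilities against integer labels.

    ``prob`` is (K, H, W) or (N, K, H, W) class probabilities (already
    softmax-normalised); ``target`` an integer label array of matching
    spatial shape. ``valid_mask`` restricts the average to selected pixels
    (used for confidence gating of pseudo-labels); with no valid pixel the
    loss is 0. Logs are clamped at 1e-12.
    """
    prob = as_tensor(prob.values if hasattr(prob, "values") else prob)
    target = np.asarray(target)
    if prob.ndim == 3:
        prob = prob.reshape(1, *prob.shape)
    if target.ndim == 2:
        target = target[None]
    n, k, h, w = prob.shape
    if target.shape != (n, h, w):
        raise ValidationError(
            f"target shape {target.shape} does not match prob {prob.shape}")
    if target.min() < 0 or target.max() >= k:
        raise ValidationError(f"target labels must be in [0, {k})")
    onehot = np.zeros((n, k, h, w))
    np.put_along_axis(onehot, target[:, None], 1.0, axis=1)
    if valid_mask is not None:
        valid = np.asarray(valid_mask, dtype=np.float64)
        if valid.ndim == 2:
            valid = valid[None]
        onehot *= valid[:, None]
        denom = float(valid.sum())
        if denom == 0:
            return Tensor(0.0)
    else:
        denom = float(n * h * w)
    logp = prob.clip_min(LOG_EPS).log()
    return -(logp * Tensor(onehot)).sum() / denom


def similarity_kernel(a, b, temperature: float) -> float:
    """r(a, b) = exp(cos(a, b) / tau); zero vectors get cosine 0."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    cos = 0.0 if na == 0 or nb == 0 else float(a @ b / (na * nb))
    return float(np.exp(cos / temperature))


def directional_mask(prob1, prob2) -> np.ndarray:
    """1 where view1's max class probability is strictly below view2's."""
    p1, p2 = _prob_array(prob1), _prob_array(prob2)
    if p1.shape != p2.shape:
        raise ValidationError("probability maps must share a shape")
    return (p1.max(axis=0) < p2.max(axis=0)).astype(np.uint8)


def confidence_filter(directional, prob2, gamma: float) -> MaskPair:
    """Zero directional-mask pixels whose positive is not confident (> gamma)."""
    directional = np.asarray(directional, dtype=np.uint8)
    conf = _prob_array(prob2).max(axis=0)
    if conf.shape != directional.shape:
        raise ValidationError("mask / probability shape mismatch")
    filtered = (directional * (conf > gamma)).astype(np.uint8)
    return MaskPair(directional=directional, filtered=filtered)


def _flatten_embeddings(emb) -> Tensor:
    """(D, h, w) -> (h*w, D) rows; accepts EmbeddingMap / Tensor / ndarray."""
    if hasattr(emb, "values"):
        emb = emb.values
    emb = as_tensor(emb)
    d = emb.shape[0]
    return emb.reshape(d, -1).transpose(1, 0)


def _normalize_rows(rows: Tensor) -> Tensor:
    # the epsilon keeps the sqrt differentiable at zero; an all-zero row
    # normalises to the zero vector, i.e. cosine 0 against everything
    norm = ((rows * rows).sum(axis=-1, keepdims=True) + 1e-24) ** 0.5
    return rows / norm


def dc_loss_one_direction(emb1, emb2, mask, negatives,
                          config: DCLossConfig) -> Tensor:
    """One direction of the DC loss: anchors in view1, positives in view2.

    ``emb1``/``emb2``: (D, h, w) embeddings on the aligned overlap grid.
    ``mask``: a :class:`MaskPair` (its filtered mask is used) or a binary
    (h, w) array. ``negatives``: (M, D) shared pool or (h*w, M, D) per-anchor
    pool; ``None`` or empty means no negatives (the loss is then 0).
    The sum is divided by N = number of overlap-grid locations.
    """
    e1, e2 = _flatten_embeddings(emb1), _flatten_embeddings(emb2)
    n_loc = e1.shape[0]
    if n_loc == 0:
        logger.warning("dc_loss_one_direction: empty overlap grid, loss = 0")
        return Tensor(0.0)
    if e1.shape != e2.shape:
        raise ValidationError("embedding grids must share a shape")
    m = mask.filtered if isinstance(mask, MaskPair) else np.asarray(mask)
    m = m.reshape(-1).astype(np.float64)
    tau = config.temperature
    u1, u2 = _normalize_rows(e1), _normalize_rows(e2)
    r_pos = ((u1 * u2).sum(axis=1) / tau).exp()          # (P,)
    neg = None
    if isinstance(negatives, (list, tuple)):
        if len(negatives):
            neg = as_tensor(np.stack([np.asarray(v, dtype=np.float64)
                                      for v in negatives]))
    elif negatives is not None:
        neg = as_tensor(negatives)
        if 0 in neg.shape:
            neg = None
    if neg is None:
        denom = r_pos
    else:
        un = _normalize_rows(neg.reshape(-1, neg.shape[-1])).reshape(neg.shape)
        if un.ndim == 2:                                  # shared pool (M, D)
            cos_neg = u1 @ un.transpose(1, 0)             # (P, M)
        elif un.ndim == 3:                                # per-anchor (P, M, D)
            cos_neg = (u1.reshape(n_loc, 1, -1)
                       @ un.transpose(0, 2, 1)).reshape(n_loc, -1)
        else:
            raise ValidationError("negatives must be (M, D) or (P, M, D)")
        r_neg = (cos_neg / tau).exp()
        denom = r_pos + r_neg.sum(axis=1)
    ratio = (r_pos / denom).clip_min(LOG_EPS)
    return -(Tensor(m) * ratio.log()).sum() / n_loc


def dc_loss(pairs, negatives, config: DCLossConfig) -> Tensor:
    """Symmetrised batch DC loss.

    ``pairs`` is a sequence of ``(emb1, emb2, prob1, prob2)`` tuples aligned
    on the overlap grid; masks are recomputed in each direction. The two
    directional terms are summed per pair and averaged over the batch.
    ``negatives`` is a shared pool, or a per-pair sequence of
    ``(neg_for_view1_anchors, neg_for_view2_anchors)``.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValidationError("dc_loss requires at least one pair")
    gamma = config.confidence_threshold
    total = Tensor(0.0)
    for i, (emb1, emb2, prob1, prob2) in enumerate(pairs):
        if isinstance(negatives, (list, tuple)) and len(negatives) == len(pairs) \
                and isinstance(negatives[i], tuple):
            neg12, neg21 = negatives[i]
        else:
            neg12 = neg21 = negatives
        m12 = confidence_filter(directional_mask(prob1, prob2), prob2, gamma)
        m21 = confidence_filter(directional_mask(prob2, prob1), prob1, gamma)
        total = total + dc_loss_one_direction(emb1, emb2, m12, neg12, config)
        total = total + dc_loss_one_direction(emb2, emb1, m21, neg21, config)
    return total / len(pairs)


@dataclass
class UnsupervisedLoss:
    total: Tensor
    pseudo_ce: Tensor
    dc: Tensor


def unsupervised_loss(prob1, prob2, emb1, emb2, negatives,
                      config: DCLossConfig) -> UnsupervisedLoss:
    """Combined unsupervised objective ``L_cl = L_ce + lambda * L_dc``.

    ``prob1``/``prob2`` are (K, h, w) probability maps and ``emb1``/``emb2``
    (D, h, w) embeddings, all on the aligned overlap grid. The pseudo-label
    cross-entropy is symmetric: each view's prediction is scored against the
    other view's argmax, restricted to pixels where the pseudo-labeling
    view's confidence exceeds ``gamma``; the two directions are averaged.
    """
    p1 = as_tensor(prob1.values if hasattr(prob1, "values") else prob1)
    p2 = as_tensor(prob2.values if hasattr(prob2, "values") else prob2)
    gamma = config.confidence_threshold
    a1, a2 = _prob_array(prob1), _prob_array(prob2)
    pseudo2, conf2 = a2.argmax(axis=0), a2.max(axis=0)
    pseudo1, conf1 = a1.argmax(axis=0), a1.max(axis=0)
    ce12 = cross_entropy(p1, pseudo2, valid_mask=conf2 > gamma)
    ce21 = cross_entropy(p2, pseudo1, valid_mask=conf1 > gamma)
    pseudo_ce = (ce12 + ce21) / 2
    dc = dc_loss([(emb1, emb2, prob1, prob2)], negatives, config)
    total = pseudo_ce + config.lambda_weight * dc
    return UnsupervisedLoss(total=total, pseudo_ce=pseudo_ce, dc=dc)
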