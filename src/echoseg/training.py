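"""Two-branch training schedule: supervised warm-up, then joint optimisation.

The supervised branch (cross-entropy on labeled images) trains alone for the
first ``warmup_epochs`` epochs; afterwards every step consumes one labeled
and one unlabeled batch and minimises

    L = L_ce(labeled) + L_ce_pseudo(views) + lambda * L_dc(views)

through the shared encoder–decoder, the shared classifier and the projector
in a single SGD update. The learning rate follows the poly decay policy
``lr0 * (1 - epoch/total)^power`` updated at epoch boundaries.

Negatives for the contrastive term are drawn per anchor pixel from the
loss-grid embeddings of the *other* images in the same unlabeled batch
(both views), excluding candidates whose pseudo-label equals the anchor's
pseudo-label; sampling is with replacement and seed-controlled.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .augment import AugmentConfig, dual_crop, map_overlap_to_grid, supervised_augment
from .data import make_split, preprocess
from .losses import DCLossConfig, cross_entropy, unsupervised_loss
from .metrics import evaluate
from .model import BackboneConfig, DilatedUNet, build_model
from .nn import functional as F
from .nn.tensor import Tensor

ABLATIONS = ("baseline", "dilation", "dilation_projector")


class ValidationError(ValueError):
    pass


@dataclass
class TrainConfig:
    lr0: float = 0.01
    power: float = 0.9
    weight_decay: float = 1e-4
    momentum: float = 0.9
    total_epochs: int = 80
    warmup_epochs: int = 5
    batch_size_labeled: int = 4
    batch_size_unlabeled: int = 4
    labeled_ratio: float = 1.0
    target_size: int = 512
    val_fraction: float = 0.1
    seed: int = 0
    amp: bool = False                      # accepted but a no-op passthrough
    ablation: str = "dilation_projector"
    supervised_only: bool = False
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    loss: DCLossConfig = field(default_factory=DCLossConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)

    def __post_init__(self):
        if self.warmup_epochs > self.total_epochs:
            raise ValidationError("warmup_epochs must be <= total_epochs")
        if self.lr0 <= 0 or self.power <= 0:
            raise ValidationError("lr0 and power must be positive")
        if self.ablation not in ABLATIONS:
            raise ValidationError(f"ablation must be one of {ABLATIONS}")


def apply_ablation(backbone: BackboneConfig, ablation: str) -> BackboneConfig:
    """Resolve the ablation switch into a concrete backbone configuration."""
    cfg = dataclasses.replace(backbone)
    if ablation == "baseline":
        cfg = dataclasses.replace(cfg, dilation_schedule=(1,) * cfg.depth,
                                  use_projector=False)
    elif ablation == "dilation":
        cfg = dataclasses.replace(cfg, use_projector=False)
    elif ablation != "dilation_projector":
        raise ValidationError(f"unknown ablation {ablation!r}")
    return cfg


def poly_lr(iteration: int, total: int, lr0: float, power: float) -> float:
    """Poly decay: lr0 * (1 - iter/total)^power."""
    if not 0 <= iteration <= total:
        raise ValidationError(f"iteration {iteration} outside [0, {total}]")
    return lr0 * (1.0 - iteration / total) ** power


# ---------------------------------------------------------------------------
def _stack_images(images) -> Tensor:
    arr = np.stack([np.asarray(im, dtype=np.float64) for im in images])
    return Tensor(arr[:, None])   # (N, 1, H, W)


def supervised_step(model: DilatedUNet, images, masks, optimizer) -> float:
    """One SGD update on the supervised cross-entropy; returns the loss."""
    x = _stack_images(images)
    target = np.stack([np.asarray(m) for m in masks])
    feats = model.forward_features(x)
    probs = model.classify(feats)
    loss = cross_entropy(probs.values, target)
    if not np.isfinite(loss.item()):
        raise RuntimeError("non-finite supervised loss; aborting step")
    optimizer.zero_grad()
    loss.backward()
    optimizer.step()
    return loss.item()


def _sample_negatives(flat_pool: Tensor, pool_img: np.ndarray,
                      pool_label: np.ndarray, anchor_img: int,
                      anchor_labels: np.ndarray, n_neg: int,
                      rng: np.random.Generator) -> Tensor | None:
    """Per-anchor negative embeddings (P, M, D) from other images in batch."""
    if n_neg == 0:
        return None
    p = anchor_labels.size
    idx = np.empty((p, n_neg), dtype=np.int64)
    others = pool_img != anchor_img
    if not np.any(others):
        return None
    fallback = np.flatnonzero(others)
    for c in np.unique(anchor_labels):
        cand = np.flatnonzero(others & (pool_label != c))
        if cand.size == 0:
            cand = fallback
        rows = np.flatnonzero(anchor_labels == c)
        idx[rows] = rng.choice(cand, size=(rows.size, n_neg), replace=True)
    return flat_pool[(idx,)]


def unsupervised_step(model: DilatedUNet, view_pairs, labeled_images,
                      labeled_masks, optimizer, config: TrainConfig,
                      rng: np.random.Generator) -> dict:
    """One joint update: labeled CE plus the unsupervised objective."""
    sup_x = _stack_images(labeled_images)
    sup_target = np.stack([np.asarray(m) for m in labeled_masks])
    sup_feats = model.forward_features(sup_x)
    sup_probs = model.classify(sup_feats)
    sup_ce = cross_entropy(sup_probs.values, sup_target)

    n_pairs = len(view_pairs)
    crop = view_pairs[0].view1.shape[0]
    grid_size = crop // model.config.grid_stride
    x = _stack_images([p.view1 for p in view_pairs]
                      + [p.view2 for p in view_pairs])
    feats = model.forward_features(x)
    probs = model.classify(feats)
    grid_feats = model.features_to_grid(feats)
    emb = model.project(grid_feats).values                  # (2B, D, g, g)
    k = model.config.grid_stride
    grid_probs = F.avg_pool2d(probs.values, k)              # (2B, K, g, g)

    pool_label = grid_probs.data.argmax(axis=1)             # (2B, g, g)
    dims = emb.shape[1]
    flat_pool = emb.transpose(0, 2, 3, 1).reshape(-1, dims)
    pool_img = np.repeat(np.concatenate([np.arange(n_pairs)] * 2),
                         grid_size * grid_size)

    pseudo_terms, dc_terms = [], []
    n_neg = config.loss.negatives_per_anchor
    for b, pair in enumerate(view_pairs):
        r1, r2 = map_overlap_to_grid(pair, grid_size)
        if r1[1] - r1[0] <= 0 or r1[3] - r1[2] <= 0:
            continue
        sl1 = (b, slice(None), slice(r1[0], r1[1]), slice(r1[2], r1[3]))
        sl2 = (n_pairs + b, slice(None), slice(r2[0], r2[1]),
               slice(r2[2], r2[3]))
        e1, e2 = emb[sl1], emb[sl2]
        p1, p2 = grid_probs[sl1], grid_probs[sl2]
        lab1 = pool_label[b, r1[0]:r1[1], r1[2]:r1[3]].ravel()
        lab2 = pool_label[n_pairs + b, r2[0]:r2[1], r2[2]:r2[3]].ravel()
        neg12 = _sample_negatives(flat_pool, pool_img, pool_label.ravel(),
                                  b, lab1, n_neg, rng)
        neg21 = _sample_negatives(flat_pool, pool_img, pool_label.ravel(),
                                  b, lab2, n_neg, rng)
        parts = unsupervised_loss(p1, p2, e1, e2, [(neg12, neg21)],
                                  config.loss)
        pseudo_terms.append(parts.pseudo_ce)
        dc_terms.append(parts.dc)

    if pseudo_terms:
        pseudo_ce = sum(pseudo_terms[1:], pseudo_terms[0]) / len(pseudo_terms)
        dc = sum(dc_terms[1:], dc_terms[0]) / len(dc_terms)
    else:
        pseudo_ce, dc = Tensor(0.0), Tensor(0.0)
    total = sup_ce + pseudo_ce + config.loss.lambda_weight * dc
    if not np.isfinite(total.item()):
        raise RuntimeError("non-finite joint loss; aborting step")
    optimizer.zero_grad()
    total.backward()
    optimizer.step()
    return {"total": total.item(), "sup_ce": sup_ce.item(),
            "pseudo_ce": pseudo_ce.item(), "dc": dc.item()}


# ---------------------------------------------------------------------------
@dataclass
class TrainResult:
    model: DilatedUNet
    log: pd.DataFrame
    checkpoint_path: Path | None = None
    val_miou: float | None = None


def _group_by_patient(samples):
    groups: dict = {}
    for s in samples:
        groups.setdefault(s.patient, []).append(s)
    return groups


def _batches(items, size, rng):
    order = rng.permutation(len(items))
    for start in range(0, len(items), size):
        yield [items[i] for i in order[start:start + size]]


def fit(config: TrainConfig, samples, out_dir=None) -> TrainResult:
    """Train on preprocessed-or-raw samples per the two-branch schedule.

    Splits are made at the patient level with ``config.seed``; a
    ``val_fraction`` slice of labeled patients is held out for checkpoint
    selection by mean IoU (when zero, the final model is kept).
    """
    rng = np.random.default_rng(config.seed)
    # preprocessing is idempotent, so raw and already-normalised samples
    # can be mixed freely
    samples = [preprocess(s, config.target_size) for s in samples]
    groups = _group_by_patient(samples)
    patients = list(groups)
    split = make_split(patients, config.labeled_ratio, 0.0, config.seed)

    n_val = int(round(config.val_fraction * len(patients)))
    n_val = min(n_val, len(split.labeled) - 1)
    val_ids = split.labeled[len(split.labeled) - n_val:] if n_val > 0 else []
    labeled_ids = [p for p in split.labeled if p not in val_ids]
    if not labeled_ids:
        raise ValidationError("at least one labeled patient is required")
    unlabeled_ids = split.unlabeled or labeled_ids

    labeled = [s for p in labeled_ids for s in groups[p]]
    unlabeled = [s for p in unlabeled_ids for s in groups[p]]
    val = [s for p in val_ids for s in groups[p]]

    backbone = apply_ablation(config.backbone, config.ablation)
    model = build_model(backbone, seed=config.seed)
    optimizer = nn.SGD(model.parameters(), lr=config.lr0,
                       momentum=config.momentum,
                       weight_decay=config.weight_decay)

    warmup = (config.total_epochs if config.supervised_only
              else config.warmup_epochs)
    rows = []
    best_miou, best_state = -1.0, None
    for epoch in range(config.total_epochs):
        optimizer.lr = poly_lr(epoch, config.total_epochs,
                               config.lr0, config.power)
        model.train()
        sup_losses, pseudo_losses, dc_losses = [], [], []
        if epoch < warmup:
            for batch in _batches(labeled, config.batch_size_labeled, rng):
                aug = [supervised_augment(s, int(rng.integers(2 ** 31)),
                                          config.augment) for s in batch]
                sup_losses.append(supervised_step(
                    model, [s.image for s in aug], [s.mask for s in aug],
                    optimizer))
            pseudo_mean = dc_mean = None
        else:
            lab_cycle = list(_batches(labeled, config.batch_size_labeled, rng))
            ci = 0
            for batch in _batches(unlabeled, config.batch_size_unlabeled, rng):
                pairs = [dual_crop(s, config.augment.crop_size,
                                   config.augment.min_overlap_fraction,
                                   int(rng.integers(2 ** 31)), config.augment)
                         for s in batch]
                lab_batch = lab_cycle[ci % len(lab_cycle)]
                ci += 1
                aug = [supervised_augment(s, int(rng.integers(2 ** 31)),
                                          config.augment) for s in lab_batch]
                parts = unsupervised_step(
                    model, pairs, [s.image for s in aug],
                    [s.mask for s in aug], optimizer, config, rng)
                sup_losses.append(parts["sup_ce"])
                pseudo_losses.append(parts["pseudo_ce"])
                dc_losses.append(parts["dc"])
            pseudo_mean = float(np.mean(pseudo_losses)) if pseudo_losses else 0.0
            dc_mean = float(np.mean(dc_losses)) if dc_losses else 0.0

        val_miou = val_mdsc = None
        if val:
            report = evaluate(model, val)
            val_miou = report.summary["mean_iou"]
            val_mdsc = report.summary["mean_dsc"]
            if val_miou > best_miou:
                best_miou = val_miou
                best_state = copy.deepcopy(model.state_dict())
        rows.append({"epoch": epoch, "lr": optimizer.lr,
                     "sup_ce": float(np.mean(sup_losses)),
                     "pseudo_ce": pseudo_mean, "dc": dc_mean,
                     "val_miou": val_miou, "val_dsc": val_mdsc})

    if best_state is not None:
        model.load_state_dict(best_state)
    log = pd.DataFrame(rows)
    checkpoint_path = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        checkpoint_path = out_dir / "checkpoint.npz"
        model.save(checkpoint_path)
        log.to_csv(out_dir / "log.csv", index=False)
    return TrainResult(model=model, log=log, checkpoint_path=checkpoint_path,
                       val_miou=best_miou if best_state is not None else None)
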