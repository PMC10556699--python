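"""Segmentation evaluation: Dice, IoU, precision and recall per class.

All aggregate scores follow the four-class averaging convention: the mean is
the unweighted average over background, LV, myocardium and LA, and the
spread statistic D(.) is the population variance of the per-case means
across evaluation cases.

Empty-class convention: a class absent from both prediction and ground
truth scores 1.0 (nothing to get wrong); absent from exactly one scores 0.0
via the plain count formulas. This avoids penalising views in which a
structure is genuinely not visible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    pass


@dataclass
class ConfusionCounts:
    """One-vs-rest pixel counts per class (exact integers)."""
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    @property
    def num_classes(self) -> int:
        return len(self.tp)


def confusion(pred: np.ndarray, truth: np.ndarray,
              num_classes: int = 4) -> ConfusionCounts:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValidationError(
            f"prediction shape {pred.shape} != truth shape {truth.shape}")
    for name, arr in (("pred", pred), ("truth", truth)):
        if arr.min() < 0 or arr.max() >= num_classes:
            raise ValidationError(f"{name} labels outside [0, {num_classes})")
    cm = np.bincount(truth.ravel() * num_classes + pred.ravel(),
                     minlength=num_classes ** 2).reshape(num_classes,
                                                         num_classes)
    tp = np.diag(cm).astype(np.int64)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    tn = pred.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _safe_ratio(num: float, den: float) -> float:
    return 1.0 if den == 0 else num / den


def dsc(counts: ConfusionCounts, c: int) -> float:
    """Dice similarity 2*TP / (2*TP + FP + FN)."""
    return _safe_ratio(2.0 * counts.tp[c],
                       2.0 * counts.tp[c] + counts.fp[c] + counts.fn[c])


def iou(counts: ConfusionCounts, c: int) -> float:
    """Intersection over union TP / (TP + FP + FN)."""
    return _safe_ratio(float(counts.tp[c]),
                       float(counts.tp[c] + counts.fp[c] + counts.fn[c]))


def precision_recall(counts: ConfusionCounts, c: int) -> tuple[float, float]:
    precision = _safe_ratio(float(counts.tp[c]),
                            float(counts.tp[c] + counts.fp[c]))
    recall = _safe_ratio(float(counts.tp[c]),
                         float(counts.tp[c] + counts.fn[c]))
    return precision, recall


@dataclass
class MetricsReport:
    """Aggregated evaluation results plus the case-level table."""
    cases: pd.DataFrame          # one row per case per class
    per_class: pd.DataFrame      # mean metric per class across cases
    summary: dict                # 4-class means and across-case variances

    def to_json(self) -> dict:
        return {"summary": self.summary,
                "per_class": self.per_class.to_dict(orient="index")}


def evaluate(model, samples, num_classes: int = 4) -> MetricsReport:
    """Evaluate a predictor on labeled samples at full preprocessed size.

    `model` is anything exposing ``predict(image) -> label mask``; samples
    must carry ground-truth masks. Cropping is never applied here.
    """
    samples = list(samples)
    if not samples:
        raise ValidationError("evaluation requires at least one sample")
    rows = []
    case_means = {"iou": [], "dsc": [], "precision": [], "recall": [],
                  "fg_dsc": []}
    for i, sample in enumerate(samples):
        if sample.mask is None:
            raise ValidationError(f"sample {i} has no ground-truth mask")
        pred = model.predict(sample.image)
        counts = confusion(pred, sample.mask, num_classes)
        per_case = {"iou": [], "dsc": [], "precision": [], "recall": []}
        for c in range(num_classes):
            p, r = precision_recall(counts, c)
            vals = {"iou": iou(counts, c), "dsc": dsc(counts, c),
                    "precision": p, "recall": r}
            rows.append({"case": i, "patient": sample.patient,
                         "view": sample.view, "phase": sample.phase,
                         "class": c, **vals})
            for k, v in vals.items():
                per_case[k].append(v)
        for k in per_case:
            case_means[k].append(float(np.mean(per_case[k])))
        case_means["fg_dsc"].append(float(np.mean(per_case["dsc"][1:])))
    cases = pd.DataFrame(rows)
    per_class = cases.groupby("class")[["iou", "dsc", "precision",
                                        "recall"]].mean()
    summary = {}
    for k, values in case_means.items():
        arr = np.asarray(values)
        key = "foreground_dsc" if k == "fg_dsc" else f"mean_{k}"
        summary[key] = float(arr.mean())
        summary[f"var_{k}" if k != "fg_dsc" else "var_foreground_dsc"] = \
            float(arr.var())  # population variance across cases
    summary["n_cases"] = len(samples)
    return MetricsReport(cases=cases, per_class=per_class, summary=summary)
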