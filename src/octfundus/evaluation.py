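"""Confusion-based segmentation metrics, ROC/AUC and cross-validation folds.

Metrics follow the standard confusion-count definitions with vessel as
the positive class:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (FP + TN)
    precision   = TP / (TP + FP)
    F1          = 2 TP / (2 TP + FP + FN)

A zero denominator yields ``None`` (an explicit undefined marker) rather
than an exception, so empty-vessel tiles aggregate cleanly.  AUC is the
exact trapezoidal area under the ROC swept over all unique probability
thresholds, equivalently the Mann–Whitney statistic with ties counted
half.  Cross-validation uses disjoint, jointly exhaustive test folds —
for the study protocol, 24 scans in 6 folds of 20 training / 4 test
items — with optional subject pairing so both eyes of a subject stay in
the same fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .core import ProbabilityMap, ValidationError, VesselMask


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValidationError(f"{name} must be a non-negative integer, got {v}")
            setattr(self, name, int(v))

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricSet:
    """The five confusion metrics plus AUC; None marks undefined values."""

    accuracy: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    precision: float | None = None
    f1: float | None = None
    auc: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "precision": self.precision,
            "f1": self.f1, "auc": self.auc,
        }


@dataclass
class FoldSplit:
    """Per-fold train/test item id lists."""

    folds: list[dict[str, list]]
    n_folds: int
    seed: int
    pairing: dict | None = None

    def __iter__(self):
        return iter(self.folds)


def confusion(pred: VesselMask, truth: VesselMask,
              roi: np.ndarray | None = None) -> ConfusionCounts:
    """Confusion counts over the (optional) region of interest."""
    if pred.shape != truth.shape:
        raise ValidationError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    p = pred.pixels.astype(bool)
    t = truth.pixels.astype(bool)
    if roi is not None:
        roi = np.asarray(roi).astype(bool)
        if roi.shape != p.shape:
            raise ValidationError(f"roi shape {roi.shape} != mask shape {p.shape}")
        p, t = p[roi], t[roi]
    return ConfusionCounts(
        TP=int(np.sum(p & t)), TN=int(np.sum(~p & ~t)),
        FP=int(np.sum(p & ~t)), FN=int(np.sum(~p & t)),
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def metrics(c: ConfusionCounts) -> MetricSet:
    """The five confusion-count ratios (AUC left unset)."""
    if c.total == 0:
        raise ValidationError("empty confusion (no evaluated pixels)")
    return MetricSet(
        accuracy=_ratio(c.TP + c.TN, c.total),
        sensitivity=_ratio(c.TP, c.TP + c.FN),
        specificity=_ratio(c.TN, c.FP + c.TN),
        precision=_ratio(c.TP, c.TP + c.FP),
        f1=_ratio(2 * c.TP, 2 * c.TP + c.FP + c.FN),
    )


def roc_auc(prob: ProbabilityMap, truth: VesselMask,
            roi: np.ndarray | None = None) -> float:
    """Exact area under the ROC curve (ties counted half)."""
    p = prob.pixels
    t = truth.pixels.astype(bool)
    if p.shape != t.shape:
        raise ValidationError(f"shape mismatch: prob {p.shape} vs truth {t.shape}")
    if roi is not None:
        roi = np.asarray(roi).astype(bool)
        p, t = p[roi], t[roi]
    p, t = p.ravel(), t.ravel()
    if t.all() or not t.any():
        raise ValidationError("truth must contain both classes for AUC")
    return float(roc_auc_score(t, p))


def evaluate(pred: VesselMask, truth: VesselMask,
             prob: ProbabilityMap | None = None,
             roi: np.ndarray | None = None) -> MetricSet:
    """All metrics for one prediction (AUC only if a probability map is given)."""
    ms = metrics(confusion(pred, truth, roi))
    if prob is not None:
        ms.auc = roc_auc(prob, truth, roi)
    return ms


def make_folds(item_ids: list, n_folds: int, seed: int = 0,
               pairing: dict | None = None) -> FoldSplit:
    """Seeded disjoint exhaustive test folds, optionally grouping paired items.

    ``pairing`` maps item id -> subject id; all items of a subject are
    assigned to the same test fold (so e.g. left/right eyes of one person
    never straddle a train/test boundary).
    """
    items = list(item_ids)
    if n_folds < 1 or n_folds > len(items):
        raise ValidationError(f"n_folds={n_folds} invalid for {len(items)} items")
    rng = np.random.default_rng(seed)
    if pairing is None:
        units = [[it] for it in items]
    else:
        groups: dict = {}
        for it in items:
            groups.setdefault(pairing.get(it, it), []).append(it)
        units = list(groups.values())
        if n_folds > len(units):
            raise ValidationError(
                f"n_folds={n_folds} exceeds {len(units)} pairable subject groups"
            )
    order = rng.permutation(len(units))
    buckets: list[list] = [[] for _ in range(n_folds)]
    # round-robin over shuffled units keeps fold sizes nearly equal
    for pos, ui in enumerate(order):
        buckets[pos % n_folds].extend(units[ui])
    folds = []
    for k in range(n_folds):
        test = sorted(buckets[k], key=items.index)
        train = [it for it in items if it not in test]
        folds.append({"train": train, "test": test})
    return FoldSplit(folds, n_folds, seed, pairing)


def aggregate_folds(per_fold: list[MetricSet]) -> tuple[MetricSet, list[dict]]:
    """Unweighted mean of each defined metric across folds, plus per-fold table.

    Undefined (None) entries are excluded from the mean; the per-fold table
    retains them and records how many folds contributed to each mean.
    """
    if not per_fold:
        raise ValidationError("need at least one fold")
    table = [ms.as_dict() for ms in per_fold]
    mean = MetricSet()
    for key in mean.as_dict():
        vals = [row[key] for row in table if row[key] is not None]
        if vals:
            setattr(mean, key, float(np.mean(vals)))
    return mean, table
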