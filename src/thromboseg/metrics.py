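"""Overlap metrics and the patient-wise k-fold cross-validation protocol.

The five metrics, for prediction A and ground truth B:

    TO      = |A ∩ B| / |B|          (total overlap)
    Dice    = 2|A ∩ B| / (|A| + |B|)
    Jaccard = |A ∩ B| / |A ∪ B|
    FN      = |B \\ A| / |B|
    FP      = |A \\ B| / |A|   (denominator |B| available behind a flag)

TO + FN = 1 holds identically for any nonempty B, and Dice = 2J/(1+J).
Empty-prediction convention: TO = Dice = Jaccard = 0, FN = 1, FP = 0
(the FP denominator would be 0; defined as 0 to keep FN informative).
Empty GT is an error — the protocol evaluates only slices with a ROI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .core_data import validate_binary_mask

__all__ = [
    "MetricsReport",
    "FoldSplit",
    "confusion_counts",
    "compute_metrics",
    "aggregate",
    "make_cv_folds",
]

Level = Literal["slice", "study", "fold", "overall"]
_LEVELS = ("slice", "study", "fold", "overall")

METRIC_NAMES = ("TO", "Dice", "Jaccard", "FN", "FP")


@dataclass(frozen=True)
class MetricsReport:
    TO: float
    Dice: float
    Jaccard: float
    FN: float
    FP: float
    level: Level = "slice"
    n_items: int = 1

    def __post_init__(self):
        for name in METRIC_NAMES:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.level not in _LEVELS:
            raise ValueError(f"unknown aggregation level {self.level!r}")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass(frozen=True)
class FoldSplit:
    fold_id: int
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]

    def __post_init__(self):
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError(f"fold {self.fold_id}: train/test overlap")


def confusion_counts(pred: np.ndarray, gt: np.ndarray) -> tuple[int, int, int]:
    """Pixel counts (TP, FP, FN) for a binary prediction/GT pair."""
    p = validate_binary_mask(pred).astype(bool)
    g = validate_binary_mask(gt).astype(bool)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    return tp, fp, fn


def compute_metrics(
    pred: np.ndarray,
    gt: np.ndarray,
    fp_denominator: Literal["prediction", "gt"] = "prediction",
) -> MetricsReport:
    """The five overlap metrics for one prediction/GT mask pair."""
    tp, fp, fn = confusion_counts(pred, gt)
    n_gt = tp + fn
    n_pred = tp + fp
    if n_gt == 0:
        raise ValueError("ground truth mask is empty; metrics undefined")
    if n_pred == 0:
        return MetricsReport(TO=0.0, Dice=0.0, Jaccard=0.0, FN=1.0, FP=0.0)
    fp_den = n_pred if fp_denominator == "prediction" else n_gt
    return MetricsReport(
        TO=tp / n_gt,
        Dice=2.0 * tp / (n_pred + n_gt),
        Jaccard=tp / (tp + fp + fn),
        FN=fn / n_gt,
        FP=min(fp / fp_den, 1.0),
    )


def aggregate(reports: Sequence[MetricsReport], level: Level) -> MetricsReport:
    """Unweighted arithmetic mean of each metric over ``reports``.

    The hierarchy is slice -> study -> fold -> overall; every report in one
    call must come from the same source level (one below ``level``).
    """
    if not reports:
        raise ValueError("cannot aggregate an empty report list")
    src = {r.level for r in reports}
    if len(src) != 1:
        raise ValueError(f"mixed source levels {sorted(src)}")
    (source,) = src
    if _LEVELS.index(level) != _LEVELS.index(source) + 1:
        raise ValueError(f"cannot aggregate {source!r} reports to {level!r}")
    means = {name: float(np.mean([getattr(r, name) for r in reports])) for name in METRIC_NAMES}
    return MetricsReport(level=level, n_items=len(reports), **means)


def make_cv_folds(study_ids: Sequence[str], k: int = 4, seed: int = 0) -> list[FoldSplit]:
    """Patient-wise k-fold split: seeded shuffle, contiguous test partitions.

    Every study is tested exactly once; test sets have size floor(n/k) or
    ceil(n/k).  With the study protocol (60 studies, k=4) each fold trains
    on 45 studies and tests on the remaining 15.
    """
    ids = list(study_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("study ids must be unique")
    n = len(ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} studies")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(n)]
    base, extra = divmod(n, k)
    folds, start = [], 0
    for fold_id in range(k):
        size = base + (1 if fold_id < extra else 0)
        test = tuple(order[start : start + size])
        train = tuple(x for x in order if x not in test)
        folds.append(FoldSplit(fold_id=fold_id, train_ids=train, test_ids=test))
        start += size
    return folds
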