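"""Classification and segmentation evaluation metrics.

Classification follows the usual confusion-count definitions
(ACC, SEN, SPE) plus the rank-based AUC.  Segmentation overlap metrics use
the set-cardinality formulation over a predicted mask ``S`` and ground
truth ``GT`` on an image of ``I`` pixels:

    DI     = 2|S n GT| / (|S| + |GT|)
    JA     = |S n GT| / |S u GT|
    ACC    = (I - |S u GT| + |S n GT|) / I
    Recall = |S n GT| / |GT|
    SPE    = (I - |S u GT|) / (I - |GT|)

DI and JA are tied by the exact identity ``DI = 2 JA / (1 + JA)``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = [
    "ConfusionCounts",
    "ClassReport",
    "SegOverlapReport",
    "classification_metrics",
    "roc_auc",
    "segmentation_metrics",
    "segmentation_metrics_batch",
    "binarize",
    "dice_from_jaccard",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ClassReport:
    acc: float
    sen: float
    spe: float
    auc: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SegOverlapReport:
    di: float
    ja: float
    acc: float
    recall: float
    spe: float

    def to_dict(self) -> dict:
        return asdict(self)


def classification_metrics(counts: ConfusionCounts) -> ClassReport:
    """ACC, SEN (recall on positives) and SPE from confusion counts."""
    if counts.total == 0:
        raise ValueError("no items: accuracy undefined")
    if counts.tp + counts.fn == 0:
        raise ValueError("no positive items: sensitivity undefined")
    if counts.tn + counts.fp == 0:
        raise ValueError("no negative items: specificity undefined")
    return ClassReport(
        acc=(counts.tp + counts.tn) / counts.total,
        sen=counts.tp / (counts.tp + counts.fn),
        spe=counts.tn / (counts.tn + counts.fp),
    )


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney formulation, ties half-credit)."""
    y = np.asarray(labels).reshape(-1)
    s = np.asarray(scores, dtype=float).reshape(-1)
    if y.size != s.size:
        raise ValueError("scores/labels length mismatch")
    if len(np.unique(y)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(y, s))


def binarize(p, threshold: float = 0.5) -> np.ndarray:
    """Probability map -> {0,1} mask; pixels with ``P >= threshold`` are 1."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    p = np.asarray(getattr(p, "data", p), dtype=float)
    return (p >= threshold).astype(np.uint8)


def _check_mask_pair(s: np.ndarray, gt: np.ndarray) -> None:
    if s.shape != gt.shape:
        raise ValueError(f"shape mismatch: {s.shape} vs {gt.shape}")
    for name, m in (("S", s), ("GT", gt)):
        if not np.isin(m, (0, 1)).all():
            raise ValueError(f"{name} is not binary")


def segmentation_metrics(s, gt) -> SegOverlapReport:
    """Overlap metrics between one predicted mask and one ground truth.

    Degenerate cases: both masks empty gives DI = JA = 1 by convention;
    an empty ground truth makes recall undefined (error), a full-image
    ground truth makes specificity undefined (error).
    """
    s = np.asarray(s)
    gt = np.asarray(gt)
    _check_mask_pair(s, gt)
    total = s.size
    inter = int(np.logical_and(s, gt).sum())
    union = int(np.logical_or(s, gt).sum())
    ns, ngt = int(s.sum()), int(gt.sum())
    if ngt == 0 and ns == 0:
        # empty-empty convention: a correctly predicted absence is perfect
        di = ja = recall = 1.0
    elif ngt == 0:
        raise ValueError("empty ground truth: recall undefined")
    else:
        di = 2.0 * inter / (ns + ngt)
        ja = inter / union
        recall = inter / ngt
    acc = (total - union + inter) / total
    if ngt == total:
        raise ValueError("ground truth covers the whole image: specificity undefined")
    spe = (total - union) / (total - ngt)
    return SegOverlapReport(di=di, ja=ja, acc=acc, recall=recall, spe=spe)


def segmentation_metrics_batch(s_batch, gt_batch
                               ) -> tuple[list[SegOverlapReport], SegOverlapReport]:
    """Per-image reports and their unweighted mean."""
    s_batch = np.asarray(s_batch)
    gt_batch = np.asarray(gt_batch)
    if s_batch.shape != gt_batch.shape or s_batch.ndim < 3:
        raise ValueError("expected matching batched masks (N, ..., H, W)")
    reports = [segmentation_metrics(si, gi) for si, gi in zip(s_batch, gt_batch)]
    mean = SegOverlapReport(
        di=float(np.mean([r.di for r in reports])),
        ja=float(np.mean([r.ja for r in reports])),
        acc=float(np.mean([r.acc for r in reports])),
        recall=float(np.mean([r.recall for r in reports])),
        spe=float(np.mean([r.spe for r in reports])),
    )
    return reports, mean


def dice_from_jaccard(ja: float) -> float:
    """The exact DI/JA identity ``DI = 2 JA / (1 + JA)``."""
    if not 0.0 <= ja <= 1.0:
        raise ValueError("Jaccard index must be in [0, 1]")
    return 2.0 * ja / (1.0 + ja)
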