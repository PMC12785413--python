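"""Detection and localization metrics: top-K image score, image/pixel
AUROC, and the per-region-overlap (PRO) curve with its capped-FPR score.

PRO is threshold-swept region recall: at each threshold the saliency maps
are binarized (strict ``>``), PRO is |P∩G|/|G| averaged over fractured
images only, and FPR is the pooled false-positive rate over the
non-anomalous pixels of *all* test images.  The PRO-score is the
normalized area under PRO-vs-FPR restricted to FPR ≤ 30 %.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .errors import UndefinedMetricError

__all__ = [
    "ScoredImage",
    "ProCurve",
    "EvalReport",
    "image_score",
    "auroc",
    "pixel_auroc",
    "pro_curve",
    "pro_score",
    "evaluate_items",
]


@dataclass
class ScoredImage:
    saliency: np.ndarray  # (H, W) in (0, 1)
    label: int  # 1 = fractured
    mask: np.ndarray | None = None  # ground truth G, required iff label=1
    score: float | None = None  # top-K image score

    def __post_init__(self):
        if self.label == 1 and (self.mask is None or not self.mask.any()):
            raise ValueError("fractured items need a non-empty ground-truth mask")

    def gt(self) -> np.ndarray:
        if self.mask is None:
            return np.zeros(self.saliency.shape, dtype=bool)
        return self.mask.astype(bool)


@dataclass
class ProCurve:
    thresholds: np.ndarray
    pro: np.ndarray
    fpr: np.ndarray


@dataclass
class EvalReport:
    image_auroc: float
    pixel_auroc: float
    pro_auc: float  # PRO-score (FPR-capped, normalized)
    image_threshold: float  # upper-left operating point of the image ROC
    pro_threshold: float  # upper-left operating point of the PRO curve
    scores: list = field(default_factory=list)  # per-image rows
    roc: dict = field(default_factory=dict)
    pro: dict = field(default_factory=dict)


def image_score(M_hat: np.ndarray, K: int = 50) -> float:
    """Mean of the K largest saliency values (image-level anomaly score)."""
    flat = np.asarray(M_hat).ravel()
    if K < 1 or K > flat.size:
        raise ValueError(f"K={K} out of range for {flat.size} pixels")
    top = np.partition(flat, flat.size - K)[-K:]
    return float(top.mean())


def auroc(scores, labels) -> float:
    """Area under the ROC curve (midrank tie convention)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("AUROC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64)))


def pixel_auroc(items: list[ScoredImage]) -> float:
    """AUROC over all pixels of all images pooled together; normal images
    contribute all-zero ground truth."""
    scores = np.concatenate([it.saliency.ravel() for it in items])
    labels = np.concatenate([it.gt().ravel() for it in items]).astype(int)
    return auroc(scores, labels)


def _threshold_sweep(items: list[ScoredImage], max_levels: int = 256) -> np.ndarray:
    vals = np.unique(np.concatenate([it.saliency.ravel() for it in items]))
    if vals.size > max_levels:
        idx = np.linspace(0, vals.size - 1, max_levels).round().astype(int)
        vals = vals[np.unique(idx)]
    return np.unique(np.concatenate([vals, [0.0, 1.0]]))


def pro_curve(items: list[ScoredImage], thresholds: np.ndarray | None = None) -> ProCurve:
    """Sweep thresholds; binarize with strict ``>``; PRO over fractured
    images, FPR pooled over every image's non-anomalous pixels."""
    fractured = [it for it in items if it.label == 1]
    if not fractured:
        raise UndefinedMetricError("PRO needs at least one fractured item")
    if thresholds is None:
        thresholds = _threshold_sweep(items)
    thresholds = np.sort(np.asarray(thresholds, dtype=np.float64))

    sal = np.stack([it.saliency for it in items]).astype(np.float64)
    gts = np.stack([it.gt() for it in items])
    is_frac = np.array([it.label == 1 for it in items])
    g_area = gts.reshape(len(items), -1).sum(axis=1)
    neg_total = (~gts).sum()

    pro = np.empty(thresholds.size)
    fpr = np.empty(thresholds.size)
    for i, thr in enumerate(thresholds):
        pred = sal > thr
        inter = (pred & gts).reshape(len(items), -1).sum(axis=1)
        pro[i] = (inter[is_frac] / g_area[is_frac]).mean()
        fpr[i] = (pred & ~gts).sum() / neg_total
    # descending threshold: P grows, so FPR and PRO are both nondecreasing
    order = np.argsort(-thresholds, kind="stable")
    return ProCurve(thresholds=thresholds[order], pro=pro[order], fpr=fpr[order])


def pro_score(curve: ProCurve, fpr_cap: float = 0.3) -> float:
    """Normalized trapezoidal area of PRO vs FPR restricted to
    FPR in [0, fpr_cap].

    Operating points sharing an FPR are collapsed to their best (maximum)
    PRO — dominated points do not lower the area.  If the sweep never
    reaches the cap the curve is extended flat from its last point; if it
    crosses the cap it is linearly interpolated there.
    """
    if curve.fpr.size == 0:
        raise ValueError("empty curve")
    order = np.argsort(curve.fpr, kind="stable")
    fpr, pro = curve.fpr[order], curve.pro[order]
    # upper envelope: max PRO at each unique FPR
    xs, idx = np.unique(fpr, return_index=True)
    ys = np.maximum.reduceat(pro, idx)
    if xs[0] > 0.0:
        xs = np.insert(xs, 0, 0.0)
        ys = np.insert(ys, 0, 0.0)
    if xs[-1] < fpr_cap:
        xs = np.append(xs, fpr_cap)
        ys = np.append(ys, ys[-1])
    keep = xs <= fpr_cap
    if xs[keep][-1] < fpr_cap:
        y_cap = float(np.interp(fpr_cap, xs, ys))
        xs = np.append(xs[keep], fpr_cap)
        ys = np.append(ys[keep], y_cap)
    else:
        xs, ys = xs[keep], ys[keep]
    return float(np.trapezoid(ys, xs) / fpr_cap)


def evaluate_items(items: list[ScoredImage], K: int = 50, fpr_cap: float = 0.3) -> EvalReport:
    """Compute the full metric trio plus operating points from scored
    saliency maps.  Operating thresholds are the upper-left points
    (max TPR−FPR, resp. max PRO−FPR) of the respective curves."""
    for it in items:
        if it.score is None:
            it.score = image_score(it.saliency, K=min(K, it.saliency.size))
    labels = [it.label for it in items]
    scores = [it.score for it in items]
    img_auroc = auroc(scores, labels)
    fpr_img, tpr_img, thr_img = roc_curve(labels, scores)
    best = int(np.argmax(tpr_img - fpr_img))
    image_thr = float(thr_img[best])

    px_auroc = pixel_auroc(items)
    curve = pro_curve(items)
    score = pro_score(curve, fpr_cap=fpr_cap)
    best_pro = int(np.argmax(curve.pro - curve.fpr))
    rows = [
        {"index": i, "label": it.label, "score": float(it.score)}
        for i, it in enumerate(items)
    ]
    return EvalReport(
        image_auroc=img_auroc,
        pixel_auroc=px_auroc,
        pro_auc=score,
        image_threshold=image_thr,
        pro_threshold=float(curve.thresholds[best_pro]),
        scores=rows,
        roc={"fpr": fpr_img.tolist(), "tpr": tpr_img.tolist()},
        pro={"fpr": curve.fpr.tolist(), "pro": curve.pro.tolist(),
             "thresholds": curve.thresholds.tolist()},
    )
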