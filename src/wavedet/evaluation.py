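"""Detection metrics and analysis utilities.

Average precision follows the COCO protocol: detections are greedily matched
to ground truth in descending score order at a given IoU threshold (each
ground-truth box consumed at most once), and AP is the 101-point interpolated
area under the precision-recall curve.  mAP50 uses IoU 0.5; mAP50-95 averages
AP over IoU in {0.50, 0.55, ..., 0.95}.  All per-class metrics are macro
averaged (unweighted class mean).

AUC for detections is not a standard notion; here each class's detections,
labeled TP/FP at IoU 0.5 across the full score range, form a binary ranking
problem scored by the rank (Mann-Whitney) statistic.  Classes with no
positives or no negatives are excluded with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

__all__ = [
    "EvalResult",
    "EffectSizeInput",
    "box_iou_xywh",
    "match_detections",
    "average_precision",
    "evaluate_detections",
    "f1_at_threshold",
    "macro_auc",
    "pooled_sd",
    "cohens_d",
    "effect_label",
    "leakage_audit",
    "feature_heatmap",
]

IOU_THRESHOLDS_50_95 = np.arange(0.50, 0.96, 0.05)


@dataclass
class EvalResult:
    per_class: dict          # class id -> dict of metrics
    macro: dict              # metric name -> unweighted class mean
    pr_curves: dict = field(default_factory=dict)   # class id -> (recall, precision)

    def table(self, categories: dict | None = None) -> str:
        cols = ["instances", "precision", "recall", "map50", "map50_95",
                "f1", "auc"]
        names = ["Instances", "Precision", "Recall", "mAP50", "mAP50-90",
                 "F1", "AUC"]
        header = "category    " + "  ".join(f"{c:>9}" for c in names)
        lines = [header]
        for cid in sorted(self.per_class):
            row = self.per_class[cid]
            name = (categories or {}).get(cid, str(cid))
            cells = []
            for c in cols:
                v = row.get(c)
                cells.append(f"{v:9.3f}" if isinstance(v, float)
                             else f"{v!s:>9}")
            lines.append(f"{name:<12}" + "  ".join(cells))
        lines.append("macro       " + "  ".join(
            f"{self.macro.get(c, float('nan')):9.3f}" if c != "instances"
            else f"{'':>9}" for c in cols))
        return "\n".join(lines)


@dataclass
class EffectSizeInput:
    mean_1: float
    mean_2: float
    sd_1: float
    sd_2: float
    n_1: int
    n_2: int

    def __post_init__(self):
        if self.n_1 < 2 or self.n_2 < 2:
            raise ValueError("effect size requires n >= 2 per group")
        if self.sd_1 < 0 or self.sd_2 < 0:
            raise ValueError("standard deviations must be >= 0")


# ---------------------------------------------------------------------------
# Matching and AP
# ---------------------------------------------------------------------------

def box_iou_xywh(a, b) -> np.ndarray:
    """Pairwise IoU between pixel-format (x, y, w, h) box sets."""
    a = np.asarray(a, dtype=np.float64).reshape(-1, 4)
    b = np.asarray(b, dtype=np.float64).reshape(-1, 4)
    ax1, ay1 = a[:, 0], a[:, 1]
    ax2, ay2 = a[:, 0] + a[:, 2], a[:, 1] + a[:, 3]
    bx1, by1 = b[:, 0], b[:, 1]
    bx2, by2 = b[:, 0] + b[:, 2], b[:, 1] + b[:, 3]
    iw = np.clip(np.minimum(ax2[:, None], bx2) - np.maximum(ax1[:, None], bx1),
                 0, None)
    ih = np.clip(np.minimum(ay2[:, None], by2) - np.maximum(ay1[:, None], by1),
                 0, None)
    inter = iw * ih
    union = (a[:, 2] * a[:, 3])[:, None] + b[:, 2] * b[:, 3] - inter
    return inter / np.maximum(union, 1e-12)


def match_detections(preds: list, gts: list, iou_threshold: float = 0.5):
    """Greedy score-descending matching of one image-class group.

    preds: list of dicts with "bbox" and "score"; gts: list of boxes.
    Returns (labels, scores, n_gt): labels[i] is True for TP.  Each ground
    truth is consumed by at most one prediction; extra detections of the
    same object are false positives.
    """
    order = np.argsort([-p["score"] for p in preds], kind="stable")
    labels = np.zeros(len(preds), dtype=bool)
    scores = np.array([preds[i]["score"] for i in order], dtype=np.float64)
    used = np.zeros(len(gts), dtype=bool)
    if gts:
        gt_arr = np.asarray([g for g in gts], dtype=np.float64)
        for rank, i in enumerate(order):
            ious = box_iou_xywh([preds[i]["bbox"]], gt_arr)[0]
            ious[used] = -1.0
            j = int(np.argmax(ious))
            if ious[j] >= iou_threshold:
                labels[rank] = True
                used[j] = True
    return labels, scores, len(gts)


def average_precision(labels: np.ndarray, scores: np.ndarray,
                      n_gt: int) -> float:
    """COCO 101-point interpolated AP from score-sorted TP/FP labels."""
    if n_gt == 0:
        return float("nan")
    if len(labels) == 0:
        return 0.0
    order = np.argsort(-np.asarray(scores), kind="stable")
    labels = np.asarray(labels)[order]
    tp = np.cumsum(labels)
    fp = np.cumsum(~labels)
    recall = tp / n_gt
    precision = tp / np.maximum(tp + fp, 1)
    # precision envelope, then sample at 101 recall points
    prec_env = np.maximum.accumulate(precision[::-1])[::-1]
    rec_points = np.linspace(0, 1, 101)
    idx = np.searchsorted(recall, rec_points, side="left")
    sampled = np.where(idx < len(prec_env), prec_env[np.minimum(idx, len(prec_env) - 1)], 0.0)
    return float(sampled.mean())


def _group_by_class_image(preds, gts):
    """Index predictions and GT boxes by (class, image)."""
    classes = sorted({g["category_id"] for g in gts}
                     | {p["category_id"] for p in preds})
    images = sorted({g["image_id"] for g in gts}
                    | {p["image_id"] for p in preds})
    pmap = {(c, i): [] for c in classes for i in images}
    gmap = {(c, i): [] for c in classes for i in images}
    for p in preds:
        pmap[(p["category_id"], p["image_id"])].append(p)
    for g in gts:
        gmap[(g["category_id"], g["image_id"])].append(g["bbox"])
    return classes, images, pmap, gmap


def _class_labels(cls, images, pmap, gmap, iou_threshold):
    labels, scores, n_gt = [], [], 0
    for img in images:
        l, s, n = match_detections(pmap[(cls, img)], gmap[(cls, img)],
                                   iou_threshold)
        labels.append(l)
        scores.append(s)
        n_gt += n
    return (np.concatenate(labels) if labels else np.zeros(0, dtype=bool),
            np.concatenate(scores) if scores else np.zeros(0), n_gt)


def evaluate_detections(preds: list, gts: list,
                        score_threshold: float = 0.3) -> EvalResult:
    """Full metric suite.

    preds: dicts {image_id, category_id, bbox, score}; gts: dicts
    {image_id, category_id, bbox}.  Classes with zero ground truth are
    excluded from macro means.
    """
    classes, images, pmap, gmap = _group_by_class_image(preds, gts)
    per_class, pr_curves = {}, {}
    for cls in classes:
        labels50, scores50, n_gt = _class_labels(cls, images, pmap, gmap, 0.5)
        if n_gt == 0:
            per_class[cls] = {"instances": 0}
            continue
        ap50 = average_precision(labels50, scores50, n_gt)
        aps = [ap50 if abs(t - 0.5) < 1e-9 else average_precision(
            *_class_labels(cls, images, pmap, gmap, t)[:2], n_gt)
            for t in IOU_THRESHOLDS_50_95]
        # operating point at the confidence threshold
        keep = scores50 > score_threshold
        tp = int(labels50[keep].sum())
        n_pred = int(keep.sum())
        precision = tp / n_pred if n_pred else 0.0
        recall = tp / n_gt
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall > 0 else 0.0)
        auc = _rank_auc(labels50, scores50)
        order = np.argsort(-scores50, kind="stable")
        tp_c = np.cumsum(labels50[order])
        fp_c = np.cumsum(~labels50[order])
        pr_curves[cls] = (tp_c / n_gt, tp_c / np.maximum(tp_c + fp_c, 1))
        per_class[cls] = {"instances": n_gt, "precision": precision,
                          "recall": recall, "map50": ap50,
                          "map50_95": float(np.mean(aps)), "f1": f1,
                          "auc": auc}
    valid = [m for m in per_class.values() if m.get("instances", 0) > 0]
    macro = {}
    for key in ("precision", "recall", "map50", "map50_95", "f1", "auc"):
        vals = [m[key] for m in valid if m.get(key) is not None
                and not (isinstance(m[key], float) and np.isnan(m[key]))]
        macro[key] = float(np.mean(vals)) if vals else float("nan")
    return EvalResult(per_class=per_class, macro=macro, pr_curves=pr_curves)


def f1_at_threshold(preds: list, gts: list, score_threshold: float = 0.3,
                    iou_threshold: float = 0.5):
    """Per-class and macro F1 at an operating score threshold."""
    kept = [p for p in preds if p["score"] > score_threshold]
    classes, images, pmap, gmap = _group_by_class_image(kept, gts)
    per_class = {}
    for cls in classes:
        labels, scores, n_gt = _class_labels(cls, images, pmap, gmap,
                                             iou_threshold)
        if n_gt == 0:
            continue
        tp = int(labels.sum())
        precision = tp / len(labels) if len(labels) else 0.0
        recall = tp / n_gt
        per_class[cls] = (2 * precision * recall / (precision + recall)
                          if precision + recall > 0 else 0.0)
    macro = float(np.mean(list(per_class.values()))) if per_class else 0.0
    return per_class, macro


def _rank_auc(labels: np.ndarray, scores: np.ndarray) -> float | None:
    pos = scores[labels]
    neg = scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        return None
    # Mann-Whitney U via rank sums, ties counted half
    u = sstats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u / (len(pos) * len(neg)))


def macro_auc(preds: list, gts: list, iou_threshold: float = 0.5):
    """Per-class and macro rank-statistic AUC over TP/FP detection labels."""
    classes, images, pmap, gmap = _group_by_class_image(preds, gts)
    per_class = {}
    for cls in classes:
        labels, scores, n_gt = _class_labels(cls, images, pmap, gmap,
                                             iou_threshold)
        auc = _rank_auc(labels, scores)
        if auc is None:
            warnings.warn(f"class {cls}: AUC undefined (needs both TP and "
                          "FP detections); excluded from macro mean")
            continue
        per_class[cls] = auc
    macro = float(np.mean(list(per_class.values()))) if per_class else None
    return per_class, macro


# ---------------------------------------------------------------------------
# Effect sizes
# ---------------------------------------------------------------------------

def pooled_sd(a: EffectSizeInput) -> float:
    """sqrt(((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2))."""
    num = (a.n_1 - 1) * a.sd_1 ** 2 + (a.n_2 - 1) * a.sd_2 ** 2
    return float(np.sqrt(num / (a.n_1 + a.n_2 - 2)))


def cohens_d(a: EffectSizeInput) -> float:
    """Standardized mean difference (X1 - X2) / pooled sd."""
    return float((a.mean_1 - a.mean_2) / pooled_sd(a))


def effect_label(d: float) -> str:
    """Magnitude labels at thresholds 0.3 / 0.5 / 0.8."""
    m = abs(d)
    if m >= 0.8:
        return "large"
    if m >= 0.5:
        return "medium"
    if m >= 0.3:
        return "small"
    return "negligible"


# ---------------------------------------------------------------------------
# Dataset audits and visualization
# ---------------------------------------------------------------------------

def leakage_audit(features: np.ndarray, group_ids) -> dict:
    """Fraction of images whose cosine-nearest neighbor shares their group.

    ``features``: (n, d) per-image feature vectors (max-pooled backbone
    maps); self-similarity excluded.
    """
    f = np.asarray(features, dtype=np.float64)
    norms = np.linalg.norm(f, axis=1, keepdims=True)
    f = f / np.maximum(norms, 1e-12)
    sim = f @ f.T
    np.fill_diagonal(sim, -np.inf)
    nn = sim.argmax(axis=1)
    groups = np.asarray(group_ids)
    same = groups[nn] == groups
    return {"count": int(same.sum()), "fraction": float(same.mean()),
            "n": len(groups)}


def feature_heatmap(feature_map: np.ndarray) -> np.ndarray:
    """Channel-sum + min-max normalization of a (C, H, W) feature map."""
    fm = np.asarray(feature_map, dtype=np.float64)
    summed = fm.sum(axis=0) if fm.ndim == 3 else fm
    lo, hi = summed.min(), summed.max()
    if hi - lo <= 0:
        warnings.warn("feature map has zero dynamic range; heatmap is all "
                      "zeros")
        return np.zeros_like(summed)
    return (summed - lo) / (hi - lo)
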