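"""Set-prediction training criterion: Hungarian matching, ground-truth
duplication and the hierarchical hybrid loss.

Each prediction layer (the encoder head, index 0, and the M decoder layers)
is matched one-to-one against a *duplicated* copy of the ground truth: layer
i sees each target w_i times, so up to w_i distinct queries can receive a
positive label for the same object.  The per-layer loss is down-weighted by
1/w_i; the final decoder layer is matched against the plain ground truth:

    L = sum_{i=0}^{M-1} (1/w_i) L_Hungarian(p_i, copy(g, w_i))
        + L_Hungarian(p_M, g)

L_Hungarian combines a sigmoid-focal classification term, an L1 box
regression term and a GIoU term.  With an all-ones schedule the criterion
reduces to the standard per-layer auxiliary-loss sum of DETR-style training.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .autograd import Tensor, no_grad

__all__ = [
    "GroundTruthSet",
    "LayerPredictions",
    "DuplicationSchedule",
    "CostWeights",
    "MatchAssignment",
    "box_cxcywh_to_xyxy",
    "generalized_iou",
    "giou_matrix",
    "pairwise_cost",
    "hungarian_assign",
    "duplicate_targets",
    "hungarian_loss",
    "hhm_loss",
    "MatchProfiler",
]


@dataclass
class GroundTruthSet:
    """Targets of one image: normalized (cx, cy, w, h) boxes and class ids."""

    boxes: np.ndarray     # (G, 4) in [0, 1]
    labels: np.ndarray    # (G,) ints in [0, num_classes)

    def __post_init__(self):
        self.boxes = np.asarray(self.boxes, dtype=np.float32).reshape(-1, 4)
        self.labels = np.asarray(self.labels, dtype=np.int64).reshape(-1)
        if len(self.boxes) != len(self.labels):
            raise ValueError("boxes/labels length mismatch")
        if len(self.boxes):
            if (self.boxes[:, 2:] <= 0).any():
                raise ValueError("ground-truth boxes must have positive w, h")
            if (self.boxes < 0).any() or (self.boxes > 1).any():
                raise ValueError("ground-truth boxes must lie in [0, 1]")

    def __len__(self):
        return len(self.boxes)


@dataclass
class LayerPredictions:
    """One layer's output: K boxes (normalized cxcywh, post-sigmoid) and
    K x num_classes logits.  layer_index 0 denotes the encoder head."""

    boxes: Tensor
    class_logits: Tensor
    layer_index: int = 0

    def __post_init__(self):
        if not isinstance(self.boxes, Tensor):
            self.boxes = Tensor(self.boxes)
        if not isinstance(self.class_logits, Tensor):
            self.class_logits = Tensor(self.class_logits)
        if self.boxes.shape[0] != self.class_logits.shape[0]:
            raise ValueError("boxes/logits query-count mismatch")

    @property
    def num_queries(self) -> int:
        return self.boxes.shape[0]


@dataclass
class DuplicationSchedule:
    """Per-layer ground-truth copy counts w_0..w_{M-1} (encoder head and
    decoder layers 1..M-1); the final decoder layer always matches
    one-to-one."""

    weights: list = field(default_factory=lambda: [12, 10, 8, 6, 4, 2])

    def __post_init__(self):
        self.weights = [int(w) for w in self.weights]
        if any(w < 1 for w in self.weights):
            raise ValueError("duplication counts must all be >= 1")

    def __len__(self):
        return len(self.weights)

    def __getitem__(self, i):
        return self.weights[i]


@dataclass
class CostWeights:
    """Matching-cost / loss-term weights and focal parameters."""

    lambda_class: float = 2.0
    lambda_l1: float = 5.0
    lambda_giou: float = 2.0
    focal_alpha: float = 0.25
    focal_gamma: float = 2.0

    def __post_init__(self):
        lams = (self.lambda_class, self.lambda_l1, self.lambda_giou)
        if any(l < 0 for l in lams):
            raise ValueError("cost weights must be nonnegative")
        if all(l == 0 for l in lams):
            raise ValueError("at least one cost weight must be positive")


@dataclass
class MatchAssignment:
    pairs: list  # of (query_index, target_index)

    def __post_init__(self):
        qs = [q for q, _ in self.pairs]
        ts = [t for _, t in self.pairs]
        if len(set(qs)) != len(qs) or len(set(ts)) != len(ts):
            raise ValueError("assignment indices must be unique")

    def query_indices(self) -> np.ndarray:
        return np.array([q for q, _ in self.pairs], dtype=np.int64)

    def target_indices(self) -> np.ndarray:
        return np.array([t for _, t in self.pairs], dtype=np.int64)


# ---------------------------------------------------------------------------
# Boxes
# ---------------------------------------------------------------------------

def box_cxcywh_to_xyxy(boxes):
    """(..., 4) center format -> corner format; works on Tensors and arrays."""
    if isinstance(boxes, Tensor):
        cx, cy, w, h = (boxes[..., 0], boxes[..., 1], boxes[..., 2], boxes[..., 3])
        from .autograd import stack
        return stack([cx - w * 0.5, cy - h * 0.5, cx + w * 0.5, cy + h * 0.5],
                     axis=-1)
    b = np.asarray(boxes, dtype=np.float32)
    out = np.empty_like(b)
    out[..., 0] = b[..., 0] - b[..., 2] / 2
    out[..., 1] = b[..., 1] - b[..., 3] / 2
    out[..., 2] = b[..., 0] + b[..., 2] / 2
    out[..., 3] = b[..., 1] + b[..., 3] / 2
    return out


def _giou_xyxy(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise GIoU between corner-format box sets a (n,4) and b (m,4)."""
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    lt = np.maximum(a[:, None, :2], b[None, :, :2])
    rb = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.clip(rb - lt, 0, None)
    inter = wh[..., 0] * wh[..., 1]
    union = area_a[:, None] + area_b[None, :] - inter
    iou = inter / union
    lt_c = np.minimum(a[:, None, :2], b[None, :, :2])
    rb_c = np.maximum(a[:, None, 2:], b[None, :, 2:])
    wh_c = rb_c - lt_c
    hull = wh_c[..., 0] * wh_c[..., 1]
    return iou - (hull - union) / hull


def generalized_iou(box_a, box_b) -> float:
    """GIoU of two normalized cxcywh boxes, in [-1, 1]."""
    a = np.asarray(box_a, dtype=np.float32).reshape(4)
    b = np.asarray(box_b, dtype=np.float32).reshape(4)
    if a[2] * a[3] <= 0 or b[2] * b[3] <= 0:
        raise ValueError("degenerate (zero-area) box in generalized_iou")
    return float(_giou_xyxy(box_cxcywh_to_xyxy(a[None]),
                            box_cxcywh_to_xyxy(b[None]))[0, 0])


def giou_matrix(boxes_a, boxes_b) -> np.ndarray:
    """Pairwise GIoU between normalized cxcywh box sets (n,4) x (m,4)."""
    a = np.asarray(boxes_a, dtype=np.float32).reshape(-1, 4)
    b = np.asarray(boxes_b, dtype=np.float32).reshape(-1, 4)
    return _giou_xyxy(box_cxcywh_to_xyxy(a), box_cxcywh_to_xyxy(b))


def _giou_pairs_tensor(pred_xyxy: Tensor, tgt_xyxy: np.ndarray) -> Tensor:
    """Differentiable elementwise GIoU of matched pairs (n,4) vs (n,4)."""
    t = Tensor(tgt_xyxy)
    area_p = (pred_xyxy[:, 2] - pred_xyxy[:, 0]) * (pred_xyxy[:, 3] - pred_xyxy[:, 1])
    area_t = Tensor((tgt_xyxy[:, 2] - tgt_xyxy[:, 0]) * (tgt_xyxy[:, 3] - tgt_xyxy[:, 1]))
    lt_x = Tensor.maximum(pred_xyxy[:, 0], t[:, 0])
    lt_y = Tensor.maximum(pred_xyxy[:, 1], t[:, 1])
    rb_x = Tensor.minimum(pred_xyxy[:, 2], t[:, 2])
    rb_y = Tensor.minimum(pred_xyxy[:, 3], t[:, 3])
    iw = (rb_x - lt_x).clamp_min_const(0.0)
    ih = (rb_y - lt_y).clamp_min_const(0.0)
    inter = iw * ih
    union = area_p + area_t - inter
    iou = inter / union
    cw = Tensor.maximum(pred_xyxy[:, 2], t[:, 2]) - Tensor.minimum(pred_xyxy[:, 0], t[:, 0])
    ch = Tensor.maximum(pred_xyxy[:, 3], t[:, 3]) - Tensor.minimum(pred_xyxy[:, 1], t[:, 1])
    hull = cw * ch
    return iou - (hull - union) / hull


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def _focal_cost_components(logits: np.ndarray, alpha: float, gamma: float):
    p = 1.0 / (1.0 + np.exp(-logits))
    eps = 1e-8
    pos = alpha * (1 - p) ** gamma * (-np.log(p + eps))
    neg = (1 - alpha) * p ** gamma * (-np.log(1 - p + eps))
    return pos, neg


def pairwise_cost(pred: LayerPredictions, gt: GroundTruthSet,
                  weights: CostWeights | None = None) -> np.ndarray:
    """Matching cost matrix (K, G): focal-style class cost + L1 + (-GIoU)."""
    weights = weights or CostWeights()
    if len(gt) == 0:
        return np.zeros((pred.num_queries, 0), dtype=np.float32)
    logits = pred.class_logits.data
    boxes = pred.boxes.data
    pos, neg = _focal_cost_components(logits, weights.focal_alpha,
                                      weights.focal_gamma)
    class_cost = (pos - neg)[:, gt.labels]          # (K, G)
    l1_cost = np.abs(boxes[:, None, :] - gt.boxes[None, :, :]).sum(-1)
    giou_cost = -giou_matrix(boxes, gt.boxes)
    return (weights.lambda_class * class_cost
            + weights.lambda_l1 * l1_cost
            + weights.lambda_giou * giou_cost).astype(np.float32)


def hungarian_assign(cost: np.ndarray) -> MatchAssignment:
    """Minimum-cost one-to-one assignment of min(K, T) pairs."""
    cost = np.asarray(cost)
    if cost.size and not np.isfinite(cost).all():
        raise ValueError("cost matrix contains NaN or inf")
    if 0 in cost.shape:
        return MatchAssignment(pairs=[])
    rows, cols = linear_sum_assignment(cost)
    return MatchAssignment(pairs=list(zip(rows.tolist(), cols.tolist())))


def duplicate_targets(gt: GroundTruthSet, w: int) -> GroundTruthSet:
    """Tile the target set w times: [t0..tG, t0..tG, ...]."""
    if w < 1:
        raise ValueError(f"duplication count must be >= 1, got {w}")
    if len(gt) == 0 or w == 1:
        return GroundTruthSet(gt.boxes.copy(), gt.labels.copy())
    return GroundTruthSet(np.tile(gt.boxes, (w, 1)), np.tile(gt.labels, w))


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def _focal_class_loss(logits: Tensor, gt: GroundTruthSet,
                      assignment: MatchAssignment, weights: CostWeights,
                      norm: float) -> Tensor:
    """Sigmoid focal loss over all queries and classes.

    Matched queries have a one-hot positive at their target's label; all
    other (query, class) cells are negatives (background).  Normalized by
    the target count.
    """
    k, c = logits.shape
    onehot = np.zeros((k, c), dtype=np.float32)
    if assignment.pairs:
        q_idx = assignment.query_indices()
        onehot[q_idx, gt.labels[assignment.target_indices()]] = 1.0
    y = Tensor(onehot)
    p = logits.sigmoid()
    log_p = -(-logits).softplus()          # log sigmoid(x)
    log_1mp = -logits.softplus()           # log (1 - sigmoid(x))
    a, g = weights.focal_alpha, weights.focal_gamma
    pos = (Tensor(1.0) - p) ** g * log_p * (-a)
    neg = p ** g * log_1mp * (-(1.0 - a))
    per_cell = y * pos + (Tensor(np.float32(1.0)) - y) * neg
    return per_cell.sum() * (1.0 / norm)


def hungarian_loss(pred: LayerPredictions, gt: GroundTruthSet,
                   weights: CostWeights | None = None,
                   assignment: MatchAssignment | None = None,
                   norm_count: int | None = None) -> dict:
    """One-to-one Hungarian loss breakdown for one layer.

    Returns dict with Tensor entries ``class``, ``l1``, ``giou``, ``total``
    plus the integer ``num_matched``.  All terms are normalized by
    ``norm_count`` (default: the target count); with empty ground truth only
    the background classification term remains.  When matching against a
    w-fold duplicated target set the caller passes the *original* target
    count, so that the 1/w layer weight exactly cancels the duplication on
    instances where every copy attracts an equally good query.
    """
    weights = weights or CostWeights()
    if assignment is None:
        with no_grad():
            cost = pairwise_cost(pred, gt, weights)
        assignment = hungarian_assign(cost)
    norm = float(max(len(gt) if norm_count is None else norm_count, 1))
    cls = _focal_class_loss(pred.class_logits, gt, assignment, weights, norm)
    if assignment.pairs:
        q_idx = assignment.query_indices()
        t_idx = assignment.target_indices()
        pb = pred.boxes[q_idx]
        tb = gt.boxes[t_idx]
        l1 = (pb - Tensor(tb)).abs().sum() * (1.0 / norm)
        giou_vals = _giou_pairs_tensor(box_cxcywh_to_xyxy(pb),
                                       box_cxcywh_to_xyxy(tb))
        giou = (Tensor(np.ones(len(t_idx), dtype=np.float32)) - giou_vals).sum() \
            * (1.0 / norm)
    else:
        l1 = Tensor(np.float32(0.0))
        giou = Tensor(np.float32(0.0))
    total = (weights.lambda_class * cls + weights.lambda_l1 * l1
             + weights.lambda_giou * giou)
    return {"class": cls, "l1": l1, "giou": giou, "total": total,
            "num_matched": len(assignment.pairs)}


def hhm_loss(all_layers: list, gt: GroundTruthSet,
             schedule: DuplicationSchedule | None = None,
             weights: CostWeights | None = None) -> dict:
    """Hierarchical hybrid loss over encoder head + M decoder layers.

    ``all_layers`` holds M+1 LayerPredictions (index 0 = encoder head).
    Layers 0..M-1 are matched against w_i-fold duplicated targets and
    weighted 1/w_i; the final layer is matched one-to-one at weight 1.
    """
    schedule = schedule or DuplicationSchedule()
    weights = weights or CostWeights()
    m = len(schedule)
    if len(all_layers) != m + 1:
        raise ValueError(
            f"expected {m + 1} prediction layers for a schedule of length {m}, "
            f"got {len(all_layers)}"
        )
    g = len(gt)
    per_layer = []
    total = Tensor(np.float32(0.0))
    for i, pred in enumerate(all_layers):
        if i < m:
            w = schedule[i]
            if g > 0 and w * g > pred.num_queries:
                raise ValueError(
                    f"layer {i}: w_i*G = {w}*{g} exceeds query count "
                    f"{pred.num_queries}; reduce the duplication schedule"
                )
            tgt = duplicate_targets(gt, w) if g else gt
            layer_loss = hungarian_loss(pred, tgt, weights, norm_count=g)
            scale = 1.0 / w
        else:
            layer_loss = hungarian_loss(pred, gt, weights)
            scale = 1.0
        contribution = layer_loss["total"] * scale
        total = total + contribution
        per_layer.append({**layer_loss, "weight": scale,
                          "contribution": contribution})
    return {"total": total, "layers": per_layer}


def _batched_layer_loss(boxes: Tensor, logits: Tensor, targets: list,
                        weights: CostWeights,
                        norm_counts: list | None = None) -> Tensor:
    """Hungarian loss of one layer over a whole batch in a single graph.

    boxes (N, K, 4), logits (N, K, C); ``targets`` is a per-image list of
    (possibly duplicated) GroundTruthSet.  Per-image terms are normalized by
    ``norm_counts`` (default: each image's target count; callers matching
    duplicated targets pass the original counts), then summed over the batch.
    """
    n, k, c = logits.shape
    onehot = np.zeros((n, k, c), dtype=np.float32)
    if norm_counts is None:
        norm_counts = [len(t) for t in targets]
    img_norm = np.array([1.0 / max(g, 1) for g in norm_counts],
                        dtype=np.float32)
    pair_img, pair_q, pair_boxes, pair_w = [], [], [], []
    for i, tgt in enumerate(targets):
        if len(tgt) == 0:
            continue
        with no_grad():
            cost = pairwise_cost(
                LayerPredictions(boxes.data[i], logits.data[i]), tgt, weights)
        a = hungarian_assign(cost)
        q_idx = a.query_indices()
        t_idx = a.target_indices()
        onehot[i, q_idx, tgt.labels[t_idx]] = 1.0
        pair_img.append(np.full(len(q_idx), i))
        pair_q.append(q_idx)
        pair_boxes.append(tgt.boxes[t_idx])
        pair_w.append(np.full(len(q_idx), img_norm[i], dtype=np.float32))
    # focal classification over every query of every image
    y = Tensor(onehot)
    p = logits.sigmoid()
    log_p = -(-logits).softplus()
    log_1mp = -logits.softplus()
    a_f, g_f = weights.focal_alpha, weights.focal_gamma
    pos = (Tensor(np.float32(1.0)) - p) ** g_f * log_p * (-a_f)
    neg = p ** g_f * log_1mp * (-(1.0 - a_f))
    per_cell = y * pos + (Tensor(np.float32(1.0)) - y) * neg
    cls = (per_cell.sum(axis=(1, 2)) * Tensor(img_norm)).sum()
    if not pair_img:
        return weights.lambda_class * cls
    pi = np.concatenate(pair_img)
    pq = np.concatenate(pair_q)
    tb = np.concatenate(pair_boxes).astype(np.float32)
    pw = Tensor(np.concatenate(pair_w))
    pb = boxes[pi, pq]                                   # (M, 4)
    l1 = ((pb - Tensor(tb)).abs().sum(axis=-1) * pw).sum()
    giou_vals = _giou_pairs_tensor(box_cxcywh_to_xyxy(pb),
                                   box_cxcywh_to_xyxy(tb))
    giou = ((Tensor(np.ones(len(tb), dtype=np.float32)) - giou_vals) * pw).sum()
    return (weights.lambda_class * cls + weights.lambda_l1 * l1
            + weights.lambda_giou * giou)


def hhm_loss_batched(all_layers: list, gts: list,
                     schedule: DuplicationSchedule | None = None,
                     weights: CostWeights | None = None,
                     return_breakdown: bool = False):
    """Batched hierarchical hybrid loss.

    ``all_layers``: M+1 LayerPredictions with batched (N, K, .) tensors;
    ``gts``: N GroundTruthSet.  Returns the summed scalar loss Tensor
    (identical to summing :func:`hhm_loss` over images, but built as one
    compact graph); with ``return_breakdown`` also the per-layer weighted
    contributions as floats.
    """
    schedule = schedule or DuplicationSchedule()
    weights = weights or CostWeights()
    m = len(schedule)
    if len(all_layers) != m + 1:
        raise ValueError("layer count does not match schedule length + 1")
    total = None
    breakdown = []
    for i, layer in enumerate(all_layers):
        k = layer.boxes.shape[1]
        if i < m:
            w = schedule[i]
            for g in gts:
                if len(g) and w * len(g) > k:
                    raise ValueError(
                        f"layer {i}: w_i*G = {w}*{len(g)} exceeds query "
                        f"count {k}; reduce the duplication schedule")
            targets = [duplicate_targets(g, w) for g in gts]
            scale = 1.0 / w
        else:
            targets = gts
            scale = 1.0
        term = _batched_layer_loss(layer.boxes, layer.class_logits,
                                   targets, weights,
                                   norm_counts=[len(g) for g in gts]) * scale
        breakdown.append(term.item())
        total = term if total is None else total + term
    if return_breakdown:
        return total, breakdown
    return total


class MatchProfiler:
    """Collects wall-clock time per Hungarian match; reports mean +/- sd ms."""

    def __init__(self):
        self.times_ms: list[float] = []

    def assign(self, cost: np.ndarray) -> MatchAssignment:
        t0 = time.perf_counter()
        out = hungarian_assign(cost)
        self.times_ms.append((time.perf_counter() - t0) * 1e3)
        return out

    def summary(self) -> dict:
        arr = np.array(self.times_ms) if self.times_ms else np.zeros(1)
        return {"mean_ms": float(arr.mean()), "sd_ms": float(arr.std(ddof=1))
                if len(arr) > 1 else 0.0, "n": len(self.times_ms)}
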