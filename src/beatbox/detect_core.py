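"""Numeric core of the two-stage (cascade) object detector.

Standalone, framework-free implementations of everything around the CNN:
anchor generation (1 scale × 3 aspect ratios per position), IoU,
center-size box encoding/decoding against anchors, smooth-L1 regression
and cross-entropy classification losses, cascade foreground/background
assignment under increasing IoU thresholds, 1:3 foreground:background
proposal sampling, greedy NMS, and the single-survivor cross-category
NMS variant used at inference (heartbeat objects never overlap, so at
most one detection may survive per overlapping cluster).

Corner boxes are half-open ``[min, max)`` arrays ``(N, 4)`` of
``xmin, ymin, xmax, ymax`` in pixel units; conversion to/from the VOC
1-based inclusive dialect happens at I/O.  Box deltas use the natural
logarithm for the width/height channels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "CascadeConfig",
    "Detection",
    "iou",
    "iou_matrix",
    "corner_to_center",
    "center_to_corner",
    "encode",
    "decode",
    "smooth_l1",
    "reg_loss",
    "cls_loss",
    "assign",
    "sample_proposals",
    "gen_anchors",
    "nms",
    "final_beat_nms",
    "stage_loss",
    "total_loss",
    "dump_detections",
    "load_detections",
]


@dataclass(frozen=True)
class CascadeConfig:
    """Hyper-parameters of the cascade pipeline (defaults as trained).

    Three detection stages with strictly increasing IoU thresholds;
    RPN-style NMS at 0.7 producing 2,000 proposals for training and
    1,000 for inference; 512 proposals sampled per step at a 1:3
    foreground:background ratio; anchors with one scale and three
    aspect ratios (k = 3 per position).  λ balances classification and
    regression loss.
    """

    iou_thresholds: tuple[float, ...] = (0.5, 0.6, 0.7)
    lam: float = 1.0
    nms_threshold: float = 0.7
    n_train_proposals: int = 2000
    n_infer_proposals: int = 1000
    n_samples: int = 512
    fg_fraction: float = 0.25
    anchor_scale: float = 64.0
    anchor_ratios: tuple[float, ...] = (0.5, 1.0, 2.0)

    def __post_init__(self) -> None:
        if list(self.iou_thresholds) != sorted(self.iou_thresholds):
            raise ValueError("cascade IoU thresholds must be increasing")

    @property
    def k(self) -> int:
        """Anchors per feature-map position."""
        return len(self.anchor_ratios)


@dataclass(frozen=True)
class Detection:
    """One scored, classed box (corner form)."""

    box: tuple[float, float, float, float]
    class12: str
    score: float
    image: str | None = None


# -- geometry ----------------------------------------------------------

def _areas(boxes: np.ndarray) -> np.ndarray:
    w = boxes[:, 2] - boxes[:, 0]
    h = boxes[:, 3] - boxes[:, 1]
    if np.any(w <= 0) or np.any(h <= 0):
        raise ValueError("degenerate (non-positive area) box")
    return w * h


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between corner-box arrays a (N,4) and b (M,4)."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    area_a = _areas(a)[:, None]
    area_b = _areas(b)[None, :]
    lt = np.maximum(a[:, None, :2], b[None, :, :2])
    rb = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.clip(rb - lt, 0.0, None)
    inter = wh[..., 0] * wh[..., 1]
    return inter / (area_a + area_b - inter)


def iou(a, b) -> float:
    """IoU (intersection area over union area) of two corner boxes."""
    return float(iou_matrix(np.asarray(a), np.asarray(b))[0, 0])


def corner_to_center(boxes: np.ndarray) -> np.ndarray:
    """(xmin, ymin, xmax, ymax) → (x, y, w, h) with (x, y) the centre."""
    boxes = np.atleast_2d(np.asarray(boxes, dtype=float))
    out = np.empty_like(boxes)
    out[:, 0] = (boxes[:, 0] + boxes[:, 2]) / 2
    out[:, 1] = (boxes[:, 1] + boxes[:, 3]) / 2
    out[:, 2] = boxes[:, 2] - boxes[:, 0]
    out[:, 3] = boxes[:, 3] - boxes[:, 1]
    return out


def center_to_corner(boxes: np.ndarray) -> np.ndarray:
    boxes = np.atleast_2d(np.asarray(boxes, dtype=float))
    out = np.empty_like(boxes)
    out[:, 0] = boxes[:, 0] - boxes[:, 2] / 2
    out[:, 1] = boxes[:, 1] - boxes[:, 3] / 2
    out[:, 2] = boxes[:, 0] + boxes[:, 2] / 2
    out[:, 3] = boxes[:, 1] + boxes[:, 3] / 2
    return out


def encode(box: np.ndarray, anchor: np.ndarray) -> np.ndarray:
    """Encode center-size boxes against anchors.

    t_x = (x − x_a)/w_a, t_y = (y − y_a)/h_a,
    t_w = ln(w/w_a),     t_h = ln(h/h_a).
    """
    box = np.atleast_2d(np.asarray(box, dtype=float))
    anchor = np.broadcast_to(
        np.atleast_2d(np.asarray(anchor, dtype=float)), box.shape
    )
    if np.any(box[:, 2:] <= 0) or np.any(anchor[:, 2:] <= 0):
        raise ValueError("box and anchor sizes must be positive")
    t = np.empty_like(box)
    t[:, 0] = (box[:, 0] - anchor[:, 0]) / anchor[:, 2]
    t[:, 1] = (box[:, 1] - anchor[:, 1]) / anchor[:, 3]
    t[:, 2] = np.log(box[:, 2] / anchor[:, 2])
    t[:, 3] = np.log(box[:, 3] / anchor[:, 3])
    return t


def decode(delta: np.ndarray, anchor: np.ndarray) -> np.ndarray:
    """Exact inverse of :func:`encode` (center-size form)."""
    delta = np.atleast_2d(np.asarray(delta, dtype=float))
    anchor = np.broadcast_to(
        np.atleast_2d(np.asarray(anchor, dtype=float)), delta.shape
    )
    box = np.empty_like(delta)
    box[:, 0] = delta[:, 0] * anchor[:, 2] + anchor[:, 0]
    box[:, 1] = delta[:, 1] * anchor[:, 3] + anchor[:, 1]
    box[:, 2] = anchor[:, 2] * np.exp(delta[:, 2])
    box[:, 3] = anchor[:, 3] * np.exp(delta[:, 3])
    return box


# -- losses ------------------------------------------------------------

def smooth_l1(x):
    """0.5·x² for |x| < 1, |x| − 0.5 otherwise (continuous at |x| = 1)."""
    x = np.abs(np.asarray(x, dtype=float))
    return np.where(x < 1.0, 0.5 * x * x, x - 0.5)


def reg_loss(t: np.ndarray, t_star: np.ndarray) -> float:
    """Smooth-L1 regression loss summed over the four delta channels."""
    t = np.asarray(t, dtype=float).reshape(-1)
    t_star = np.asarray(t_star, dtype=float).reshape(-1)
    if t.shape != t_star.shape:
        raise ValueError("delta shapes differ")
    return float(np.sum(smooth_l1(t - t_star)))


def cls_loss(p: np.ndarray, c: int, eps: float = 1e-12) -> float:
    """Cross entropy −log p_c; class 0 is background.

    Probabilities are clamped at ``eps`` so a (numerically) zero
    probability yields a large finite loss rather than infinity.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or not 0 <= c < p.size:
        raise ValueError("p must be a probability vector containing class c")
    if np.any(p < -1e-9) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("p must be a probability vector (non-negative, sum 1)")
    return float(-np.log(max(p[c], eps)))


# -- assignment & sampling ---------------------------------------------

@dataclass
class Proposal:
    """A proposal after foreground/background assignment."""

    box: np.ndarray  # corner form (4,)
    is_foreground: bool
    matched_gt: int | None  # index into the ground-truth list
    p_star: int = field(init=False)

    def __post_init__(self) -> None:
        if self.is_foreground != (self.matched_gt is not None):
            raise ValueError("foreground iff matched to a ground truth")
        self.p_star = int(self.is_foreground)


def assign(
    proposals: np.ndarray, gts: np.ndarray, iou_thres: float
) -> list[Proposal]:
    """Label proposals foreground/background at one cascade stage.

    Foreground = the max-IoU proposal of each ground truth (so every gt
    keeps at least one positive, matched to that gt) plus every proposal
    whose best IoU exceeds ``iou_thres``, matched to its max-IoU ground
    truth.  Everything else is background.
    """
    if not 0 < iou_thres < 1:
        raise ValueError("iou_thres must lie in (0, 1)")
    proposals = np.atleast_2d(np.asarray(proposals, dtype=float))
    if proposals.size == 0:
        return []
    if gts is None or np.asarray(gts).size == 0:
        return [Proposal(p, False, None) for p in proposals]
    gts = np.atleast_2d(np.asarray(gts, dtype=float))
    m = iou_matrix(proposals, gts)
    best_gt = np.argmax(m, axis=1)
    best_iou = m[np.arange(len(proposals)), best_gt]
    fg = best_iou > iou_thres
    # per-gt argmax proposals become foreground for that gt, even below
    # the threshold — the cascade must keep a positive for every object
    for g, p_idx in enumerate(np.argmax(m, axis=0)):
        fg[p_idx] = True
        best_gt[p_idx] = g
    return [
        Proposal(p, bool(f), int(g) if f else None)
        for p, f, g in zip(proposals, fg, best_gt)
    ]


def sample_proposals(
    assigned: list[Proposal],
    n: int = 512,
    fg_fraction: float = 0.25,
    seed: int | None = None,
) -> list[Proposal]:
    """Sample a training minibatch at the 1:3 foreground:background ratio.

    At most ``round(n·fg_fraction)`` foregrounds (128 of 512); the rest
    background; a deficit in either pool is filled from the other.
    Deterministic given the seed.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not assigned:
        raise ValueError("cannot sample from an empty proposal pool")
    rng = np.random.default_rng(seed)
    fg_idx = [i for i, p in enumerate(assigned) if p.is_foreground]
    bg_idx = [i for i, p in enumerate(assigned) if not p.is_foreground]
    n_fg = min(len(fg_idx), int(round(n * fg_fraction)))
    n_bg = min(len(bg_idx), n - n_fg)
    if n_fg + n_bg < n:  # deficit: top up from the other pool
        n_fg = min(len(fg_idx), n - n_bg)
    take_fg = rng.choice(len(fg_idx), size=n_fg, replace=False) if n_fg else []
    take_bg = rng.choice(len(bg_idx), size=n_bg, replace=False) if n_bg else []
    chosen = sorted(
        [fg_idx[i] for i in np.sort(np.asarray(take_fg, dtype=int))]
        + [bg_idx[i] for i in np.sort(np.asarray(take_bg, dtype=int))]
    )
    return [assigned[i] for i in chosen]


def gen_anchors(
    grid_h: int,
    grid_w: int,
    stride: float,
    scale: float = 64.0,
    ratios: tuple[float, ...] = (0.5, 1.0, 2.0),
) -> np.ndarray:
    """Anchors for a feature grid: k = len(ratios) per position.

    All anchors at a position share its centre; at fixed scale the three
    aspect ratios have equal area scale² (ratio = h/w, so w = scale/√r,
    h = scale·√r).  Returns corner boxes (grid_h·grid_w·k, 4).
    """
    ratios = np.asarray(ratios, dtype=float)
    ws = scale / np.sqrt(ratios)
    hs = scale * np.sqrt(ratios)
    cy, cx = np.meshgrid(
        (np.arange(grid_h) + 0.5) * stride,
        (np.arange(grid_w) + 0.5) * stride,
        indexing="ij",
    )
    centers = np.stack([cx.ravel(), cy.ravel()], axis=1)  # (P, 2)
    out = np.empty((centers.shape[0], ratios.size, 4))
    out[:, :, 0] = centers[:, None, 0] - ws[None, :] / 2
    out[:, :, 1] = centers[:, None, 1] - hs[None, :] / 2
    out[:, :, 2] = centers[:, None, 0] + ws[None, :] / 2
    out[:, :, 3] = centers[:, None, 1] + hs[None, :] / 2
    return out.reshape(-1, 4)


# -- non-maximum suppression -------------------------------------------

def nms(boxes: np.ndarray, scores: np.ndarray, thresh: float = 0.7) -> list[int]:
    """Greedy NMS; returns kept indices in descending score order.

    Score ties break toward the lower index.
    """
    boxes = np.atleast_2d(np.asarray(boxes, dtype=float))
    scores = np.asarray(scores, dtype=float)
    if boxes.shape[0] != scores.shape[0]:
        raise ValueError("boxes and scores must have equal length")
    if boxes.shape[0] == 0:
        return []
    order = np.argsort(-scores, kind="stable")
    keep: list[int] = []
    alive = np.ones(len(scores), dtype=bool)
    m = iou_matrix(boxes, boxes)
    for i in order:
        if not alive[i]:
            continue
        keep.append(int(i))
        alive &= ~(m[i] > thresh)
    return keep


def final_beat_nms(
    detections: list[Detection], overlap_thresh: float = 0.0
) -> list[Detection]:
    """Cross-category suppression for non-overlapping heartbeat objects.

    Greedy like :func:`nms` but class-agnostic: the top-scoring box
    suppresses overlapping boxes of *any* category.  With the default
    threshold 0, any positive overlap suppresses, so exactly one
    detection survives per overlapping cluster (the single-survivor
    variant); pass the RPN threshold (e.g. 0.7) for the conventional
    variant.  Runs per image when detections carry image keys.
    Idempotent.
    """
    if not detections:
        return []
    keys = {d.image for d in detections}
    if len(keys) > 1:
        out: list[Detection] = []
        for key in sorted(keys, key=str):
            out.extend(final_beat_nms(
                [d for d in detections if d.image == key], overlap_thresh
            ))
        return out
    boxes = np.array([d.box for d in detections], dtype=float)
    scores = np.array([d.score for d in detections], dtype=float)
    keep = nms(boxes, scores, thresh=overlap_thresh)
    return [detections[i] for i in keep]


# -- losses per stage --------------------------------------------------

def stage_loss(
    cls_probs: np.ndarray,
    labels: np.ndarray,
    deltas: np.ndarray,
    target_deltas: np.ndarray,
    p_star: np.ndarray,
    lam: float = 1.0,
) -> float:
    """One cascade stage: Σ cls loss + λ Σ p*·reg loss.

    ``labels`` are true class ids (0 = background); regression is
    counted only for foreground samples (p* = 1).
    """
    cls_probs = np.atleast_2d(np.asarray(cls_probs, dtype=float))
    labels = np.asarray(labels, dtype=int)
    p_star = np.asarray(p_star, dtype=int)
    total = 0.0
    for p, c in zip(cls_probs, labels):
        total += cls_loss(p, int(c))
    for t, ts, ps in zip(
        np.atleast_2d(deltas), np.atleast_2d(target_deltas), p_star
    ):
        if ps:
            total += lam * reg_loss(t, ts)
    return float(total)


def total_loss(stage_losses) -> float:
    """Total training loss: the sum over the cascade stages."""
    return float(np.sum(np.asarray(list(stage_losses), dtype=float)))


# -- detection dumps ---------------------------------------------------

def dump_detections(dets: list[Detection], path: str | Path) -> None:
    """Write detections as JSON lines (image, class, score, corners)."""
    with open(path, "w") as fh:
        for d in dets:
            xmin, ymin, xmax, ymax = d.box
            fh.write(json.dumps({
                "image": d.image, "class": d.class12, "score": d.score,
                "xmin": xmin, "ymin": ymin, "xmax": xmax, "ymax": ymax,
            }) + "\n")


def load_detections(path: str | Path) -> list[Detection]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        rec = json.loads(line)
        out.append(Detection(
            (rec["xmin"], rec["ymin"], rec["xmax"], rec["ymax"]),
            rec["class"], rec["score"], rec.get("image"),
        ))
    return out
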