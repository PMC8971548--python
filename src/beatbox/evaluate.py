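"""Beat-level evaluation of QRS detections.

Detections are matched one-to-one to ground-truth boxes at IoU ≥ 0.5 in
descending score order.  Every ground-truth beat becomes one evaluation
item whose predicted class is its matched detection's class (or a miss);
unmatched detections become false-positive items.  From these items the
module builds one-vs-rest confusion counts per class and derives

    Acc = (TP + TN) / (TP + FN + FP + TN)
    Sen = TP / (TP + FN)
    Spe = TN / (TN + FP)

with unweighted (macro) averages across classes, and score-ranked
precision–recall curves giving per-class AP and mAP@0.5 (all-points
interpolation by default, 11-point optional).

Reports emit percentages with two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detect_core import Detection, iou_matrix

__all__ = [
    "MatchedBeat",
    "EvalCounts",
    "EvalReport",
    "match_detections",
    "confusion_counts",
    "metrics",
    "macro_average",
    "ap_map",
    "REFERENCE_PER_CLASS_METRICS",
]


@dataclass(frozen=True)
class MatchedBeat:
    """One evaluation item after detection↔truth matching.

    true_class is None for a spurious detection with no ground truth;
    pred_class is None for a missed ground truth.
    """

    true_class: str | None
    pred_class: str | None
    score: float | None
    iou: float | None


@dataclass
class EvalCounts:
    """One-vs-rest TP/TN/FP/FN per class over a fixed item set."""

    per_class: dict[str, dict[str, int]] = field(default_factory=dict)

    def total(self, cls: str) -> int:
        c = self.per_class[cls]
        return c["TP"] + c["TN"] + c["FP"] + c["FN"]


def _as_gt_array(gt_boxes, n: int) -> np.ndarray:
    gt_boxes = np.atleast_2d(np.asarray(gt_boxes, dtype=float)) \
        if n else np.zeros((0, 4))
    if gt_boxes.shape[0] != n:
        raise ValueError("gt_boxes and gt_classes must have equal length")
    return gt_boxes


def _match_one_group(
    dets: list[Detection],
    gt_boxes: np.ndarray,
    gt_classes: list[str],
    iou_min: float,
) -> list[MatchedBeat]:
    taken = np.zeros(len(gt_classes), dtype=bool)
    matched_gt: dict[int, tuple[Detection, float]] = {}
    leftovers: list[Detection] = []
    order = np.argsort([-d.score for d in dets], kind="stable")
    if len(gt_classes):
        for i in order:
            d = dets[i]
            ious = iou_matrix(np.asarray(d.box), gt_boxes)[0]
            ious = np.where(taken, -1.0, ious)
            j = int(np.argmax(ious))
            if ious[j] >= iou_min:
                taken[j] = True
                matched_gt[j] = (d, float(ious[j]))
            else:
                leftovers.append(d)
    else:
        leftovers = [dets[i] for i in order]

    items: list[MatchedBeat] = []
    for j, cls in enumerate(gt_classes):
        if j in matched_gt:
            d, ov = matched_gt[j]
            items.append(MatchedBeat(cls, d.class12, d.score, ov))
        else:
            items.append(MatchedBeat(cls, None, None, None))
    for d in leftovers:
        items.append(MatchedBeat(None, d.class12, d.score, None))
    return items


def match_detections(
    dets: list[Detection],
    gt_boxes: np.ndarray,
    gt_classes: list[str],
    iou_min: float = 0.5,
    gt_images: list | None = None,
) -> list[MatchedBeat]:
    """Greedy one-to-one matching of detections to ground truths.

    Detections are visited in descending score order; each claims its
    highest-IoU unmatched ground truth with IoU ≥ ``iou_min``
    (class-agnostic, so a wrong-class hit still consumes the beat and
    records the misclassification).  Unmatched detections and unmatched
    ground truths both produce items.

    When detections carry an ``image`` key and ``gt_images`` labels each
    ground truth with its image, matching runs independently per image
    (boxes from different images never compete).
    """
    gt_boxes = _as_gt_array(gt_boxes, len(gt_classes))
    if gt_images is None and all(d.image is None for d in dets):
        return _match_one_group(dets, gt_boxes, gt_classes, iou_min)
    gt_keys = list(gt_images) if gt_images is not None \
        else [None] * len(gt_classes)
    if len(gt_keys) != len(gt_classes):
        raise ValueError("gt_images and gt_classes must have equal length")
    det_keys = [d.image for d in dets]
    items: list[MatchedBeat] = []
    for key in sorted({*det_keys, *gt_keys}, key=str):
        d_sub = [d for d, k in zip(dets, det_keys) if k == key]
        g_idx = [i for i, k in enumerate(gt_keys) if k == key]
        items.extend(_match_one_group(
            d_sub, gt_boxes[g_idx], [gt_classes[i] for i in g_idx], iou_min
        ))
    return items


def confusion_counts(items: list[MatchedBeat], classes: list[str]) -> EvalCounts:
    """One-vs-rest TP/TN/FP/FN per class from matched items.

    The item set (ground-truth beats plus spurious detections) is fixed
    across classes, so TP+TN+FP+FN is identical for every class and the
    per-class TPs sum to the number of correctly classified beats.
    """
    counts = EvalCounts()
    for cls in classes:
        tp = sum(1 for m in items if m.true_class == cls and m.pred_class == cls)
        fn = sum(1 for m in items if m.true_class == cls and m.pred_class != cls)
        fp = sum(1 for m in items if m.true_class != cls and m.pred_class == cls)
        tn = len(items) - tp - fn - fp
        counts.per_class[cls] = {"TP": tp, "TN": tn, "FP": fp, "FN": fn}
    return counts


def macro_average(values) -> float:
    """Unweighted mean across classes (NaN values excluded)."""
    values = np.asarray(list(values), dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        raise ValueError("no finite per-class values to average")
    return float(np.mean(finite))


@dataclass
class EvalReport:
    """Per-class Acc/Sen/Spe in percent plus macro averages."""

    table: pd.DataFrame  # index: class; columns Acc, Sen, Spe (%)
    macro_acc: float
    macro_sen: float
    macro_spe: float
    undefined: list[tuple[str, str]] = field(default_factory=list)

    def __str__(self) -> str:
        t = self.table.round(2)
        t.loc["Average"] = [self.macro_acc, self.macro_sen, self.macro_spe]
        return t.round(2).to_string()


def metrics(counts: EvalCounts) -> EvalReport:
    """Acc/Sen/Spe (%) per class with macro averages.

    A zero denominator flags the metric as undefined (NaN, listed in
    ``report.undefined``) rather than silently reporting 0.
    """
    rows = {}
    undefined: list[tuple[str, str]] = []
    for cls, c in counts.per_class.items():
        n = c["TP"] + c["TN"] + c["FP"] + c["FN"]
        acc = 100.0 * (c["TP"] + c["TN"]) / n if n else np.nan
        if c["TP"] + c["FN"]:
            sen = 100.0 * c["TP"] / (c["TP"] + c["FN"])
        else:
            sen = np.nan
            undefined.append((cls, "Sen"))
        if c["TN"] + c["FP"]:
            spe = 100.0 * c["TN"] / (c["TN"] + c["FP"])
        else:
            spe = np.nan
            undefined.append((cls, "Spe"))
        if not n:
            undefined.append((cls, "Acc"))
        rows[cls] = {"Acc": acc, "Sen": sen, "Spe": spe}
    table = pd.DataFrame.from_dict(rows, orient="index")

    def _macro(col):
        finite = table[col][np.isfinite(table[col])]
        return float(finite.mean()) if len(finite) else float("nan")

    return EvalReport(
        table, _macro("Acc"), _macro("Sen"), _macro("Spe"), undefined,
    )


def _ap_from_flags(flags: np.ndarray, n_gts: int, interpolation: str) -> float:
    """AP from score-ranked TP(1)/FP(0) flags against n_gts ground truths."""
    if n_gts == 0:
        return np.nan
    tp = np.cumsum(flags)
    fp = np.cumsum(1 - flags)
    recall = tp / n_gts
    precision = tp / (tp + fp)
    if interpolation == "all-points":
        # area under the step PR curve with precision envelope
        mrec = np.concatenate([[0.0], recall, [recall[-1] if len(recall) else 0.0]])
        mpre = np.concatenate([[0.0], precision, [0.0]])
        for i in range(len(mpre) - 2, -1, -1):
            mpre[i] = max(mpre[i], mpre[i + 1])
        changed = np.where(mrec[1:] != mrec[:-1])[0]
        return float(np.sum((mrec[changed + 1] - mrec[changed]) * mpre[changed + 1]))
    if interpolation == "11-point":
        ap = 0.0
        for r in np.linspace(0, 1, 11):
            mask = recall >= r
            ap += float(np.max(precision[mask])) if np.any(mask) else 0.0
        return ap / 11.0
    raise ValueError(f"unknown interpolation {interpolation!r}")


def ap_map(
    dets: list[Detection],
    gt_boxes: np.ndarray,
    gt_classes: list[str],
    iou_min: float = 0.5,
    interpolation: str = "all-points",
    gt_images: list | None = None,
) -> tuple[pd.DataFrame, float]:
    """Per-class gts/dets/recall/AP table and mAP@``iou_min``.

    Matching is per class (a detection can only claim a same-class
    ground truth for AP purposes) and, when image keys are present, per
    image; TP/FP flags are then pooled across images in score order.
    Classes with zero ground truths are excluded from the mAP mean and
    flagged with NaN AP.
    """
    gt_boxes = _as_gt_array(gt_boxes, len(gt_classes))
    gt_keys = list(gt_images) if gt_images is not None \
        else [None] * len(gt_classes)
    classes = sorted(set(gt_classes) | {d.class12 for d in dets})
    rows = {}
    for cls in classes:
        cls_dets = sorted(
            (d for d in dets if d.class12 == cls),
            key=lambda d: -d.score,
        )
        scored_flags: list[tuple[float, int]] = []
        n_gts = sum(1 for c in gt_classes if c == cls)
        n_matched = 0
        keys = sorted(
            {d.image for d in cls_dets}
            | {k for k, c in zip(gt_keys, gt_classes) if c == cls},
            key=str,
        )
        for key in keys:
            cls_gt = np.array(
                [i for i, (c, k) in enumerate(zip(gt_classes, gt_keys))
                 if c == cls and k == key],
                dtype=int,
            )
            img_dets = [d for d in cls_dets if d.image == key]
            taken = np.zeros(len(cls_gt), dtype=bool)
            for d in img_dets:
                flag = 0
                if len(cls_gt):
                    ious = iou_matrix(np.asarray(d.box), gt_boxes[cls_gt])[0]
                    ious = np.where(taken, -1.0, ious)
                    j = int(np.argmax(ious))
                    if ious[j] >= iou_min:
                        taken[j] = True
                        flag = 1
                scored_flags.append((d.score, flag))
            n_matched += int(taken.sum())
        scored_flags.sort(key=lambda t: -t[0])
        flags = np.array([f for _, f in scored_flags], dtype=int)
        ap = _ap_from_flags(flags, n_gts, interpolation) if len(cls_dets) \
            else (0.0 if n_gts else np.nan)
        recall = 100.0 * n_matched / n_gts if n_gts else np.nan
        rows[cls] = {
            "gts": n_gts,
            "dets": len(cls_dets),
            "recall": recall,
            "AP": 100.0 * ap if np.isfinite(ap) else np.nan,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    with_gts = table["AP"][table["gts"] > 0]
    m_ap = float(np.mean(with_gts)) if len(with_gts) else np.nan
    return table, m_ap


#: Published per-class testing-set results of a 12-class beat-level QRS
#: detector on MIT-BIH (Acc, Sen, Spe in percent).  Kept as reference
#: input for validating the macro-averaging conventions of this module;
#: this package does not train that detector.
REFERENCE_PER_CLASS_METRICS = pd.DataFrame.from_dict(
    {
        "N": {"Acc": 99.19, "Sen": 93.52, "Spe": 99.70},
        "L": {"Acc": 99.94, "Sen": 99.60, "Spe": 99.97},
        "R": {"Acc": 99.47, "Sen": 96.20, "Spe": 99.77},
        "e": {"Acc": 99.92, "Sen": 99.90, "Spe": 99.92},
        "j": {"Acc": 99.47, "Sen": 96.99, "Spe": 99.70},
        "A": {"Acc": 98.87, "Sen": 93.14, "Spe": 99.36},
        "a": {"Acc": 99.87, "Sen": 99.07, "Spe": 99.94},
        "J": {"Acc": 99.68, "Sen": 98.23, "Spe": 99.81},
        "S": {"Acc": 99.81, "Sen": 99.81, "Spe": 99.81},
        "V": {"Acc": 99.49, "Sen": 96.59, "Spe": 99.75},
        "E": {"Acc": 99.98, "Sen": 99.90, "Spe": 99.98},
        "F": {"Acc": 99.50, "Sen": 97.77, "Spe": 99.66},
    },
    orient="index",
)
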