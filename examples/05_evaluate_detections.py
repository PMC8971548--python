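"""Score a set of beat detections against ground truth.

Builds a small ground-truth set, corrupts a few detections (one missed
beat, one misclassified beat, one spurious box), and prints the
per-class Acc/Sen/Spe report plus the recall/AP/mAP table.
"""

import numpy as np

from beatbox import evaluate as ev
from beatbox.detect_core import Detection

gt_boxes = np.array([[i * 120.0, 50, i * 120 + 80, 400] for i in range(8)])
gt_classes = ["N", "N", "V", "N", "L", "V", "N", "L"]

dets = [
    Detection(tuple(b), c, 0.9, "img0")
    for b, c in zip(gt_boxes[:6], gt_classes[:6])
]
dets[2] = Detection(tuple(gt_boxes[2]), "N", 0.8, "img0")     # V mislabeled N
dets.append(Detection((900.0, 50, 980, 400), "V", 0.7, "img0"))  # spurious
# beat 6 (N) and beat 7 (L) have no detection at all: misses

items = ev.match_detections(dets, gt_boxes, gt_classes,
                            gt_images=["img0"] * len(gt_classes))
counts = ev.confusion_counts(items, ["N", "L", "V"])
report = ev.metrics(counts)
print(report)

table, m_ap = ev.ap_map(dets, gt_boxes, gt_classes,
                        gt_images=["img0"] * len(gt_classes))
print()
print(table.round(1).to_string())
print(f"mAP@0.5: {m_ap:.1f}")
# Sen drops for classes with missed or mislabeled beats; the spurious V
# box costs V precision (AP) but not sensitivity.
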