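"""Walk through the detector's numeric core on a toy configuration.

Generates anchors on a small feature grid, encodes a ground-truth box,
assigns and samples proposals under the cascade thresholds, and runs
both NMS variants.
"""

import numpy as np

from beatbox import detect_core as dc

cfg = dc.CascadeConfig()
print("cascade IoU thresholds:", cfg.iou_thresholds, "| k =", cfg.k,
      "anchors/position | sample", cfg.n_samples, "at fg:bg 1:3")

anchors = dc.gen_anchors(8, 8, stride=32, scale=cfg.anchor_scale,
                         ratios=cfg.anchor_ratios)
print("anchors:", anchors.shape[0])

gt = np.array([[100.0, 90, 180, 170]])  # one 80x80 QRS box
delta = dc.encode(dc.corner_to_center(gt), dc.corner_to_center(anchors[10]))
print("encoded (tx,ty,tw,th) vs anchor 10:", np.round(delta[0], 3))

rng = np.random.default_rng(0)
jitter = rng.normal(0, 25, size=(600, 4))
proposals = np.clip(gt + jitter, 0, None)
proposals[:, 2:] = np.maximum(proposals[:, 2:], proposals[:, :2] + 1)
for th in cfg.iou_thresholds:
    assigned = dc.assign(proposals, gt, th)
    n_fg = sum(p.is_foreground for p in assigned)
    print(f"IoU_thres {th}: {n_fg} foreground of {len(assigned)}")

assigned = dc.assign(proposals, gt, 0.5)
batch = dc.sample_proposals(assigned, n=cfg.n_samples,
                            fg_fraction=cfg.fg_fraction, seed=1)
print("sampled:", len(batch), "with",
      sum(p.is_foreground for p in batch), "foreground")

dets = [
    dc.Detection((100, 90, 180, 170), "V", 0.95),
    dc.Detection((105, 92, 182, 168), "N", 0.90),  # overlapping rival
    dc.Detection((300, 90, 380, 170), "N", 0.85),  # separate beat
]
final = dc.final_beat_nms(dets)
print("final detections:", [(d.class12, d.score) for d in final])
# The foreground pool shrinks as the cascade threshold rises; the final
# single-survivor NMS keeps exactly one box per overlapping cluster.
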