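# beatbox

Beat-level ECG interpretation treated as an object-detection problem.

Long-term ECG monitoring produces far more beats than cardiologists can
read. A productive framing is to stop detecting R peaks and classifying
beats as two separate steps: render the signal as an image, draw a
bounding box around every QRS complex, and let an object detector
localize *and* classify each beat in one pass. `beatbox` implements the
full data side of that pipeline and the detector's numeric core, for
researchers working with MIT-BIH-style WFDB records (lead MLII, 360 Hz)
or with fully synthetic records generated in-package:

- **Preprocessing** — 10th-order Butterworth low-pass at 45 Hz
  (zero-phase) against mains interference, plus baseline-wander removal
  by subtracting a running median of width fs/2 computed on
  endpoint-replicated padding.
- **Automatic QRS annotation** — with the annotated R peak as
  reference, Q and S are located from the scale-1 wavelet detail: the
  modulus minimum before R (the Q→R upstroke) and the modulus maximum
  after R (the R→S downstroke), each refined to the adjacent
  zero-crossing where the smoothed derivative vanishes — the trough
  itself. The QRS box is then `[Q, S] × [min(Q,S) amplitude, R
  amplitude]`.
- **Dataset construction** — deterministic rendering of signal windows
  to beat images, exact signal→pixel affine transforms, VOC XML
  annotation files, translate/resize augmentation that moves boxes with
  pixels, and stratified 8:2 train/test manifests.
- **Detector core** — anchors (1 scale × 3 aspect ratios), IoU,
  center-size box encoding `t_x=(x−x_a)/w_a, t_w=ln(w/w_a)`, smooth-L1
  regression and cross-entropy classification losses, per-stage loss
  `L_s = Σ L_cls + λ Σ p* L_reg`, cascade foreground/background
  assignment under increasing IoU thresholds (0.5/0.6/0.7), 1:3
  proposal sampling, and greedy NMS including the cross-category
  single-survivor variant (heartbeats never overlap).
- **Evaluation** — one-to-one detection↔truth matching at IoU ≥ 0.5,
  one-vs-rest per-class `Acc=(TP+TN)/(TP+FN+FP+TN)`, `Sen=TP/(TP+FN)`,
  `Spe=TN/(TN+FP)` with macro averages, and per-class recall/AP with
  mAP@0.5.

Beat classes follow the 12-label MIT-BIH scheme
(N, L, R, e, j, A, a, J, S, V, E, F) with the AAMI 5-group mapping
(N, SVEB, VEB, F, Q); paced beats (`/`, `f`) and unclassifiable beats
(`Q`) fall outside the 12-class scheme. The CNN itself (backbone, RPN
convolutions, RoI pooling, training) is deliberately out of scope: this
package provides everything a training harness plugs into, plus a
synthetic generator so every stage is testable without downloading
PhysioNet data. A compact WFDB reader/writer (text headers, format
16/212 signals, MIT annotation format) is included.

## Worked example

```python
from beatbox import annotate, synthetic_ecg

sr = synthetic_ecg.make_record(12, ["N", "L", "V", "A"], fs=360.0, seed=42)
boxes, fids = annotate.annotate_record(sr.record, sr.beats())
for fid, truth, cls, box in zip(fids, sr.truth_fiducials,
                                sr.truth_classes, boxes):
    print(cls, fid.q_sample - truth.q_sample, fid.s_sample - truth.s_sample,
          (box.left, box.right), (round(box.bottom, 2), round(box.top, 2)))
```

prints (first beats):

```
N 0 0 (273, 302) (-0.25, 1.14)
L 0 0 (557, 604) (-0.39, 0.87)
V 0 0 (826, 876) (-0.53, 1.31)
A 0 0 (1137, 1166) (-0.24, 1.15)
```

Each line is one beat: the class, the Q and S localization errors in
samples versus the generator's ground truth (0 = exact recovery at
360 Hz), the box's horizontal extent in sample indices (note the wide
ventricular `V` complex spans ~50 samples ≈ 140 ms versus ~30 for `N`),
and its vertical extent in mV. The scripts in `examples/` walk through
each capability the same way: filtering known contaminants, building an
image dataset with VOC annotations, exercising the detector math, and
scoring detections.

A thin CLI mirrors the library:

```sh
beatbox simulate --n-beats 20 --classes N,V --seed 3 --out rec/
beatbox annotate --record rec/synth --out boxes.json
beatbox build-dataset --record rec/synth --out ds/
beatbox evaluate --dets dets.jsonl --truth ds/
```

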