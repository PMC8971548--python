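# Methods

This note documents the models and procedures implemented in `beatbox`,
the defaults and why they were chosen, and what the synthetic-data
tests do and do not demonstrate about real ECG data.

## Signal model and preprocessing

The input is a single-lead ECG sampled at `fs` Hz (360 Hz for
MIT-BIH-style records), in mV. Two additive contaminants are handled:

**Power-line interference.** Mains pickup at 50/60 Hz. The diagnostic
content of the ECG concentrates below ~35 Hz, so a low-pass Butterworth
filter with cutoff 45 Hz and order 10 removes mains while leaving the
QRS band essentially untouched. The filter is applied forward-backward
(`scipy.signal.sosfiltfilt`), i.e. zero-phase: bounding boxes are
anchored to sample indices, and a causal application's group delay
would bias every Q/R/S position. The effective magnitude is therefore
the squared single-pass response — 0.5 (not 1/√2) at the 45 Hz cutoff,
0.086 at 50 Hz, 0.0013 at 60 Hz. Tests compare measured sine gains
against the closed-form Butterworth magnitude evaluated at the
bilinear-warped frequency `tan(πf/fs)/tan(πf_c/fs)`, which matches the
discrete design to ~1e−3; the unwarped analog form differs by ~20% at
50 Hz and is only used as a sanity bound.

**Baseline wander.** Respiration and electrode drift below ~0.5 Hz.
The baseline is estimated by a running median of width `round(fs/2)`
samples — wide enough to straddle any single beat, narrow enough to
track drift — and subtracted. The window is forced odd (181 at 360 Hz)
so the median has a central element. Edges use endpoint-value
replication (`mode="nearest"`), not zero padding, so the record's ends
are not pulled toward zero. One median pass is used; cascaded
two-stage medians exist in the literature but a single pass already
suppresses a 0.3 Hz, 1 mV sinusoidal wander by >95% at these settings.
A median is homogeneous but not additive, so the removal is measured
component-wise in tests: wander suppression on the 0.3 Hz residual of
the contaminated trace, and QRS distortion as the stage's effect on the
clean trace (below 5% of the R amplitude for the default morphologies;
the residual bias comes from the beat occupying a nontrivial fraction
of the 0.5 s window).

Stage order is low-pass first, then baseline removal; both are linear
(-ish) smoothers so the order is not critical, but it is fixed for
determinism.

## Automatic QRS annotation

The annotation algorithm turns each reference R peak (taken from the
annotation file — R detection is deliberately not reimplemented) into a
QRS bounding box.

**Scale-1 wavelet detail.** Sharp transients are singularities; in a
derivative-style (one-vanishing-moment) undecimated wavelet transform a
monotone edge produces one modulus extremum at its steepest point, and
a wave peak/trough produces an extremum *pair* whose zero-crossing sits
at the extremum of the (smoothed) signal. At scale 1 of the
quadratic-spline filter bank the wavelet filter is the two-tap
derivative kernel; the implementation uses `d[n] = 2(x[n] − x[n+1])`,
so an upstroke is a negative excursion. Constants map to zero and a
ramp maps to a constant. The transform is same-length and alignment is
half-sample centred, so the default fixed delay compensation is 0
samples (the knob exists in `AnnotateConfig` for other filter choices).

**Q/S localization.** Within a search window before R (default 100 ms,
clipped to half the RR interval toward the previous beat) the detail's
minimum marks the Q→R upstroke; within the window after R, its maximum
marks the R→S downstroke. Each extremum is then refined to the
adjacent zero-crossing of the detail — scanning left from the upstroke
extremum for Q, right from the downstroke extremum for S — which is the
trough where the derivative changes sign. A fixed sample shift cannot
land on the trough for both narrow (~80 ms) and wide (~140 ms) QRS
morphologies; the zero-crossing refinement is what achieves median
localization error ≤1 sample across all twelve default templates in
the noise-free case. Refinement can be disabled to obtain the raw
extremum positions. Ties among equal extrema resolve toward R; if no
sign change exists inside the window the raw extremum is used.

**Box construction.** Left = Q sample, right = S sample, top = signal
amplitude at R, bottom = min(amplitude at Q, amplitude at S). The rule
assumes an upright R; a beat whose R amplitude does not exceed both
the Q and S amplitudes raises a degenerate-box error and is skipped
(with `allow_inverted=True` the extremum signs flip instead).
Amplitudes are read from the preprocessed signal, since annotation
follows preprocessing in the pipeline. Search windows are clipped at
RR midpoints, so boxes of consecutive beats can never overlap on the
sample axis — the property the final cross-category NMS later relies
on. Beats whose windows would cross the record boundary are skipped
and counted.

## Synthetic records

Each beat is a sum of Gaussian bumps for P, Q, R, S and T
(centre offset, σ, amplitude per wave). This is not a physiological
simulator: it is the simplest morphology whose fiducials are
unambiguous — the ground-truth Q/R/S are the arg-extrema of the
rendered trace near each component centre, recomputed after amplitude
jitter so truth is always exact. Class identity is expressed as
morphology knobs only: ventricular classes (V, E) get ~140 ms QRS
complexes, bundle-branch blocks (L, R) 120–130 ms, junctional/escape and
ventricular classes (e, j, J, V, E) lose the P wave, and the default
normal QRS
spans 80 ms with a 1.1 mV R. RR intervals are N(0.8 s, 0.05 s)
truncated so adjacent QRS complexes cannot overlap; records carry
0.8 s lead-in/out margins; amplitude jitter defaults to 5%.
Contaminants (mains sine, wander sine, white noise) are added after
the clean trace and truth are stored, so noise can never alter truth.

What passing tests show: the annotation machinery recovers known
fiducials exactly on clean Gaussian morphology and within a few ms
after realistic contamination plus preprocessing. What they do not
show: performance on real inter-patient morphology variation, muscle
artifact, electrode motion spikes, or genuinely inverted/biphasic QRS
complexes — the generator does not emulate those.

## Dataset construction

Rendering uses a fixed 512×512 canvas with 5% margins, black trace on
white, 2 px stroke, drawn with Pillow (deterministic; no anti-aliasing
dependence on platform state). Amplitude scaling is per-segment
min/max; the exact affine sample→column and mV→row maps are returned
as a `RenderTransform`, so any signal-frame point or box maps to pixels
and back exactly (rows grow downward, so the mV top edge becomes
`ymin`). Windows default to 3 s centred on each beat and include the
boxes of any neighbouring beats that fall fully inside. Images are
PNG by default (lossless; JPEG export exists but compression must not
move corners). VOC XML corners are written 1-based inclusive — the
common VOC dialect — and converted back to 0-based on read; detector
arithmetic uses half-open corners internally.

Augmentation (translate, resize) applies one affine to pixels and
boxes together; clipped boxes whose visible area drops below 25% of
their transformed area are dropped with a warning. Splits are
stratified per class with train count `round(0.8·n)`, deterministic
given a seed; classes under 5 images warn and split best-effort.

## Detector core

All detector math is framework-free NumPy, designed to be plugged into
a training harness. Conventions and defaults:

- Box deltas use the natural logarithm for width/height channels.
- Cascade stage thresholds default to (0.5, 0.6, 0.7) — the canonical
  increasing schedule; λ = 1 balances classification and regression.
- Assignment: foreground = proposals whose best IoU exceeds the stage
  threshold (matched to their max-IoU ground truth) plus, regardless of
  threshold, each ground truth's own max-IoU proposal (matched to that
  ground truth) — so every object keeps at least one positive and the
  foreground count is monotonically non-increasing in the threshold.
- Sampling: 512 proposals per step at a 1:3 fg:bg ratio (128 + 384),
  deficits in either pool filled from the other, seeded RNG.
- Anchors: one scale, three aspect ratios (k = 3 per position),
  centred on the feature-grid cell, equal areas across ratios
  (`w = s/√r, h = s·√r`). Scale and stride are configuration; no value
  is canonical for ECG beat images.
- NMS: greedy on descending score, ties to the lower index, threshold
  0.7 in the proposal stage. The inference-stage variant is
  class-agnostic with overlap threshold 0 (any positive overlap
  suppresses): since heartbeat boxes never overlap on the sample axis,
  exactly one detection should survive per cluster. Both variants are
  exposed; evaluation and final NMS group boxes per image whenever
  detections carry image keys, so boxes from different images never
  compete.
- `cls_loss` clamps probabilities at 1e−12 so numerically zero
  probabilities yield large finite losses.

The CNN backbone, RPN convolutions, RoI pooling/Align and the training
schedule are intentionally absent; their hyper-parameters (2,000/1,000
proposals, 512 samples, NMS 0.7) are carried in `CascadeConfig` as
configuration constants.

## Evaluation

Detections are matched greedily to ground-truth boxes in descending
score order at IoU ≥ 0.5, one-to-one and class-agnostic: a wrong-class
hit consumes the beat and records the misclassification; unmatched
ground truths are misses; unmatched detections are spurious items.
Per-class one-vs-rest TP/TN/FP/FN counts are built over this fixed
item set (so totals agree across classes), and Acc/Sen/Spe are
reported in percent with unweighted macro averages — undefined
denominators are flagged rather than silently zeroed. AP uses
per-class, per-image matching with all-points interpolation (area
under the precision-envelope step curve; 11-point optional), and mAP
averages classes with at least one ground truth. A published
twelve-class per-class reference table is bundled solely to validate
the macro-averaging conventions; this package does not train the
detector that produced it.

## Problem sizes and determinism

The test suite and the acceptance script run on synthetic records of
tens of beats (6 beats × 12 classes for parameter recovery, 24–60-beat
mixed records for robustness and the end-to-end run) and oracle checks
on a few hundred random boxes across 100 seeds — sizes at which every
check is exact or tightly bounded and the whole suite completes in
seconds. All randomness flows through explicit seeds
(`numpy.random.default_rng`); renders, filters and WFDB round trips
are bit-deterministic. Known limitations: the WFDB codec covers
formats 16 and 212 with single-file records only; the generator's
class morphologies are caricatures, not clinical references; and
detection performance of a trained CNN is out of scope, so no claim is
made about reproducing published detector accuracy.
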