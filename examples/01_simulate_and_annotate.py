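"""Generate a synthetic ECG record and annotate its QRS complexes.

Builds a 12-beat record cycling through four beat classes, runs the
wavelet-based annotation against the known R peaks, and compares the
located Q/S fiducials with the generator's ground truth.
"""

from beatbox import annotate, synthetic_ecg

sr = synthetic_ecg.make_record(
    12, ["N", "L", "V", "A"], fs=360.0, seed=42
)
boxes, fids = annotate.annotate_record(sr.record, sr.beats())

print("beat  class  q_err  s_err   box [left,right] samples, [bottom,top] mV")
for i, (fid, truth, cls, box) in enumerate(
    zip(fids, sr.truth_fiducials, sr.truth_classes, boxes)
):
    q_err = fid.q_sample - truth.q_sample
    s_err = fid.s_sample - truth.s_sample
    print(
        f"{i:4d}  {cls:>5}  {q_err:5d}  {s_err:5d}   "
        f"[{box.left}, {box.right}], [{box.bottom:+.2f}, {box.top:+.2f}]"
    )

# q_err/s_err are the located-minus-true fiducial offsets in samples
# (1 sample = 2.8 ms at 360 Hz); 0 means exact recovery.  The box spans
# Q→S horizontally and min(Q,S) amplitude → R amplitude vertically.
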