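"""Show what the two preprocessing stages do to known contaminants.

Adds a 50 Hz mains tone and a 0.3 Hz baseline wander to a clean
synthetic record, then measures how much of each survives the
Butterworth low-pass + median-filter chain.
"""

import numpy as np

from beatbox import preprocess, synthetic_ecg

FS = 360.0
sr = synthetic_ecg.make_record(
    12, "N", fs=FS, seed=7,
    noise=synthetic_ecg.NoiseConfig(powerline_amp_mv=0.3, wander_amp_mv=0.8),
)
clean = preprocess.preprocess(sr.clean_signal, FS)
filtered = preprocess.preprocess(sr.record.signal[:, 0], FS)
resid = filtered - clean

t = np.arange(resid.size) / FS
for name, freq, amp_in in (("50 Hz mains", 50.0, 0.3),
                           ("0.3 Hz wander", 0.3, 0.8)):
    c, s = np.cos(2 * np.pi * freq * t), np.sin(2 * np.pi * freq * t)
    amp_out = 2 * np.hypot(resid @ c, resid @ s) / resid.size
    print(f"{name}: {amp_in:.2f} mV in -> {amp_out:.4f} mV out "
          f"({100 * (1 - amp_out / amp_in):.1f}% removed)")

gains = preprocess.powerline_response(np.array([5.0, 35, 45, 50, 60]), FS)
print("low-pass magnitude (zero-phase) at 5/35/45/50/60 Hz:",
      np.round(gains, 4))
# Passband (≤35 Hz) gain stays ≈1 so ECG morphology is untouched; the
# 45 Hz cutoff is the −3 dB point (0.5 after the squared forward-backward
# pass) and mains at 50 Hz is cut by more than 10×.
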