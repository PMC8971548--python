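"""Build a beat-image detection dataset from an annotated record.

Renders one 3 s window per beat, writes PNG + VOC XML pairs, applies a
translate augmentation to one image, and makes a stratified 8:2 split.
"""

import tempfile
from pathlib import Path

from beatbox import annotate, dataset, io_formats, synthetic_ecg

sr = synthetic_ecg.make_record(20, ["N", "V"], fs=360.0, seed=3)
boxes, _ = annotate.annotate_record(sr.record, sr.beats())

with tempfile.TemporaryDirectory() as td:
    manifest = dataset.build_images(
        sr.record.signal[:, 0], 360.0, boxes, td, window_s=3.0
    )
    manifest = dataset.split_manifest(manifest, ratio=0.8, seed=0)
    print(manifest.groupby(["classes", "split"]).size())

    ann = io_formats.read_voc(manifest.iloc[0]["annotation"])
    print(f"\nfirst image: {ann.filename} ({ann.width}x{ann.height}),"
          f" {len(ann.objects)} boxes")
    for o in ann.objects:
        print(f"  {o.name}: ({o.xmin},{o.ymin})-({o.xmax},{o.ymax})")

    # augmentation moves boxes with the pixels
    from PIL import Image
    img = Image.open(manifest.iloc[0]["image"])
    pix = [dataset.PixelBox(o.xmin, o.ymin, o.xmax, o.ymax, o.name)
           for o in ann.objects]
    _, moved = dataset.augment(img, pix, dataset.Translate(15, -10))
    print("\nafter translate(15,-10):")
    for b in moved:
        print(f"  {b.class12}: ({b.xmin},{b.ymin})-({b.xmax},{b.ymax})")
# Per class the split is within one image of 80/20; each VOC box tightly
# encloses the rendered QRS trace of its beat.
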