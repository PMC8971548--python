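"""Beat-image dataset construction.

Renders signal windows to raster images (white background, black trace),
carries the exact affine signal→pixel transform so QRS rectangles in the
signal frame (samples × mV) can be mapped to pixel bounding boxes,
applies translate/resize augmentation that moves boxes with the pixels,
and produces stratified train/test manifests (default 8:2).

Default canvas is 512×512 with 5% margins; windows default to 3 s
centred on beats but any length renders (the transform adapts), so
strips with several beats work the same way.  Images save losslessly as
PNG by default, with JPEG export optional.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from .annotate import SignalBox
from .io_formats import VocAnnotation, VocObject, write_voc

__all__ = [
    "RenderConfig",
    "RenderTransform",
    "PixelBox",
    "Translate",
    "Resize",
    "render_segment",
    "to_pixels",
    "augment",
    "split_manifest",
    "build_images",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RenderConfig:
    width: int = 512
    height: int = 512
    margin_frac: float = 0.05
    stroke: int = 2  # trace line width in pixels
    fg: int = 0  # trace gray level
    bg: int = 255  # background gray level


@dataclass(frozen=True)
class RenderTransform:
    """Affine sample→column / mV→row maps of a rendered segment.

    col = x_offset + x_scale · (sample − start_sample), x_scale > 0
    row = y_offset − y_scale · mV, y_scale > 0 (rows grow downward)
    """

    start_sample: int
    x_scale: float
    x_offset: float
    y_scale: float
    y_offset: float
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.x_scale <= 0 or self.y_scale <= 0:
            raise ValueError("transform scales must be positive")

    def col(self, sample: float) -> float:
        return self.x_offset + self.x_scale * (sample - self.start_sample)

    def row(self, mv: float) -> float:
        return self.y_offset - self.y_scale * mv

    def sample(self, col: float) -> float:
        return self.start_sample + (col - self.x_offset) / self.x_scale

    def mv(self, row: float) -> float:
        return (self.y_offset - row) / self.y_scale


@dataclass(frozen=True)
class PixelBox:
    """Integer-corner box in image coordinates (0-based, corners inside)."""

    xmin: int
    ymin: int
    xmax: int
    ymax: int
    class12: str | None = None

    def __post_init__(self) -> None:
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise ValueError(f"degenerate pixel box {self}")

    @property
    def area(self) -> int:
        return (self.xmax - self.xmin) * (self.ymax - self.ymin)

    def as_voc(self) -> VocObject:
        return VocObject(self.class12 or "beat", self.xmin, self.ymin,
                         self.xmax, self.ymax)


def render_segment(
    segment: np.ndarray,
    fs: float,
    cfg: RenderConfig = RenderConfig(),
    start_sample: int = 0,
) -> tuple[Image.Image, RenderTransform]:
    """Rasterize a trace deterministically; returns (image, transform).

    Amplitude scaling is per-segment min/max with the configured margin
    headroom; the transform records the exact affine so any (sample, mV)
    point maps to pixels and back.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.size < 2:
        raise ValueError("segment must contain at least 2 samples")
    vmin, vmax = float(np.min(segment)), float(np.max(segment))
    if vmax - vmin <= 0:
        raise ValueError("segment has zero amplitude range; nothing to render")

    mx = cfg.margin_frac * cfg.width
    my = cfg.margin_frac * cfg.height
    x_scale = (cfg.width - 2 * mx - 1) / (segment.size - 1)
    y_scale = (cfg.height - 2 * my - 1) / (vmax - vmin)
    t = RenderTransform(
        start_sample=start_sample,
        x_scale=x_scale,
        x_offset=mx,
        y_scale=y_scale,
        y_offset=my + y_scale * vmax,
        width=cfg.width,
        height=cfg.height,
    )
    img = Image.new("L", (cfg.width, cfg.height), cfg.bg)
    draw = ImageDraw.Draw(img)
    pts = [
        (t.col(start_sample + i), t.row(v)) for i, v in enumerate(segment)
    ]
    draw.line(pts, fill=cfg.fg, width=cfg.stroke, joint="curve")
    return img, t


def to_pixels(box: SignalBox, t: RenderTransform) -> PixelBox:
    """Map a signal-frame QRS rectangle into pixel coordinates.

    The mV top maps to ymin and the mV bottom to ymax (row inversion);
    corners are clipped to the image bounds.
    """
    xmin = int(np.floor(t.col(box.left)))
    xmax = int(np.ceil(t.col(box.right)))
    ymin = int(np.floor(t.row(box.top)))
    ymax = int(np.ceil(t.row(box.bottom)))
    if xmax < 0 or xmin > t.width - 1 or ymax < 0 or ymin > t.height - 1:
        raise ValueError("box lies fully outside the rendered extent")
    xmin = max(0, min(xmin, t.width - 2))
    ymin = max(0, min(ymin, t.height - 2))
    xmax = max(xmin + 1, min(xmax, t.width - 1))
    ymax = max(ymin + 1, min(ymax, t.height - 1))
    return PixelBox(xmin, ymin, xmax, ymax, box.class12)


@dataclass(frozen=True)
class Translate:
    dx: int
    dy: int


@dataclass(frozen=True)
class Resize:
    sx: float
    sy: float


def augment(
    img: Image.Image,
    boxes: list[PixelBox],
    op: Translate | Resize,
    min_visible_frac: float = 0.25,
    bg: int = 255,
) -> tuple[Image.Image, list[PixelBox]]:
    """Apply one augmentation op to the image and its boxes together.

    Boxes are transformed by the same affine as the pixels, then clipped
    to the canvas; a box whose remaining area falls below
    ``min_visible_frac`` of its transformed area is dropped (logged).
    """
    w, h = img.size
    if isinstance(op, Translate):
        out = Image.new(img.mode, (w, h), bg)
        out.paste(img, (op.dx, op.dy))
        def fwd(x, y):
            return x + op.dx, y + op.dy
    elif isinstance(op, Resize):
        if op.sx <= 0 or op.sy <= 0:
            raise ValueError("resize factors must be positive")
        nw, nh = max(1, int(round(w * op.sx))), max(1, int(round(h * op.sy)))
        scaled = img.resize((nw, nh), Image.BILINEAR)
        out = Image.new(img.mode, (w, h), bg)
        out.paste(scaled, (0, 0))
        def fwd(x, y):
            return x * op.sx, y * op.sy
    else:
        raise TypeError(f"unsupported augmentation op {op!r}")

    kept: list[PixelBox] = []
    for b in boxes:
        x0, y0 = fwd(b.xmin, b.ymin)
        x1, y1 = fwd(b.xmax, b.ymax)
        full = max(0.0, x1 - x0) * max(0.0, y1 - y0)
        cx0, cy0 = max(0.0, x0), max(0.0, y0)
        cx1, cy1 = min(float(w - 1), x1), min(float(h - 1), y1)
        vis = max(0.0, cx1 - cx0) * max(0.0, cy1 - cy0)
        if full <= 0 or vis < min_visible_frac * full:
            log.warning("augment %r: dropping box %s (visible %.0f%%)",
                        op, b, 100 * vis / full if full else 0.0)
            continue
        kept.append(PixelBox(int(round(cx0)), int(round(cy0)),
                             max(int(round(cx0)) + 1, int(round(cx1))),
                             max(int(round(cy0)) + 1, int(round(cy1))),
                             b.class12))
    return out, kept


def split_manifest(
    manifest: pd.DataFrame,
    ratio: float = 0.8,
    seed: int | None = None,
    class_column: str = "classes",
) -> pd.DataFrame:
    """Assign a stratified train/test split (default 8:2) to a manifest.

    Stratification groups rows by ``class_column``; per class the train
    count is round(ratio·n), so each class lands within one image of the
    target ratio.  Deterministic given the seed.  Classes with fewer
    than 5 rows are split best-effort with a warning.
    """
    if not 0 <= ratio <= 1:
        raise ValueError("ratio must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    split = pd.Series("train", index=manifest.index, dtype=object)
    for cls, idx in manifest.groupby(class_column).groups.items():
        idx = np.asarray(idx)
        if len(idx) < 5:
            log.warning("class %r has only %d images; split is best-effort",
                        cls, len(idx))
        n_train = int(round(ratio * len(idx)))
        perm = rng.permutation(len(idx))
        split.loc[idx[perm[n_train:]]] = "test"
    out = manifest.copy()
    out["split"] = split
    return out


def balance_classes(
    manifest: pd.DataFrame,
    per_class_target: int,
    out_dir: str | Path | None = None,
    seed: int | None = None,
    max_translate: int = 24,
    resize_range: tuple[float, float] = (0.9, 1.1),
    class_column: str = "classes",
) -> pd.DataFrame:
    """Equalize per-class image counts toward ``per_class_target``.

    Over-represented classes are subsampled; under-represented ones are
    topped up with augmented copies (random small translate or resize)
    of their existing images, written next to the originals (or into
    ``out_dir``) with re-derived VOC annotations.  Augmented copies
    whose boxes all fall out of view are skipped.  Deterministic given
    the seed.
    """
    if per_class_target < 1:
        raise ValueError("per_class_target must be positive")
    rng = np.random.default_rng(seed)
    out_rows: list[pd.Series] = []
    for cls, idx in manifest.groupby(class_column).groups.items():
        idx = np.asarray(idx)
        if len(idx) >= per_class_target:
            take = rng.choice(len(idx), size=per_class_target, replace=False)
            out_rows.extend(manifest.loc[i] for i in idx[np.sort(take)])
            continue
        out_rows.extend(manifest.loc[i] for i in idx)
        n_extra = per_class_target - len(idx)
        for k in range(n_extra):
            src = manifest.loc[idx[int(rng.integers(len(idx)))]]
            img = Image.open(src["image"])
            voc_path = Path(src["annotation"])
            from .io_formats import read_voc, VocAnnotation, write_voc
            ann = read_voc(voc_path)
            boxes = [
                PixelBox(o.xmin, o.ymin, o.xmax, o.ymax, o.name)
                for o in ann.objects
            ]
            if rng.random() < 0.5:
                op = Translate(int(rng.integers(-max_translate, max_translate + 1)),
                               int(rng.integers(-max_translate, max_translate + 1)))
            else:
                op = Resize(float(rng.uniform(*resize_range)),
                            float(rng.uniform(*resize_range)))
            aug_img, aug_boxes = augment(img, boxes, op)
            if not aug_boxes:
                continue
            dest_dir = Path(out_dir) if out_dir else voc_path.parent
            stem = f"{voc_path.stem}_aug{k:03d}"
            img_path = dest_dir / f"{stem}{Path(src['image']).suffix}"
            xml_path = dest_dir / f"{stem}.xml"
            aug_img.save(img_path)
            write_voc(
                VocAnnotation(img_path.name, aug_img.width, aug_img.height,
                              [b.as_voc() for b in aug_boxes]),
                xml_path,
            )
            row = src.copy()
            row["image"] = str(img_path)
            row["annotation"] = str(xml_path)
            out_rows.append(row)
    return pd.DataFrame(out_rows).reset_index(drop=True)


def build_images(
    signal: np.ndarray,
    fs: float,
    boxes: list[SignalBox],
    out_dir: str | Path,
    prefix: str = "beat",
    window_s: float = 3.0,
    cfg: RenderConfig = RenderConfig(),
    image_format: str = "png",
) -> pd.DataFrame:
    """Render one window per annotated beat and write image + VOC XML.

    Each window is ``window_s`` seconds centred on the beat's box; boxes
    of neighbouring beats that fall inside the window are included in
    its annotation.  Returns a manifest DataFrame (image, annotation,
    classes, split placeholder).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    half = int(round(window_s * fs / 2))
    rows = []
    for i, box in enumerate(boxes):
        center = (box.left + box.right) // 2
        lo = max(0, center - half)
        hi = min(len(signal), center + half)
        img, t = render_segment(signal[lo:hi], fs, cfg, start_sample=lo)
        in_window = [
            b for b in boxes if b.left >= lo and b.right < hi
        ]
        pixel_boxes = [to_pixels(b, t) for b in in_window]
        stem = f"{prefix}_{i:05d}"
        img_path = out_dir / f"{stem}.{image_format}"
        xml_path = out_dir / f"{stem}.xml"
        img.save(img_path)
        ann = VocAnnotation(img_path.name, cfg.width, cfg.height,
                            [pb.as_voc() for pb in pixel_boxes])
        write_voc(ann, xml_path)
        rows.append(
            {
                "image": str(img_path),
                "annotation": str(xml_path),
                "classes": box.class12 or "beat",
                "split": "train",
            }
        )
    return pd.DataFrame(rows)
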