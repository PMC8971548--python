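"""Rendering, pixel-box transforms, augmentation, and splits."""

import numpy as np
import pandas as pd
import pytest

from beatbox import annotate as an
from beatbox import dataset as ds

FS = 360.0


def _segment_and_box(annotated, i=2, pad=120):
    sr, boxes, _ = annotated
    x = sr.record.signal[:, 0]
    box = boxes[i]
    lo, hi = box.left - pad, box.right + pad
    return x[lo:hi], box, lo


class TestRender:
    def test_deterministic(self, annotated):
        seg, _, lo = _segment_and_box(annotated)
        img1, _ = ds.render_segment(seg, FS, start_sample=lo)
        img2, _ = ds.render_segment(seg, FS, start_sample=lo)
        assert np.array_equal(np.asarray(img1), np.asarray(img2))

    def test_max_amplitude_maps_to_smallest_row(self, annotated):
        seg, _, lo = _segment_and_box(annotated)
        img, t = ds.render_segment(seg, FS, start_sample=lo)
        arr = np.asarray(img)
        rows, _ = np.nonzero(arr < 128)
        peak_row = t.row(float(np.max(seg)))
        assert abs(rows.min() - peak_row) <= ds.RenderConfig().stroke + 1

    def test_truth_fiducials_land_on_trace(self, annotated):
        sr, boxes, fids = annotated
        seg, box, lo = _segment_and_box(annotated)
        img, t = ds.render_segment(seg, FS, start_sample=lo)
        arr = np.asarray(img)
        x = sr.record.signal[:, 0]
        fid = fids[2]
        stroke = ds.RenderConfig().stroke
        for s in (fid.q_sample, fid.r_sample, fid.s_sample):
            col = int(round(t.col(s)))
            row = int(round(t.row(x[s])))
            patch = arr[
                max(0, row - stroke - 1): row + stroke + 2,
                max(0, col - stroke - 1): col + stroke + 2,
            ]
            assert np.any(patch < 128)

    def test_flat_segment_rejected(self):
        with pytest.raises(ValueError, match="amplitude"):
            ds.render_segment(np.zeros(100), FS)

    def test_transform_round_trips(self, annotated):
        seg, _, lo = _segment_and_box(annotated)
        _, t = ds.render_segment(seg, FS, start_sample=lo)
        assert t.sample(t.col(lo + 50)) == pytest.approx(lo + 50)
        assert t.mv(t.row(0.37)) == pytest.approx(0.37)


class TestToPixels:
    def test_row_inversion_keeps_ymin_below_ymax(self, annotated):
        seg, box, lo = _segment_and_box(annotated)
        _, t = ds.render_segment(seg, FS, start_sample=lo)
        pb = ds.to_pixels(box, t)
        assert pb.ymin < pb.ymax and pb.xmin < pb.xmax

    def test_identity_like_transform_computable_by_hand(self):
        t = ds.RenderTransform(
            start_sample=0, x_scale=1.0, x_offset=0.0,
            y_scale=100.0, y_offset=100.0, width=200, height=101,
        )
        box = an.SignalBox(left=10, right=50, top=1.0, bottom=0.2, class12="N")
        pb = ds.to_pixels(box, t)
        # col = sample; row = 100 − 100·mV
        assert (pb.xmin, pb.xmax) == (10, 50)
        assert (pb.ymin, pb.ymax) == (0, 80)

    def test_box_straddling_margin_clipped(self):
        t = ds.RenderTransform(0, 1.0, 0.0, 100.0, 100.0, 40, 101)
        box = an.SignalBox(left=10, right=70, top=1.0, bottom=0.2)
        pb = ds.to_pixels(box, t)
        assert pb.xmax == 39

    def test_box_outside_extent_rejected(self):
        t = ds.RenderTransform(0, 1.0, 0.0, 100.0, 100.0, 40, 101)
        box = an.SignalBox(left=200, right=300, top=1.0, bottom=0.2)
        with pytest.raises(ValueError):
            ds.to_pixels(box, t)

    def test_pixel_box_encloses_qrs_trace(self, annotated):
        sr, boxes, fids = annotated
        x = sr.record.signal[:, 0]
        seg, box, lo = _segment_and_box(annotated)
        img, t = ds.render_segment(seg, FS, start_sample=lo)
        pb = ds.to_pixels(box, t)
        fid = fids[2]
        for s in range(fid.q_sample, fid.s_sample + 1):
            col = t.col(s)
            row = t.row(x[s])
            assert pb.xmin - 1 <= col <= pb.xmax + 1
            assert pb.ymin - 1 <= row <= pb.ymax + 1


class TestAugment:
    def _img_and_boxes(self, annotated):
        seg, box, lo = _segment_and_box(annotated)
        img, t = ds.render_segment(seg, FS, start_sample=lo)
        return img, [ds.to_pixels(box, t)]

    def test_translate_moves_every_corner(self, annotated):
        img, boxes = self._img_and_boxes(annotated)
        _, out = ds.augment(img, boxes, ds.Translate(10, 0))
        assert out[0].xmin == boxes[0].xmin + 10
        assert out[0].xmax == boxes[0].xmax + 10
        assert out[0].ymin == boxes[0].ymin

    def test_resize_doubles_box_widths(self, annotated):
        img, boxes = self._img_and_boxes(annotated)
        small = [ds.PixelBox(10, 10, 50, 60, "N")]
        _, out = ds.augment(img, small, ds.Resize(2.0, 2.0))
        assert out[0].xmax - out[0].xmin == 2 * (small[0].xmax - small[0].xmin)
        assert out[0].ymax - out[0].ymin == 2 * (small[0].ymax - small[0].ymin)

    def test_box_pushed_mostly_out_is_dropped(self, annotated):
        img, _ = self._img_and_boxes(annotated)
        w, h = img.size
        boxes = [ds.PixelBox(w - 100, 10, w - 10, 60, "N")]
        _, out = ds.augment(img, boxes, ds.Translate(81, 0))
        assert out == []  # ~90% outside → below the visibility floor

    def test_translate_moves_pixels_with_boxes(self, annotated):
        img, boxes = self._img_and_boxes(annotated)
        out_img, out = ds.augment(img, boxes, ds.Translate(7, 5))
        a = np.asarray(img)
        b = np.asarray(out_img)
        assert np.array_equal(a[:-5, :-7], b[5:, 7:])


class TestSplit:
    def _manifest(self, n_per_class, classes=("N", "V", "L")):
        rows = [
            {"image": f"{c}_{i}.png", "annotation": f"{c}_{i}.xml",
             "classes": c, "split": ""}
            for c in classes
            for i in range(n_per_class)
        ]
        return pd.DataFrame(rows)

    def test_eight_two_split_counts(self):
        mf = ds.split_manifest(self._manifest(5000), ratio=0.8, seed=0)
        counts = mf.groupby(["classes", "split"]).size()
        for c in ("N", "V", "L"):
            assert counts[(c, "train")] == 4000
            assert counts[(c, "test")] == 1000

    def test_split_is_a_partition(self):
        mf = ds.split_manifest(self._manifest(97), ratio=0.8, seed=3)
        assert set(mf["split"]) == {"train", "test"}
        assert len(mf) == 3 * 97

    def test_ratio_one_puts_everything_in_train(self):
        mf = ds.split_manifest(self._manifest(50), ratio=1.0, seed=0)
        assert (mf["split"] == "train").all()

    def test_same_seed_same_membership_different_seed_same_counts(self):
        base = self._manifest(100)
        a = ds.split_manifest(base, 0.8, seed=1)
        b = ds.split_manifest(base, 0.8, seed=1)
        c = ds.split_manifest(base, 0.8, seed=2)
        assert (a["split"] == b["split"]).all()
        assert not (a["split"] == c["split"]).all()
        assert a["split"].value_counts().equals(c["split"].value_counts())

    def test_tiny_class_warns_and_still_splits(self, caplog):
        mf = self._manifest(3, classes=("N",))
        with caplog.at_level("WARNING"):
            out = ds.split_manifest(mf, 0.8, seed=0)
        assert "best-effort" in caplog.text
        assert len(out) == 3


class TestBuildImages:
    def test_images_and_voc_files_written(self, annotated, tmp_path):
        from beatbox import io_formats as iof
        sr, boxes, _ = annotated
        mf = ds.build_images(
            sr.record.signal[:, 0], FS, boxes[:4], tmp_path, window_s=3.0
        )
        assert len(mf) == 4
        for _, row in mf.iterrows():
            ann = iof.read_voc(row["annotation"])
            assert len(ann.objects) >= 1
            ann.validate()


class TestBalanceClasses:
    def test_majority_subsampled_minority_augmented(self, annotated, tmp_path):
        sr, boxes, _ = annotated
        mf = ds.build_images(
            sr.record.signal[:, 0], FS, boxes, tmp_path, window_s=3.0
        )
        counts = mf["classes"].value_counts()
        target = int(counts.max()) + 2  # force augmentation for every class
        out = ds.balance_classes(mf, target, seed=0)
        got = out["classes"].value_counts()
        for cls in counts.index:
            assert got[cls] == target
        # augmented copies carry valid, re-derived VOC annotations
        from beatbox import io_formats as iof
        aug_rows = out[out["annotation"].str.contains("_aug")]
        assert len(aug_rows) > 0
        for _, row in aug_rows.iterrows():
            iof.read_voc(row["annotation"]).validate()

    def test_subsampling_to_smaller_target(self, annotated, tmp_path):
        sr, boxes, _ = annotated
        mf = ds.build_images(
            sr.record.signal[:, 0], FS, boxes, tmp_path, window_s=3.0
        )
        out = ds.balance_classes(mf, 1, seed=0)
        assert (out["classes"].value_counts() == 1).all()

    def test_deterministic_given_seed(self, annotated, tmp_path):
        sr, boxes, _ = annotated
        mf = ds.build_images(
            sr.record.signal[:, 0], FS, boxes, tmp_path, window_s=3.0
        )
        a = ds.balance_classes(mf, 3, seed=5)
        b = ds.balance_classes(mf, 3, seed=5)
        assert a["image"].tolist() == b["image"].tolist()
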