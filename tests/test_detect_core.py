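"""Detector math: IoU, encoding, losses, assignment, sampling, NMS."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from beatbox import detect_core as dc


def raster_iou(a, b, scale=1):
    """Brute-force IoU oracle: rasterize half-open integer boxes."""
    a = [int(round(v * scale)) for v in a]
    b = [int(round(v * scale)) for v in b]
    w = max(a[2], b[2]) + 1
    h = max(a[3], b[3]) + 1
    ga = np.zeros((h, w), dtype=bool)
    gb = np.zeros((h, w), dtype=bool)
    ga[a[1]: a[3], a[0]: a[2]] = True
    gb[b[1]: b[3], b[0]: b[2]] = True
    inter = np.sum(ga & gb)
    union = np.sum(ga | gb)
    return inter / union


def random_boxes(rng, n, span=100, max_side=40):
    x = rng.integers(0, span, n)
    y = rng.integers(0, span, n)
    w = rng.integers(1, max_side, n)
    h = rng.integers(1, max_side, n)
    return np.stack([x, y, x + w, y + h], axis=1).astype(float)


class TestIou:
    def test_self_iou_is_one(self):
        assert dc.iou((0, 0, 5, 7), (0, 0, 5, 7)) == 1.0

    def test_disjoint_boxes_zero(self):
        assert dc.iou((0, 0, 2, 2), (10, 10, 12, 12)) == 0.0

    def test_half_overlap_is_one_third(self):
        assert dc.iou((0, 0, 2, 2), (1, 0, 3, 2)) == pytest.approx(1 / 3)

    def test_matches_rasterization_oracle_on_random_boxes(self):
        rng = np.random.default_rng(0)
        a = random_boxes(rng, 60)
        b = random_boxes(rng, 60)
        for ai, bi in zip(a, b):
            assert dc.iou(ai, bi) == pytest.approx(raster_iou(ai, bi))

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(1)
        a = random_boxes(rng, 40)
        b = random_boxes(rng, 40)
        m1 = dc.iou_matrix(a, b)
        m2 = dc.iou_matrix(b, a)
        assert np.allclose(m1, m2.T)
        assert np.all((m1 >= 0) & (m1 <= 1))

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            dc.iou((0, 0, 0, 5), (0, 0, 2, 2))


class TestEncodeDecode:
    def test_box_equal_anchor_encodes_to_zero(self):
        anchor = np.array([[10.0, 10, 10, 10]])
        assert np.allclose(dc.encode(anchor, anchor), 0.0)

    def test_hand_example(self):
        t = dc.encode(np.array([[15.0, 10, 20, 10]]),
                      np.array([[10.0, 10, 10, 10]]))
        assert t[0] == pytest.approx([0.5, 0.0, np.log(2.0), 0.0])

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        vals=st.lists(
            st.floats(min_value=-50, max_value=50, allow_nan=False),
            min_size=2, max_size=2,
        ),
        sizes=st.lists(
            st.floats(min_value=0.1, max_value=80, allow_nan=False),
            min_size=4, max_size=4,
        ),
    )
    def test_decode_inverts_encode(self, vals, sizes):
        box = np.array([[vals[0], vals[1], sizes[0], sizes[1]]])
        anchor = np.array([[0.0, 0.0, sizes[2], sizes[3]]])
        assert np.allclose(dc.decode(dc.encode(box, anchor), anchor), box,
                           rtol=1e-10, atol=1e-8)

    def test_translation_invariance(self):
        box = np.array([[5.0, 6, 8, 12]])
        anchor = np.array([[3.0, 4, 10, 10]])
        shifted = dc.encode(box + [17, -9, 0, 0], anchor + [17, -9, 0, 0])
        assert np.allclose(dc.encode(box, anchor), shifted)

    def test_nonpositive_size_rejected(self):
        with pytest.raises(ValueError):
            dc.encode(np.array([[0.0, 0, -1, 2]]), np.array([[0.0, 0, 1, 1]]))


class TestLosses:
    def test_smooth_l1_zero_at_zero(self):
        assert dc.smooth_l1(0.0) == 0.0

    def test_smooth_l1_continuous_at_one(self):
        eps = 1e-9
        below = dc.smooth_l1(1.0 - eps)
        above = dc.smooth_l1(1.0 + eps)
        assert float(dc.smooth_l1(1.0)) == pytest.approx(0.5)
        assert below == pytest.approx(above, abs=1e-8)

    def test_reg_loss_hand_example(self):
        t = np.array([0.5, 0.0, 0.0, 2.0])
        assert dc.reg_loss(t, np.zeros(4)) == pytest.approx(1.625)

    def test_cls_loss_values_and_monotonicity(self):
        assert dc.cls_loss(np.array([0.0, 1.0]), 1) == 0.0
        assert dc.cls_loss(np.array([0.5, 0.5]), 1) == pytest.approx(np.log(2))
        ps = np.linspace(0.1, 0.9, 9)
        losses = [dc.cls_loss(np.array([1 - p, p]), 1) for p in ps]
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_cls_loss_clamps_zero_probability(self):
        loss = dc.cls_loss(np.array([1.0, 0.0]), 1)
        assert np.isfinite(loss) and loss > 20

    def test_stage_and_total_loss(self):
        probs = np.array([[0.2, 0.8], [0.9, 0.1]])
        labels = np.array([1, 0])
        deltas = np.array([[0.5, 0, 0, 0], [0, 0, 0, 0.0]])
        targets = np.zeros((2, 4))
        p_star = np.array([1, 0])
        got = dc.stage_loss(probs, labels, deltas, targets, p_star, lam=1.0)
        want = -np.log(0.8) - np.log(0.9) + 0.5 * 0.25
        assert got == pytest.approx(want)
        # λ = 0 → classification only
        cls_only = dc.stage_loss(probs, labels, deltas, targets, p_star, lam=0.0)
        assert cls_only == pytest.approx(-np.log(0.8) - np.log(0.9))
        assert dc.total_loss([1.0, 0.5, 0.25]) == 1.75

    def test_all_background_batch_has_zero_regression(self):
        probs = np.array([[0.9, 0.1], [0.8, 0.2]])
        labels = np.zeros(2, dtype=int)
        deltas = np.ones((2, 4)) * 5  # would be huge if counted
        got = dc.stage_loss(probs, labels, deltas, np.zeros((2, 4)),
                            np.zeros(2, dtype=int), lam=10.0)
        assert got == pytest.approx(-np.log(0.9) - np.log(0.8))


class TestAssign:
    def test_no_gts_all_background(self):
        rng = np.random.default_rng(0)
        props = random_boxes(rng, 10)
        out = dc.assign(props, np.zeros((0, 4)), 0.5)
        assert all(not p.is_foreground for p in out)

    def test_high_iou_is_foreground(self):
        props = np.array([[0.0, 0, 10, 10]])
        gts = np.array([[1.0, 0, 10, 10]])
        (p,) = dc.assign(props, gts, 0.5)
        assert p.is_foreground and p.matched_gt == 0

    def test_max_iou_guarantee_even_below_threshold(self):
        props = np.array(
            [[50.0, 50, 60, 60], [70.0, 70, 80, 80], [0.0, 0, 4, 4]]
        )
        gts = np.array([[0.0, 0, 10, 10]])
        out = dc.assign(props, gts, 0.5)
        assert out[2].is_foreground  # best available for the gt
        assert not out[0].is_foreground and not out[1].is_foreground

    def test_every_gt_gets_a_foreground(self):
        rng = np.random.default_rng(3)
        props = random_boxes(rng, 100)
        gts = random_boxes(rng, 5)
        out = dc.assign(props, gts, 0.7)
        matched = {p.matched_gt for p in out if p.is_foreground}
        assert matched == set(range(5))

    def test_foreground_count_monotone_in_threshold(self):
        rng = np.random.default_rng(4)
        props = random_boxes(rng, 300)
        gts = random_boxes(rng, 8)
        counts = [
            sum(p.is_foreground for p in dc.assign(props, gts, th))
            for th in (0.5, 0.6, 0.7)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_increasing_thresholds_enforced_in_config(self):
        with pytest.raises(ValueError):
            dc.CascadeConfig(iou_thresholds=(0.7, 0.6, 0.5))


class TestSampleProposals:
    def _assigned(self, n_fg, n_bg, rng):
        props = random_boxes(rng, n_fg + n_bg)
        out = [dc.Proposal(p, i < n_fg, 0 if i < n_fg else None)
               for i, p in enumerate(props)]
        return out

    def test_one_to_three_ratio_of_512(self):
        rng = np.random.default_rng(0)
        sub = dc.sample_proposals(self._assigned(500, 5000, rng), 512, seed=1)
        n_fg = sum(p.is_foreground for p in sub)
        assert len(sub) == 512
        assert n_fg == 128 and len(sub) - n_fg == 384

    def test_foreground_deficit_filled_with_background(self):
        rng = np.random.default_rng(1)
        sub = dc.sample_proposals(self._assigned(10, 5000, rng), 512, seed=1)
        n_fg = sum(p.is_foreground for p in sub)
        assert n_fg == 10 and len(sub) == 512

    def test_background_deficit_filled_with_foreground(self):
        rng = np.random.default_rng(2)
        sub = dc.sample_proposals(self._assigned(1000, 100, rng), 512, seed=1)
        assert len(sub) == 512
        assert sum(not p.is_foreground for p in sub) == 100

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        pool = self._assigned(300, 3000, rng)
        a = dc.sample_proposals(pool, 512, seed=7)
        b = dc.sample_proposals(pool, 512, seed=7)
        assert [id(p) for p in a] == [id(p) for p in b]

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            dc.sample_proposals([], 512)


class TestAnchors:
    def test_three_per_position(self):
        a = dc.gen_anchors(4, 4, stride=16)
        assert a.shape == (48, 4)

    def test_shared_center_per_position(self):
        a = dc.gen_anchors(1, 1, stride=16, scale=32)
        centers = dc.corner_to_center(a)[:, :2]
        assert np.allclose(centers, centers[0])
        assert np.allclose(centers[0], [8.0, 8.0])

    def test_equal_areas_across_ratios(self):
        a = dc.gen_anchors(1, 1, stride=16, scale=32, ratios=(0.5, 1.0, 2.0))
        wh = dc.corner_to_center(a)[:, 2:]
        areas = wh[:, 0] * wh[:, 1]
        assert np.allclose(areas, 32.0**2)


def nms_oracle(boxes, scores, thresh):
    """Independent O(n²) greedy reference with its own IoU arithmetic."""
    def one_iou(a, b):
        ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
        iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
        inter = ix * iy
        ua = (a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter
        return inter / ua

    idx = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    keep, dead = [], set()
    for i in idx:
        if i in dead:
            continue
        keep.append(i)
        for j in idx:
            if j not in dead and one_iou(boxes[i], boxes[j]) > thresh:
                dead.add(j)
    return keep


class TestNms:
    def test_single_box_kept(self):
        assert dc.nms(np.array([[0.0, 0, 5, 5]]), np.array([0.3])) == [0]

    def test_high_overlap_suppressed(self):
        boxes = np.array([[0.0, 0, 10, 10], [0.5, 0, 10.5, 10]])
        assert dc.nms(boxes, np.array([0.9, 0.8]), 0.7) == [0]

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 120))
        boxes = random_boxes(rng, n, span=60, max_side=30)
        scores = rng.random(n)
        for thresh in (0.3, 0.7):
            assert dc.nms(boxes, scores, thresh) == nms_oracle(
                boxes, scores, thresh
            )

    def test_order_independence_up_to_ties(self):
        rng = np.random.default_rng(5)
        boxes = random_boxes(rng, 50)
        scores = rng.random(50)
        perm = rng.permutation(50)
        kept = dc.nms(boxes, scores, 0.5)
        kept_perm = dc.nms(boxes[perm], scores[perm], 0.5)
        assert sorted(perm[kept_perm]) == sorted(kept)

    def test_kept_scores_non_increasing(self):
        rng = np.random.default_rng(6)
        boxes = random_boxes(rng, 80)
        scores = rng.random(80)
        kept = dc.nms(boxes, scores, 0.5)
        s = scores[kept]
        assert np.all(np.diff(s) <= 0)


class TestFinalBeatNms:
    def test_cross_category_overlap_keeps_only_top(self):
        dets = [
            dc.Detection((0, 0, 10, 10), "N", 0.9),
            dc.Detection((1, 1, 11, 11), "V", 0.95),
        ]
        out = dc.final_beat_nms(dets)
        assert [d.class12 for d in out] == ["V"]

    def test_disjoint_beats_all_kept(self):
        dets = [
            dc.Detection((0, 0, 10, 10), "N", 0.9),
            dc.Detection((20, 0, 30, 10), "V", 0.8),
            dc.Detection((40, 0, 50, 10), "L", 0.7),
        ]
        assert len(dc.final_beat_nms(dets)) == 3

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        boxes = random_boxes(rng, 30)
        dets = [
            dc.Detection(tuple(b), "N", float(s))
            for b, s in zip(boxes, rng.random(30))
        ]
        once = dc.final_beat_nms(dets)
        twice = dc.final_beat_nms(once)
        assert once == twice
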