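"""Anchor generation, box codec, matching, multibox loss, NMS, IoU."""

import numpy as np
import pytest

from osteoquant.annotation import BBox
from osteoquant.detector import (
    AnchorSet,
    DetectorConfig,
    decode_boxes,
    desk_profile,
    encode_boxes,
    generate_anchors,
    iou,
    iou_matrix,
    match_anchors,
    multibox_loss,
    nms,
    full_profile,
)
from osteoquant import nn


class TestIoU:
    def test_identical_boxes(self):
        b = BBox(2, 3, 10, 12)
        assert iou(b, b) == 1.0

    def test_disjoint_boxes(self):
        assert iou(BBox(0, 0, 1, 1), BBox(5, 5, 6, 6)) == 0.0

    def test_hand_computed_overlap(self):
        # intersection 1, union 7
        assert iou(BBox(0, 0, 2, 2), BBox(1, 1, 3, 3)) == pytest.approx(1 / 7)

    def test_matrix_agrees_with_scalar(self, random_boxes):
        a = random_boxes(20)
        b = random_boxes(15)
        mat = iou_matrix(a, b)
        for i in (0, 7, 19):
            for j in (0, 5, 14):
                assert mat[i, j] == pytest.approx(
                    iou(BBox(*a[i]), BBox(*b[j])), abs=1e-12
                )


class TestAnchors:
    def test_count_is_closed_form(self):
        cfg = full_profile()
        anchors = generate_anchors(cfg)
        expected = cfg.anchors_per_position * sum(
            s * s for s in cfg.head_feature_sizes()
        )
        assert len(anchors) == expected
        # the full-scale profile keeps the classic SSD pyramid sizes
        assert cfg.head_feature_sizes() == [38, 19, 10, 5]

    def test_anchors_inside_unit_square(self):
        for cfg in (full_profile(), desk_profile()):
            c = generate_anchors(cfg).corners
            assert (c >= 0).all() and (c <= 1).all()
            assert (c[:, 2] > c[:, 0]).all() and (c[:, 3] > c[:, 1]).all()

    def test_physical_size_coverage(self):
        """The desk profile's anchors span the 51-383 μm cell-size range at
        its documented pixel scale."""
        lo, hi = desk_profile().anchor_physical_range()
        assert lo <= 51.0
        assert hi >= 383.0

    def test_physical_range_requires_pixel_scale(self):
        with pytest.raises(ValueError, match="um_per_input_px"):
            full_profile().anchor_physical_range()

    def test_determinism(self):
        a = generate_anchors(desk_profile()).corners
        b = generate_anchors(desk_profile()).corners
        np.testing.assert_array_equal(a, b)


class TestBoxCodec:
    def test_box_equal_to_anchor_encodes_to_zero(self):
        anchors = np.array([[0.5, 0.5, 0.2, 0.2]])
        boxes = np.array([[0.4, 0.4, 0.6, 0.6]])
        np.testing.assert_allclose(encode_boxes(boxes, anchors), 0.0, atol=1e-12)

    def test_round_trip_on_random_pairs(self, rng):
        n = 1000
        anchors = np.stack(
            [
                rng.uniform(0.1, 0.9, n),
                rng.uniform(0.1, 0.9, n),
                rng.uniform(0.02, 0.4, n),
                rng.uniform(0.02, 0.4, n),
            ],
            axis=1,
        )
        x0 = rng.uniform(0, 0.7, n)
        y0 = rng.uniform(0, 0.7, n)
        boxes = np.stack(
            [x0, y0, x0 + rng.uniform(0.01, 0.3, n), y0 + rng.uniform(0.01, 0.3, n)],
            axis=1,
        )
        rt = decode_boxes(encode_boxes(boxes, anchors), anchors)
        assert np.abs(rt - boxes).max() < 1e-6

    def test_hand_encoded_pair(self):
        # anchor (cx,cy,w,h) = (0.5, 0.5, 0.2, 0.1); box corners give
        # center (0.56, 0.52), size (0.3, 0.2)
        anchor = np.array([[0.5, 0.5, 0.2, 0.1]])
        box = np.array([[0.41, 0.42, 0.71, 0.62]])
        t = encode_boxes(box, anchor)[0]
        assert t[0] == pytest.approx((0.56 - 0.5) / (0.2 * 0.1))
        assert t[1] == pytest.approx((0.52 - 0.5) / (0.1 * 0.1))
        assert t[2] == pytest.approx(np.log(0.3 / 0.2) / 0.2)
        assert t[3] == pytest.approx(np.log(0.2 / 0.1) / 0.2)

    def test_nonpositive_box_rejected(self):
        anchors = np.array([[0.5, 0.5, 0.2, 0.2]])
        with pytest.raises(ValueError):
            encode_boxes(np.array([[0.5, 0.5, 0.5, 0.7]]), anchors)


def _toy_anchorset(corners):
    corners = np.asarray(corners, dtype=float)
    centers = np.stack(
        [
            (corners[:, 0] + corners[:, 2]) / 2,
            (corners[:, 1] + corners[:, 3]) / 2,
            corners[:, 2] - corners[:, 0],
            corners[:, 3] - corners[:, 1],
        ],
        axis=1,
    )
    return AnchorSet(corners, centers, np.zeros(len(corners), dtype=int))


class TestMatchAnchors:
    def test_no_ground_truth_all_background(self):
        anchors = _toy_anchorset([[0, 0, 0.1, 0.1], [0.5, 0.5, 0.6, 0.6]])
        assert (match_anchors(anchors, np.zeros((0, 4))) == -1).all()

    def test_high_iou_anchor_positive(self):
        anchors = _toy_anchorset([[0, 0, 0.1, 0.1], [0.48, 0.48, 0.62, 0.62]])
        gt = np.array([[0.5, 0.5, 0.6, 0.6]])
        assignment = match_anchors(anchors, gt)
        assert assignment[1] == 0 and assignment[0] == -1

    def test_best_anchor_forced_even_below_threshold(self):
        anchors = _toy_anchorset([[0, 0, 0.2, 0.2], [0.4, 0.4, 0.9, 0.9]])
        gt = np.array([[0.41, 0.41, 0.55, 0.55]])  # IoU < 0.5 with both
        assignment = match_anchors(anchors, gt)
        assert (assignment >= 0).sum() == 1
        assert assignment[1] == 0

    def test_equals_brute_force_matcher(self, rng, random_boxes):
        for _ in range(20):
            n_a, n_g = int(rng.integers(5, 50)), int(rng.integers(1, 8))
            a = random_boxes(n_a, size=1.0, min_side=0.05, max_side=0.4)
            g = random_boxes(n_g, size=1.0, min_side=0.05, max_side=0.4)
            anchors = _toy_anchorset(a)
            got = match_anchors(anchors, g, 0.5)
            # brute force: threshold step then per-gt bipartite override
            ious = iou_matrix(a, g)
            want = np.full(n_a, -1)
            for i in range(n_a):
                j = int(np.argmax(ious[i]))
                if ious[i, j] >= 0.5:
                    want[i] = j
            for j in range(n_g):
                want[int(np.argmax(ious[:, j]))] = j
            np.testing.assert_array_equal(got, want)


class TestMultiboxLoss:
    def _instance(self, rng, n_anchors=10, n_classes=5):
        logits = rng.normal(size=(n_anchors, n_classes))
        offsets = rng.normal(size=(n_anchors, 4))
        assignment = np.full(n_anchors, -1)
        assignment[2] = 0
        assignment[7] = 1
        gt_labels = np.array([1, 3])
        loc_targets = np.zeros((n_anchors, 4))
        loc_targets[2] = rng.normal(size=4)
        loc_targets[7] = rng.normal(size=4)
        return logits, offsets, assignment, gt_labels, loc_targets

    def test_perfect_localization_has_zero_loc_loss(self, rng):
        logits, offsets, assignment, labels, loc_t = self._instance(rng)
        offsets = loc_t.copy()
        out = multibox_loss(logits, offsets, assignment, labels, loc_t)
        assert out.loc == 0.0
        assert out.total == pytest.approx(out.conf)

    def test_loss_decreases_as_true_logit_grows(self, rng):
        logits, offsets, assignment, labels, loc_t = self._instance(rng)
        base = multibox_loss(logits, offsets, assignment, labels, loc_t).total
        logits2 = logits.copy()
        logits2[2, 1] += 1.0  # raise the true-class logit of a positive
        better = multibox_loss(logits2, offsets, assignment, labels, loc_t).total
        assert better < base

    def test_equals_naive_summation(self, rng):
        """Value matches a literal per-anchor summation with hard-negative
        selection done by explicit sort."""
        logits, offsets, assignment, labels, loc_t = self._instance(rng)
        out = multibox_loss(logits, offsets, assignment, labels, loc_t,
                            neg_pos_ratio=3)
        # naive reference
        pos = np.where(assignment >= 0)[0]
        n_pos = len(pos)
        p = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        ce = np.zeros(len(logits))
        for i in range(len(logits)):
            target = labels[assignment[i]] if assignment[i] >= 0 else 0
            ce[i] = -np.log(p[i, target])
        negs = sorted(
            [i for i in range(len(logits)) if assignment[i] < 0],
            key=lambda i: -ce[i],
        )[: 3 * n_pos]
        l_conf = ce[pos].sum() + sum(ce[i] for i in negs)
        l_loc = 0.0
        for i in pos:
            d = offsets[i] - loc_t[i]
            l_loc += np.where(np.abs(d) < 1, 0.5 * d**2, np.abs(d) - 0.5).sum()
        assert out.total == pytest.approx((l_conf + l_loc) / n_pos)

    def test_no_positives_contract(self, rng):
        logits = rng.normal(size=(20, 5))
        offsets = rng.normal(size=(20, 4))
        out = multibox_loss(
            logits, offsets, np.full(20, -1), np.zeros(0, dtype=int),
            np.zeros((20, 4)), neg_pos_ratio=3,
        )
        assert out.loc == 0.0
        assert out.n_pos == 0
        assert out.total > 0  # confidence over the capped hardest negatives

    def test_gradient_matches_finite_differences(self, rng):
        logits, offsets, assignment, labels, loc_t = self._instance(rng)
        out = multibox_loss(logits, offsets, assignment, labels, loc_t)
        eps = 1e-6
        for idx in [(2, 1), (7, 0), (0, 2)]:
            lp = logits.copy()
            lp[idx] += eps
            num = (
                multibox_loss(lp, offsets, assignment, labels, loc_t).total
                - out.total
            ) / eps
            assert num == pytest.approx(out.dlogits[idx], abs=1e-4)
        op = offsets.copy()
        op[2, 3] += eps
        num = (
            multibox_loss(logits, op, assignment, labels, loc_t).total - out.total
        ) / eps
        assert num == pytest.approx(out.doffsets[2, 3], abs=1e-4)


class TestNMS:
    def test_identical_boxes_keep_higher_score(self):
        boxes = np.array([[0, 0, 10, 10], [0, 0, 10, 10]])
        keep = nms(boxes, np.array([0.4, 0.9]), 0.45)
        assert list(keep) == [1]

    def test_disjoint_all_kept_in_score_order(self):
        boxes = np.array([[0, 0, 5, 5], [20, 20, 25, 25], [40, 0, 45, 5]])
        keep = nms(boxes, np.array([0.2, 0.9, 0.5]), 0.45)
        assert list(keep) == [1, 2, 0]

    def test_matches_quadratic_oracle(self, rng, random_boxes):
        """Greedy vectorized NMS equals a literal O(n²) reference on random
        instances up to 200 boxes."""

        def oracle(boxes, scores, thr):
            order = list(np.argsort(-scores, kind="stable"))
            kept = []
            while order:
                i = order.pop(0)
                kept.append(i)
                order = [
                    j
                    for j in order
                    if iou(BBox(*boxes[i]), BBox(*boxes[j])) <= thr
                ]
            return kept

        for trial in range(30):
            n = int(rng.integers(2, 200))
            boxes = random_boxes(n, size=60.0, min_side=3, max_side=25)
            scores = rng.uniform(size=n)
            thr = float(rng.uniform(0.2, 0.7))
            assert list(nms(boxes, scores, thr)) == oracle(boxes, scores, thr)

    def test_no_surviving_high_overlap_pair(self, rng, random_boxes):
        boxes = random_boxes(100, size=40.0)
        scores = rng.uniform(size=100)
        keep = nms(boxes, scores, 0.45)
        kept = boxes[keep]
        m = iou_matrix(kept, kept)
        np.fill_diagonal(m, 0.0)
        assert m.max() <= 0.45 + 1e-12


class TestNetworkPlumbing:
    def test_conv_gradient_matches_finite_differences(self, rng):
        conv = nn.Conv2d(2, 3, 3, stride=2, rng=rng)
        x = rng.standard_normal((1, 2, 9, 9)).astype(np.float32)
        out = conv.forward(x)
        g = np.ones_like(out)
        dx = conv.backward(g)
        eps = 1e-3
        for idx in [(0, 0, 0, 0), (0, 1, 4, 5), (0, 0, 8, 8)]:
            xp = x.copy()
            xp[idx] += eps
            num = (conv.forward(xp).sum() - out.sum()) / eps
            assert num == pytest.approx(dx[idx], abs=1e-2)
        wp = conv.params["W"].copy()
        conv.params["W"][0, 0, 1, 1] += eps
        num = (conv.forward(x).sum() - out.sum()) / eps
        conv.params["W"][...] = wp
        assert num == pytest.approx(conv.grads["W"][0, 0, 1, 1], rel=1e-2, abs=1e-2)

    def test_maxpool_adjoint(self, rng):
        pool = nn.MaxPool2()
        x = rng.standard_normal((1, 1, 6, 6)).astype(np.float64)
        out = pool.forward(x)
        dx = pool.backward(np.ones_like(out))
        # the adjoint routes each output gradient to the max input(s)
        assert dx.sum() == pytest.approx(out.size)
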