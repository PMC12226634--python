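import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repromptseg import (
    Detection,
    DetectionSet,
    GroundTruthFlowProvider,
    LabelSchema,
    MaskSequence,
    compute_flow,
    contour_distance,
    detection_report,
    macro_overlap,
    match_detections,
    temporal_consistency_report,
    warp_mask,
)
from repromptseg.metrics import box_iou

from _oracles import brute_contour_distance, brute_overlap


# ---------------------------------------------------------------------------
# Warping
# ---------------------------------------------------------------------------

class TestWarpMask:
    def test_zero_flow_is_identity(self):
        mask = np.random.default_rng(0).integers(0, 4, (10, 10)).astype(np.uint8)
        np.testing.assert_array_equal(warp_mask(mask, np.zeros((10, 10, 2))), mask)

    def test_integer_shift_moves_square(self):
        mask = np.zeros((8, 8), np.uint8)
        mask[2:5, 2:5] = 3
        flow = np.zeros((8, 8, 2))
        flow[..., 1] = 1.0
        out = warp_mask(mask, flow)
        expected = np.zeros((8, 8), np.uint8)
        expected[2:5, 3:6] = 3
        np.testing.assert_array_equal(out, expected)

    def test_subhalf_flow_rounds_to_identity(self):
        mask = np.zeros((8, 8), np.uint8)
        mask[2:5, 2:5] = 3
        flow = np.full((8, 8, 2), 0.4)
        np.testing.assert_array_equal(warp_mask(mask, flow), mask)

    def test_half_rounds_away_from_zero(self):
        mask = np.zeros((4, 4), np.uint8)
        mask[1, 1] = 2
        flow = np.zeros((4, 4, 2))
        flow[..., 1] = 0.5
        assert warp_mask(mask, flow)[1, 2] == 2
        flow[..., 1] = -0.5
        assert warp_mask(mask, flow)[1, 0] == 2

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(seed=st.integers(0, 10_000), dr=st.integers(-3, 3), dc=st.integers(-3, 3))
    def test_integer_flow_preserves_label_multiset(self, seed, dr, dc):
        """Uniform integer flow is a bijection up to frame-exit pixels."""
        rng = np.random.default_rng(seed)
        mask = rng.integers(0, 4, (9, 9)).astype(np.uint8)
        flow = np.zeros((9, 9, 2))
        flow[..., 0], flow[..., 1] = dr, dc
        out = warp_mask(mask, flow)
        r0, r1 = max(dr, 0), 9 + min(dr, 0)
        c0, c1 = max(dc, 0), 9 + min(dc, 0)
        np.testing.assert_array_equal(
            out[r0:r1, c0:c1], mask[r0 - dr : r1 - dr, c0 - dc : c1 - dc]
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            warp_mask(np.zeros((4, 4), np.uint8), np.zeros((5, 4, 2)))


class TestComputeFlow:
    def test_identical_frames_give_near_zero_flow(self, static_scene):
        f = static_scene.frames[0]
        flow = compute_flow(f, f)
        assert np.median(np.hypot(flow[..., 0], flow[..., 1])) < 0.1

    def test_gt_provider_requires_flow(self):
        with pytest.raises(ValueError, match="no ground-truth flow"):
            GroundTruthFlowProvider(None)


# ---------------------------------------------------------------------------
# Overlap / contour metrics
# ---------------------------------------------------------------------------

class TestMacroOverlap:
    def test_identical_masks_are_perfect(self):
        m = np.random.default_rng(1).integers(0, 3, (8, 8)).astype(np.uint8)
        assert macro_overlap(m, m) == (1.0, 1.0)

    def test_disjoint_blobs_score_zero_for_class(self):
        a = np.zeros((8, 8), np.uint8)
        b = np.zeros((8, 8), np.uint8)
        a[0:2, 0:4] = 1
        b[6:8, 0:4] = 1
        dice, iou = macro_overlap(a, b)
        # macro over {background, class 1}: class 1 contributes 0
        bg_dice = 2 * 48 / (56 + 56)
        assert dice == pytest.approx((bg_dice + 0.0) / 2)

    def test_worked_example_on_6x6_grid(self):
        """Two 8-pixel class-1 regions overlapping in 4 pixels on a 6x6 grid."""
        a2 = np.zeros((6, 6), np.uint8)
        b2 = np.zeros((6, 6), np.uint8)
        a2[0:2, 0:4] = 1
        b2[0:2, 2:6] = 1           # overlap 2x2 = 4 pixels
        dice, iou = macro_overlap(a2, b2)
        d1, i1 = 2 * 4 / 16, 4 / 12
        bg_inter = 36 - 12
        d0, i0 = 2 * bg_inter / (28 + 28), bg_inter / (28 + 28 - bg_inter)
        assert dice == pytest.approx((d0 + d1) / 2, abs=1e-12)
        assert iou == pytest.approx((i0 + i1) / 2, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = rng.integers(0, 4, (8, 8)).astype(np.uint8)
            b = rng.integers(0, 4, (8, 8)).astype(np.uint8)
            assert macro_overlap(a, b) == macro_overlap(b, a)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            macro_overlap(np.zeros((4, 4), np.uint8), np.zeros((5, 4), np.uint8))


class TestContourDistance:
    def test_identical_masks_are_zero(self):
        m = np.zeros((8, 8), np.uint8)
        m[2:6, 2:6] = 1
        assert contour_distance(m, m) == 0.0

    def test_vertical_lines_two_columns_apart(self):
        a = np.zeros((8, 8), np.uint8)
        b = np.zeros((8, 8), np.uint8)
        a[:, 2] = 1
        b[:, 4] = 1
        assert contour_distance(a, b) == pytest.approx(2.0)

    def test_one_sided_class_pays_diagonal_penalty(self):
        a = np.zeros((3, 4), np.uint8)
        a[1, 1] = 2
        b = np.zeros((3, 4), np.uint8)
        assert contour_distance(a, b) == pytest.approx(5.0)  # sqrt(9 + 16)

    def test_all_background_is_undefined(self):
        nan = contour_distance(np.zeros((4, 4), np.uint8), np.zeros((4, 4), np.uint8))
        assert math.isnan(nan)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.integers(0, 3, (8, 8)).astype(np.uint8)
            b = rng.integers(0, 3, (8, 8)).astype(np.uint8)
            assert contour_distance(a, b) == pytest.approx(
                contour_distance(b, a), nan_ok=True
            )


class TestBruteForceAgreement:
    """Implementation vs independent pixel/pair enumeration on random masks."""

    @pytest.mark.parametrize("seed", range(100))
    def test_overlap_and_contours_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 4, (8, 8)).astype(np.uint8)
        b = rng.integers(0, 4, (8, 8)).astype(np.uint8)
        dice, iou = macro_overlap(a, b)
        bdice, biou = brute_overlap(a, b)
        assert abs(dice - bdice) < 1e-12 and abs(iou - biou) < 1e-12
        cd, bcd = contour_distance(a, b), brute_contour_distance(a, b)
        if math.isnan(bcd):
            assert math.isnan(cd)
        else:
            assert abs(cd - bcd) < 1e-12


# ---------------------------------------------------------------------------
# Detection matching / reports
# ---------------------------------------------------------------------------

def _det(cid, score, box, shape=(10, 10)):
    mask = np.zeros(shape, bool)
    x0, y0, x1, y1 = box
    mask[int(y0 * shape[0]) : int(y1 * shape[0]),
         int(x0 * shape[1]) : int(x1 * shape[1])] = True
    return Detection(cid, score, box, mask)


class TestMatchDetections:
    def test_single_pair_above_threshold_matches(self):
        p = DetectionSet(0, (10, 10), [_det(1, 0.9, (0.0, 0.0, 0.5, 0.6))])
        g = DetectionSet(0, (10, 10), [_det(1, 1.0, (0.0, 0.0, 0.5, 1.0))])
        iou = box_iou(p.detections[0].box, g.detections[0].box)
        assert iou == pytest.approx(0.6)
        m = match_detections(p, g, 0.5)
        assert len(m.tp) == 1 and not m.fp and not m.fn

    def test_empty_predictions_are_all_fn(self):
        g = DetectionSet(0, (10, 10), [
            _det(1, 1.0, (0.0, 0.0, 0.5, 0.5)),
            _det(2, 1.0, (0.5, 0.5, 1.0, 1.0)),
        ])
        m = match_detections(DetectionSet(0, (10, 10)), g, 0.5)
        assert (len(m.tp), len(m.fp), len(m.fn)) == (0, 0, 2)

    def test_greedy_prefers_higher_score(self):
        g = DetectionSet(0, (10, 10), [_det(1, 1.0, (0.0, 0.0, 0.5, 0.5))])
        p = DetectionSet(0, (10, 10), [
            _det(1, 0.8, (0.0, 0.0, 0.5, 0.6)),
            _det(1, 0.9, (0.0, 0.0, 0.5, 0.5)),
        ])
        m = match_detections(p, g, 0.5)
        assert len(m.tp) == 1 and m.tp[0][0] == 1  # the 0.9 prediction
        assert m.fp == [0]

    def test_class_mismatch_never_matches(self):
        p = DetectionSet(0, (10, 10), [_det(1, 0.9, (0.0, 0.0, 0.5, 0.5))])
        g = DetectionSet(0, (10, 10), [_det(2, 1.0, (0.0, 0.0, 0.5, 0.5))])
        m = match_detections(p, g, 0.5)
        assert not m.tp and m.fp == [0] and m.fn == [0]


class TestDetectionReport:
    def test_perfect_detector_scores_one(self, entry_scene, schema):
        rep = detection_report(
            entry_scene.gt_detections, entry_scene.gt_detections, schema
        )
        assert rep.summary() == {
            "class_f1": 1.0, "bb_iou": 1.0, "mask_dice": 1.0, "semantic_dice": 1.0,
        }

    def test_f1_formula_on_constructed_counts(self, schema):
        gts = DetectionSet(0, (10, 10), [
            _det(1, 1.0, (0.0, 0.0, 0.4, 0.4)),
            _det(2, 1.0, (0.5, 0.0, 0.9, 0.4)),
            _det(3, 1.0, (0.0, 0.5, 0.4, 0.9)),
        ])
        preds = DetectionSet(0, (10, 10), [
            _det(1, 0.9, (0.0, 0.0, 0.4, 0.4)),
            _det(2, 0.8, (0.5, 0.0, 0.9, 0.4)),
        ])
        rep = detection_report([preds], [gts], schema)
        assert rep.class_f1 == pytest.approx(2 * 2 / (2 * 2 + 0 + 1))

    def test_bb_iou_is_mean_over_true_positives(self, schema):
        g = DetectionSet(0, (10, 10), [
            _det(1, 1.0, (0.0, 0.0, 0.5, 1.0)),
            _det(2, 1.0, (0.5, 0.0, 1.0, 0.5)),
        ])
        p = DetectionSet(0, (10, 10), [
            _det(1, 0.9, (0.0, 0.0, 0.5, 0.6)),   # IoU 0.6
            _det(2, 0.9, (0.5, 0.0, 1.0, 0.4)),   # IoU 0.8
        ])
        rep = detection_report([p], [g], schema)
        assert rep.bb_iou == pytest.approx(0.7)

    def test_vacuous_case_warns(self, schema):
        empty = [DetectionSet(0, (8, 8))]
        with pytest.warns(UserWarning, match="vacuous"):
            rep = detection_report(empty, empty, schema)
        assert rep.class_f1 == 1.0

    @pytest.mark.parametrize("seed", range(50))
    def test_report_matches_brute_force_counts(self, schema, seed):
        """Pooled F1 agrees with an independent greedy pair enumeration."""
        rng = np.random.default_rng(seed)

        def random_set():
            ds = DetectionSet(0, (10, 10))
            for _ in range(rng.integers(0, 4)):
                x0, y0 = rng.integers(0, 5, 2) / 10
                w, h = rng.integers(2, 5, 2) / 10
                ds.detections.append(
                    _det(int(rng.integers(1, 3)), float(rng.random()),
                         (x0, y0, min(x0 + w, 1.0), min(y0 + h, 1.0)))
                )
            return ds

        preds, gts = random_set(), random_set()
        m = match_detections(preds, gts, 0.5)
        # brute force: enumerate all same-class pairs, greedy by (score, iou)
        pairs = sorted(
            (
                (pi, gi, box_iou(p.box, g.box))
                for pi, p in enumerate(preds)
                for gi, g in enumerate(gts)
                if p.class_id == g.class_id
                and box_iou(p.box, g.box) >= 0.5
            ),
            key=lambda c: (-preds.detections[c[0]].score, -c[2], c[0], c[1]),
        )
        up, ug, tp = set(), set(), 0
        for pi, gi, _ in pairs:
            if pi not in up and gi not in ug:
                up.add(pi)
                ug.add(gi)
                tp += 1
        assert len(m.tp) == tp
        assert len(m.fp) == len(preds) - tp
        assert len(m.fn) == len(gts) - tp


# ---------------------------------------------------------------------------
# Sequence-level consistency
# ---------------------------------------------------------------------------

class TestTemporalConsistency:
    def test_exact_flow_gives_perfect_pairs(self, entry_scene, schema):
        rep = temporal_consistency_report(
            entry_scene.frames,
            entry_scene.gt_masks,
            GroundTruthFlowProvider(entry_scene.gt_flow),
            schema,
        )
        for t, (d, i) in enumerate(zip(rep.dice_of, rep.iou_of)):
            if t == 19:  # entry event at frame 20
                continue
            assert d == 1.0 and i == 1.0

    def test_static_scene_is_perfectly_consistent(self, static_scene, schema):
        rep = temporal_consistency_report(
            static_scene.frames,
            static_scene.gt_masks,
            GroundTruthFlowProvider(static_scene.gt_flow),
            schema,
        )
        assert rep.mean_cd_t == 0.0 and rep.mean_iou_t == 1.0

    def test_flicker_scores_worse_than_stable(self, static_scene, schema):
        stable = static_scene.gt_masks
        flicker = stable.masks.copy()
        flicker[1::2][flicker[1::2] == 3] = 0  # drop class 3 on odd frames
        frep = temporal_consistency_report(
            static_scene.frames, MaskSequence(flicker),
            GroundTruthFlowProvider(static_scene.gt_flow), schema,
        )
        srep = temporal_consistency_report(
            static_scene.frames, stable,
            GroundTruthFlowProvider(static_scene.gt_flow), schema,
        )
        assert frep.mean_iou_t < srep.mean_iou_t
        assert frep.mean_cd_t > srep.mean_cd_t

    def test_length_mismatch_rejected(self, static_scene, schema):
        short = MaskSequence(static_scene.gt_masks.masks[:-1])
        with pytest.raises(ValueError, match="length mismatch"):
            temporal_consistency_report(
                static_scene.frames, short,
                GroundTruthFlowProvider(static_scene.gt_flow), schema,
            )
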