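"""Detection scoring: TP/FP/FN, average precision, NMS, stitching, ratios."""

import numpy as np
import pytest

from cellconcord import (
    AnnotationSet,
    CellLabel,
    CellRecord,
    DetectorModel,
    average_precision,
    class_ratio,
    evaluate_detections,
    mean_average_precision,
    nms_merge,
    simulate_detector,
    stitch_patch_detections,
)
from cellconcord.errors import UndefinedStatisticError, ValidationError
from cellconcord.records import REAL_LABELS

from conftest import make_set, random_set


def scored(centers, labels, scores, source_id="det", roi_id="roi"):
    return make_set(centers, labels, source_id=source_id, roi_id=roi_id, scores=scores)


class TestEvaluateDetections:
    def test_identical_detections_are_all_tp(self, rng):
        ref = random_set(rng, 30, extent=400.0, source_id="ref")
        det = scored(
            [c.center for c in ref], [c.label for c in ref], [1.0] * 30
        )
        counts, _ = evaluate_detections(ref, det, threshold=0.0)
        for label in REAL_LABELS:
            assert counts[label].fp == 0 and counts[label].fn == 0
            assert counts[label].tp == ref.count(label)

    def test_unannotated_detection_is_fp(self):
        ref = make_set([], source_id="ref")
        det = scored([(10, 10)], ["tumor"], [0.9])
        counts, _ = evaluate_detections(ref, det)
        assert counts[CellLabel.TUMOR].fp == 1

    def test_unscored_detections_rejected(self):
        ref = make_set([(0, 0)], source_id="ref")
        det = make_set([(0, 0)], source_id="det")
        with pytest.raises(ValidationError):
            evaluate_detections(ref, det)

    def test_class_swap_counts_fn_and_fp(self):
        ref = make_set([(50, 50)], ["tumor"], source_id="ref")
        det = scored([(52, 50)], ["cd3_positive"], [0.8])
        counts, _ = evaluate_detections(ref, det)
        assert counts[CellLabel.TUMOR].fn == 1
        assert counts[CellLabel.CD3_POSITIVE].fp == 1
        assert counts[CellLabel.TUMOR].tp == 0

    def test_threshold_discards_low_scores(self):
        ref = make_set([(50, 50)], ["tumor"], source_id="ref")
        det = scored([(50, 50)], ["tumor"], [0.3])
        counts, _ = evaluate_detections(ref, det, threshold=0.5)
        assert counts[CellLabel.TUMOR].tp == 0
        assert counts[CellLabel.TUMOR].fn == 1

    def test_diverse_reference_and_its_detection_excluded(self):
        ref = make_set(
            [(50, 50), (200, 200)], [CellLabel.DIVERSE, CellLabel.TUMOR], source_id="ref"
        )
        det = scored([(51, 50), (201, 200)], ["tumor", "tumor"], [0.9, 0.9])
        counts, ecm = evaluate_detections(ref, det)
        # the detection sitting on the diverse cell is neither TP nor FP;
        # only the tumor cell and its detection remain in the matrix
        assert counts[CellLabel.TUMOR].tp == 1
        assert counts[CellLabel.TUMOR].fp == 0
        assert ecm.total == 1

    def test_tp_fn_conservation_across_thresholds(self, small_truth):
        det, _ = simulate_detector(small_truth, DetectorModel(seed=4))
        for thr in (0.0, 0.3, 0.7, 1.0):
            counts, _ = evaluate_detections(small_truth, det, threshold=thr)
            for label in REAL_LABELS:
                assert counts[label].tp + counts[label].fn == small_truth.count(label)

    def test_planted_counts_recovered(self, small_truth):
        """Provenance bookkeeping is the oracle for TP/FP at threshold 0."""
        model = DetectorModel(recall=(0.8, 0.8, 0.8), clutter_rate=20.0,
                              jitter_sd=2.0, seed=12)
        det, prov = simulate_detector(small_truth, model)
        counts, _ = evaluate_detections(small_truth, det, threshold=0.0)
        true_rows = prov[prov.truth_index >= 0]
        clutter_rows = prov[prov.truth_index < 0]
        for k, label in enumerate(REAL_LABELS):
            expected_tp = sum(
                1
                for r in true_rows.itertuples()
                if r.assigned_label == label.value
                and small_truth[r.truth_index].label is label
            )
            assert counts[label].tp == expected_tp
        assert sum(c.fp for c in counts.values()) == len(clutter_rows)


class TestAveragePrecision:
    def test_perfect_detector_scores_one(self, rng):
        ref = random_set(rng, 20, extent=400.0, source_id="ref")
        det = scored([c.center for c in ref], [c.label for c in ref], [1.0] * 20)
        for label in REAL_LABELS:
            if ref.count(label):
                assert average_precision(ref, det, label).ap == pytest.approx(1.0)

    def test_pure_clutter_scores_zero(self):
        ref = make_set([(50, 50)], ["tumor"], source_id="ref")
        det = scored([(500, 500), (800, 800)], ["tumor", "tumor"], [0.9, 0.8])
        assert average_precision(ref, det, CellLabel.TUMOR).ap == pytest.approx(0.0)

    def test_absent_class_reported_absent_not_zero(self):
        ref = make_set([(50, 50)], ["tumor"], source_id="ref")
        det = scored([(50, 50)], ["tumor"], [1.0])
        with pytest.raises(UndefinedStatisticError):
            average_precision(ref, det, CellLabel.CD3_POSITIVE)
        _, per_class = mean_average_precision(ref, det)
        assert CellLabel.CD3_POSITIVE not in per_class

    def test_toy_instance_matches_hand_tallied_pr_pairs(self):
        """4 tumor reference cells; detections: 3 true (scores .95/.75/.55),
        1 clutter (.65).  PR pairs tallied by hand over the 11 thresholds and
        summed per the recall-increment rule."""
        ref = make_set(
            [(0, 0), (100, 0), (200, 0), (300, 0)], ["tumor"] * 4, source_id="ref"
        )
        det = scored(
            [(0, 0), (100, 0), (200, 0), (700, 0)],
            ["tumor"] * 4,
            [0.95, 0.75, 0.55, 0.65],
        )
        result = average_precision(ref, det, CellLabel.TUMOR)
        # sigma 1.0: empty: P=1 (convention), R=0
        # sigma in {0.8, 0.9}: keep {.95}: P=1, R=1/4
        # sigma 0.7: keep {.95,.75}: P=1, R=1/2
        # sigma 0.6: +clutter .65: P=2/3, R=1/2
        # sigma <= 0.5: +true .55: P=3/4, R=3/4
        # sorted by increasing recall, AP = sum (R_{k+1}-R_k) * P_k
        # increments: 0->1/4 at P=1; 1/4->1/2 at P=1; 1/2->3/4 at P=2/3
        expected = 0.25 * 1.0 + 0.25 * 1.0 + 0.25 * (2 / 3)
        assert result.ap == pytest.approx(expected)
        assert len(result.points) == 11

    def test_monotone_score_transform_preserves_ap(self, small_truth):
        det, _ = simulate_detector(small_truth, DetectorModel(seed=8))
        ap1 = average_precision(small_truth, det, CellLabel.TUMOR).ap
        squeezed = AnnotationSet(
            roi_id=det.roi_id,
            source_id=det.source_id,
            cells=[
                CellRecord(
                    center_x=c.center_x, center_y=c.center_y, label=c.label,
                    source_id=c.source_id, box=c.box,
                    # affine squeeze within each 0.1 bin keeps bin membership
                    score=(np.floor(c.score * 10) / 10 + (c.score * 10 % 1) * 0.0999),
                )
                for c in det.cells
            ],
        )
        ap2 = average_precision(small_truth, squeezed, CellLabel.TUMOR).ap
        assert ap2 == pytest.approx(ap1, abs=1e-12)

    def test_ap_collapses_as_gate_shrinks(self, small_truth):
        """Shrinking the gate never raises AP beyond a small assignment
        rearrangement tolerance (the class-blind matcher may re-pair a few
        cells), and a gate below the localization error collapses AP."""
        det, _ = simulate_detector(small_truth, DetectorModel(jitter_sd=6.0, seed=9))
        aps = [
            average_precision(small_truth, det, CellLabel.TUMOR, gate=g).ap
            for g in (40.0, 25.0, 10.0, 4.0)
        ]
        assert all(b <= a + 0.01 for a, b in zip(aps, aps[1:]))
        assert aps[-1] < aps[0] / 2


class TestNmsMerge:
    def test_sparse_set_is_identity(self):
        det = scored([(0, 0), (100, 100), (200, 0)], ["tumor"] * 3, [0.5, 0.9, 0.7])
        merged = nms_merge([det], radius=25.0)
        assert len(merged) == 3
        assert [c.score for c in merged] == [0.9, 0.7, 0.5]  # descending

    def test_exact_duplicates_suppressed(self):
        det = scored([(0, 0), (100, 100)], ["tumor", "cd3_positive"], [0.8, 0.6])
        merged = nms_merge([det, det.with_source_id("copy")], radius=25.0)
        assert len(merged) == 2
        assert {c.label for c in merged} == {CellLabel.TUMOR, CellLabel.CD3_POSITIVE}

    def test_output_pairwise_distances_exceed_radius(self, rng):
        sets = [
            random_set(rng, 60, extent=300.0, source_id=f"m{k}", scores=True)
            for k in range(3)
        ]
        merged = nms_merge(sets, radius=30.0)
        centers = merged.centers()
        d = np.sqrt(((centers[:, None] - centers[None, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert d.min() > 30.0

    def test_matches_greedy_oracle(self, rng):
        """Independent re-implementation: sort all detections by score and
        sweep, suppressing within radius."""
        sets = [
            random_set(rng, 25, extent=200.0, source_id=f"m{k}", scores=True)
            for k in range(2)
        ]
        radius = 30.0
        merged = nms_merge(sets, radius=radius)

        cells = [c for s in sets for c in s.cells]
        order = sorted(
            range(len(cells)),
            key=lambda i: (-cells[i].score, cells[i].source_id,
                           cells[i].center_x, cells[i].center_y),
        )
        kept, out = [], []
        for i in order:
            ci = np.array(cells[i].center)
            if all(np.linalg.norm(ci - np.array(cells[j].center)) > radius for j in kept):
                kept.append(i)
                out.append(cells[i].center)
        assert [c.center for c in merged] == out

    def test_negative_radius_rejected(self):
        det = scored([(0, 0)], ["tumor"], [0.5])
        with pytest.raises(ValidationError):
            nms_merge([det], radius=-1.0)


class TestStitchPatchDetections:
    def test_single_patch_is_pure_translation(self):
        patch = scored([(10, 20)], ["tumor"], [0.9])
        merged = stitch_patch_detections([((128.0, 256.0), patch)])
        assert merged[0].center == (138.0, 276.0)

    def test_duplicate_in_overlap_collapses(self):
        # same ROI position (192, 64) seen by patches at x=0 and x=128
        p1 = scored([(192, 64)], ["tumor"], [0.9], source_id="p1")
        p2 = scored([(64, 64)], ["tumor"], [0.8], source_id="p2")
        merged = stitch_patch_detections([((0.0, 0.0), p1), ((128.0, 0.0), p2)])
        assert len(merged) == 1
        assert merged[0].center == (192.0, 64.0)
        assert merged[0].score == 0.9

    def test_off_grid_origin_rejected(self):
        patch = scored([(10, 10)], ["tumor"], [0.9])
        with pytest.raises(ValidationError):
            stitch_patch_detections([((100.0, 0.0), patch)])

    def test_detection_outside_patch_rejected(self):
        patch = scored([(300, 10)], ["tumor"], [0.9])
        with pytest.raises(ValidationError):
            stitch_patch_detections([((0.0, 0.0), patch)])

    def test_planted_duplicates_resolved_to_unique_cells(self, rng):
        """Cells in overlap bands are emitted by every covering patch; the
        stitched set must contain each planted cell exactly once."""
        stride, patch_size = 128.0, 256.0
        roi = 512.0
        n = 40
        centers = rng.uniform(20.0, roi - 20.0, size=(n, 2))
        # enforce >50 px separation so NMS cannot merge distinct cells
        kept_idx: list[int] = []
        for i in range(n):
            if all(np.linalg.norm(centers[i] - centers[j]) > 50.0 for j in kept_idx):
                kept_idx.append(i)
        centers = centers[kept_idx]
        patches = []
        origins = [
            (ox, oy)
            for ox in np.arange(0.0, roi - stride, stride)
            for oy in np.arange(0.0, roi - stride, stride)
        ]
        for ox, oy in origins:
            local = []
            for cx, cy in centers:
                if ox <= cx <= ox + patch_size and oy <= cy <= oy + patch_size:
                    local.append((cx - ox, cy - oy))
            patches.append(
                (
                    (ox, oy),
                    scored(local, ["tumor"] * len(local), [0.9] * len(local),
                           source_id=f"p{int(ox)}x{int(oy)}"),
                )
            )
        merged = stitch_patch_detections(patches, nms_radius=25.0)
        assert len(merged) == len(centers)


class TestClassRatio:
    def test_equal_counts_give_one(self):
        s = make_set(
            [(30.0 * i, 0.0) for i in range(20)],
            ["cd3_positive"] * 10 + ["non_specified"] * 10,
        )
        assert class_ratio(s, CellLabel.CD3_POSITIVE, CellLabel.NON_SPECIFIED) == 1.0

    def test_sixteen_percent_ratio(self):
        s = make_set(
            [(10.0 * i, 0.0) for i in range(116)],
            ["cd3_positive"] * 16 + ["non_specified"] * 100,
        )
        assert class_ratio(
            s, CellLabel.CD3_POSITIVE, CellLabel.NON_SPECIFIED
        ) == pytest.approx(0.16)

    def test_zero_denominator_undefined(self):
        s = make_set([(0, 0)], ["tumor"])
        with pytest.raises(UndefinedStatisticError):
            class_ratio(s, CellLabel.CD3_POSITIVE, CellLabel.NON_SPECIFIED)
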