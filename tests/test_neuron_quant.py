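"""Detection pipeline: reference detector, cleanup rules, densities, mAP."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from nigraquant import neuron_quant as nq
from nigraquant.imaging_io import RoiPolygon, Tile, TilingParams
from nigraquant.synthetic_data import HistologyFixtureParams, generate_histology_fixture


def _det(x, y, w, h, label="pigmented_nucleolus", conf=1.0, tile=None):
    return nq.Detection(bbox=(x, y, w, h), label=label, confidence=conf, source_tile=tile)


# ---------------------------------------------------------------------------
# Independent mAP oracle: naive loops, no shared code with the implementation.


def _oracle_ap(preds, gts, thr):
    """Greedy confidence-ordered matching and trapezoid-free 101-point AP,
    written as explicit loops."""
    order = sorted(range(len(preds)), key=lambda i: (-preds[i].confidence,
                                                     -preds[i].area, preds[i].bbox))
    matched_gt = set()
    flags = []
    for i in order:
        best_j, best_iou = None, None
        for j, g in enumerate(gts):
            if j in matched_gt:
                continue
            iou = nq.box_iou(preds[i].bbox, g.bbox)
            if iou >= thr - 1e-9 and (best_iou is None or iou > best_iou):
                best_j, best_iou = j, iou
        if best_j is not None:
            matched_gt.add(best_j)
            flags.append(True)
        else:
            flags.append(False)
    tp = fp = 0
    curve = []  # (recall, precision) after each prediction
    for f in flags:
        tp, fp = tp + int(f), fp + int(not f)
        curve.append((tp / len(gts), tp / (tp + fp)))
    total = 0.0
    for k in range(101):
        r = k / 100.0
        best_p = 0.0
        for rec, prec in curve:
            if rec >= r - 1e-9 and prec > best_p:
                best_p = prec
        total += best_p
    return total / 101.0


def _oracle_map(preds, gts, thresholds=nq.IOU_SWEEP):
    labels = sorted({g.label for g in gts})
    vals = []
    for lbl in labels:
        p = [x for x in preds if x.label == lbl]
        g = [x for x in gts if x.label == lbl]
        for thr in thresholds:
            vals.append(_oracle_ap(p, g, thr))
    return sum(vals) / len(vals)


class TestReferenceDetector:
    def test_blank_tile_yields_no_detections(self):
        tile = np.full((200, 200, 3), 228, np.uint8)
        assert nq.reference_detect(tile, 0.5) == []

    def test_fixture_neurons_all_detected_with_correct_labels(self, small_histology):
        params, image, roi, truth = small_histology
        dets = nq.run_roi_inference(image, roi)
        assert len(dets) == len(truth)
        # Each truth box matched by exactly one detection of the same label.
        for t in truth:
            matches = [d for d in dets if nq.box_iou(d.bbox, t.bbox) > 0.5]
            assert len(matches) == 1
            assert matches[0].label == t.label

    def test_clutter_only_fixture_yields_no_nucleolus_detections(self):
        params = HistologyFixtureParams(
            image_width_px=600, image_height_px=600,
            n_pigmented=0, n_non_pigmented=0,
            pigment_clutter_density=30.0, seed=8,
        )
        image, roi, truth = generate_histology_fixture(params)
        assert truth == []
        dets = nq.run_roi_inference(image, roi)
        assert [d for d in dets if d.label.endswith("_nucleolus")
                and not d.label.endswith("no_nucleolus")] == []


class TestRunRoiInference:
    def test_single_tile_equals_detector_output_offset(self, small_histology):
        _, image, roi, _ = small_histology
        bbox = roi.bounds()
        tiling = TilingParams(tile_size_px=max(bbox[2], bbox[3]), overlap_px=0)
        dets = nq.run_roi_inference(image, roi, tiling=tiling)
        raw = nq.reference_detect(
            image.pixels[bbox[1] : bbox[1] + bbox[3], bbox[0] : bbox[0] + bbox[2]],
            image.microns_per_pixel,
        )
        assert len(dets) == len(raw)
        offset_boxes = sorted(
            (b[0] + bbox[0], b[1] + bbox[1], b[2], b[3]) for b in (r.bbox for r in raw)
        )
        assert sorted(d.bbox for d in dets) == offset_boxes

    def test_tiling_invariance_single_vs_multi(self, small_histology):
        """Same fixture processed as 1 tile vs many overlapping tiles gives
        the identical final detections (boxes within 1 px)."""
        _, image, roi, truth = small_histology
        bbox = roi.bounds()
        one = TilingParams(tile_size_px=max(bbox[2], bbox[3]), overlap_px=0)
        d_one = nq.run_roi_inference(image, roi, tiling=one)
        d_multi = nq.run_roi_inference(image, roi, tiling=TilingParams(300, 50))
        assert len(d_one) == len(d_multi) == len(truth)
        for a, b in zip(sorted(d_one, key=lambda d: d.bbox),
                        sorted(d_multi, key=lambda d: d.bbox)):
            assert a.label == b.label
            assert np.allclose(a.bbox, b.bbox, atol=1.0)

    def test_empty_detector_empty_output(self, small_histology):
        _, image, roi, _ = small_histology
        assert nq.run_roi_inference(image, roi, detector=lambda t, m: []) == []

    def test_contract_violating_detector_rejected_with_log(self, small_histology, caplog):
        _, image, roi, _ = small_histology

        def bad_detector(tile, mpp):
            return [_det(-50, -50, 10, 10)]

        with caplog.at_level("ERROR"):
            out = nq.run_roi_inference(image, roi, detector=bad_detector)
        assert out == []
        assert any("out-of-tile" in r.message for r in caplog.records)


class TestFilterTruncated:
    _tiles = [Tile(0, 0, 100, 100), Tile(80, 0, 100, 100)]
    _bbox = (0, 0, 180, 100)

    def test_box_flush_on_interior_edge_removed(self):
        # Right edge of tile 0 at x=100 is interior (bbox ends at 180).
        d = _det(90, 40, 10, 10, tile=0)
        assert nq.filter_truncated([d], self._tiles, self._bbox) == []

    def test_box_flush_on_roi_bbox_edge_kept(self):
        d = _det(0, 40, 10, 10, tile=0)  # left edge of bbox: nothing beyond
        assert nq.filter_truncated([d], self._tiles, self._bbox) == [d]

    def test_interior_box_kept(self):
        d = _det(30, 30, 20, 20, tile=0)
        assert nq.filter_truncated([d], self._tiles, self._bbox) == [d]

    def test_every_small_neuron_survives_in_some_tile(self, small_histology):
        """Neurons smaller than the 50-px overlap are never lost to the
        truncation filter in the full pipeline."""
        _, image, roi, truth = small_histology
        assert all(max(t.bbox[2], t.bbox[3]) < 50 for t in truth)
        dets = nq.run_roi_inference(image, roi, tiling=TilingParams(250, 50))
        for t in truth:
            assert any(nq.box_iou(d.bbox, t.bbox) > 0.5 for d in dets)


class TestResolveDuplicates:
    def test_highest_confidence_label_wins_on_coincident_boxes(self):
        a = _det(10, 10, 20, 20, "pigmented_nucleolus", 0.8)
        b = _det(10, 10, 20, 20, "non_pigmented_nucleolus", 0.6)
        out = nq.resolve_duplicates([a, b])
        assert out == [a]

    def test_disjoint_boxes_unchanged(self):
        a = _det(0, 0, 10, 10, conf=0.9)
        b = _det(50, 50, 10, 10, conf=0.8)
        assert sorted(nq.resolve_duplicates([a, b]), key=lambda d: d.bbox) == [a, b]

    def test_three_way_cluster_single_survivor_matches_bruteforce(self):
        """Mutually overlapping boxes at IoU ~0.9 collapse to the highest-
        confidence member, as exhaustive clustering of <=10 boxes does."""
        boxes = [_det(10 + i, 10, 40, 40, conf=0.9 - 0.1 * i) for i in range(3)]
        out = nq.resolve_duplicates(boxes, iou_threshold=0.5)
        assert out == [boxes[0]]
        # Brute-force: connected components of the IoU>=thr graph.
        n = len(boxes)
        adj = {i: {i} for i in range(n)}
        for i, j in itertools.combinations(range(n), 2):
            if nq.box_iou(boxes[i].bbox, boxes[j].bbox) >= 0.5:
                adj[i].add(j)
                adj[j].add(i)
        seen, clusters = set(), []
        for i in range(n):
            if i in seen:
                continue
            stack, comp = [i], set()
            while stack:
                k = stack.pop()
                if k in comp:
                    continue
                comp.add(k)
                stack.extend(adj[k] - comp)
            seen |= comp
            clusters.append(comp)
        survivors = [max(c, key=lambda k: boxes[k].confidence) for c in clusters]
        assert out == [boxes[k] for k in survivors]

    def test_idempotent(self, rng):
        boxes = [
            _det(float(x), float(y), 20, 20, conf=float(c))
            for x, y, c in zip(
                rng.uniform(0, 100, 20), rng.uniform(0, 100, 20), rng.uniform(0.1, 1, 20)
            )
        ]
        once = nq.resolve_duplicates(boxes)
        assert nq.resolve_duplicates(once) == once

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            nq.resolve_duplicates([], iou_threshold=0.0)


class TestComputeDensity:
    _roi = RoiPolygon(vertices=((0, 0), (2000, 0), (2000, 2000), (0, 2000)))  # 1 mm² @0.5

    def test_no_detections_zero_density(self):
        d = nq.compute_density([], self._roi, 0.5)
        assert d.pigmented_density == d.non_pigmented_density == d.total_density == 0

    def test_density_is_count_over_area(self):
        dets = [_det(10 * i, 10, 8, 8, "pigmented_nucleolus") for i in range(10)]
        d = nq.compute_density(dets, self._roi, 0.5)
        assert d.pigmented_density == pytest.approx(10.0)

    def test_nucleolus_free_labels_excluded_from_density(self):
        dets = [
            _det(10, 10, 8, 8, "pigmented_nucleolus"),
            _det(40, 10, 8, 8, "pigmented_no_nucleolus"),
            _det(70, 10, 8, 8, "non_pigmented_no_nucleolus"),
        ]
        d = nq.compute_density(dets, self._roi, 0.5)
        assert d.pigmented_density == pytest.approx(1.0)
        assert d.total_density == pytest.approx(1.0)
        assert d.counts["pigmented_no_nucleolus"] == 1


class TestEvaluateDetections:
    def test_perfect_predictions_map_one(self, rng):
        gts = [_det(float(10 * i), 5, 9, 9) for i in range(5)]
        res = nq.evaluate_detections(gts, gts)
        assert res.map50_95 == pytest.approx(1.0)

    def test_no_predictions_map_zero(self):
        gts = [_det(0, 0, 10, 10)]
        res = nq.evaluate_detections([], gts)
        assert res.map50_95 == 0.0

    def test_iou_exactly_070_gives_half(self):
        """1 truth, 1 prediction overlapping at IoU exactly 0.70: AP 1 for
        thresholds <= 0.70, 0 above, so the 10-threshold mean is 0.5."""
        gt = _det(0, 0, 17, 10)
        pred = _det(3, 0, 17, 10)  # intersection 14x10=140, union 200
        assert nq.box_iou(gt.bbox, pred.bbox) == pytest.approx(0.7)
        res = nq.evaluate_detections([pred], [gt])
        assert res.map50_95 == pytest.approx(0.5)
        assert res.ap["pigmented_nucleolus"][0.70] == pytest.approx(1.0)
        assert res.ap["pigmented_nucleolus"][0.75] == pytest.approx(0.0)

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            nq.evaluate_detections([_det(0, 0, 5, 5)], [])

    def test_matches_bruteforce_oracle_on_small_instances(self, rng):
        """Evaluator equals the naive loop oracle exactly on every random
        instance with <= 5 predictions and <= 5 truths."""
        labels = ["pigmented_nucleolus", "non_pigmented_nucleolus"]
        for trial in range(60):
            n_gt = int(rng.integers(1, 6))
            n_pred = int(rng.integers(0, 6))
            gts = [
                _det(float(rng.integers(0, 60)), float(rng.integers(0, 60)),
                     float(rng.integers(5, 20)), float(rng.integers(5, 20)),
                     label=labels[rng.integers(0, 2)])
                for _ in range(n_gt)
            ]
            preds = [
                _det(float(rng.integers(0, 60)), float(rng.integers(0, 60)),
                     float(rng.integers(5, 20)), float(rng.integers(5, 20)),
                     label=labels[rng.integers(0, 2)],
                     conf=float(np.round(rng.uniform(0.1, 1.0), 3)))
                for _ in range(n_pred)
            ]
            res = nq.evaluate_detections(preds, gts)
            assert res.map50_95 == pytest.approx(_oracle_map(preds, gts), abs=1e-12)


class TestDetectionCsv:
    def test_roundtrip(self, tmp_path):
        dets = [_det(1, 2, 3, 4, conf=0.5), _det(9, 9, 5, 5, "non_pigmented_nucleolus")]
        path = tmp_path / "d.csv"
        nq.save_detections_csv(dets, path)
        loaded = nq.load_detections_csv(path)
        assert [(d.bbox, d.label, d.confidence) for d in loaded] == [
            (d.bbox, d.label, d.confidence) for d in dets
        ]
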