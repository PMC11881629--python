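"""Tile-wise nigral neuron detection, cleanup, densities, and mAP scoring.

The quantification contract: a detector is any callable mapping an RGB tile
(plus its µm/px calibration) to labeled, scored boxes in tile-local
coordinates. The orchestrator tiles the ROI with overlapping 500-px tiles,
remaps tile detections to slide coordinates, discards neurons truncated by
interior tile borders (each neuron smaller than the overlap survives
untruncated in at least one tile), merges duplicate labels across tiles by
highest confidence, and reports per-class densities over the ROI area.
Only nucleolus-bearing classes enter the densities — the nucleolus is the
classical guard against double-counting split somata; the nucleolus-free
classes exist to sharpen the detector, not the counts.

A classical color-rule reference detector for the synthetic fixture palette
is included so the full pipeline runs without any trained model.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from . import palette
from .imaging_io import CalibratedImage, RoiPolygon, Tile, TilingParams, make_tiles

__all__ = [
    "LABELS",
    "NUCLEOLUS_LABELS",
    "Detection",
    "NeuronDensity",
    "DetectionEvalResult",
    "reference_detect",
    "run_roi_inference",
    "filter_truncated",
    "resolve_duplicates",
    "compute_density",
    "evaluate_detections",
    "box_iou",
    "save_detections_csv",
    "load_detections_csv",
]

logger = logging.getLogger(__name__)

LABELS = (
    "pigmented_nucleolus",
    "non_pigmented_nucleolus",
    "pigmented_no_nucleolus",
    "non_pigmented_no_nucleolus",
)
NUCLEOLUS_LABELS = ("pigmented_nucleolus", "non_pigmented_nucleolus")

#: IoU thresholds of the mAP(0.50:0.95) sweep.
IOU_SWEEP = tuple(0.50 + 0.05 * k for k in range(10))
#: Floating-point guard for IoU-vs-threshold comparisons.
_IOU_EPS = 1e-9


@dataclass(frozen=True)
class Detection:
    """A scored, labeled box; ``bbox`` is half-open (x, y, w, h)."""

    bbox: tuple[float, float, float, float]
    label: str
    confidence: float
    source_tile: int | None = None

    def __post_init__(self) -> None:
        x, y, w, h = self.bbox
        if w <= 0 or h <= 0:
            raise ValueError("bbox must have positive width and height")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must be in [0, 1]")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def area(self) -> float:
        return self.bbox[2] * self.bbox[3]

    @property
    def center(self) -> tuple[float, float]:
        x, y, w, h = self.bbox
        return (x + w / 2.0, y + h / 2.0)


def box_iou(a: Sequence[float], b: Sequence[float]) -> float:
    """Intersection-over-union of two half-open (x, y, w, h) boxes."""
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union if union > 0 else 0.0


Detector = Callable[[np.ndarray, float], list[Detection]]


# ---------------------------------------------------------------------------
# Reference detector (classical color rules over the fixture palette)


def reference_detect(
    tile: np.ndarray,
    microns_per_pixel: float,
    soma_area_um2: tuple[float, float] = (60.0, 2500.0),
    color_tol: float = 45.0,
    nucleolus_tol: float = 40.0,
    min_nucleolus_px: int = 3,
) -> list[Detection]:
    """Detect somata in one RGB tile by palette color rules.

    Pigmented somata are the brown components (base fill, granules, or
    clutter colors); non-pigmented somata are recovered from their darker
    rim plus pale fill, hole-filled. Components outside the configured soma
    area range (µm²) are rejected — this is what removes pigment clutter,
    which is far smaller than any soma. A component becomes a
    nucleolus-bearing detection when a high-contrast nucleolus-colored disc
    of at least ``min_nucleolus_px`` pixels lies inside it. Confidence is a
    monotone function of how elliptical the component is (its bbox fill
    ratio against the ideal π/4).
    """
    px = np.asarray(tile)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError("tile must be an H x W x 3 RGB raster")
    min_px = soma_area_um2[0] / microns_per_pixel**2
    max_px = soma_area_um2[1] / microns_per_pixel**2

    brown = (
        (palette.color_distance(px, palette.PIGMENT_BASE) < color_tol)
        | (palette.color_distance(px, palette.PIGMENT_GRANULE) < color_tol)
        | (palette.color_distance(px, palette.CLUTTER) < color_tol)
    )
    pink = (palette.color_distance(px, palette.NONPIGMENT_RIM) < color_tol) | (
        palette.color_distance(px, palette.NONPIGMENT_FILL) < 25.0
    )
    nucleolus = palette.color_distance(px, palette.NUCLEOLUS) < nucleolus_tol

    detections: list[Detection] = []
    for mask, kind in ((brown, "pigmented"), (pink, "non_pigmented")):
        # The nucleolus punches a hole in the soma colors; fill it back.
        filled = binary_fill_holes(mask)
        labeled = cc_label(filled, connectivity=2)
        for region in regionprops(labeled):
            if not min_px <= region.area <= max_px:
                continue
            y0, x0, y1, x1 = region.bbox
            comp = labeled[y0:y1, x0:x1] == region.label
            has_nucleolus = int(np.sum(nucleolus[y0:y1, x0:x1] & comp)) >= min_nucleolus_px
            extent = region.area / ((y1 - y0) * (x1 - x0))
            conf = float(np.clip(1.0 - abs(extent - np.pi / 4) / (np.pi / 4), 0.05, 0.99))
            suffix = "nucleolus" if has_nucleolus else "no_nucleolus"
            detections.append(
                Detection(
                    bbox=(float(x0), float(y0), float(x1 - x0), float(y1 - y0)),
                    label=f"{kind}_{suffix}",
                    confidence=conf,
                )
            )
    return detections


# ---------------------------------------------------------------------------
# Orchestration


def filter_truncated(
    detections: Iterable[Detection],
    tiles: Sequence[Tile],
    roi_bbox: tuple[int, int, int, int],
    tol: float = 1.0,
) -> list[Detection]:
    """Drop detections whose box touches an interior tile border.

    A box edge within ``tol`` px of its source tile's edge marks a neuron
    truncated by the tile border — unless that tile edge coincides with the
    ROI bounding box edge (nothing lies beyond the slide there). With the
    default 50-px overlap, any neuron smaller than the overlap survives in
    at least one tile.
    """
    bx, by, bw, bh = roi_bbox
    kept = []
    for det in detections:
        if det.source_tile is None:
            kept.append(det)
            continue
        t = tiles[det.source_tile]
        x, y, w, h = det.bbox
        truncated = (
            (x <= t.x0 + tol and abs(t.x0 - bx) > tol)
            or (x + w >= t.x1 - tol and abs(t.x1 - (bx + bw)) > tol)
            or (y <= t.y0 + tol and abs(t.y0 - by) > tol)
            or (y + h >= t.y1 - tol and abs(t.y1 - (by + bh)) > tol)
        )
        if not truncated:
            kept.append(det)
    return kept


def _priority(det: Detection) -> tuple[float, float, str]:
    # Descending confidence, then larger area, then lexicographic label.
    return (-det.confidence, -det.area, det.label)


def resolve_duplicates(
    detections: Iterable[Detection], iou_threshold: float = 0.5
) -> list[Detection]:
    """Merge boxes that describe the same neuron, keeping one per cluster.

    Boxes are taken in descending confidence (ties: larger area, then
    lexicographic label); each seed absorbs every remaining box with
    IoU ≥ ``iou_threshold`` and is emitted as its cluster's sole survivor.
    Idempotent: surviving boxes have pairwise IoU below the threshold.
    """
    if not 0.0 < iou_threshold < 1.0:
        raise ValueError("iou_threshold must be in (0, 1)")
    pool = sorted(detections, key=_priority)
    out: list[Detection] = []
    while pool:
        seed = pool.pop(0)
        out.append(seed)
        pool = [d for d in pool if box_iou(seed.bbox, d.bbox) < iou_threshold - _IOU_EPS]
    return out


def run_roi_inference(
    image: CalibratedImage,
    roi: RoiPolygon,
    detector: Detector = reference_detect,
    tiling: TilingParams | None = None,
    iou_threshold: float = 0.5,
    filter_truncated_first: bool = True,
) -> list[Detection]:
    """Run a detector tile-by-tile over the ROI and clean up the result.

    Steps: tile the ROI bounding box (clipped to the image), run the
    detector per tile, offset boxes by the tile origin, keep only boxes
    whose center lies inside the ROI polygon, drop tile-truncated boxes,
    and merge cross-tile duplicates by highest confidence. Detections that
    violate the detector contract (box outside its tile) are rejected with
    a logged error. The truncation filter runs before deduplication by
    default; the order is configurable.
    """
    if tiling is None:
        tiling = TilingParams()
    x0, y0, w, h = roi.bounds()
    x0c, y0c = max(x0, 0), max(y0, 0)
    bbox = (
        x0c,
        y0c,
        min(x0 + w, image.width) - x0c,
        min(y0 + h, image.height) - y0c,
    )
    tiles = make_tiles(bbox, tiling)
    remapped: list[Detection] = []
    for idx, tile in enumerate(tiles):
        view = image.pixels[tile.y0 : tile.y1, tile.x0 : tile.x1]
        for det in detector(view, image.microns_per_pixel):
            dx, dy, dw, dh = det.bbox
            if dx < -1e-6 or dy < -1e-6 or dx + dw > tile.width + 1e-6 or dy + dh > tile.height + 1e-6:
                logger.error(
                    "detector returned out-of-tile box %s on tile %d; rejected",
                    det.bbox,
                    idx,
                )
                continue
            remapped.append(
                replace(det, bbox=(dx + tile.x0, dy + tile.y0, dw, dh), source_tile=idx)
            )
    inside = [d for d in remapped if roi.contains_point(*d.center)]
    if filter_truncated_first:
        kept = filter_truncated(inside, tiles, bbox)
        return resolve_duplicates(kept, iou_threshold)
    merged = resolve_duplicates(inside, iou_threshold)
    return filter_truncated(merged, tiles, bbox)


# ---------------------------------------------------------------------------
# Densities


@dataclass(frozen=True)
class NeuronDensity:
    """Per-class counts and nucleolus-bearing densities over the ROI.

    Densities (/mm²) use nucleolus-bearing labels only; the nucleolus-free
    labels are tabulated but contribute to no density.
    """

    counts: dict[str, int]
    roi_area_mm2: float

    def __post_init__(self) -> None:
        if not self.roi_area_mm2 > 0:
            raise ValueError("ROI area must be > 0")
        counts = {lbl: int(self.counts.get(lbl, 0)) for lbl in LABELS}
        object.__setattr__(self, "counts", counts)

    @property
    def pigmented_density(self) -> float:
        return self.counts["pigmented_nucleolus"] / self.roi_area_mm2

    @property
    def non_pigmented_density(self) -> float:
        return self.counts["non_pigmented_nucleolus"] / self.roi_area_mm2

    @property
    def total_density(self) -> float:
        return self.pigmented_density + self.non_pigmented_density


def compute_density(
    detections: Iterable[Detection], roi: RoiPolygon, microns_per_pixel: float
) -> NeuronDensity:
    """Count detections by label and normalize by the ROI area in mm²."""
    area = roi.area_mm2(microns_per_pixel)
    if not area > 0:
        raise ValueError("ROI area must be > 0")
    counts = Counter(d.label for d in detections)
    return NeuronDensity(counts=dict(counts), roi_area_mm2=area)


# ---------------------------------------------------------------------------
# Evaluation: mAP(0.50:0.95)


@dataclass(frozen=True)
class DetectionEvalResult:
    """AP per (class, IoU threshold) and their grand mean."""

    ap: dict[str, dict[float, float]]
    map50_95: float

    def class_ap(self, label: str) -> float:
        vals = self.ap[label]
        return float(np.mean(list(vals.values())))


def _average_precision(
    matched_flags: Sequence[bool], n_truth: int
) -> float:
    """101-point interpolated AP from confidence-ordered TP/FP flags."""
    if n_truth == 0:
        return float("nan")
    tp = np.cumsum(np.asarray(matched_flags, dtype=float))
    fp = np.cumsum(1.0 - np.asarray(matched_flags, dtype=float))
    recall = tp / n_truth
    precision = tp / np.maximum(tp + fp, 1e-12)
    ap = 0.0
    for r in np.linspace(0.0, 1.0, 101):
        mask = recall >= r - _IOU_EPS
        ap += float(precision[mask].max()) if mask.any() else 0.0
    return ap / 101.0


def evaluate_detections(
    predictions: Sequence[Detection],
    truths: Sequence,
    iou_thresholds: Sequence[float] = IOU_SWEEP,
) -> DetectionEvalResult:
    """Score predictions against ground truth by mAP(IoU = 0.50:0.95).

    Per class and per IoU threshold, predictions are matched to truths
    greedily in descending confidence; each truth is matched at most once,
    to the unmatched truth of highest IoU at or above the threshold. AP is
    101-point interpolated precision over recall; ``map50_95`` averages
    over the thresholds and over the classes present in the truth set.

    ``truths`` may be :class:`Detection` objects or any objects with
    ``bbox`` and ``label`` attributes (e.g. ground-truth annotations).
    """
    truth_labels = sorted({t.label for t in truths})
    if not truth_labels:
        raise ValueError("truth set is empty for all classes")
    ap: dict[str, dict[float, float]] = {}
    for label in truth_labels:
        preds = sorted(
            (p for p in predictions if p.label == label),
            key=lambda p: (-p.confidence, -p.area, p.bbox),
        )
        gts = [t for t in truths if t.label == label]
        ap[label] = {}
        for thr in iou_thresholds:
            used = [False] * len(gts)
            flags: list[bool] = []
            for p in preds:
                best, best_iou = -1, thr - _IOU_EPS
                for j, g in enumerate(gts):
                    if used[j]:
                        continue
                    iou = box_iou(p.bbox, g.bbox)
                    if iou >= best_iou:
                        best, best_iou = j, iou
                if best >= 0:
                    used[best] = True
                    flags.append(True)
                else:
                    flags.append(False)
            ap[label][thr] = _average_precision(flags, len(gts))
    map50_95 = float(
        np.mean([ap[lbl][thr] for lbl in truth_labels for thr in iou_thresholds])
    )
    return DetectionEvalResult(ap=ap, map50_95=map50_95)


# ---------------------------------------------------------------------------
# CSV I/O


def save_detections_csv(detections: Iterable[Detection], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x", "y", "w", "h", "label", "confidence"])
        for d in detections:
            writer.writerow([*d.bbox, d.label, d.confidence])


def load_detections_csv(path: str | Path) -> list[Detection]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                Detection(
                    bbox=(float(row["x"]), float(row["y"]), float(row["w"]), float(row["h"])),
                    label=row["label"],
                    confidence=float(row["confidence"]),
                )
            )
    return out
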