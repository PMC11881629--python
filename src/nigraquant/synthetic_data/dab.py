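"""DAB optical-density fixtures: threads, tangles and pigment objects.

Objects mimic the three object classes that the tau segmentation must
separate: neuropil threads (small, moderate OD), neurofibrillary tangles
(high OD), and neuromelanin pigment (large, moderate OD — pigment absorbs in
the DAB channel but is not tau). Class membership is enforced at
construction, so any valid fixture has an unambiguous expected tau area:
exactly the thread plus tangle pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import disk, polygon2mask

from ..imaging_io import OpticalDensityMap, RoiPolygon

__all__ = [
    "DabObject",
    "DabFixtureSpec",
    "generate_dab_fixture",
    "make_thread_mask",
    "make_blob_mask",
    "random_dab_spec",
]

KINDS = ("thread", "tangle", "pigment")

#: Object-class boundaries shared with the tau segmentation defaults.
_OD_LOW = 0.3
_OD_HIGH = 0.8
_AREA_CUTOFF_UM2 = 50.0


@dataclass(frozen=True)
class DabObject:
    """One painted object: a boolean patch placed at ``origin`` (x, y).

    ``kind`` fixes the allowed (area, OD) region:

    - ``thread``: area ≤ 50 µm², OD in [0.3, 0.8)
    - ``tangle``: OD ≥ 0.8 (any area)
    - ``pigment``: area > 50 µm², OD in [0.3, 0.8)
    """

    mask: np.ndarray
    origin: tuple[int, int]
    od_value: float
    kind: str

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 2 or not mask.any():
            raise ValueError("object mask must be a non-empty 2-D boolean patch")
        if self.kind not in KINDS:
            raise ValueError(f"unknown object kind {self.kind!r}")
        if not self.od_value >= _OD_LOW:
            raise ValueError("object OD must be >= 0.3 to be segmentable")
        object.__setattr__(self, "mask", mask)

    def area_um2(self, microns_per_pixel: float) -> float:
        return float(self.mask.sum()) * microns_per_pixel**2

    def validate_kind(self, microns_per_pixel: float) -> None:
        area = self.area_um2(microns_per_pixel)
        if self.kind == "thread":
            if area > _AREA_CUTOFF_UM2:
                raise ValueError(f"thread area {area:.1f} um2 exceeds 50 um2")
            if not (_OD_LOW <= self.od_value < _OD_HIGH):
                raise ValueError("thread OD must be in [0.3, 0.8)")
        elif self.kind == "tangle":
            if not self.od_value >= _OD_HIGH:
                raise ValueError("tangle OD must be >= 0.8")
        else:  # pigment
            if area <= _AREA_CUTOFF_UM2:
                raise ValueError(f"pigment area {area:.1f} um2 must exceed 50 um2")
            if not (_OD_LOW <= self.od_value < _OD_HIGH):
                raise ValueError("pigment OD must be in [0.3, 0.8)")

    def pixel_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(rows, cols) of object pixels in map coordinates."""
        rr, cc = np.nonzero(self.mask)
        ox, oy = self.origin
        return rr + oy, cc + ox


@dataclass(frozen=True)
class DabFixtureSpec:
    """A set of disjoint objects inside an ROI, with calibration.

    Construction asserts the class invariants (intensity/area rules per
    kind), pairwise disjointness, and containment in the ROI raster.
    """

    objects: tuple[DabObject, ...]
    roi: RoiPolygon
    microns_per_pixel: float
    map_shape: tuple[int, int]

    def __post_init__(self) -> None:
        if not self.microns_per_pixel > 0:
            raise ValueError("microns_per_pixel must be > 0")
        H, W = self.map_shape
        roi_mask = rasterize_roi(self.roi, self.map_shape)
        occupied = np.zeros((H, W), dtype=bool)
        for obj in self.objects:
            obj.validate_kind(self.microns_per_pixel)
            rr, cc = obj.pixel_coords()
            if rr.min() < 0 or cc.min() < 0 or rr.max() >= H or cc.max() >= W:
                raise ValueError("object extends outside the map")
            if not roi_mask[rr, cc].all():
                raise ValueError("object extends outside the ROI")
            if occupied[rr, cc].any():
                raise ValueError("objects overlap")
            occupied[rr, cc] = True
        object.__setattr__(self, "objects", tuple(self.objects))


def rasterize_roi(roi: RoiPolygon, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside the ROI polygon."""
    verts_rc = [(y, x) for (x, y) in roi.vertices]
    return polygon2mask(shape, np.asarray(verts_rc))


def generate_dab_fixture(spec: DabFixtureSpec) -> tuple[OpticalDensityMap, float]:
    """Paint the fixture and return (OD map, expected percent tau area).

    The expectation is computed by direct pixel counting on the painted
    masks: 100 × (thread + tangle pixels) / ROI pixels — pigment objects
    contribute nothing, because pigment is not tau.
    """
    od = np.zeros(spec.map_shape, dtype=float)
    tau_pixels = 0
    for obj in spec.objects:
        rr, cc = obj.pixel_coords()
        od[rr, cc] = obj.od_value
        if obj.kind in ("thread", "tangle"):
            tau_pixels += rr.size
    roi_pixels = int(rasterize_roi(spec.roi, spec.map_shape).sum())
    if roi_pixels == 0:
        raise ValueError("ROI rasterizes to zero pixels")
    expected_percent = 100.0 * tau_pixels / roi_pixels
    return OpticalDensityMap(values=od, microns_per_pixel=spec.microns_per_pixel), expected_percent


# ---------------------------------------------------------------------------
# Shape helpers


def make_thread_mask(n_pixels: int, rng: np.random.Generator) -> np.ndarray:
    """A thin, thread-like path of exactly ``n_pixels`` set pixels."""
    if n_pixels < 1:
        raise ValueError("n_pixels must be >= 1")
    side = max(4, int(3 * np.sqrt(n_pixels)) + 4)
    grid = np.zeros((side, side), dtype=bool)
    r, c = side // 2, side // 2
    grid[r, c] = True
    count = 1
    heading = rng.uniform(0, 2 * np.pi)
    while count < n_pixels:
        heading += rng.normal(0, 0.5)
        r = int(np.clip(round(r + np.sin(heading)), 1, side - 2))
        c = int(np.clip(round(c + np.cos(heading)), 1, side - 2))
        if not grid[r, c]:
            grid[r, c] = True
            count += 1
    return _crop(grid)


def make_blob_mask(n_pixels: int, rng: np.random.Generator) -> np.ndarray:
    """A compact blob of exactly ``n_pixels`` set pixels (disc grown/eroded)."""
    if n_pixels < 1:
        raise ValueError("n_pixels must be >= 1")
    radius = max(1.0, np.sqrt(n_pixels / np.pi))
    side = int(2 * radius) + 5
    grid = np.zeros((side, side), dtype=bool)
    rr, cc = disk((side / 2, side / 2), radius + 1, shape=grid.shape)
    grid[rr, cc] = True
    # Trim or pad pixels farthest/nearest to the centroid to hit the target.
    ys, xs = np.nonzero(grid)
    d = (ys - side / 2) ** 2 + (xs - side / 2) ** 2
    order = np.argsort(d, kind="stable")
    if len(order) >= n_pixels:
        keep = order[:n_pixels]
        out = np.zeros_like(grid)
        out[ys[keep], xs[keep]] = True
        return _crop(out)
    # Disc smaller than target (rounding): grow ring by ring.
    while grid.sum() < n_pixels:
        radius += 1
        rr, cc = disk((side / 2, side / 2), radius, shape=grid.shape)
        grid[rr, cc] = True
    ys, xs = np.nonzero(grid)
    d = (ys - side / 2) ** 2 + (xs - side / 2) ** 2
    keep = np.argsort(d, kind="stable")[:n_pixels]
    out = np.zeros_like(grid)
    out[ys[keep], xs[keep]] = True
    return _crop(out)


def _crop(mask: np.ndarray) -> np.ndarray:
    ys, xs = np.nonzero(mask)
    return mask[ys.min() : ys.max() + 1, xs.min() : xs.max() + 1]


def random_dab_spec(
    rng: np.random.Generator,
    map_shape: tuple[int, int] = (220, 220),
    microns_per_pixel: float = 0.5,
    max_threads: int = 8,
    max_tangles: int = 4,
    max_pigments: int = 5,
) -> DabFixtureSpec:
    """Draw a random valid fixture spec with disjoint, in-ROI objects.

    Areas and ODs are sampled safely inside each class region (threads
    5–45 µm² at OD 0.35–0.75, tangles 20–150 µm² at OD 0.85–1.60, pigments
    60–200 µm² at OD 0.35–0.75).
    """
    H, W = map_shape
    margin = 4
    roi = RoiPolygon(
        vertices=((margin, margin), (W - margin, margin), (W - margin, H - margin), (margin, H - margin))
    )
    px_area = microns_per_pixel**2
    objects: list[DabObject] = []
    occupied = np.zeros(map_shape, dtype=bool)

    def place(mask: np.ndarray, od: float, kind: str) -> None:
        h, w = mask.shape
        for _ in range(300):
            oy = int(rng.integers(margin + 1, H - margin - h))
            ox = int(rng.integers(margin + 1, W - margin - w))
            region = occupied[oy : oy + h, ox : ox + w]
            # 1-px dilated footprint keeps objects from touching diagonally.
            y0, y1 = max(oy - 1, 0), min(oy + h + 1, H)
            x0, x1 = max(ox - 1, 0), min(ox + w + 1, W)
            if not occupied[y0:y1, x0:x1].any() and not region.any():
                occupied[oy : oy + h, ox : ox + w] |= mask
                objects.append(DabObject(mask=mask, origin=(ox, oy), od_value=od, kind=kind))
                return

    for _ in range(int(rng.integers(0, max_threads + 1))):
        area_um2 = rng.uniform(5.0, 45.0)
        mask = make_thread_mask(max(1, int(round(area_um2 / px_area))), rng)
        if mask.sum() * px_area <= _AREA_CUTOFF_UM2:
            place(mask, float(rng.uniform(0.35, 0.75)), "thread")
    for _ in range(int(rng.integers(0, max_tangles + 1))):
        area_um2 = rng.uniform(20.0, 150.0)
        mask = make_blob_mask(max(1, int(round(area_um2 / px_area))), rng)
        place(mask, float(rng.uniform(0.85, 1.60)), "tangle")
    for _ in range(int(rng.integers(0, max_pigments + 1))):
        area_um2 = rng.uniform(60.0, 200.0)
        mask = make_blob_mask(int(round(area_um2 / px_area)), rng)
        if mask.sum() * px_area > _AREA_CUTOFF_UM2:
            place(mask, float(rng.uniform(0.35, 0.75)), "pigment")

    return DabFixtureSpec(
        objects=tuple(objects), roi=roi, microns_per_pixel=microns_per_pixel, map_shape=map_shape
    )
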