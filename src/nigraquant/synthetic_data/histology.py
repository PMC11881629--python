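"""H&E-like histology fixture generator with bounding-box ground truth.

Draws elliptical neuron somata on a noisy neuropil background: pigmented
neurons as brown-granule-textured ellipses, non-pigmented neurons as pale
pink ellipses with a darker rim, nucleoli as small high-contrast discs, and
extracellular pigment clutter as small irregular brown clumps without a soma
outline. Every drawn neuron is recorded as a bounding box with one of the
four detector labels, so detector output can be scored against exact truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import disk, ellipse

from .. import palette
from ..imaging_io import CalibratedImage, RoiPolygon

__all__ = ["HistologyFixtureParams", "GroundTruthNeuron", "generate_histology_fixture"]

LABELS = (
    "pigmented_nucleolus",
    "non_pigmented_nucleolus",
    "pigmented_no_nucleolus",
    "non_pigmented_no_nucleolus",
)

#: Margin (px) between the image border and the rectangular default ROI.
_ROI_MARGIN_PX = 12
#: Minimum soma radius in pixels — guarantees detectable shapes.
_MIN_RADIUS_PX = 3


@dataclass(frozen=True)
class HistologyFixtureParams:
    """Parameters of one synthetic slide.

    ``neuron_radius_um`` is the (mean, sd) of the soma radius in microns;
    radii are drawn from a normal truncated below at 3 px.
    ``pigment_clutter_density`` is in clumps per mm² of ROI.
    """

    image_width_px: int = 1024
    image_height_px: int = 1024
    microns_per_pixel: float = 0.5
    n_pigmented: int = 15
    n_non_pigmented: int = 10
    nucleolus_fraction: float = 1.0
    pigment_clutter_density: float = 2.0
    neuron_radius_um: tuple[float, float] = (8.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_width_px < 1 or self.image_height_px < 1:
            raise ValueError("image dimensions must be positive")
        if not self.microns_per_pixel > 0:
            raise ValueError("microns_per_pixel must be > 0")
        if self.n_pigmented < 0 or self.n_non_pigmented < 0:
            raise ValueError("neuron counts must be >= 0")
        if not 0.0 <= self.nucleolus_fraction <= 1.0:
            raise ValueError("nucleolus_fraction must be in [0, 1]")
        if self.pigment_clutter_density < 0:
            raise ValueError("pigment_clutter_density must be >= 0")
        mean, sd = self.neuron_radius_um
        if mean <= 0 or sd < 0:
            raise ValueError("neuron_radius_um mean must be > 0, sd >= 0")


@dataclass(frozen=True)
class GroundTruthNeuron:
    """One annotated neuron: half-open bbox ``[x, x+w) × [y, y+h)`` + label."""

    bbox: tuple[int, int, int, int]
    label: str

    def __post_init__(self) -> None:
        x, y, w, h = self.bbox
        if w <= 0 or h <= 0:
            raise ValueError("bbox must have positive width and height")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


@dataclass
class _Soma:
    cy: float
    cx: float
    a: float  # semi-axis along y after rotation handled by skimage
    b: float
    rotation: float
    pigmented: bool
    nucleolus: bool
    rr: np.ndarray = field(default=None, repr=False)
    cc: np.ndarray = field(default=None, repr=False)

    @property
    def radius(self) -> float:
        return max(self.a, self.b)


def _truncated_radius(rng: np.random.Generator, mean_px: float, sd_px: float) -> float:
    for _ in range(100):
        r = rng.normal(mean_px, sd_px)
        if r >= _MIN_RADIUS_PX:
            return float(r)
    return float(_MIN_RADIUS_PX)


def _place_somata(
    rng: np.random.Generator,
    params: HistologyFixtureParams,
    roi: RoiPolygon,
) -> list[_Soma]:
    mean_px = params.neuron_radius_um[0] / params.microns_per_pixel
    sd_px = params.neuron_radius_um[1] / params.microns_per_pixel
    n_total = params.n_pigmented + params.n_non_pigmented
    # Capacity guard: somata with a spacing margin must fit in half the ROI.
    expected_footprint = math.pi * (mean_px + 2 * sd_px + 4) ** 2
    if n_total * expected_footprint > 0.5 * roi.area_px:
        raise ValueError("requested neuron area exceeds image capacity")

    x0, y0, w, h = roi.bounds()
    somata: list[_Soma] = []
    flags = [True] * params.n_pigmented + [False] * params.n_non_pigmented
    for pigmented in flags:
        a = _truncated_radius(rng, mean_px, sd_px)
        b = a * rng.uniform(0.75, 1.0)
        rot = rng.uniform(0, math.pi)
        placed = False
        for _ in range(500):
            margin = a + 3
            cx = rng.uniform(x0 + margin, x0 + w - margin)
            cy = rng.uniform(y0 + margin, y0 + h - margin)
            if not roi.contains_point(cx, cy):
                continue
            ok = all(
                math.hypot(cx - s.cx, cy - s.cy) > a + s.radius + 6 for s in somata
            )
            if ok:
                somata.append(
                    _Soma(
                        cy=cy,
                        cx=cx,
                        a=a,
                        b=b,
                        rotation=rot,
                        pigmented=pigmented,
                        nucleolus=bool(rng.random() < params.nucleolus_fraction),
                    )
                )
                placed = True
                break
        if not placed:
            raise ValueError("requested neuron area exceeds image capacity")
    return somata


def _draw_soma(img: np.ndarray, soma: _Soma, rng: np.random.Generator) -> None:
    shape = img.shape[:2]
    rr, cc = ellipse(soma.cy, soma.cx, soma.a, soma.b, shape=shape, rotation=soma.rotation)
    soma.rr, soma.cc = rr, cc
    if soma.pigmented:
        img[rr, cc] = palette.PIGMENT_BASE
        # Granule texture: small dark discs covering roughly 40% of the soma.
        n_granules = max(3, int(0.12 * rr.size))
        idx = rng.integers(0, rr.size, size=n_granules)
        for i in idx:
            grr, gcc = disk((rr[i], cc[i]), rng.uniform(1.0, 2.0), shape=shape)
            keep = _inside(grr, gcc, rr, cc, shape)
            img[grr[keep], gcc[keep]] = palette.PIGMENT_GRANULE
    else:
        img[rr, cc] = palette.NONPIGMENT_FILL
        # Rim: ellipse minus a 2-px-eroded inner ellipse.
        irr, icc = ellipse(
            soma.cy, soma.cx, max(soma.a - 2, 1), max(soma.b - 2, 1),
            shape=shape, rotation=soma.rotation,
        )
        rim = np.ones(len(rr), dtype=bool)
        inner = set(zip(irr.tolist(), icc.tolist()))
        for k, (r_, c_) in enumerate(zip(rr.tolist(), cc.tolist())):
            if (r_, c_) in inner:
                rim[k] = False
        img[rr[rim], cc[rim]] = palette.NONPIGMENT_RIM
    if soma.nucleolus:
        nr = max(2.0, 0.15 * min(soma.a, soma.b))
        off = 0.3 * min(soma.a, soma.b)
        ncy = soma.cy + rng.uniform(-off, off)
        ncx = soma.cx + rng.uniform(-off, off)
        nrr, ncc = disk((ncy, ncx), nr, shape=shape)
        keep = _inside(nrr, ncc, rr, cc, shape)
        img[nrr[keep], ncc[keep]] = palette.NUCLEOLUS


def _inside(
    sub_rr: np.ndarray, sub_cc: np.ndarray, rr: np.ndarray, cc: np.ndarray,
    shape: tuple[int, int],
) -> np.ndarray:
    """Boolean mask of (sub_rr, sub_cc) pixels that lie inside (rr, cc)."""
    member = np.zeros(shape, dtype=bool)
    member[rr, cc] = True
    return member[sub_rr, sub_cc]


def _draw_clutter(
    img: np.ndarray,
    rng: np.random.Generator,
    roi: RoiPolygon,
    somata: list[_Soma],
    n_clumps: int,
) -> None:
    shape = img.shape[:2]
    x0, y0, w, h = roi.bounds()
    for _ in range(n_clumps):
        for _try in range(200):
            cx = rng.uniform(x0 + 6, x0 + w - 6)
            cy = rng.uniform(y0 + 6, y0 + h - 6)
            if not roi.contains_point(cx, cy):
                continue
            if all(math.hypot(cx - s.cx, cy - s.cy) > s.radius + 10 for s in somata):
                break
        else:
            continue
        # Irregular clump: a few overlapping 1-2 px discs on a short walk.
        py, px = cy, cx
        for _ in range(rng.integers(3, 7)):
            rr, cc = disk((py, px), rng.uniform(1.0, 2.0), shape=shape)
            img[rr, cc] = palette.CLUTTER
            py += rng.uniform(-2, 2)
            px += rng.uniform(-2, 2)


def _truth_from_somata(somata: list[_Soma]) -> list[GroundTruthNeuron]:
    truth = []
    for s in somata:
        ys, xs = s.rr, s.cc
        x, y = int(xs.min()), int(ys.min())
        w, h = int(xs.max()) - x + 1, int(ys.max()) - y + 1
        prefix = "pigmented" if s.pigmented else "non_pigmented"
        suffix = "nucleolus" if s.nucleolus else "no_nucleolus"
        truth.append(GroundTruthNeuron(bbox=(x, y, w, h), label=f"{prefix}_{suffix}"))
    return truth


def generate_histology_fixture(
    params: HistologyFixtureParams,
) -> tuple[CalibratedImage, RoiPolygon, list[GroundTruthNeuron]]:
    """Render one synthetic slide and its exact annotation list.

    Returns the calibrated RGB image, the rectangular ROI (image border inset
    by a fixed margin), and one :class:`GroundTruthNeuron` per drawn soma.
    Identical parameters (including seed) produce a byte-identical image and
    an identical truth list.
    """
    rng = np.random.default_rng(params.seed)
    H, W = params.image_height_px, params.image_width_px
    m = min(_ROI_MARGIN_PX, max(0, (min(H, W) - 2) // 2))
    roi = RoiPolygon(vertices=((m, m), (W - m, m), (W - m, H - m), (m, H - m)))

    img = np.empty((H, W, 3), dtype=float)
    img[:] = palette.BACKGROUND
    img += rng.normal(0.0, palette.BACKGROUND_NOISE_SD, size=img.shape)

    somata = _place_somata(rng, params, roi)
    for s in somata:
        _draw_soma(img, s, rng)
    roi_mm2 = roi.area_mm2(params.microns_per_pixel)
    n_clumps = int(round(params.pigment_clutter_density * roi_mm2))
    _draw_clutter(img, rng, roi, somata, n_clumps)

    image = CalibratedImage(
        pixels=np.clip(np.round(img), 0, 255).astype(np.uint8),
        microns_per_pixel=params.microns_per_pixel,
    )
    return image, roi, _truth_from_somata(somata)
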