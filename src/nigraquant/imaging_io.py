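"""Calibrated image / ROI input-output and DAB stain separation.

Histology rasters carry a physical calibration (microns per pixel) that every
downstream quantity — neuron densities per mm², tau areas in µm² — depends on.
This module provides the calibrated containers, RGB → optical-density
conversion with stain-vector (color deconvolution) separation of the DAB
channel, region-of-interest polygons read from GeoJSON, and the overlapping
tile grid used for tile-wise detector inference.

Conventions: pixel coordinates are 0-based, x to the right, y down; boxes are
half-open ``[x, x+w) × [y, y+h)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image
from shapely.geometry import Polygon, shape

__all__ = [
    "CalibratedImage",
    "RoiPolygon",
    "StainBasis",
    "OpticalDensityMap",
    "TilingParams",
    "Tile",
    "RUIFROK_HDAB",
    "rgb_to_od",
    "od_to_rgb",
    "deconvolve_dab",
    "estimate_stain_basis",
    "make_tiles",
    "load_roi",
    "load_image",
    "save_image",
    "area_mm2",
]

#: Default calibration assumed for a typical ×20 scan when no sidecar exists.
DEFAULT_MICRONS_PER_PIXEL = 0.50

#: Incident intensity for optical density; the +1 offset keeps log finite.
_I0 = 256.0


@dataclass(frozen=True)
class CalibratedImage:
    """An RGB raster with physical pixel size.

    Parameters
    ----------
    pixels : ndarray, shape (H, W, 3), uint8
        8-bit RGB image data.
    microns_per_pixel : float
        Edge length of one pixel in microns; must be positive.
    """

    pixels: np.ndarray
    microns_per_pixel: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("CalibratedImage requires an H x W x 3 RGB raster")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image dimensions must be >= 1")
        if not self.microns_per_pixel > 0:
            raise ValueError("microns_per_pixel must be > 0")
        object.__setattr__(self, "pixels", np.ascontiguousarray(px, dtype=np.uint8))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class OpticalDensityMap:
    """Single-channel non-negative optical-density raster with calibration."""

    values: np.ndarray
    microns_per_pixel: float

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValueError("OpticalDensityMap requires a 2-D raster")
        if not np.all(np.isfinite(vals)):
            raise ValueError("optical density values must be finite")
        if np.any(vals < 0):
            raise ValueError("optical density values must be >= 0")
        if not self.microns_per_pixel > 0:
            raise ValueError("microns_per_pixel must be > 0")
        object.__setattr__(self, "values", vals)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class RoiPolygon:
    """A simple (non-self-intersecting) closed polygon in pixel coordinates."""

    vertices: tuple[tuple[float, float], ...]
    polygon: Polygon = field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        verts = [tuple(map(float, v)) for v in self.vertices]
        if len(verts) >= 2 and verts[0] == verts[-1]:
            verts = verts[:-1]
        if len(verts) < 3:
            raise ValueError("polygon needs at least 3 distinct vertices")
        poly = Polygon(verts)
        if not poly.is_valid:
            raise ValueError("polygon is self-intersecting or otherwise invalid")
        if poly.area <= 0:
            raise ValueError("polygon area must be > 0")
        object.__setattr__(self, "vertices", tuple(verts))
        object.__setattr__(self, "polygon", poly)

    @property
    def area_px(self) -> float:
        """Area in square pixels (shoelace formula via shapely)."""
        return self.polygon.area

    def area_mm2(self, microns_per_pixel: float) -> float:
        return area_mm2(self, microns_per_pixel)

    def bounds(self) -> tuple[int, int, int, int]:
        """Integer bounding box (x0, y0, w, h) enclosing the polygon."""
        minx, miny, maxx, maxy = self.polygon.bounds
        x0, y0 = int(np.floor(minx)), int(np.floor(miny))
        return x0, y0, int(np.ceil(maxx)) - x0, int(np.ceil(maxy)) - y0

    def contains_point(self, x: float, y: float) -> bool:
        """Membership test including the boundary."""
        from shapely.geometry import Point

        return bool(self.polygon.covers(Point(x, y)))


def area_mm2(roi: RoiPolygon, microns_per_pixel: float) -> float:
    """Polygon area in mm²: ``area_px * (microns_per_pixel / 1000)**2``."""
    if not microns_per_pixel > 0:
        raise ValueError("microns_per_pixel must be > 0")
    return roi.area_px * (microns_per_pixel / 1000.0) ** 2


@dataclass(frozen=True)
class StainBasis:
    """Two unit vectors in OD space: hematoxylin and DAB.

    Components are non-negative (absorbance cannot be negative) and the two
    vectors must not be collinear, otherwise the least-squares unmixing is
    singular.
    """

    hematoxylin: tuple[float, float, float]
    dab: tuple[float, float, float]

    def __post_init__(self) -> None:
        for name in ("hematoxylin", "dab"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,) or np.any(v < 0):
                raise ValueError(f"{name} vector must be 3 non-negative components")
            n = float(np.linalg.norm(v))
            if n <= 0:
                raise ValueError(f"{name} vector must be non-zero")
            object.__setattr__(self, name, tuple(v / n))
        h = np.asarray(self.hematoxylin)
        d = np.asarray(self.dab)
        if abs(float(np.dot(h, d))) > 1 - 1e-6:
            raise ValueError("stain vectors are collinear")

    def matrix(self) -> np.ndarray:
        """3x2 matrix with stain vectors as columns (H first, DAB second)."""
        return np.stack([self.hematoxylin, self.dab], axis=1)


#: Standard H-DAB stain vectors (Ruifrok & Johnston calibration), unit norm.
RUIFROK_HDAB = StainBasis(
    hematoxylin=(0.650, 0.704, 0.286),
    dab=(0.268, 0.570, 0.776),
)


def rgb_to_od(pixels: np.ndarray) -> np.ndarray:
    """Per-channel optical density: ``-log10((I + 1) / 256)``.

    The +1 offset bounds the OD at ``log10(256) ≈ 2.41`` and avoids log(0)
    for pure black pixels; a pure white pixel maps exactly to OD 0.
    """
    px = np.asarray(pixels, dtype=float)
    return -np.log10((px + 1.0) / _I0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_od`, clipped and rounded to uint8."""
    intensity = _I0 * np.power(10.0, -np.asarray(od, dtype=float)) - 1.0
    return np.clip(np.round(intensity), 0, 255).astype(np.uint8)


def deconvolve_dab(image: CalibratedImage, basis: StainBasis | None = None) -> OpticalDensityMap:
    """Project per-pixel OD onto a two-stain basis and return the DAB channel.

    Each pixel's 3-vector OD is decomposed by unweighted least squares onto
    the hematoxylin/DAB basis; the DAB coefficient is clamped at zero (small
    negative solutions arise from noise outside the stain plane).

    Parameters
    ----------
    image : CalibratedImage
        RGB input.
    basis : StainBasis, optional
        Stain vectors; defaults to the standard H-DAB calibration.
    """
    if basis is None:
        basis = RUIFROK_HDAB
    od = rgb_to_od(image.pixels).reshape(-1, 3)
    m = basis.matrix()  # 3x2
    coef, *_ = np.linalg.lstsq(m, od.T, rcond=None)
    dab = np.clip(coef[1], 0.0, None).reshape(image.pixels.shape[:2])
    return OpticalDensityMap(values=dab, microns_per_pixel=image.microns_per_pixel)


def estimate_stain_basis(
    image: CalibratedImage,
    od_floor: float = 0.15,
    percentile: float = 1.0,
    min_stained_pixels: int = 200,
) -> StainBasis:
    """Estimate the two extreme stain directions of the image's OD cloud.

    Stained pixels (OD magnitude above ``od_floor``) are projected onto the
    plane of their top-2 principal directions; the directions at the
    ``percentile``-th and ``(100 - percentile)``-th percentile of the angle
    within that plane are taken as the two stain vectors. This is the robust
    plane-projection estimator commonly used for H&E/H-DAB normalization.
    Falls back to the standard H-DAB basis when too few stained pixels exist,
    so a usable basis is always returned.
    """
    od = rgb_to_od(image.pixels).reshape(-1, 3)
    stained = od[np.linalg.norm(od, axis=1) > od_floor]
    if stained.shape[0] < min_stained_pixels:
        return RUIFROK_HDAB
    # Plane of top-2 principal directions of the stained OD cloud.
    _, _, vt = np.linalg.svd(stained - 0.0, full_matrices=False)
    plane = vt[:2]  # 2x3
    # Orient plane axes so that typical OD vectors have positive coordinates.
    for i in range(2):
        if np.median(stained @ plane[i]) < 0:
            plane[i] = -plane[i]
    proj = stained @ plane.T  # N x 2
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(phi, [percentile, 100.0 - percentile])
    v1 = np.cos(lo) * plane[0] + np.sin(lo) * plane[1]
    v2 = np.cos(hi) * plane[0] + np.sin(hi) * plane[1]
    vecs = []
    for v in (v1, v2):
        v = np.clip(v, 0.0, None)
        n = np.linalg.norm(v)
        if n == 0:
            return RUIFROK_HDAB
        vecs.append(v / n)
    # Single-stain images give near-identical extremes; substitute the
    # standard vector of the *other* stain so the basis stays invertible.
    if abs(float(np.dot(vecs[0], vecs[1]))) > 1 - 1e-6:
        ref_h = np.asarray(RUIFROK_HDAB.hematoxylin)
        ref_d = np.asarray(RUIFROK_HDAB.dab)
        v = vecs[0]
        if abs(float(np.dot(v, ref_d))) > abs(float(np.dot(v, ref_h))):
            return StainBasis(hematoxylin=tuple(ref_h), dab=tuple(v))
        return StainBasis(hematoxylin=tuple(v), dab=tuple(ref_d))
    # Assign by similarity to the standard vectors: DAB is the browner one.
    sim_d = [float(np.dot(v, RUIFROK_HDAB.dab)) for v in vecs]
    d_idx = int(np.argmax(sim_d))
    return StainBasis(hematoxylin=tuple(vecs[1 - d_idx]), dab=tuple(vecs[d_idx]))


@dataclass(frozen=True)
class TilingParams:
    """Square tiling with overlapping edges (defaults: 500 px, 50 px)."""

    tile_size_px: int = 500
    overlap_px: int = 50

    def __post_init__(self) -> None:
        if self.tile_size_px < 1:
            raise ValueError("tile_size_px must be >= 1")
        if not 0 <= self.overlap_px < self.tile_size_px:
            raise ValueError("overlap_px must satisfy 0 <= overlap < tile_size")

    @property
    def stride(self) -> int:
        return self.tile_size_px - self.overlap_px


@dataclass(frozen=True)
class Tile:
    """One tile of the inference grid, in parent (bbox-anchored) coordinates."""

    x0: int
    y0: int
    width: int
    height: int

    @property
    def x1(self) -> int:
        return self.x0 + self.width

    @property
    def y1(self) -> int:
        return self.y0 + self.height


def _axis_origins(extent: int, tile: int, stride: int, start: int) -> list[int]:
    if extent <= tile:
        return [start]
    origins = list(range(start, start + extent - tile, stride))
    # Final tile shifted inward so it never exceeds the bbox.
    last = start + extent - tile
    if origins[-1] != last:
        origins.append(last)
    return origins


def make_tiles(bbox: tuple[int, int, int, int], params: TilingParams | None = None) -> list[Tile]:
    """Lay a grid of overlapping square tiles over a bounding box.

    Tiles are placed on a stride of ``tile_size - overlap`` starting at the
    bbox origin; the final row/column is shifted inward so no tile exceeds
    the bbox, and the union of tiles covers every bbox pixel. A bbox smaller
    than the tile yields a single tile clamped to the bbox.
    """
    if params is None:
        params = TilingParams()
    x, y, w, h = bbox
    if w < 1 or h < 1:
        raise ValueError("bbox must span at least 1 px in each dimension")
    tw = min(params.tile_size_px, w)
    th = min(params.tile_size_px, h)
    xs = _axis_origins(w, tw, params.stride, x)
    ys = _axis_origins(h, th, params.stride, y)
    return [Tile(x0=xx, y0=yy, width=tw, height=th) for yy in ys for xx in xs]


# ---------------------------------------------------------------------------
# File I/O


def load_roi(path: str | Path) -> RoiPolygon:
    """Read the first polygon from a GeoJSON file (pixel coordinates)."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        geoms = [f["geometry"] for f in gj["features"]]
    elif gj.get("type") == "Feature":
        geoms = [gj["geometry"]]
    else:
        geoms = [gj]
    for geom in geoms:
        if geom.get("type") == "Polygon":
            poly = shape(geom)
            return RoiPolygon(vertices=tuple(poly.exterior.coords))
    raise ValueError(f"no Polygon geometry found in {path}")


def save_roi(roi: RoiPolygon, path: str | Path) -> None:
    ring = list(roi.vertices) + [roi.vertices[0]]
    gj = {
        "type": "Feature",
        "geometry": {"type": "Polygon", "coordinates": [[list(v) for v in ring]]},
        "properties": {},
    }
    with open(path, "w") as fh:
        json.dump(gj, fh)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def load_image(path: str | Path, microns_per_pixel: float | None = None) -> CalibratedImage:
    """Read a TIFF/PNG image plus its calibration sidecar.

    The sidecar is ``<image>.<ext>.json`` containing
    ``{"microns_per_pixel": float}``. When neither an explicit value nor a
    sidecar is available, a typical ×20-scan calibration of 0.50 µm/px is
    assumed with a warning.
    """
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        px = tifffile.imread(path)
    else:
        px = np.asarray(Image.open(path).convert("RGB"))
    if microns_per_pixel is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            with open(sidecar) as fh:
                microns_per_pixel = float(json.load(fh)["microns_per_pixel"])
        else:
            warnings.warn(
                f"no calibration sidecar for {path.name}; assuming "
                f"{DEFAULT_MICRONS_PER_PIXEL} um/px",
                stacklevel=2,
            )
            microns_per_pixel = DEFAULT_MICRONS_PER_PIXEL
    return CalibratedImage(pixels=px, microns_per_pixel=microns_per_pixel)


def save_image(image: CalibratedImage, path: str | Path) -> None:
    """Write a TIFF/PNG image and its calibration sidecar."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, image.pixels, photometric="rgb")
    else:
        Image.fromarray(image.pixels).save(path)
    with open(_sidecar_path(path), "w") as fh:
        json.dump({"microns_per_pixel": image.microns_per_pixel}, fh)
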