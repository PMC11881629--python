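"""Three-step tau segmentation separating tau from neuromelanin pigment.

In the DAB optical-density channel of a tau-immunostained nigral section,
three object classes overlap in intensity: neuropil threads (small,
moderate OD), neurofibrillary tangles (high OD, any size), and neuromelanin
pigment (moderate OD but large). Pigment would inflate any naive threshold,
so segmentation proceeds in three steps:

1. low-OD threshold (default 0.3) inside the ROI segments tau *and* pigment;
2. components larger than an area cutoff (default 50 µm²) are removed —
   this discards pigment and, temporarily, large tangles;
3. components of the high-OD threshold (default 0.8) are added back —
   tangles are darker than pigment, so only tangles return.

The reported burden is the percent of ROI area occupied by the final mask.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.measure import label as cc_label

from .imaging_io import OpticalDensityMap, RoiPolygon
from .synthetic_data.dab import rasterize_roi

__all__ = ["TauParams", "TauBurden", "segment_tau"]


@dataclass(frozen=True)
class TauParams:
    """Cutoffs of the 3-step segmentation.

    ``od_low`` — step-1 threshold capturing all tau and pigment;
    ``area_cutoff_um2`` — step-2 size cutoff above which components are
    removed; ``od_high`` — step-3 threshold whose components are re-added
    regardless of size. All OD comparisons are inclusive (≥).
    """

    od_low: float = 0.3
    area_cutoff_um2: float = 50.0
    od_high: float = 0.8
    #: "component": object-level re-inclusion — any step-1 component that
    #: contains a pixel ≥ od_high returns in full; "pixel": re-add only the
    #: pixels ≥ od_high themselves.
    reinclusion: str = "component"

    def __post_init__(self) -> None:
        if not 0 < self.od_low < self.od_high:
            raise ValueError("must satisfy 0 < od_low < od_high")
        if not self.area_cutoff_um2 > 0:
            raise ValueError("area_cutoff_um2 must be > 0")
        if self.reinclusion not in ("component", "pixel"):
            raise ValueError("reinclusion must be 'component' or 'pixel'")


@dataclass(frozen=True)
class TauBurden:
    """Final tau mask and the percent of ROI area it occupies."""

    mask: np.ndarray = field(compare=False)
    tau_area_um2: float
    roi_area_um2: float

    @property
    def percent_area(self) -> float:
        return 100.0 * self.tau_area_um2 / self.roi_area_um2

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "tau_area_um2": self.tau_area_um2,
                    "roi_area_um2": self.roi_area_um2,
                    "percent_area": self.percent_area,
                },
                fh,
                indent=2,
            )

    def save_mask_png(self, path: str | Path) -> None:
        Image.fromarray((self.mask * 255).astype(np.uint8)).save(path)


def segment_tau(
    od: OpticalDensityMap, roi: RoiPolygon, params: TauParams | None = None
) -> TauBurden:
    """Apply the 3-step segmentation and measure percent occupied area.

    Components are 8-connected. Areas are pixel counts × (µm/px)²; the ROI
    area is the pixel count of the rasterized polygon, so the percent is an
    exact pixel-counting ratio on the same grid as the mask.
    """
    if params is None:
        params = TauParams()
    H, W = od.shape
    x0, y0, w, h = roi.bounds()
    if x0 < 0 or y0 < 0 or x0 + w > W or y0 + h > H:
        raise ValueError("ROI extends outside the optical-density raster")
    px_area_um2 = od.microns_per_pixel**2
    roi_mask = rasterize_roi(roi, od.shape)
    roi_px = int(roi_mask.sum())
    if roi_px == 0:
        raise ValueError("ROI rasterizes to zero pixels")

    # Step 1: low threshold inside the ROI → tau + pigment candidates.
    low = (od.values >= params.od_low) & roi_mask
    labeled = cc_label(low, connectivity=2)

    # Step 2: remove components larger than the area cutoff.
    keep = low.copy()
    if labeled.max() > 0:
        sizes = np.bincount(labeled.ravel())
        too_big = sizes * px_area_um2 > params.area_cutoff_um2
        too_big[0] = False
        keep[too_big[labeled]] = False

    # Step 3: re-add high-OD material (tangles) regardless of size.
    high = (od.values >= params.od_high) & roi_mask
    if params.reinclusion == "component" and labeled.max() > 0:
        # Object-level: any step-1 component containing a high-OD pixel
        # returns in full, not just its dark core.
        dark_ids = np.unique(labeled[high])
        dark_ids = dark_ids[dark_ids > 0]
        readd = np.isin(labeled, dark_ids)
    else:
        readd = high
    final = keep | readd

    tau_area = float(final.sum()) * px_area_um2
    return TauBurden(
        mask=final, tau_area_um2=tau_area, roi_area_um2=roi_px * px_area_um2
    )
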