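"""Fixed color palette shared by the H&E-like fixture generator and the
reference color-rule detector.

The palette is deliberately part of the public contract: the synthetic slides
are drawn with exactly these RGB anchors, and the classical reference
detector segments by distance to the same anchors. Keeping both sides pinned
to one table makes the detector's color rules stable and auditable.
"""

from __future__ import annotations

import numpy as np

#: Neuropil background (pale pink-gray) with mild Gaussian pixel noise.
BACKGROUND = (228, 208, 216)
BACKGROUND_NOISE_SD = 3.0

#: Pigmented (neuromelanin-bearing) soma: brown base fill plus darker granules.
PIGMENT_BASE = (125, 85, 55)
PIGMENT_GRANULE = (78, 50, 30)

#: Non-pigmented soma: pale pink fill with a distinct darker rim.
NONPIGMENT_FILL = (246, 182, 188)
NONPIGMENT_RIM = (172, 92, 112)

#: Nucleolus: small high-contrast violet disc inside the soma.
NUCLEOLUS = (55, 25, 70)

#: Extracellular pigment clutter: brown clumps without a soma outline.
CLUTTER = (95, 60, 38)


def color_distance(pixels: np.ndarray, anchor: tuple[int, int, int]) -> np.ndarray:
    """Euclidean RGB distance of each pixel to a palette anchor."""
    diff = pixels.astype(float) - np.asarray(anchor, dtype=float)
    return np.sqrt(np.sum(diff * diff, axis=-1))
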