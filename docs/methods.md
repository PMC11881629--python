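# Methods

This note records the models, conventions and numerical choices behind
`nigraquant`, and what the synthetic test beds do and do not establish.

## Coordinate and raster conventions

Pixel coordinates are 0-based, x to the right, y down. Boxes are half-open
`[x, x+w) × [y, y+h)`; this must be fixed for IoU and tile remapping to be
bit-stable. Calibration is carried as microns per pixel (µm/px) on every
raster; when an image arrives without a sidecar, 0.50 µm/px — typical for a
×20 scan — is assumed with a warning. ROI polygons are simple closed rings
in pixel coordinates (GeoJSON); polygon area uses the shoelace formula, and
`area_mm2 = area_px × (µm/px ÷ 1000)²`. Where a mask and an area must agree
exactly (tau burden), the ROI is rasterized by pixel-center containment and
the area is the rasterized pixel count, so numerator and denominator live
on the same grid.

## Optical density and stain separation

Per-channel OD is `−log10((I+1)/256)`: the +1 offset bounds OD at
log10(256) ≈ 2.41 and avoids log(0); a pure white pixel maps exactly to 0.
The DAB signal is the least-squares projection of each pixel's OD 3-vector
onto a two-stain basis (hematoxylin, DAB), with the DAB coefficient clamped
at zero. The default basis is the standard Ruifrok–Johnston H-DAB
calibration. Basis estimation from an image projects stained pixels (OD
norm > 0.15) onto their top-2 principal plane and takes the directions at
the 1st/99th percentile of in-plane angle — the common robust
extreme-direction estimator; with fewer than 200 stained pixels it falls
back to the standard basis, so a usable basis is always returned.
Round-trip accuracy is quantization-limited: with 8-bit rasters the
forward-synthesize-then-invert error stays below 2% for stain coefficients
in roughly [0.3, 1.0] and grows at the dark end, where one intensity step
is a large OD step. The round-trip test therefore samples that
mid-absorbance range.

## Tiling and detection cleanup

Tiles are 500-px squares on a stride of tile − overlap = 450 px starting at
the ROI bounding-box origin; the final row/column is shifted inward so no
tile exceeds the box, and the tile union covers it. Detections whose box
comes within 1 px of an interior tile border are discarded as truncated;
borders coinciding with the ROI bounding box are exempt (nothing lies
beyond the slide). Because somata are smaller than the 50-px overlap, every
neuron appears untruncated in at least one tile, which is what makes
single-tile and multi-tile processing agree exactly. Truncation filtering
runs before cross-tile deduplication (the order is configurable).
Deduplication is greedy by descending confidence (ties: larger area, then
lexicographic label) absorbing boxes with IoU ≥ 0.5 — the threshold is a
design default, as is the center-in-polygon rule for ROI membership, which
is stable for boxes straddling the boundary. Densities divide the
nucleolus-bearing counts by the ROI area in mm²; nucleolus-free labels are
tabulated but never counted, because the nucleolus criterion guards
against double-counting split somata.

## mAP evaluation

AP is computed per class and per IoU threshold 0.50:0.95 (step 0.05) with
greedy confidence-ordered matching — each truth matched at most once, to
the unmatched truth of highest IoU at or above the threshold — and
101-point interpolated precision over recall. mAP averages over thresholds
and over the classes present in truth. 101-point interpolation is the
common modern convention; an IoU-vs-threshold comparison uses a 1e-9
epsilon so an overlap engineered to be exactly at a threshold counts at
that threshold. The test suite pins the evaluator to an independently
written brute-force oracle on small instances and to three analytic cases
(1.0 / 0.0 / 0.5).

## Tau segmentation choices

Components are 8-connected (connectivity was an open choice; 8 is the more
inclusive convention for thin threads). All OD thresholds compare with ≥,
so boundary values are included; the size filter removes components
strictly larger than the cutoff. Step-3 re-inclusion is object-level by
default: any step-1 component containing a pixel ≥ 0.8 OD returns in full,
reading "tangles are re-included" as statements about objects, not pixels;
a pixel-level mode is available (`TauParams(reinclusion="pixel")`). On the
synthetic fixtures both modes coincide because object OD is uniform.
Pigment exclusion is structural: fixture pigment is by construction larger
than 50 µm² and below 0.8 OD, so it is removed in step 2 and never
re-added; the acceptance sweep verifies zero pigment pixels in the final
mask across 100 random fixtures.

## Text abstraction choices

A "line" is a physical newline-delimited line. Term matching is
case-insensitive at word boundaries (no word character may abut either end
of the term), with at most one excerpt per (line, symptom); the recorded
term is the leftmost, then longest, match. Redaction replaces date, titled
person-name and facility patterns with `[REDACTED]`, never touching a span
containing the matched symptom term; it is idempotent. The rule classifier
checks hedge cues ("possible", "could not be assessed", "family history
of", ...) on the whole matched line first, then negation cues ("no",
"denies", "without", "negative for", ...) scoped to the clause containing
the term (clauses split on ";", "," and "but") — a simple, auditable
stand-in for a learned assertion classifier, and the interface accepts any
substitute. Patient aggregation ignores undetermined calls; one present
call dominates any number of absent calls; no informative call gives NA.
Grouping terms are present if any member is present, absent if at least
one member was evaluated and all evaluated members are absent, NA
otherwise. Parkinsonism "absent" requires falsification (bradykinesia
absent, or bradykinesia present with rigidity and rest tremor both
absent), not merely missing data.

## Statistics

Chi-squared is Pearson's statistic without continuity correction,
df = (r−1)(c−1). The choice was validated on a printed 2×2 worked example:
[[9, 53], [1, 46]] gives p = 0.0265, which prints as the published 0.03,
whereas Yates' correction gives 0.06 and does not reproduce it.
Mann–Whitney U is two-sided, exact by enumeration of the null distribution
when n₁+n₂ ≤ 12 without ties, otherwise the normal approximation with tie
and continuity corrections. Spearman's rho is the Pearson correlation of
mid-ranks with a t-approximation p. Quartiles use linear interpolation
(the common default; no quantile rule is prescribed by the reporting
convention emulated). Percents round half away from zero to one decimal —
the rule that reproduces every printed count–percent pair used in the
tests. No multiple-testing correction is applied, matching the emulated
reporting style.

## Synthetic data: what it emulates and what it does not

The histology generator draws elliptical somata (radius ~ N(8, 1) µm,
truncated at 3 px, axis ratio 0.75–1) on a noisy neuropil background with
a fixed, documented RGB palette: brown granule-textured fill for pigmented
somata, pale pink fill with a darker rim for non-pigmented ones, a small
high-contrast violet disc for the nucleolus, and rimless brown clumps
(~10 µm²) for extracellular pigment clutter. Somata are placed without
overlap and wholly inside the ROI; truth boxes are the exact bounding
boxes of the drawn pixels. The palette is shared with the reference
detector by design — the fixture exists to test the *pipeline* (tiling,
remapping, truncation, deduplication, densities, mAP), not color
robustness. Passing tests show the orchestration is exact; they do not
show that any detector generalizes to real H&E variability, and the
reference detector's perfect mAP on fixtures says nothing about
performance on scanned slides.

The DAB generator paints disjoint uniform-OD objects with class invariants
enforced at construction (threads ≤ 50 µm² at OD [0.3, 0.8); tangles
≥ 0.8; pigment > 50 µm² at [0.3, 0.8)) and reports the expected percent
area by pixel counting. Real immunostains have graded OD, touching
objects, and pigment-tau colocalization, none of which the fixture
contains.

The corpus generator plants at most one mention per (patient, symptom) in
templated sentences that the rule classifier's cue inventories cover by
construction; accuracy ≈ 1 on fixtures is a consistency check of the
search-excerpt-classify-aggregate chain, not an estimate of accuracy on
real clinical notes. The cohort simulator draws total density log-normal —
positive and right-skewed, matching asymmetric published IQRs — with
median 17.0 /mm² (σ = 0.25 on the log scale, from the printed IQR
14.4–20.1 of the non-parkinsonism group) and multiplies parkinsonism
cases by 0.83, the published median ratio 14.1/17.0; prevalence defaults
to 62/109. These defaults were fixed from the emulated study conditions
before any simulation was run.

## Problem sizes

The test and acceptance runs use: 100 random DAB fixtures (220² px); one
2 mm² histology fixture (2853² px, 45 neurons, 15 pigmented/mm²) processed
both as ~36 overlapping tiles and one tile; a 200-patient corpus
(~1500 mentions); 2000 null cohorts of n = 100 and 1000 effect cohorts of
n = 109 for the Mann–Whitney calibration and power; 10,000 cases for
median-ratio recovery. All generators are pure functions of their
parameters including the seed, so every number is reproducible.

## Known limitations

No scanner pyramid formats (plain TIFF/PNG only); no color normalization
beyond stain-vector estimation; no OCR (inputs are plain text); the
shipped symptom dictionary is a documented, editable stand-in covering the
key parkinsonian and cognitive symptoms rather than an exhaustive clinical
inventory; no onset/severity/temporal modeling; no multiple-testing
correction.
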