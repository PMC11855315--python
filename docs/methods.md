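# Methods

## Problem and model

SEM micrographs of macroporous gel scaffolds (cryogels, hydrogels)
show pores as dark regions on a lighter polymer matrix: darkness
correlates with depth, so voids read darker than the surrounding
material. poremorph characterizes the pore population of such an image
as a set of closed contours with per-pore area, perimeter,
isoperimetric ratio, fitted-ellipse orientation, centroid and feret
diameters, plus population summaries (mean/median/std pore area, mean
IPR, pore density).

The segmentation model is deliberately simple and fully
user-controlled — no learned components:

1. **CLAHE** (contrast-limited adaptive histogram equalization)
   flattens uneven illumination so one global threshold treats the
   whole frame consistently. The image is divided into an N×N tile
   grid (`clahe_size`, default 8); each tile's histogram is clipped at
   `clahe_clip_limit × tile_area / 256` (default clip 2.0), the excess
   redistributed, and the equalization maps blended bilinearly between
   tiles.
2. **Non-local-means denoising** removes grain and stray pixels that
   would otherwise be traced as spurious contours. Each pixel becomes
   a weighted mean of pixels with similar patch neighborhoods; weights
   decay with patch distance scaled by `denoise_strength` (default 30,
   on the 0–255 gray scale). The patch side is `denoise_size` (default
   7 px, odd); the search window is fixed at 21 px.
3. **Cutoff thresholding**: pixels strictly below
   `grayscale_threshold` (default 100) become black (pore
   candidates), the rest white. A tie at the cutoff goes white.
   Raising the cutoff grows the black set monotonically, visually
   "eroding" pore edges outward.
4. **Contour tracing with hierarchy**: every boundary loop between
   black and white becomes a contour. Black regions are 8-connected,
   white background 4-connected (the standard duality that keeps loops
   well defined). Implementation: connected-component labeling, then
   Moore-neighbor border following with Jacob's stopping criterion for
   the outer loop of each region and for each hole's inner loop;
   islands inside holes recurse. Containment links give each nested
   contour a parent.
5. **Rejection rules**, applied in a fixed order: any contour that
   touches the image border or is nested inside another contour is
   rejected outright ("hierarchy" class); surviving root contours with
   shoelace area below `min_pore_size_px` (default 100 px²) or above
   `max_pore_size_px` (default 10⁶ px²) are rejected by size. The two
   size gates compare **area in pixels²**, the same quantity the size
   filter reports.
6. **Measurement** of each accepted contour (see below), optionally
   converted to physical units by the scalebar ratio
   `um_per_px = scalebar_reading_um / scalebar_length_px`.

The default settings above are the package's documented, config-visible
baseline; every CSV row echoes the settings that produced it.

## Per-pore quantities

- **Perimeter** is the sum of Euclidean edge lengths around the closed
  vertex loop ("measured directly" on the traced chain). Note the
  known chain-code bias: an 8-connected boundary of a smooth convex
  shape overestimates its true perimeter by about 5% (measured 1.049×
  on a digitized radius-30 disc). We do not apply a
  Vossepoel–Smeulders-style correction, because the uncorrected sum is
  exact for axis-aligned polygons and matches what OpenCV-based tools
  report; consumers comparing IPRs across tools should be aware of the
  bias.
- **Area** has two modes. `polygon` is the shoelace area of the
  boundary polygon; since traced vertices sit at pixel *centers*, it
  misses the half-pixel rim and under-measures a region by roughly
  perimeter/2. `pixel` counts the lattice pixels inside-or-on the
  contour (equivalently shoelace + B/2 + 1 by Pick's theorem, B the
  boundary count). The analysis pipeline uses `pixel`, which tracks
  the physical pore area to well under 1% for semi-axes ≥ 10 px; the
  `polygon` mode is retained for direct comparison against
  shoelace-based tools and is what the size gate uses.
- **IPR** = 4πA/P²: 1 for a perfect disc, π/4 for a square, smaller
  for elongated or irregular pores. Because of the perimeter bias
  above, a *digitized* disc reads ≈ 0.88, not 1.0; the closed-form
  value 1.0 holds for analytic inputs. Values above ~1.05 are not
  reachable for convex digitized shapes.
- **Ellipse fit**: direct least-squares conic fit constrained to
  ellipses (the numerically stable Halir–Flusser formulation of the
  Fitzgibbon–Fisher method), exact on noiseless elliptical point sets.
  Contours with fewer than 5 distinct vertices cannot determine a
  conic; their orientation/feret fields are left undefined rather than
  failing the pore.
- **Orientation**: pores carry no inherent direction, so the
  major-axis angle is reported in [0°, 180°), measured from +x with y
  increasing downward ("all pores point rightward"). The orientation
  *vector* points along the major axis with magnitude
  major − minor axis length — a circle has no orientation and gets the
  zero vector.
- **Centroid**: arithmetic mean of all lattice pixels contained within
  the contour (interior plus boundary), matching a brute-force pixel
  scan; a contour with no interior falls back to its vertex mean.
- **Feret diameters** are read from the fitted ellipse's axis lengths
  (min = minor, max = major); a rotating-calipers mode on the convex
  hull is available as an alternative (`feret_mode="calipers"`).

## Sessions, save profiles, reproducibility

One *pass* = one run of the pipeline with one settings bundle. Saved
pores persist across passes and permanently carry their pass's frozen
settings (*save profile*); detected-but-unsaved pores are replaced by
the next pass. Pore numbering restarts at 1 each pass; exports key on
(pass_id, pore_id). A session is drivable from a plain-text script
(`analyze`/`save`/`remove`/`saverange`/`removerange`), and replaying
the same script on the same image byte-reproduces the CSV — the CSV
writer formats floats by shortest round-trip `repr`, so parsing an
export recovers every value exactly.

A new pass may re-detect a region already saved earlier; the package
does not deduplicate automatically (curation is the caller's job,
mirroring interactive use). No automatic scalebar OCR is attempted;
the scale is always given explicitly (pixel mode or supplied
length/reading).

## Summary statistics

Sample (n−1) standard deviations throughout, matching spreadsheet
STDEV conventions; a single-pore summary reports std 0 with a
degenerate-n flag. Pore density divides the pore count by the full
image area converted to mm² (the user supplies a cropped micrograph,
so the whole frame is the analyzed region); it is undefined in pixel
mode. Display rounding is half-even to 1 decimal; internal values stay
full-precision.

## Method-comparison statistics

`percent_deviation(ref, test) = |ref − test|/|ref| × 100` scores
per-pore agreement against a reference method (manual freehand
tracing). Group comparisons summarize each analyst by mean and sample
std per parameter, then report mean-of-averages, std-of-averages
(between-analyst variability) and mean-of-stds (within-analyst
spread), compared across methods by the signed difference
`(test − ref)/ref × 100`. The published benchmark tables shipped in
`poremorph.benchmarks` include only the percent cells that are
internally consistent with their rounded printed inputs; the remaining
cells were evidently computed from unrounded source data and cannot be
reproduced from the tables, so they are excluded from automated
checks. Significance testing (F/t/Welch) is intentionally out of
scope; the comparison table carries values only.

## Synthetic phantoms

`generate_phantom` renders dark filled ellipses (default intensity 40)
on a light matrix (200) with optional linear illumination gradient,
Gaussian and salt-and-pepper noise, and an optional dark information
band with a white scalebar. Placement is rejection-sampled so pores
are non-overlapping (bounding-circle test plus `min_gap`, default
8 px) and fully interior; a deliberate border-crossing pore can be
appended to exercise the border-rejection rule. Everything is
deterministic given the seed.

Phantom defaults (1024×1024, 20 pores, semi-axes 10–40 px, uniform
angles, zero noise) are the clean baseline used for recovery scoring;
tests that exercise a specific preprocessing rationale switch on
exactly the relevant corruption (gradient ±40 levels for CLAHE,
salt-and-pepper for denoising). Most tests use 384–512 px frames with
6–15 pores, which preserve every geometric property of the full-size
baseline while keeping the suite fast; the recovery acceptance test
itself runs the full 1024² / 20-pore condition.

`score_recovery` matches accepted pores to planted pores by nearest
center (gate: the pore's semi-minor axis), then reports recall,
spurious count, relative area error against the analytic πab, and
angular error modulo 180°. Angular error is scored only for pores
whose planted semi-axis difference is at least 2 px — twice the
half-pixel digitization scale of each boundary. A pore whose axes
differ by less than the pixel grid has no resolvable orientation on
the lattice (a circle has none at all); empirically, all resolvable
pores recover their angle within ~1.6°, while sub-pixel-eccentricity
pores scatter up to ~9°.

What phantom results do **not** show: performance on real micrographs
with merged pores, rough walls, charging artifacts or depth-of-field
blur. Phantoms bound the digitization and pipeline error under the
model's own assumptions (elliptical, well-separated pores).

## Numerical and design choices

- CLAHE clip limit is exposed on the conventional absolute scale
  (default 2.0, max bin count = clip × tile_area/256); the kernel-size
  knob defaults to tiles-per-side (`clahe_mode="tiles"`), with
  pixels-per-tile selectable, since both conventions exist in the
  wild.
- A constant image is returned unchanged by CLAHE (a single-bin
  histogram has nothing to redistribute).
- Thresholding tie-break: a pixel exactly at the cutoff goes white
  ("strictly under" is black).
- Single-pixel regions yield valid 1-vertex contours with area 0; any
  positive minimum-size gate removes them.
- All nested contours are rejected, not only first-level children:
  a contour inside a pore is a feature of the pore wall, not a pore.
- Overlay colors: detected green (0,255,0), saved gold (255,215,0),
  removed-by-size pure blue (0,0,255), removed-by-hierarchy magenta
  (255,0,255), removed-by-user orange (255,165,0), labels red.
- 16-bit inputs are linearly min–max rescaled to 8-bit (logged);
  color inputs are converted by ITU-R BT.601 luminance.
- Replay abort: any malformed command or unknown pore id aborts with
  the script line number; ids in a range command that are not
  currently detected are skipped silently by design.

## Known limitations

- Two-dimensional only: no interconnectivity, tortuosity or 3-D pore
  volume; a 2-D slice systematically under-represents pore size.
- Merged pores are traced as one contour; no watershed splitting.
- The chain-perimeter bias (~+5% on smooth shapes) propagates into
  IPR (digitized disc ≈ 0.88); comparisons are consistent within the
  tool but not calibrated to analytic perimeters.
- Pore density assumes the full frame is analyzable tissue; an
  un-cropped information band would dilute it.
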