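# Methods

This note records the modeling assumptions, parameter choices and numerical
conventions behind `drquad`, and what the synthetic-data tests do and do not
establish about real fundus photographs.

## Grid geometry

The modified ETDRS grid keeps the 1500 µm foveal central ring and the four
diagonal quadrants, extending the quadrants to the periphery of the 45°
field instead of stopping at the outer ETDRS ring. Conventions, all
deterministic and documented in `drquad.geometry`:

* Pixel coordinates are 0-based, x rightward, y downward; "superior" means
  smaller y. Angles are measured counter-clockwise from the horizontal
  through the fovea with "up" positive.
* Quadrant boundaries are the ±45° diagonals through the fovea (the classic
  ETDRS "X"), not a vertical/horizontal cross. A point exactly on a
  boundary ray belongs to the counter-clockwise neighbouring wedge, making
  the wedges the half-open intervals [45°,135°), [135°,225°), [225°,315°),
  [315°,45°).
* The central ring is *excluded* from the quadrants: membership is decided
  first (distance from fovea < 750 µm), so ring lesions never enter
  quadrant totals. This turns the anatomical expectation of an avascular,
  lesion-free fovea into a structural guarantee of the pipeline's outputs.
* The 45° field is modeled as the circle inscribed in the image rectangle,
  centered at the image center; points beyond it are `outside_field` and
  excluded from all totals. Corners of the rectangle are thus never
  counted. (The true camera aperture is approximately this circle.)
* Laterality: the photograph is assumed macula-centered and non-mirrored,
  so the optic disc lies nasal to the fovea and a disc on the image right
  means a right eye. The horizontal wedges are labeled temporal = side
  opposite the disc, nasal = disc side. Mirrored acquisition dialects can
  be handled by mirroring the frame (`FundusFrame.mirrored_x`), which flips
  the inferred laterality and leaves all anatomical labels invariant.
* Physical scale: µm/px = fov_deg × (µm per degree) / width_px, with
  1° ≈ 288 µm of retina as the default conversion for an emmetropic adult
  eye; both factors are overridable per frame. At 1440 px / 45° this gives
  9 µm/px and a 750 µm ring radius of ~83 px.

## Grading

The MESSIDOR rule set grades from whole-image totals (μA, H, NV). The
published clauses overlap at their boundaries; the classifier therefore
evaluates severe → moderate → mild → none, which makes it total over all
non-negative inputs and monotone in each count (verified exhaustively in the
tests against a brute-force re-evaluation of the boolean formulas). Counts
used for grading are whole-image, not per-quadrant: the rules predate the
quadrant division, and no per-quadrant grading is defined. When a frame is
supplied, marks outside the 45° field are excluded from the totals. Macular
edema is outside the scale as used here.

Note an inherent tension in the calibration data: mild-DR strata are
defined by H = 0, yet published per-quadrant hemorrhage means for mild
cohorts are nonzero. The grader follows the rules verbatim; the simulator
addresses the tension explicitly (below).

## Statistics

* Summaries use the n−1 sample SD and SEM = SD/√n.
* Two-sample t is computed from summary statistics (mean, SD, n per group);
  the raw-data form summarizes first, so the two routes agree to floating
  precision by construction (asserted at 1e−9 in the tests, alongside
  scipy cross-checks). Welch is the default; with equal group sizes the
  Welch and pooled t values coincide exactly and only the df/p differ.
  Both groups constant with equal means raises a zero-variance error at the
  operation level; the cohort report maps that degenerate case to t = 0,
  p = 1 (no evidence of a difference).
* One-way ANOVA is the classic fixed-effects F from explicit sums of
  squares; an all-constant input yields F = 0, p = 1, and zero within-group
  variance with distinct means yields F = ∞, p = 0.
* Quadrant groups are treated as independent samples, not paired within
  eyes: published quadrant t-values of this kind are reproducible only
  under the independent two-sample formula with the stratum n per group.
  No multiple-testing correction is applied; p-values are reported raw.
* The report grid covers 2 lesion types × graded strata × 4 quadrants of
  summaries, ANOVA margins across quadrants and across grades, and
  pairwise t's of a reference quadrant (default temporal) against the other
  three. Cells with n < 2 are listed in `missing`, never zero-filled.

## Synthetic cohorts

The generator emulates the *statistical* structure of graded screening
cohorts, not their images:

* **Count law.** Only (mean, SD) per cell are available, so the law is
  chosen as negative binomial with moment-matched mean and variance
  (size r = mean²/(SD²−mean)) when SD² > mean, Poisson(mean) otherwise,
  and identically 0 at mean 0. Every severe-stratum cell is overdispersed
  and is matched in both moments; some mild/moderate hemorrhage cells are
  *under*dispersed (e.g. 1.07 ± 0.27), which no Poisson/NB mixture can
  match — there the mean is exact and the simulated SD is the Poisson one.
  Means, not SDs, are the recovery surface of the acceptance checks.
* **Placement.** Uniform within the target wedge annulus (outside the
  750 µm ring, inside the field), by rejection sampling that re-checks
  `assign_region`, so counting recovers the drawn counts exactly. Lesions
  keep ≥ 2000 µm from the disc center (real discs obscure lesions, and the
  detector masks that area) and, by default, a 150 µm surface-to-surface
  gap from each other; in pathologically dense images the gap (only) is
  relaxed rather than dropping lesions. No sub-quadrant spatial law is
  imposed — none is published.
* **Geometry.** Frames default to 1440×960 px, 45°, fovea jittered ±12 px
  around the image center, disc 4500 µm nasal and 270 µm superior to the
  fovea; laterality is an even right/left mix by default. Diameters: MA
  uniform 30–110 µm, HEM 150–800 µm, straddling the detector's 125 µm
  cutoff with a margin on each side.
* **Consistency modes.** `table_calibrated` (default) draws counts exactly
  as calibrated even where the resulting image would not regrade into its
  declared stratum (the mild-H tension above). `rule_consistent`
  deterministically adjusts each draw into the declared grade's feasible
  region — hemorrhages zeroed for mild, totals clamped below the severe
  thresholds for moderate, microaneurysms topped up temporally for severe —
  trading calibration fidelity for grading consistency. Adjustment rather
  than resampling: calibrated mild draws would essentially never satisfy
  H = 0 by chance.
* **Rendering.** The optional renderer paints a schematic fundus: uniform
  orange background, gentle macular darkening, bright soft-edged disc
  ellipse, MAs as dark-red circles and HEMs as randomly oriented dark-red
  ellipses of equivalent area, plus mild Gaussian pixel noise. Lesion edges
  are feathered so that a half-contrast threshold recovers the nominal
  diameter. The black circular camera aperture is deliberately *not*
  painted: the detector's background subtraction would otherwise see a huge
  artificial edge, and the aperture carries no information for this
  pipeline. Vessels, exudates, texture and illumination gradients are
  absent.

## Detection

The detector is a stand-in for a trained segmentation model, and is
documented as such: a background-subtraction blob detector on the green
channel (background = Gaussian blur at σ = 1000 µm, far above the largest
lesion radius; contrast = background − image), disc neighbourhood masked
within 1400 µm, threshold at a normalized contrast of 0.08 (about a quarter
of the rendered lesion contrast of ~0.33), connected components measured by
centroid, equivalent-circle diameter and mean contrast, size-gated to
20–1500 µm. Classification is by size alone: ≤ 125 µm equivalent diameter
is a microaneurysm (the conventional clinical boundary), larger is a
hemorrhage. The detector is deterministic, and raising the threshold can
only shrink the thresholded set — on unimodal rendered lesions the
candidate count is monotone non-increasing in the threshold.

Passing round-trip tests on these renders shows the *pipeline plumbing* is
lossless for well-separated lesions; it says nothing about detection
performance on real fundus photographs, which is explicitly out of scope.

## Problem sizes and reproducibility

Simulated strata use their full calibrated sizes (261 and 300 images for
the severe strata; 182/162 mild/moderate), which run in seconds. The
detector round-trip checks use 10 rendered 1440×960 images carrying 200
lesions in total; replicate-based significance checks use 100 seeded
replicates of four n=261 count groups via the count-law fast path (spatial
placement is count-preserving by construction, so the ANOVA distribution is
unchanged). All randomness flows through explicit `numpy` generators seeded
from a single integer; identical seeds reproduce cohorts, reports and
written artifacts byte for byte.

## Known limitations

* The renderer and detector are schematic; no claim transfers to real
  images (pigmentation, vessels, media opacities, camera vignetting).
* Underdispersed calibration cells are matched in mean only (see above).
* Quadrant comparisons assume independent groups; within-eye pairing would
  change the t denominators and is not modeled.
* The pipeline analyses a single macula-centered 45° field; wide-field or
  multi-field montage geometry is out of scope, as are exudates,
  neovascularization detection (NV is an input flag) and macular edema.
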