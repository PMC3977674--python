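# Methods

This note documents the models implemented in `froa`, the parameters that
matter, the numerical choices behind them, and what the synthetic-data
validation does and does not establish.

## Viewing geometry

All analyses operate on an 800 × 800 px stimulus frame subtending 18° of
visual angle horizontally (≈44.44 px/°).  Pixel↔degree conversion is a
single linear factor; at this eccentricity a tangent-corrected mapping would
differ by under 2%, which is far below every tolerance used here.
Coordinates are 0-based pixels, origin top-left, x rightward, y downward.

## Silhouette contours and curvature

A silhouette must be a single 4-connected, hole-free foreground component of
at least 100 px.  Its boundary is traced with marching squares at the 0.5
level, simplified with a sub-pixel Douglas–Peucker pass (tolerance 0.7 px)
to remove the rasterisation staircase, offset 0.5 px toward the interior so
the contour runs through boundary pixel centres, and resampled to uniform
~1 px arc-length spacing in a canonical orientation (counter-clockwise in a
y-up frame, interior on the left).  With these steps a 10 × 10 px square
traces to a perimeter of ≈35.7 px (pixel-centre perimeter 36) and an
r = 100 px disc to ≈629 px (2πr ≈ 628.3).

Signed curvature is estimated in tangent-turning form, κ = dθ/ds: the
tangent direction along the contour is unwrapped, detrended by the +2π
total turning of a simple closed curve, and differentiated with a periodic
Gaussian-derivative filter.  This is mathematically the same quantity as
the arc-length parametrisation formula κ = (x′y″ − y′x″)/(x′² + y′²)^{3/2},
but unlike direct coordinate smoothing it does not shrink the contour, so
the smoothing window can be wide without biasing κ.  The default width is
**σ = 15 samples (~px)**, chosen because narrower windows beat against the
15–25 px chord spacing left by any sub-pixel contour tracing of a rasterised
curve and leave large per-sample ripple; at σ = 15 a rasterised circle of
radius 60–150 px recovers κ = 1/r within ≤9% at every sample.  The cost is
that curvature detail at scales below ~15 px is averaged out; part-junction
concavities in the intended stimulus regime are far sharper than this.
Convention: κ > 0 convex, κ < 0 concave (a circle has κ = +1/r).

## Curvature-polarity ROI models

Every contour sample with |κ| ≥ `kappa_min` (default 0.005 px⁻¹) stamps a
filled disk centred on the sample, with radius growing linearly in |κ|:

    r = r_min + (r_max − r_min) · min(|κ| / kappa_sat, 1)

with defaults r_min = 2 px, r_max = 20 px, kappa_sat = 0.05 px⁻¹ on the
800 px frame.  Disks accumulate into a concave mask (κ < 0) and a convex
mask (κ > 0), built independently; they may overlap near sign changes, and
the pipeline's diagnostics table reports the overlap fraction (typically
≪1% for the synthetic families).  All four constants are config-exposed;
the linear-with-saturation law is the package's own concrete reading of a
"proportionally sized disk" construction.

## Part boundaries (minima / short-cut rule)

Concavity extrema are local minima of κ with κ < 0 and peak prominence
above `prominence` (default 0.01 px⁻¹), detected with periodic wrap-around.
Candidate cuts are extremum pairs whose chord

1. lies entirely inside the silhouette (tested against the traced polygon
   grown by 1 px to absorb rasterisation disagreement),
2. is shorter than both boundary arcs it separates (the short-cut
   condition), and
3. traverses the interior rather than skimming the boundary: the chord
   midpoint must lie at least a quarter of the chord length away from the
   contour.  Without this depth condition, two concavities flanking a
   gently bent region (e.g. the inner side of an elbow-shaped object) get
   joined by a short boundary-hugging chord that consumes both extrema and
   suppresses the true junction cuts.

Accepted greedily in order of increasing length (ties by lower contour
index), each extremum used at most once.  The part-boundary ROI is the
union of flat-capped bands of half-width `band_px` (default 8 px) around
each cut, clipped to the silhouette.

## FROA and the MMC statistic

The retained fixations of one participant on one stimulus become a
fixation-region map: the union of disks of radius `region_radius_deg`
(default 1.0°, roughly the foveal extent) around the fixation centres,
clipped to the frame.  Overlap with an ROI is pixel-area based,
O = 100·|fixmap ∩ ROI|/|fixmap|; a fixation-count mode (fraction of
fixation centres inside the ROI) is available as an option.

The chance distribution draws the *same number* of fixations i.i.d. from a
null density — `uniform_object` (uniform over the silhouette; the default,
since it controls for the object-versus-background bias of real gaze),
`uniform_frame`, a `saliency` map, or any user-supplied density — builds a
region map, and records its overlap; the default is 1000 iterations.  The
"95% confidence bound" is operationalised as the **one-sided 95th
percentile** (linear interpolation) of the chance overlaps, because the
statistic's sign convention (negative = less overlap than expected at the
bound) references a single upper bound; a two-sided option (97.5th
percentile) is config-exposed.  Then

    MMC = O − C95   (percentage points).

Under the null, MMC > 0 in ≈5% of draws; the test suite and acceptance
script verify this calibration with 1000 independent replicates of 1000
iterations each on a 200 × 200 grid (a reduced grid keeps the study to
about a minute; the statistic is scale-free because the region radius is
specified in degrees).

Per participant, MMC is computed per stimulus × model with the Monte-Carlo
fixation count matched to that participant's retained count, then averaged
over stimuli to one value per participant × model — aggregation at the
participant level is the package's choice and keeps the ANOVA units
independent.  Chance distributions depend only on (stimulus, model, count),
not on the participant, and are cached on that key.  The Monte-Carlo inner
loop is vectorised (batched sorted-index union counting), which makes the
calibration study and full-frame analyses fast on one CPU.

## Saliency stand-in

The saliency null is a deliberately simple conspicuity map: centre-surround
intensity contrast (|G_σ − G_{4σ}| at σ = 4, 8, 16 px) plus Gabor
orientation energy at four orientations, each channel max-normalised,
summed, floored at 0.1% of its peak (so it remains usable as a sampling
density), and normalised to unit mass.  It is pluggable — any non-negative
map of frame dimensions can be substituted — and makes no claim to
reproduce any specific published saliency model.

## Scanpath metrics

Preprocessing discards the fixation with index 1 in every trial (the
centrally-pinned trial-onset fixation), drops out-of-frame fixations rather
than clamping them (a clamped fixation would inflate edge-ROI overlap), and
flags trials left empty.  Saccade amplitudes are Euclidean distances
between consecutive retained fixations within a trial — never across
trials — divided by px/°; dwell time is the arithmetic mean fixation
duration.  Both are aggregated to one value per participant.

## Synthetic data

The generator emulates the structure of a two-group recognition experiment:

* **Shapes**: six families of unions of convex primitives (ellipse,
  capsule, rectangle) — a two-disc dumbbell, a three-disc chain, a bent
  elbow, a pear, a capsule-plus-disc club and a rectangle-plus-disc mallet.
  Junctions between linked primitives create paired boundary concavities
  exactly where the minima rule predicts cuts, and each junction's
  ground-truth chord (the segment joining the two boundary-intersection
  points) is recorded.  Metric jitter (independent per-axis size factors,
  default range 0.9–1.2) creates within-family variants with preserved
  adjacency; placements that would let unlinked parts collide, disconnect
  the mask, or create holes are rejected with bounded retries.  The elbow's
  bend is 40°: at much tighter bends the two inner-corner concavities fall
  within one smoothing window of each other and merge, which is a genuine
  resolution limit of any smoothed-curvature detector, not a property of
  the rule.
* **Scanpaths**: the first fixation is pinned to the frame centre.  In
  mixture mode, each subsequent fixation is drawn from the target ROI with
  probability π and from the null density otherwise — so the fraction of
  fixations in the ROI is π + (1 − π)·(ROI share under the null), the
  closed form the tests check.  In step mode, fixations form a random walk
  with gamma step lengths (mean in degrees, shape `step_shape`); when a
  step would leave the frame its *direction* is redrawn with the length
  kept, so the amplitude distribution is preserved (lengths are redrawn
  only in the rare case that no direction fits).  Durations are i.i.d.
  gamma with configurable mean and shape.
* **Defaults as study conditions**: groups of 12 participants; step-length
  means 2.30° and 3.64° with gamma shapes (mean/SD)² from spreads of 1.26°
  and 1.71°, i.e. the spread is carried by the within-scanpath amplitude
  distribution (per-participant mean amplitudes then differ mainly by the
  group mean, which is what makes a 24-participant comparison decisive);
  duration means ≈198 and ≈196 ms with shapes matching SDs ≈46 ms.  Trial
  counts and fixations per trial (demo: 6 trials × 8 fixations; validation
  studies: 4 × 16) are conventions chosen to give stable per-participant
  means at desk scale, as no per-trial fixation counts are available to
  emulate.

What passing on synthetic data shows: the pipeline recovers known part
structure, known ROI preferences and known group differences, and its null
statistic is calibrated.  What it does not show: robustness to real
eye-tracker noise (drift, calibration error, fixation-parsing choices),
non-stationary gaze strategies, or 3D-rendered stimuli whose internal
shading creates features the 2D silhouette models cannot see.

## Statistics

The split-plot ANOVA uses the closed-form balanced decomposition (between
factor: task group; within factor: ROI model; subjects nested in groups);
F(task) is tested against subjects-within-groups, F(model) and the
interaction against model × subjects-within-groups, with partial
η² = SS_effect/(SS_effect + SS_error).  Unbalanced or incomplete tables are
an error — no silent sum-of-squares type choice, no imputation.  No
sphericity correction is applied by default (with three within levels and
planned contrasts this is conventional); zero-variance degenerate inputs
are reported as F = 0, p = 1 (no effect) or F = ∞, p = 0 (effect over a
zero error stratum) rather than NaN.

Planned comparisons are two-sided paired t-tests between models within a
task and independent t-tests (pooled variance by default, Welch optional)
between tasks per model, uncorrected by default with a Bonferroni flag.
Mann–Whitney U (for accuracy-type metrics) uses an exact p when there are
no ties and min(n) ≤ 12, full enumeration over group assignments when there
are ties and C(n₁+n₂, n₁) ≤ 50 000, and the tie-corrected normal
approximation beyond that — exhaustively enumerating tied designs at
n = 12/12 (~2.7 million assignments) buys no practical accuracy over the
corrected approximation.

## Determinism

Every source of randomness descends from one master seed through
`numpy.random.SeedSequence` spawns in fixed order: stimulus seeds, one
stream per participant, and one chance-distribution seed per (stimulus,
model, count) key.  Re-running any stage with the same config and seed
reproduces its CSV outputs byte for byte, which the test suite asserts.

## Known limitations

* Curvature below the ~15 px smoothing scale is invisible; very small or
  very thin silhouettes (pinching under a 0.5 px inward offset) are
  rejected rather than analysed badly.
* The greedy shortest-first pairing is a heuristic; the depth condition
  removes its main failure mode on blunt concavity pairs, but adversarial
  shapes with many similar-length candidate chords can still pair
  suboptimally.
* Polarity masks may overlap near curvature sign changes; downstream
  overlap statistics treat the models independently.
* The saliency stand-in is intentionally minimal and should not be used to
  make claims about any specific saliency model.
* Fixation parsing from raw gaze samples, blink handling and binocular
  fusion are out of scope; the pipeline starts from fixation tables.
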