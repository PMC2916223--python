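# Methods

This note records the models, parameter choices and numerical conventions
behind `her2ia`, the reasoning where the design was genuinely open, and
what the synthetic validation does and does not demonstrate.

## Optical density and stain separation

Brightfield absorbance follows Beer–Lambert: a pixel with incident
(blank-glass) intensity `I0` and transmitted intensity `I` has optical
density `OD = −log10((I + ε)/I0)` per channel, with `ε = 1` so that a
saturated black pixel (I = 0) stays finite; the offset is negligible
elsewhere (< 0.002 OD at half background). Negative ODs (pixels brighter
than background, from noise) clamp to zero.

Because co-localised stains add in OD space, per-pixel stain amounts are
the solution of `OD = c_h·S_h + c_d·S_d + c_r·S_r` for the unit stain
vectors S. The default basis is the widely used haematoxylin
(0.650, 0.704, 0.286) and DAB (0.268, 0.570, 0.776) reference vectors with
an orthogonal residual completing it; laboratories calibrate their own
vectors per antibody kit through the colour-definition file, since
published vectors are only a reasonable starting point for any particular
scanner/stainer combination. Negative deconvolution coefficients are
clamped to zero rather than treated as errors — they arise routinely from
noise. The basis must be well conditioned (condition number < 1e8).

Thresholds: a pixel is **immunopositive** when its DAB coefficient is
≥ 0.15 OD, and **tissue** when its OD magnitude is ≥ 0.10, both
configurable; tissue components smaller than 16 px are dropped as speckle.
There are no canonical published values for these cutoffs; 0.15 OD is
comfortably above sensor noise (< 0.01 OD at 8-bit quantisation) and below
the weakest membrane staining the classifier must see (~0.2 OD).
Boundary convention is ≥ throughout.

## Membrane tracing and continuity

The quantity that matters clinically is the fraction of each cell's
circumference that stains — *continuity* — because guideline categories
hinge on "incomplete" versus "complete" membranous staining. The tracer
must therefore (a) find cells whose membrane may be almost entirely
unstained, and (b) measure stained extent against the *full* perimeter,
not just the detected arc.

Detection: the haematoxylin channel is smoothed (σ = 2 px) and nuclei are
its local maxima (min peak 0.2 OD, min separation 8 px). The DAB channel
is smoothed (σ = 1.5 px), thresholded at the positivity cutoff, and
skeletonised; skeleton pixels are assigned to their nearest nucleus when
their distance is compatible with the cell-size prior (enclosed area
80–2000 px², i.e. radii ≈ 5–25 px at the ~0.46 µm/px scale the defaults
assume). The membrane circle for a cell is centred on its nucleus with
radius equal to the median assigned-skeleton distance (stragglers beyond
±max(3 px, 25%) of that radius are discarded and the radius re-estimated);
the contour is the full circle sampled at ~1 px spacing, so an open arc
still divides by its completed perimeter. Nuclei with no assigned ridge
become zero-continuity traces with a default radius (geometric mean of the
bounds) — unstained cells must enter the per-cell continuity mean, not
vanish from it. Skeleton components assigned to no nucleus are kept only
if a least-squares circle fit closes at cell scale (angular coverage
≥ 90%, radial spread small), a fallback for nucleus-detection failures.

A contour vertex counts as stained when its pixel or any 8-neighbour
(1-px tolerance) is in the *unsmoothed* immunopositive mask. Smoothing is
deliberately excluded here: a smoothed threshold crossing migrates with
staining intensity, and continuity must measure extent, not intensity.
With the defaults the dilation tolerance biases continuity upward by
roughly +0.03 (about two extra pixels at each arc end on a ~75 px
circumference); the calibration test bounds the overall mean absolute
error at 0.05. In fragmented (dashed-arc) rendering the bias grows with
the number of dash ends — a known limitation of tolerance-based counting.

Artefact exclusion flags connected DAB components that are (a)
near-saturated (mean ≥ 1.8 OD) and larger than a cell, (b) solid shapes
(solidity > 0.95, area ≥ 80 px²) with no interior haematoxylin nucleus, or
(c) size outliers beyond 10× the cell-area bounds. Flagged pixels are
removed from the positive and tissue masks before aggregation and any
trace touching them is dropped, so an excluded pixel appears in no
numerator or denominator downstream.

## Slide features and region restriction

Analysis is restricted to pathologist-annotated invasive tumour: the
inclusion mask is the union of include polygons (whole frame if none)
minus all exclude polygons, with pixel-centre coverage (a pixel belongs to
a polygon iff its centre does; origin top-left, polygons in (x, y)). Cells
straddling the boundary count iff their centroid is inside — a
deterministic, orientation-free rule.

Features over the included region: `% immunopositive pixels` and
`% membrane-positive pixels` are ratios to included tissue pixels; mean
membrane absorbance is the mean DAB OD over positive membrane pixels (0 if
none); `% membrane continuity` is 100 × the unweighted per-cell mean
(a perimeter-weighted variant is available — whether the clinical quantity
is averaged per cell or pooled over membrane pixels is not standardised,
and the per-cell mean was chosen as the default because the guideline
rules are phrased per cell). An empty tissue∩inclusion denominator is an
error at the operation level; the pipeline maps a fully blank slide to
all-zero features and a rule-based negative call instead, since a blank
slide is a legitimate input to batch analysis.

## Probability classifier

The classifier maps (mean membrane absorbance, % membrane continuity) to a
category with a confidence. A Gaussian class-conditional model (quadratic
discriminant) was chosen because it is directly probabilistic — the
confidence is `100 × max posterior`, exactly the quantity reported — is
trainable from ~150 cases, and has no opaque machinery. Features are
standardized by the training mean/SD; each class gets an empirical prior,
mean and covariance, the latter regularized by `λI` with `λ = 1e-3` to
keep 50-case class covariances well conditioned. Posterior ties break
toward 2+ — the clinically conservative direction, since equivocal cases
are referred to FISH. A hard override precedes the model: < 1%
immunopositive pixels (relative to tissue pixels, consistent with the
"in tissue" convention of the pixel features) forces 0/1+ at confidence
100, because the rule is deterministic by construction. FISH categories
use HER2/Chr17 < 1.8 / 1.8–2.2 (inclusive) / > 2.2.

Training-set selection reproduces the highest-random-number design: every
case in each assay cohort draws a uniform [0, 1) number and the n largest
per cohort train the model. Models serialize to a versioned YAML file with
full-precision parameters.

## Validation statistics

Concordance is `100 × trace/n` of the 3×3 table; Cohen's κ is unweighted,
`(p_o − p_e)/(1 − p_e)` with chance agreement from the marginal products,
labelled on the Landis–Koch scale (0.80 exclusive lower bound for "almost
perfect"). Sensitivity and specificity use FISH as gold standard with
equivocal *test* calls excluded from both denominators (those cases are
referred, not called) and FISH-equivocal cases always dropped with a
logged count; this convention is the only one that reproduces the
reference tables' printed percentages. Zero denominators yield NaN flagged
as undefined, never a silent 0. Reported percentages round half-up to
integers, with unrounded values retained. AUC is the rank-based
(Mann–Whitney) estimator with half-credit for ties. The control drift
check flags a staining batch when any control-slide feature leaves
mean ± 3 SD of a reference established from at least three prior batches.

## Synthetic slides

The generator renders what the algorithm must measure and nothing more:
haematoxylin nuclear discs (0.6 OD, radius half the cell radius) and DAB
membrane annuli (3 px thick) covering a contiguous arc of each cell's
continuity fraction at its intensity, on 256×256 px slides of 40
non-overlapping cells (dart-throwing, ≤ 1e4 retries) with radii 9–14 px,
Gaussian pixel noise (SD 2 intensity units), optional saturated artefact
discs and exclusion rectangles. Intensity composes as
`I = I0·10^(−OD) − ε`, the exact inverse of the analysis transform, so the
generator is an inverse model of the stain module up to uint8 quantisation
(≲ 1% concentration error over 0.05–1.5 OD). Identical spec and seed give
byte-identical output.

Ground-truth labels apply the guideline cell-fraction rules with explicit
cutoffs: a cell has *complete* membranous staining when continuity ≥ 0.5,
is *uniform* when ≥ 0.9, *intense* when ≥ 0.6 OD; a slide is negative when
< 10% of (non-excluded) cells stain completely, positive when > 30% are
uniform and intense, equivocal otherwise.

Training/validation tables draw each slide's staining parameters around
its category phenotype: negatives are a mixture of essentially unstained
tumours and the weak-incomplete-but-widespread (1+) phenotype; equivocals
have moderate, partially continuous staining in most cells; positives
intense near-complete membranes. The per-case parameter jitter gives each
class honest within-class dispersion, and the 1+ mode is what forces the
classifier to use continuity rather than stained extent to separate 0/1+
from 2+ — the discrimination the equal-intensity acceptance test checks.

What passing these tests shows: the measurement chain is calibrated
(continuity to ±0.05, pixel fractions to ±0.5 points), intensity and
extent are decoupled, and the classifier recovers generating parameters
and separates phenotypes at the rendered separation. What it does not
show: performance on real tissue, where membranes are non-circular and
crowded, stain vectors drift, chromatic noise is structured, and the
category boundaries are far less clean. No claim about clinical accuracy
follows from the synthetic results; the clinical agreement statistics in
`her2ia.datasets` come from the reference validation tables, not from
images.

## Problem sizes and numerical conventions

Default study sizes — 150 training and 90 held-out slides (50/30 per
category), 40 cells per 256×256 slide, 20-cell slides for the
six-point continuity calibration sweep — keep a full
generate–analyse–train–validate cycle under a minute on one CPU while
leaving per-class estimates stable. All randomness flows through
`numpy.random.default_rng` seeds carried in the specs; pixel coordinates
are 0-based (row, col); polygon vertices are (x, y).

## Known limitations

- Circular-contour reconstruction assumes roughly isotropic cells; highly
  elongated or crowded cells would need a deformable tracer.
- Continuity carries a small positive bias from the 1-px tolerance, larger
  for fragmented staining.
- One Gaussian per class is a coarse density for the bimodal negative
  phenotype; a mixture would fit it better at the cost of transparency.
- Whole-slide pyramid formats, tile streaming and cross-scanner colour
  normalization are out of scope; inputs are fixed-size 8-bit rasters.
- Automated discrimination of invasive tumour from DCIS is deliberately
  not attempted; pathologist annotation is a prerequisite.
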