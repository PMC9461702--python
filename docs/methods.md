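# Methods

This note documents the models, algorithms and numerical choices behind
`spherofuse`, what the synthetic phantom does and does not emulate, and the
known limitations.

## The fusion model

Doublet fusion is summarized by the bounded exponential

    roundness(t) = plateau + b · exp(−t/τ)

with roundness = 4πA/P² of the doublet mask. The plateau (steady-state
roundness, fusion quality) is constrained to [0.5, 1]: two externally
tangent equal disks have analytic roundness exactly 0.5, a circle 1. The
amplitude b is constrained to [−0.6, −0.1], so the response starts at
plateau + b and increases monotonically. τ (hours) is the time at which the
response has closed 1 − 1/e ≈ 63.2 % of its gap to the plateau; it is not
bounded above — real assays occasionally produce nearly flat responses whose
likelihood in τ is flat, which is why the fit multi-starts at
τ₀ ∈ {0.5, 2, 8, 24} h and keeps the best residual sum of squares
(`scipy.optimize.least_squares` with exact box constraints). Whether to fit
raw or smoothed roundness is an open choice; the package fits raw values.

The early normalized contact length is fitted by a bounded line
(intercept ∈ [0.05, 1.4], slope ∈ [0, 1] h⁻¹) on the t ≤ 5 h subset only,
where the response is approximately linear; later points are excluded, not
down-weighted. Area is normalized to the frame-0 area; contact length to the
mean initial spheroid width over the first 10 timepoints.

Time zero is the first acquired frame. The ≈1 h pre-acquisition delay
(spheroid contact and temperature equilibration) is carried as metadata
(`acquisition_delay_h`) and is not added to the fitted time axis by default,
so fitted τ refers to acquired data.

## Pipeline

**Detection.** Circular Hough transform (scikit-image) on the Canny edge map
(σ = 3) over the configured radius range. The Hough accumulator cannot
distinguish the inner and outer edge of the dark rim annulus, so each
accepted circle's radius is refined to the inner rim edge: the radius at
which the angular-averaged radial intensity profile drops fastest going
outward. Peaks are accepted greedily in score order with a minimum centre
separation.

**Tracking.** Each doublet's well is re-detected every frame in a crop of
half-side radius + 20 px around its previous position. The best candidate is
the highest-scoring circle within half a well radius of the previous centre
and within 15 % of the previous radius (ties break toward the smallest
displacement) — wells are anchored in agarose, so only slow stage drift is
expected. A sample is dropped when no circle qualifies or any part of the
selected well disk lies outside the frame ("partly out of the field of
view" is operationalized as any part of the disk).

**Segmentation.** Frame 0: the crop is flattened by dividing by a coarse
Gaussian illumination estimate, Otsu-thresholded inside the well interior
(the detected disk eroded by 1 px — the rim annulus lies outside the
refined inner-edge radius), morphologically closed (disk of radius 2),
hole-filled, and the one or two largest components of at least `min_area`
(150 px) are kept, the second only if it reaches 25 % of the largest. Both a
binary mask and the grayscale reference (raw intensities under the mask) are
stored.

Later frames: the grayscale reference is registered rigidly to the new crop
by normalized cross-correlation (`skimage.feature.match_template` on
inverted intensities) with parabolic sub-pixel interpolation of the
translation peak and a coarse-then-fine rotation grid (1° then 0.25° over
±6°). Sub-degree rotations move boundary pixels by fractions of a pixel —
below what integer-grid correlation resolves, and rotation interpolation
slightly penalizes any non-zero angle — so the sequence driver additionally
estimates the rotation from the change in the mask's second-moment
orientation and injects it as a hint that wins unless a grid angle beats its
correlation score by more than 0.025. A correlation score below 0.35 flags
registration failure and drops the sample.

The fresh segmentation is refined against the reference transformed by the
registration: components overlapping the 3-px-dilated transformed reference
by more than 30 % survive; holes are filled; if the refined area jumps more
than 20 % relative to the previous frame (fusion changes area slowly at
5-min sampling) or the fine segmentation is empty, the transformed reference
itself is used (fallback, logged per frame). Both references are then
replaced by the new masks.

**Morphometrics.** Masks are aligned with the horizontal axis by the
second-moment orientation (0-based pixel coordinates, x rightward, y
downward). Area is the pixel count; the perimeter is the arc length of the
marching-squares contour of the mask smoothed with a Gaussian of σ = 0.9 px
— raw pixel-edge contours overestimate the perimeter by ~5 % and depress
the roundness of even a perfect disk to ~0.91, while stronger smoothing
fills the neck notch; σ = 0.9 keeps the rendered-vs-analytic roundness
error below 0.02 from the near-cusp regime up to full fusion for radii
≥ 30 px. Length and width are contour extents along/across the principal
axis.

The neck is selected among (upper, lower) pairs of prominence-filtered local
minima of the boundary distance profiles by the cost

    w₁·|x_mid − x_interface| + w₂·(profile height) + w₃·|x_up − x_down|

with each term min–max normalized over the candidate set and default weights
1/1/1 (no published weights exist; the three terms encode agreement with the
inscribed-circle interface, neck depth, and vertical alignment).
x_interface comes from the two maximally inscribed circles of the interior
distance transform: the global maximum, then the maximum restricted to
points farther than r₁ from the first centre; a second maximum below
0.35·r₁ flags an effectively fused single blob. From frame 1 on, candidates
are windowed (±12 px) around the previous neck position expressed relative
to the mask centroid; with no surviving minima the previous position is
reused. Neck points are snapped to the raw marching-squares contour for
half-pixel placement (the smoothed contour would round the concave notch
outward and lengthen the chord). Contact length is the distance between the
neck points; the mask is split by the line through them and each side's
width is its extent perpendicular to the major axis.

**Intersphere angles.** At each neck anchor two tangent rays are drawn, one
per spheroid, and the reported angle between them lies in [0°, 180°]:
a smooth merged boundary gives 180°, a first-contact cusp 0°. Straight-line
fits to k nearby contour points are biased by roughly (k/r) radians on a
boundary of curvature 1/r (each chord deviates from the tangent by half its
arc), which at r = 30 px and k = 7 already exceeds 10°; the package
therefore uses circle-based tangents. When each anchor lies on both
inscribed-circle boundaries (within 15 % of the radius) the ray is the
tangent of the respective inscribed circle at the anchor — accurate down to
the near-cusp regime. Otherwise (shallow necks, where the
farther-than-r₁ restriction mislocates the second circle, and near-fused
masks) each ray comes from a least-squares circle fit (Kåsa) to k = 7
boundary samples spread over about one spheroid radius of arc on that side
of the anchor. On noiseless two-disk phantoms with r ∈ [30, 100] px this
keeps the angle within ~9° of the closed-form circle-intersection value
across d/r ∈ [0.5, 1.9], and returns 180° ± 2° on smooth circular masks.

**Staging.** Frame 0 is stage 1 (full extraction); stage 2 adds temporal
neck windowing; stage 3 is entered at the first frame whose measured
roundness reaches 0.8 — no hysteresis, the simplest consistent rule — after
which only area, length, width, roundness and rotation are reported: near
full fusion the neck is no longer a well-defined structure. Per-frame
feature failures are recorded on the row, never raised, so one bad frame
cannot lose a series.

**Candidate triage.** Each well crop yields a fixed 32-descriptor vector
(object count, areas/shape/roundness of the two largest objects and their
ratio, normalized centroid distance, small-object debris statistics,
interior intensity statistics, gradient-energy focus proxy, covered
fraction, mask-moment eccentricity). The published descriptor set is not
publicly specified; this one is a declared substitute with the same intent.
Manual labels 0/1/2 are binarized (positive = {1, 2}) and a random forest is
trained with the published settings: 60 trees, 30 predictors per split
(capped at the feature count), minimum leaf size 3, and a 5:1
false-negative:false-positive cost. The cost enters twice — class weights
during training and a decision threshold chosen to minimize the empirical
5·FN + 1·FP on the training set, resolving ties toward the lower (more
sensitive) threshold; the contract is the 5:1 asymmetry, not a specific
mechanism. Evaluation is stratified 5-fold cross-validation on
group × class (each fold ≈ 20 % validation — the k-fold analogue of a
grouped 80/20 split), reporting accuracy, sensitivity, precision and F1 as
mean ± SD per group and overall; folds where a ratio is undefined are
recorded as missing, not zero.

**Statistics.** Groups of kinetic parameters are compared by a decision
tree: Shapiro–Wilk per group (α = 0.05; the normality test is not named in
the source protocol, Shapiro–Wilk is the standard choice at these n) and
Bartlett's test for equal variances select one-way ANOVA with Tukey–Kramer
post hoc, otherwise Kruskal–Wallis with Dunn's rank-sum pairwise z-tests
under Šidák adjustment (implemented directly; the closed form is standard).
Zero-variance groups force the nonparametric branch and are flagged.
Population mean ± SEM curves are truncated at the first timepoint where
≥ 30 % of samples have dropped out.

## The phantom

The generator is geometric, not mechanistic: a doublet is the union of two
disks whose centre distance d(t) is obtained by inverting the analytic
roundness of the union (area from the lens formula, perimeter as the sum of
the two major arcs — an exact, monotone, invertible map solved by Brent's
method) so that the rendered roundness follows the bounded-exponential
trajectory exactly. Ground truth per frame: rasterized mask, disk centres
and radii, centre distance, common chord (contact), intersphere angle
(180° minus the angle between the radius vectors at an intersection point),
union area, roundness, well centre.

Appearance: dark spheroids (40 % of background intensity) with a faint
low-contrast halo (8 %) as a surrogate for the translucent ECM rim of
matured microtissues, inside a darker-rimmed circular well (35 % rim
contrast) on a bright background, with optional Poisson debris specks
(1–2.5 px) and single cells (3–5 px) kept clear of the doublet so ground
truth stays exact, a linear illumination gradient, Gaussian sensor noise,
and linear stage drift. Defaults follow the targeted acquisition regime:
1.6 µm/px (4× bright-field), 100 µm well radius, spheroid radii 40–75 µm
(diameters < 150 µm), 5-min frame interval, 349 frames (29 h); test presets
use 30–60 frames. Edges are anti-aliased over 1 px, so thresholding a
noiseless frame at the midpoint intensity recovers the true mask with
≥ 99.5 % pixel agreement inside the well. All randomness flows from one
seeded `numpy.random.Generator`; identical seeds give bit-identical stacks.

Labelled well populations for classifier work render five negative subtypes
(empty, debris-only, single spheroid, triplet, heavily overlapping pair),
"possible candidate" pairs (moderate overlap or strong size mismatch) and
clean side-by-side pairs, at a default class mix putting ≈ 8.3 % of wells
in the positive classes — the empirically realistic doublet seeding
efficiency for this format.

What the phantom does **not** emulate: viscoelastic neck dynamics (the
two-disk union has a sharp corner where real tissue necks are smoothed),
out-of-focus blur and extended-focal-imaging artifacts, uneven rim
appearance, spheroids deforming against the well wall, or debris drifting
through the doublet. Passing the phantom suite therefore demonstrates the
correctness of the geometry, tracking, registration and fitting machinery
under the intended imaging regime — not segmentation robustness to every
real-world artifact.

## Numerical choices and degenerate inputs

- Two-disk geometry handles the full parameter range: disjoint disks return
  a zero-contact sentinel (chord 0, angle 0), containment returns the larger
  circle (angle 180°).
- A doublet whose initial separation would overflow the well radius is a
  configuration error, raised at render time.
- Registration rotation search is bounded (±6°/frame by default); the
  moment-orientation hint is wrapped to (−90°, 90°].
- `fit_exponential` requires ≥ 10 finite points and strictly increasing
  times; `fit_linear_contact` ≥ 5 usable points within 5 h. Bound-active
  solutions are returned as-is (e.g. slope clamped to 0 on a decreasing
  contact artifact).
- Empty reference masks leave sensitivity undefined (NaN), empty automatic
  masks leave precision undefined; undefined values are propagated as
  missing, never as zero.
- Test-suite problem sizes: 30-frame phantoms at 220² px for segmentation
  checks, 100-seed Monte-Carlo for parameter recovery, 20 paired seeds for
  the classifier cost comparison — small enough to run the whole suite in a
  few minutes on one core while leaving the statistical checks
  well-powered.

## Known limitations

- The registration's rotation estimate for sub-degree per-frame motion
  comes from mask moments, so it degrades for nearly circular (late-fusion)
  masks, where rotation is ill-defined anyway.
- Neck detection assumes a single doublet per well; triplets or intruding
  spheroids are a triage problem (label 0/1), not a segmentation one.
- The classifier descriptor set and the neck cost weights are package
  choices; retraining on real labelled wells is expected before use on a
  new imaging setup.
- Manual exclusion of shifting/floating doublets is supported via an
  exclusion-list file (`exclude_wells`), mirroring what is otherwise a
  by-eye step.
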