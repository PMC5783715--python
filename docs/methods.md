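# Methods

This note documents the models and procedures `gliamotion` implements, the
parameters that matter, the design choices made where the method was
genuinely open, and what the synthetic-data validation does and does not
establish.

## Motility metrics

**Motion maps and surveillance index.** A binarised single-cell movie
F_t (t, y, x) is frame-differenced into extension maps PE_t = F_t ∧ ¬F_{t−1}
and retraction maps PR_t = F_{t−1} ∧ ¬F_t.  The per-transition surveillance
sum S_t = |PE_t| + |PR_t| counts pixels swept by process movement between
consecutive frames.  In normalised mode B_t = S_t / ⟨S⟩_control, where the
control mean is taken over all transitions whose timestamps fall strictly
within the first `control_window_min` minutes (default 20).  A transition is
timestamped at its *later* frame.  If the control mean is zero (a perfectly
static movie) normalisation is impossible; absolute values are returned
with a flag.  Absolute mode skips normalisation entirely — the form used
when comparing genotypes or treatment groups, which are then normalised to
a reference group's pooled mean.

**Ramification index.** R = (P/A) / (2√(π/A)) ≡ P/(2√(πA)), dimensionless
and scale-free: R = 1 for an ideal disk, larger for any other shape (the
isoperimetric inequality).  The default perimeter estimator is the Crofton
formula with four directions (`skimage.measure.perimeter_crofton`), which
converges to the true boundary length — rasterized disks of radius ≥ 100 px
give R = 1.00 ± 0.02, and a rasterized 5-armed star agrees with the
analytic polar-curve perimeter within 1%.  A `pixel_count` mode counts
foreground pixels with at least one background 8-neighbour (the MATLAB
`bwperim(BW, 8)` convention used by legacy scripts); it is biased on smooth
shapes and provided for compatibility only.  All connected components of
the mask contribute to area and perimeter: detached process fragments
inside the ROI are still part of the cell's territory.  Empty frames in a
trace are recorded as NaN rather than dropped, preserving time alignment.

**Cumulative survey.** C_t = |∪_{s≤t} F_s| is non-decreasing and starts at
the first-frame cell area.  Its initial slope is a least-squares fit of
C_t against time over the frames with timestamp ≤ 2 min — a regression
rather than a two-point difference, for robustness at 30–60 s sampling —
reported in px/min and μm²/min.  The early window is used because pixel
overlap in the maximum projection saturates the curve later.

## Chemotaxis front tracking

The field around the target is decomposed into concentric rings of
`ring_um` (default 2 μm) crossed with `n_sectors` (default 32) equal-angle
sectors; sector k spans [2πk/n, 2π(k+1)/n) counterclockwise from +x in
pixel coordinates.  Per frame and sector, rings are scanned outward from
the target; the front is the *inner* radius of the first patch containing
strictly more than `min_pixels` (default 10) foreground pixels — "more
than" is kept strict (11 qualifies, 10 does not), and the inner radius is
the conservative choice among inner/outer/centroid, none of which is
canonical.  Sectors with no qualifying patch are censored at
`max_radius_um` and flagged.  The enclosed "clear" area is the closed-form
sum of circular sectors Σ_k π d_k² / n_sectors; the difference from a
rasterized front polygon is O(1/n_sectors) and immaterial at 32 sectors.
The front is monotone in mask inclusion by construction: adding foreground
can only move fronts inward.

The target position is a configuration value (pixels or μm) rather than an
interactive click.  With 10-pixel patches at ~0.44 μm pixels, patches
closer than ~3 μm to the target are geometrically too small ever to
qualify, so front distances below the first one or two rings are not
resolvable — an intrinsic property of the counting rule, not an artifact.

## Preprocessing

The chain, in the surveillance order: rolling-ball background subtraction
(ball radius 30 px) per z-slice, 3×3 median filter per slice (reflected
edge padding), lateral registration, axial registration, maximum intensity
projection, binarisation, ROI masking.  The branch order for movies without
a stated convention is configurable (`background_first`).

*Background subtraction caveat*: the rolling ball must be larger than the
structures to preserve; with ~4 μm somata at ~0.44 μm/px (≈ 18 px diameter)
the 30 px ball is adequate, but shrinking the ball below the soma diameter
carves intensity out of the soma centre.  When working on spatially
scaled-down images the ball radius must not be scaled below that bound.

*Registration.* Lateral drift is estimated per frame against the first
frame by the cross-correlation peak (integer shifts by default, subpixel
optional), applied with zero fill; an all-zero frame gets shift (0, 0) and
a warning flag.  Axial drift follows the reslice recipe — view the stack
from the side, estimate the per-frame z-translation, shift in z, return to
the original orientation — but the z-estimator is an explicit integer-shift
correlation search rather than an FFT phase correlation: with only 20–30
slices, FFT correlation is cyclic and aliases any shift larger than half
the stack, which would make the "drift exceeds half the stack → drop the
frame" rule undetectable.  The explicit search is exact and costs O(n_z²)
per frame, negligible at this depth.

*Binarisation.* One threshold per movie, computed by Otsu's method on the
temporal-mean frame and applied to every frame (pixel foreground iff
intensity ≥ threshold).  A per-frame threshold would let photobleaching
modulate mask size over time; a single threshold makes the masks — and
hence B — exactly invariant to uniform intensity rescaling, which is also
why bleaching does not bias the surveillance index.  A fixed manual
threshold is available; absolute R and B values are threshold-dependent, so
cross-study comparisons of absolute values require matched thresholding.

*ROI.* Polygons are [x, y] vertex lists in pixel units, even-odd fill,
boundary pixels inside; self-intersecting polygons are rejected
(shapely simplicity check).  Pixels outside the ROI are erased in every
frame.

## Sholl analysis and morphometrics

SWC files (7 whitespace-delimited columns, `#` comments, one root with
parent −1) are parsed with validation of parent references, single-rootness
and acyclicity; unknown type codes are preserved.  Shells are spheres at
`dr_um` (default 1 μm) increments centred on the *soma centroid* — the mean
of soma-type nodes (the file format does not define "the soma" more
precisely).  Each edge is a straight 3-D segment; its crossings of the
shell of radius r are the roots of the quadratic |p(t)|² = r² in t ∈ [0, 1)
— the half-open interval makes chains of edges count each crossing exactly
once, and tangential touches (double roots) count zero.  This includes the
rare two-crossing case where a segment dips inside a shell with both
endpoints outside, which a pure endpoint-straddle test would miss; the
analytic count agrees exactly with a dense-resampling oracle (0.05 μm
steps) on every random tree tested.  Zero-length edges are skipped;
intra-soma edges are excluded from both crossings and total length.

"Number of processes" counts primary stems (edges leaving a soma node);
branch points are non-soma nodes with ≥ 2 children.  Both are reported
because the literature is inconsistent about whether "processes" means
stems or all branches.

Group comparison builds a tidy (group, cell, radius, intersections) table —
profiles zero-padded to a common radius grid — summarises per-radius
mean ± SEM, and fits `intersections ~ C(group) * C(radius)` by OLS with a
two-way ANOVA (statsmodels `anova_lm`, type II; identical to the classical
decomposition for balanced designs, which the tests verify against
hand-computed sums of squares).

## Statistics

The sequential multiple-comparison correction multiplies the i-th smallest
p-value by (N − i + 1), then enforces monotonicity in rank order and caps
at 1 — the two standard steps of the Holm step-down procedure that the
informal "multiply by N, N−1, …" description leaves implicit; without them
corrected values could invert the significance ranking or exceed 1.  The
implementation is cross-checked against an independent Holm implementation
(statsmodels `multipletests`) on random inputs.

Sample size for a two-sided two-sample t-test is the smallest integer n
with power ≥ target, where power is the exact noncentral-t tail probability
with df = 2n − 2 and noncentrality √(n/2)·|Δ|/σ.  The normal approximation
is deliberately not used: for Δ/σ = 2, α = 0.05, power 0.80 it returns 4,
while the exact calculation gives 6 (power at n = 5 is 0.791, at n = 6 is
0.876) — matching the worked example the test suite pins.  A 20 000-
replicate Monte-Carlo simulation confirms the analytic power within ±0.01.

Normality tests, F-tests, t-tests and Mann-Whitney comparisons are
delegated to scipy/statsmodels and merely orchestrated.

## Synthetic-data generator

The generator emulates the acquisition geometry of two-photon microglia
imaging: 512 × 512 frames covering a 225 μm field (pixel size 0.44 μm,
within the 0.39–0.49 μm range of a 200–250 μm field), 25 z-slices at 2 μm,
frames every 60 s (surveillance) or 30 s (chemotaxis).

**Cell model.** Each cell is a disk soma (radius 4 μm) with
`n_primary_processes` (default 6) stems fanned around it.  Processes are
polylines grown in ~1.2 μm sub-segments with Gaussian direction noise
(SD 0.18 rad); branching is a Poisson process along newly extended length
(`branch_prob_per_um`, default 0.04 /μm), with side branches anchored at
interior points so every branch point is a genuine bifurcation.  Each
branch lives at a fixed z-offset within ±3 slices of the soma plane, so the
maximum projection is the meaningful 2-D view.  Per frame, every tip either
extends or retracts (probability ½ each) by rate × frame-interval × U(0.5,
1.5); the default tip speed of 1.5 μm/min is a plausible literature-scale
value, *not* a measured one — no tip velocities are available to calibrate
against, so kinetic rates are phenomenological knobs.  Retraction never
passes a live side-branch anchor.  In chemotaxis mode the extension
direction is blended toward the target with weight `bias_strength` and the
retraction probability scales as (1 − bias)/2, so at bias 1 every tip
marches straight at the target (never overshooting), and at bias 0 the
model reduces to the undirected walk.  Somata in chemotaxis mode are
stratified in angle around the target (microglia tile the parenchyma
roughly evenly) at 45–70 μm radius.

**Ground truth and rendering.** The continuous skeleton is the ground
truth.  Rasterized true masks are soma ∪ skeleton dilated to
`process_width_um`/2 (default 1 μm half-width); true PE/PR counts are set
differences of consecutive true masks by construction.  The rendered
intensity is a steep super-Gaussian cross-section, exp(−ln2·(d/w)⁸), with
half-maximum exactly at the true mask radius, soma 1.6× brighter than
processes, distributed across z by a Gaussian profile (σ = 1.2 slices)
around each structure's z-offset, plus additive Gaussian noise (SD 0.05 of
process amplitude) and optional exponential bleaching exp(−t/τ) applied to
signal before noise.  The steep shoulder is a deliberate choice: it puts
the half-height contour of the image at the true boundary, so any
binarisation threshold in a wide band recovers the true process width, and
the full preprocessing chain achieves ≥ 0.9 Jaccard overlap with the true
masks at default settings.  A shallower (pure Gaussian) profile would make
the recovered width strongly threshold-dependent and the ground truth
unrecoverable in principle — a property of real data too, which is exactly
why absolute mask-derived quantities are threshold-dependent (see
Binarisation above).

The analytic per-frame area/perimeter ground truth is the
overlap-ignoring sum (soma disk + 2wL tube per branch + end caps); it is an
upper bound where branches overlap and is not used by any quantitative
test.  The chemotaxis ground-truth front applies the same
qualifying-patch rule as the tracker (> min_pixels pixels' worth of area)
but measures truly occupied area on the *continuous* footprint — the union
of soma disks and skeleton tubes evaluated on a 3× oversampled grid —
independent of rendering, noise, thresholding or image-raster effects.

**Reproducibility.** Every cell owns a generator seeded by (master seed,
stream id, cell index); placement, growth and noise use separate streams,
so adding cells or toggling rendering never perturbs existing cells, and
identical (config, seed) reproduces stacks, masks and SWC files
bit-identically.

**SWC population generator.** Fixed-tissue-style morphologies are grown in
3-D (z compressed ×0.4, emulating slice-flattened arbors) with the same
segment/branching logic, written as canonical SWC.  Its ground truth (stem
count, branch points, total length, shell crossings) is computed from the
continuous tree and verified against the dense-resampling oracle.

**What passing tests do and do not show.** The generator produces
plausible ramified morphologies and motion statistics, but real data differ
in ways the simulation does not model: non-uniform background, motion blur,
light scattering with depth, anisotropic PSF, cell-to-cell brightness
variation, and genuinely manual thresholding.  Green tests therefore
demonstrate that the *algorithms* are correct against ground truth and
internally consistent — not that absolute R, B or front values from real
movies are unbiased; those remain threshold- and resolution-dependent, as
the original method's reliance on per-movie manual thresholds implies.

## Problem sizes used in the test and acceptance suites

Validation simulations run at reduced field sizes (75–120 μm fields at the
native ~0.45 μm pixel size, 3–7 z-slices, 5–40 frames, 1–10 cells), chosen
so each property is measured in seconds while preserving the spatial scale
that the metrics' pixel-count rules (10-pixel patches, 30-pixel ball,
2 μm rings) assume.  Monte-Carlo batteries use 100 random instances per
oracle comparison, 10 paired seeds for kinetic-rate recovery, and 20 000
replicates for the power confirmation.
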