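# Methods

`sporemorph` implements a landmark-based geometric-morphometrics pipeline
for crescent-shaped (ceratomyxid-type) myxospores viewed in the sutural
plane, together with a synthetic spore-population generator that stands in
for micrograph-derived data.  This note records the models, the numeric
choices, and the reasoning behind the design decisions that were genuinely
open.

## The landmark scheme

A spore outline in sutural view is a closed 2-D polygon with two annotated
suture-axis points.  Eight landmarks are constructed:

* **L1, L5** — the suture line's crossings of the outline on the convex
  (anterior) and concave (posterior) side.  The suture is the bilateral
  symmetry axis of the spore.
* **L3, L7** — the left and right shell-valve tips, located as the boundary
  points of maximal discrete curvature.  Curvature is estimated per vertex
  by the three-point circumradius formula and smoothed with a cyclic moving
  average (odd window, default 7 vertices); the two lateral halves, split
  by the suture axis, are searched independently and left/right is assigned
  by the sign of the cross product with the axis direction.  A maximum must
  exceed the half's median curvature by 5 % to count as a tip; a circle
  therefore has no resolvable tips.
* **L2/L4 and L8/L6** — derived landmarks.  With M the midpoint of the
  suture chord L1–L5, a line is drawn through the midpoint of M–tip,
  perpendicular to M–tip.  Its two crossings of the boundary that bracket
  the valve interior give the outer (anterior; L2, L8) and inner
  (posterior; L4, L6) landmarks.  Orientation is made explicit by pointing
  the perpendicular towards the anterior half-plane (positive component
  along L5→L1); the anterior-most crossing of the bracketing pair is the
  outer landmark.  This generalizes cleanly to outlines where the chord
  midpoint lies outside the spore (strongly curved crescents).

The bilateral pairing map is (L2,L8), (L3,L7), (L4,L6) with L1 and L5 on
the midline.

**Traditional measures.** Length = |L1−L5| (the axial diameter), thickness
= |L3−L7| (straight tip-to-tip chord), posterior angle = the angle at L5
between the rays to the two tips (arccos of the normalized dot product, so
in (0°, 180°)).  Whether "thickness" should be the tip chord or the curved
valve extent is not decidable from the landmark definitions alone; the
chord is implemented.  One consequence, discussed below, is that the
absolute centroid-size scale of the synthetic spores is fixed by the three
traditional measures and comes out near 27 µm.

## The crescent shape family

Synthetic outlines are built from a circular-arc centerline of radius R
spanning polar angles ±φ, thickened symmetrically along the centerline
normals by the half-width profile

    w(t) = W (1 − t²)^e ,   t ∈ [−1, 1],

with taper exponent e = 0.7 by default (0 < e < 1 gives rounded tips whose
continuum curvature diverges at the apex, so tip detection is exact).
Vertices are spaced by a sinusoidal parameter mapping that concentrates
resolution at the tips.  The three mean-shape parameters follow in closed
form from the target traditional measures: length = 2W; thickness =
2R sin φ; and the posterior angle fixes the vertical drop from the tips to
L5, giving tan(φ/2) = (W + drop)/(thickness/2).  For the default targets
(8.6 µm, 20.5 µm, 104.3°) this yields R ≈ 10.42 µm, φ ≈ 100.2°, W = 4.3 µm
— a strongly curved crescent whose valve tips hang below the posterior
suture point, as they must for a posterior angle under 180°.

### Population structure

Each simulated spore deviates from the mean along two interpretable
symmetric modes plus asymmetric and size components:

* **Mode 1 — valve bending** (score in radians): the half-angle becomes
  φ + m1 while R shrinks to preserve the centerline arc length.  Bending
  changes the posterior angle strongly but leaves centroid size nearly
  unchanged; this is what lets the population combine a large
  posterior-angle SD (≈ 23°) with a modest centroid-size CV (15 %).
* **Mode 2 — width/length** (log scale): W → W e^{m2}.  The score is
  centered by −½Var(m2) (and by the allometric covariance term) so the
  expected spore length stays at the mean-parameter value despite the
  lognormal form.
* **Size**: a lognormal factor s with unit mean; its log-SD within host is
  `size_cv`.  Host identity shifts the log-mean by a fixed standardized
  five-vector scaled by `host_size_shift_sd`.  Host effects are implemented
  as fixed patterns rather than fresh random draws: the five hosts are the
  fixed design of the emulated study, and fixed patterns make the
  between-host variance (hence the host R² of the size ANOVA) a property
  of the calibration instead of a lottery over seeds.
* **Allometry**: m2 gains `allometric_slope · CS₀ · (log s + σ²/2)`, i.e.
  larger spores are relatively longer.  Coupling to *log* size keeps the
  within-host shape dispersion identical across hosts (the size factor is
  multiplicative), so the dispersion-homogeneity check is exactly null by
  construction.
* **Host shape effects**: a second fixed standardized pattern scaled by
  `host_shape_shift_sd` shifts m2 per host (location shifts only, equal
  within-host covariance).
* **Fluctuating asymmetry**: two antisymmetric perturbation fields — an
  even polar-angle term t²·δφ/2 (one valve's arc lengthens, the other
  shortens) and an odd log-width term t·δw/2 (one valve wider).  Scores are
  normalized through the finite-difference landmark sensitivities so that
  `asymmetry_sd` is the RMS landmark displacement in µm; the variance is
  split ≈ 65/35 between the two fields.  Because the fields are
  antisymmetric, the symmetric component of each spore remains the
  unperturbed shape to first order.
* **Directional asymmetry**: a constant offset along the angle-type
  asymmetric field (`directional_asymmetry`, µm).  This term is essential
  to the calibration: a constant left/right bias adds to the asymmetric
  sum of squares of the symmetry decomposition but, being a mean shift,
  adds nothing to the centered PCA variance.  Without it a population
  whose PC1+PC2 carry ~83 % of the variance could never show a symmetric
  component as low as ~78 % — the symmetric share would always be at least
  the PC1+PC2 share.  Biologically it emulates consistent valve bias
  (true directional asymmetry is known in ceratomyxids) and/or a
  digitizer's systematic left/right tendency.
* **Digitization**: each replicate adds i.i.d. N(0, `digitization_sd`²)
  noise (default 0.05 µm ≈ one pixel at 100×) to every landmark
  coordinate.
* **Pose**: each specimen receives a random rotation and translation, as
  photographed spores would; superimposition has real work to do.

All randomness derives from one root seed through named substreams
(sizes, modes, hosts, asymmetry, digitization, pose), so stages can be
toggled without reshuffling the others.  Draws yielding non-simple
outlines are redrawn (at most 100 times per specimen, counted and
reported); at the default calibration this affects ≲ 1 spore per cohort.

### Default calibration

The frozen defaults were obtained by a two-stage numeric calibration run
before the pipeline was finalized: per-source variance probes (each noise
source switched on alone in a large cohort) gave the linear-response
coefficients, a closed-form solve distributed the tangent-space variance
budget, and a damped fixed-point refinement over multi-seed batches of
535-spore cohorts polished the values.  The calibration targets were the
emulated study's printed statistics: mean length 8.6 µm, thickness
20.5 µm, posterior angle 104.3° (SD anchored at 22.8°), centroid-size CV
15.2 % with host identity explaining ≈ 25 % of size variation, PC1 ≈ 64 %,
PC1+PC2 ≈ 83 %, symmetric component ≈ 78 %, repeatability > 0.99 and
measurement error < 1 % over two replicates, and the ANCOVA significance
pattern (size and host significant, interaction not, with the size : host
R² proportion near 2 : 1).  Verification over 30 fresh cohorts of 107
spores gives means within a fraction of a replicate-SD of every target.

The width-mode variance is split ½ allometric, ⅓ host, ⅙ residual; the
host share was set so the ANCOVA host term is reliably significant at the
levels the emulated study reports while keeping the size : host R²
proportion.

## Superimposition

Generalized Procrustes analysis: center, scale to unit centroid size,
rotate each configuration onto the running consensus by the closed-form
2-D optimal rotation (reflections excluded — valve identity is
biologically meaningful and reflection is handled explicitly by the
symmetry module), re-estimate the consensus, and iterate to an RMS
consensus change below 1e−10 (maximum 100 iterations; non-convergence is
flagged, never silent).  Full-Procrustes scaling is used throughout (unit
centroid size, no cos ρ re-scaling).  The final frame aligns the consensus
principal axes with the coordinate axes, with signs fixed so the anterior
suture landmark has positive y — a deterministic frame for reproducible
plots.

Tangent coordinates are the orthogonal projection of the aligned
configurations onto the hyperplane orthogonal to the consensus (the
consensus maps to the zero vector).  The tangent-space adequacy check
regresses, over all specimen pairs, the tangent Euclidean distance on the
Procrustes geodesic distance through the origin and reports the slope and
uncentered correlation; at the default calibration the correlation exceeds
0.9999.  Note that with shape variation this large the *total* tangent SS
sits ≈ 1 % below the summed squared Procrustes distances (the cos²(ρ/2)
curvature correction); the two agree to first order, which the tests
verify in the small-variation limit.

## Symmetry decomposition

Object symmetry: each configuration and its reflected-relabelled copy
(x negated, paired landmarks swapped) enter one joint GPA of 2m
configurations.  The symmetric component of specimen i is the mean of its
two aligned copies; the asymmetric component is the remainder.  Because
orig = sym + asym and mirror = sym − asym in tangent coordinates, the sum
of squares about the joint consensus splits *exactly* (machine precision)
into symmetric and asymmetric parts; the percentages reported are shares
of that total.  With two digitization replicates, replicates are averaged
per specimen before the decomposition; the replicate-resolved partition
used for measurement error lives in the QC module.  (Whether the emulated
study averaged replicates before its 78.1/21.9 split is not stated; the
averaged variant is the default here.)

## Quality control

All m·r replicate configurations are superimposed in one joint GPA so that
replicate placements are compared in a common frame.  Repeatability is the
one-way random-effects ICC per tangent coordinate (specimen as group,
s²_among = (MS_among − MS_within)/r truncated at zero), averaged over the
16 coordinates.  Percent measurement error pools the 16 coordinates into
one Procrustes ANOVA and reports the within-specimen variance component as
a share of the total.  Both agree in ordering across digitization-noise
levels (tested on a grid).

Outlier screening orders specimens by Procrustes distance from the
consensus.  Two rules ship: the default Tukey fence (d > Q3 + 1.5 IQR) and
a literal above-the-upper-quartile rule that flags ~25 % of any sample.
The literal rule cannot be the intended screening procedure — it would
discard a quarter of every dataset — but is retained behind a flag for
comparison.  On default cohorts the fence flags 0–3 of 107 spores; the
Procrustes-distance distribution is right-skewed, so occasional flags in a
homogeneous cohort are expected.

## Morphospace

Covariance PCA of the tangent coordinates (SVD of the centered matrix),
with a deterministic sign convention (largest-magnitude loading positive).
PC retention uses the eigenvalue-ratio rule: the leading run of PCs with
λ_i ≥ 1.32·λ_{i+1}; the last eigenvalue, having no successor, is never
counted.  On synthetic cohorts the rule typically keeps 5–6 PCs: the
spectrum's tail decays faster than real digitizing noise would make it, so
the retained count runs one above the value the rule gives on real data
with the same leading shares.  Landmark contributions to a PC are the per-
landmark sums of squared x/y loadings as percentages; landmarks above
12.5 % (= 100/8) contribute more than average.  On default cohorts PC1 is
dominated by L7, L3, L1 (the posterior-angle landmarks) and PC2 by L5, L4,
L6 (the length landmarks) — the calibrated modes are recovered.

Extreme shapes along a PC are consensus + (min/max observed score) ×
loading vector.  Deformation grids use the exact interpolating thin-plate
spline with kernel U(r) = r² log r² (0 at r = 0) plus an affine part; the
bending energy (quadratic form of the non-affine coefficients) is
reported, and an affine source→target map has zero bending energy exactly.
Convex hulls per host group come from Qhull, degenerate (< 3 points or
collinear) groups flagged rather than failed.

## RRPP inference

Linear models on the symmetric tangent coordinates (or on centroid size)
are fitted by sequential (type I) sums of squares: SS of term k is the
drop in residual trace between the nested models with terms 1..k−1 and
1..k, computed via orthonormal bases (SVD) of the growing design;
pseudo-F uses the full-model residual mean square.  Aliased terms are
reported by name.  The covariate is raw centroid size (a log option
exists); the shape response is the symmetric component.

Residual randomization: for each term, the reduced model holds the
preceding terms; its residuals are permuted across specimens (one shared
permutation per iteration across all terms), added back to the reduced
fit, and the term's pseudo-F recomputed.  Because the reduced fit lies in
the column space of every larger model, the permuted statistics reduce to
projections of the permuted residuals, which is what the implementation
computes (vectorized over permutation batches).  The observed arrangement
counts as one iteration, so p ≥ 1/n_perm always.  The effect size Z
standardizes log F_obs within the permuted log F distribution (log
transform chosen to tame the right skew of F; the convention is stated
because Z has no universal definition).  Defaults: 10,000 iterations.

The dispersion-homogeneity check computes each specimen's distance to its
group centroid in tangent space, takes the one-way ANOVA F over these
distances, and permutes group labels (centroids and distances recomputed
per permutation).  Both tests hold their nominal 5 % level within
[0.035, 0.065] over 1,000 null simulations, and the RRPP p agrees with
full enumeration of row permutations at m ≤ 7.

## What the synthetic data do and do not show

The generator reproduces the *statistical structure* of a real digitized
cohort — the variance budget across modes, hosts, size, asymmetry and
digitization noise, and the moments of the traditional measures.  It does
not emulate photographic artefacts (focus, contour extraction error),
polar capsules or sporoplasm (deliberately excluded from the landmark
scheme), imaging error from re-mounting (unmeasurable even in the real
protocol), non-Gaussian digitizing blunders, or within-host clonal
substructure.  Passing round-trip tests therefore demonstrates that the
pipeline recovers known structure of the assumed kind, not that the
biological conclusions would survive artefacts outside the model.  Two
intentional simplifications matter when comparing to printed values: the
absolute centroid-size scale (≈ 27 µm mean here, implied ≈ 23 by the
printed size range) follows from the tip-chord thickness convention, and
the eigenvalue tail (hence the retained-PC count) is cleaner than real
data would give.

## Problem sizes

Cohort-level statistics are means over replicate 107-spore cohorts (12 in
the test suite, 24 in the acceptance script) — averaging replicate
simulations is the natural estimator for a stochastic study condition, and
the replicate SD is what the test tolerances are derived from.  The
traditional-measure means use one ~5,000-spore cohort.  Null error rates
use 1,000 simulations at 199 permutations; parameter recovery uses 100
cohorts at 299 permutations.
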