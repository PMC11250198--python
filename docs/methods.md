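# Methods

## Problem and scope

After resection of a cerebellar tumour, roughly one in five paediatric
patients develops cerebellar mutism syndrome (CMS): post-surgical mutism or
severely reduced speech with emotional lability.  The anatomical hypothesis
this package operationalizes is that CMS risk is driven by damage to the
*cerebellar outflow pathway* — the efferent route from the deep cerebellar
nuclei through the superior cerebellar peduncles (SCP) toward the thalamus.
The package scores binary lesion masks (resection cavities registered to a
common 1 mm template grid) against that pathway and against a continuous
lesion-symptom weight map, compares the scores between CMS+ and CMS−
groups, builds the standard descriptive lesion maps, and fits a simplified
sparse canonical-correlation lesion-symptom map.  Registration itself
(nonlinear warps, cost-function masking, cerebellum isolation) is out of
scope: every input must already live on one common grid, and nothing is
resampled silently.

## Outflow-pathway lesion load

The pathway ROI is cut into oblique coronal slices perpendicular to the
SCPs: a voxel with world coordinate (x, y, z) belongs to slice
`floor(u / t)` with

    u = y·cos θ − s·z·sin θ,       θ = 17°, t = 1 mm by default,

where `s = ±1` selects which way the slice normal tips (the direction is
not uniquely determined by "perpendicular to the peduncles"; the default
tips anterior–posterior toward superior, and the sign is configurable
because the statistic is invariant to it for ROIs symmetric about the slab
axis).  Voxels are assigned by their centre coordinate to half-open
intervals `[k·t, (k+1)·t)` anchored at u = 0, which makes the assignment a
deterministic partition — the test suite verifies it against a per-voxel
brute-force enumeration on randomized small grids.

Per slice, the load is `100 · (ROI voxels intersected by the lesion) / (ROI
voxels in the slice)`; the subject's **lesion load** is the maximum over
eligible slices, so 100% means some slice of the pathway is fully
transected and 0% means the pathway is spared.  Slices with fewer than
`min_roi_voxels` ROI voxels (default 1, i.e. no filtering) can be excluded
because tiny end-slices can yield unstable 100% values; this is surfaced as
a sensitivity parameter rather than a fixed rule.  Argmax ties are broken
toward the smallest slice index.

## Weight-map lesion load

Given a continuous weight map W on [0, 1] with an attached scalar
eigenvalue γ, a lesion L scores `raw = γ · Σ_v W_v L_v`.  "Standardizing"
this quantity is ambiguous, so three normalizations are implemented and the
choice is recorded in every output row:

- `none` — the raw product;
- `weight_sum` (default) — `raw / Σ_v W_v`, bounded and independent of the
  cohort;
- `cohort_z` — z-score of raw across the analysed cohort (sample SD).

The default is the bounded, cohort-independent variant; reports always name
the variant used because the three are not interchangeable.

## Descriptive maps

`overlap_count` is the voxelwise sum of masks; group proportion maps divide
by group size; `proportional_subtraction` is the plain difference
p⁺ − p⁻ of group lesion proportions (values in [−1, 1]).  Peak localization
reports the world-coordinate maximum with an explicit tie count and a
deterministic canonical voxel (lexicographically smallest index) instead of
silently dropping ties.  A lesion "crosses the midline" when it has voxels
strictly on both sides of world x = 0 outside a half-voxel exclusion band,
so exactly-midline voxels never count as bilateral.

## Group statistics

Welch's unequal-variance t-test is used for all two-group comparisons, with
Satterthwaite degrees of freedom reported both exactly and floored
(published tables print the floor).  The two primary hypotheses — higher
outflow-pathway load and higher weight-map load in CMS+ — are one-tailed at
α = 0.05; age and lesion-volume comparisons are two-sided.  Both Cohen's d
conventions are computed (pooled-SD, and `d = t·√(1/n₁+1/n₂)` from the t
statistic) because published effect sizes mix the two and neither can be
recovered unambiguously from rounded summary tables.  The site comparison
is a Pearson chi-square on the 2×2 site-by-CMS table, without Yates
correction by default (flag available).

The CMS-rate-by-load curve bins loads into [0,25), [25,50), [50,75),
[75,100] by default; empty bins are reported as empty, not as rate zero.
An `isolate_zero` flag places exactly-zero loads in their own leading bin.
It is off by default: at realistic CMS rates the expected rates of the zero
bin and the first nonzero bin differ by less than sampling noise even at
n = 2000 (sigmoid(α) vs sigmoid(α + β·0.1) with α ≈ −4.6), so the isolated
bin mostly manufactures spurious inversions in an otherwise monotone curve.

## Sparse canonical-correlation mapping

With a single binary outcome, canonical correlation between the lesion
matrix X (subjects × voxels, columns restricted to voxels lesioned in at
least `min_subjects` subjects, default `max(3, 10%)`) and y reduces to one
sparse direction w maximizing corr(Xw, y).  The solver alternates between
the outcome variate (the centred, unit-norm y — a single column, so only
its sign updates) and the voxel side `w = X_cᵀ v`, hard-thresholded to keep
the top fraction `s` of weights by magnitude with soft shrinkage at the
cut, renormalized, and iterated to `tol` or `max_iter`.  This is an
intentional simplification of multi-component SCCAN optimizers and is
documented as such, not as a reimplementation.

Sparseness is selected by repeated stratified 75/25 splits (default 4):
each candidate `s` is scored by the mean Pearson correlation between
held-out predicted scores and held-out outcomes; ties go to the sparser
model; the winner is refit on all subjects.  Reported maps follow the
0-to-1 lesion-symptom-map convention: weights are rectified to non-negative
(default; a signed map is retained for diagnostics) and normalized by their
maximum absolute value, with the retained scale — the "eigenvalue", the L2
norm of the unnormalized solution — applied at prediction time:
`scores = X · (eigenvalue · weights)`.  Fixed seed and data give
bit-identical fits.

## Synthetic cohort generator

The generator emulates the study conditions the analyses target: cohorts of
56 subjects, a marginal CMS rate of 17.9%, resection cavities with
lognormal volumes (median ~7000 mm³), a midline placement bias, and a
planted lesion-location effect with a CMS+/CMS− load difference around
d ≈ 0.7–0.9.

Geometry (fixed, 64³ grid at 1 mm, world origin mid-grid): the template is
an ellipsoid with semi-axes (29, 25, 21) mm; the outflow-pathway stand-in
is a midline slab-like tube — elliptical cross-section 24 mm (left–right)
× 6 mm, 30 mm long — whose axis runs along (0, cos 17°, −sin 17°), i.e.
perpendicular to the default slicing planes, mimicking a pathway that is
wide across the midline and thin along its course; the weight map decays as
a Gaussian of the elliptical distance from that axis.  Cavities are
axis-aligned ellipsoids with lognormal volume (μ = ln 7000, σ = 0.5), mild
random anisotropy at constant volume, centres drawn near the midline with
probability `midline_bias` (0.8; midline draws are clipped so the cavity
reaches the midline column), and clipped to the template — clipping shrinks
the realized median volume to ≈6100 mm³.

Labels come from a logistic model, `P(CMS) = sigmoid(α + β·load/100)` with
β = 4 by default.  α is calibrated by bisection so the marginal rate over a
fixed-seed calibration draw of 1500 lesion loads hits the target rate; it
is a deterministic function of the generator's scientific parameters (not
of the cohort seed), so replicate cohorts share one intercept.  The
logistic form is a simulation-harness choice — monotone and easy to
calibrate — not a claim about how real CMS risk arises.  Covariates (age,
sex, site, tumour type) are sampled to match the published cohort
composition and carry no planted effect.

The abstract planted-signal benchmark for the sparse mapper
(`planted_signal_matrix`, 80 subjects × 600 voxels, 20 signal voxels)
generates signal voxels spatially coherent through a latent per-subject
"critical-region hit" (probability 0.35; lesion probability 0.7 if hit,
0.05 if spared; background voxels i.i.d. at 0.15), because real cavities
either involve or spare a region as a unit.  With fully independent voxels
the per-voxel signal correlation (≈0.16 at n = 80) sits below the noise
floor of 580 null columns and no method could recover the support; the
latent-hit structure is both the realistic case and the one in which
support recovery is well-posed.  The outcome is
Bernoulli(sigmoid(2·z(signal count))).

### What the generator does not emulate

Real resection cavities are not ellipsoids: they follow surgical corridors,
have irregular margins, co-occur with oedema and hydrocephalus, and their
registration to a template carries error.  Sites, scanners and tracing
protocols introduce heterogeneity the generator ignores.  Passing tests on
synthetic cohorts therefore demonstrate that the *pipeline* is correct and
statistically calibrated under its stated model — not that the anatomical
effect generalizes to any particular clinical cohort.

## Numerical choices and problem sizes

Affine agreement tolerance is 1e-4 mm with exact shape match; binarization
threshold 0.5 with negatives mapped to 0; all-zero masks are allowed but
logged.  Degenerate cavities are resampled (up to 50 attempts).  Held-out
correlations on constant score vectors are defined as 0.  The test suite
and the acceptance script size their simulations to run on one CPU in a few
minutes: power and type-I error use 200 replicate cohorts of n = 200; the
rate-curve and calibration checks use one n = 2000 cohort; oracle
equivalence uses 60 randomized grids up to 20³.

## Known limitations

The sparse mapper fits a single component and a single binary outcome; it
does not reproduce any specific multi-component SCCAN implementation, its
eigenvalue convention, or published cross-validated correlations on real
cohorts.  The slicing statistic depends on the (configurable) tilt sign and
slice anchoring for asymmetric ROIs.  The weight-map "standardization" is
deliberately plural; numbers computed under different normalizations are
not comparable across reports.
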