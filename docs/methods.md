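# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and the known limitations of the package.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Diffusion signal models

All diffusivities are handled internally in mm²/s and reported in
10⁻³ mm²/s; b-values are in s/mm².  The default acquisition is three
shells at b = 1000/2000/3000 s/mm² with 60 near-uniform directions each
(spherical Fibonacci, with a per-shell azimuthal offset) plus five b = 0
measurements.  The 60/60/60 split across shells is a package choice; any
near-uniform scheme works and the scheme is stored alongside outputs in
FSL bval/bvec dialect.

**DTI** is fitted by ordinary least squares on log-signals using only the
b ≤ 1000 shell plus b = 0 — at stronger weighting the single-tensor model
is contaminated by non-Gaussian effects.  Negative eigenvalues (possible
under noise) are clamped to zero and flagged.  The derived metrics satisfy
MD = (AD + 2·RD)/3 exactly by construction.

**Spherical-mean models.**  The per-shell, direction-averaged normalized
signal ε(b) of an axially symmetric compartment has the closed form
`exp(−bλ⊥)·√π·erf(√x)/(2√x)` with x = b(λ∥−λ⊥); the factor is evaluated by
a Taylor series for x < 1e−8 so the isotropic limit is continuous.  The
single micro-tensor fit estimates (λ∥, λ⊥); the two-compartment (MC-SMT)
fit estimates (f_in, λ_diff) with the extra-neurite zeppelin tied by the
tortuosity approximation λ⊥ = (1−f_in)·λ_diff.  v_AD and v_MD are derived
identities, exact at the solution.  The governing equations are fixed here
as the normative model of this package (the descriptive literature the
analysis follows does not print them).

Fitting is bounded least squares (`scipy.optimize.least_squares`) on a box
with λ_free = 3.0×10⁻³ mm²/s, chosen as the free-water ceiling that the
reference data visibly pile up against (which is also why µAD/AD are
screened out before clustering).  A coarse grid multi-start (16 starts)
guards against local minima; ties are broken by lowest residual, then
lowest f_in.  λ⊥ is parametrized as a fraction of λ∥ so the ordering
constraint is built into the box.  Convergence tolerances are 1e−12 on
cost, gradient and step; noise-free round trips recover parameters to
better than 1e−6 relative error (tested).

**Rician noise.**  Magnitude noise is simulated as
`sqrt((S+ε₁)² + ε₂²)`, ε ~ N(0, σ²).  At low SNR the noise floor inflates
the high-b shell means and biases f_in upward.  `spherical_mean` accepts a
known noise level and applies the second-moment debiasing
`S² ≈ M² − 2σ²` per measurement; with it, the regression suite holds the
median |f_in| error at SNR 20 below 0.05 over 500 simulated voxels.
Estimating σ from data is out of scope.

## Lesion topography

Lesions are connected components (26-connectivity, configurable to 6) of a
binary mask on a voxel grid shared with the region atlas — no resampling
happens inside the package.  Location rules are applied in a fixed
precedence order with strict inequalities: periventricular if > 5 % of the
lesion volume is in *contact* with the lateral ventricles, else
juxtacortical if > 20 % overlaps cortex, else infratentorial if > 50 %
lies in brainstem + cerebellum jointly (sub-labelled by the larger share),
else deep white matter.  Contact is operationalized as lesion voxels
within a one-voxel 26-neighborhood dilation of the ventricle mask, because
periventricular lesions abut CSF rather than overlap it; cortex and
infratentorial overlaps are plain mask intersections.  The precedence
order resolves multi-qualifying lesions (the rule list itself does not);
the joint reading of the brainstem/cerebellum criterion is a package
decision.  Components smaller than 27 mm³ are excluded; a 27 mm³ component
is retained.  Per-lesion features are voxel means of the metric maps.

## Lesion typing

Features are z-scored before clustering because the metrics span different
scales (FA unitless, diffusivities in 10⁻³ mm²/s).  k-means uses a small
vectorized Lloyd implementation with k-means++ seeding and 10 restarts;
it accepts counter-derived child generators, which keeps the 500-split
replication loop and its permutation null reproducible and fast.  Its
partitions are cross-checked against scikit-learn's KMeans in the test
suite.  k is fixed at 2 (the two-type scenario); other k values run but
are untested.

Prediction strength follows the worst-case pair-agreement definition:
test-half clusters of size ≤ 1 contribute 1 (no pairs to violate), and
each split is symmetrized by averaging both train/test role assignments.
Per-location values are computed from the pooled half-clusterings by
restricting the pair counting to stratum members ("pooled" mode); running
the whole procedure inside one stratum is available by subsetting rows.

The permutation null shuffles each feature column independently across
lesions.  Shuffling whole rows would be a no-op (clustering is row-order
invariant), so the column-wise reading — which destroys multivariate
structure while preserving marginals — is adopted as normative.  The
p-value uses the add-one estimator and is bounded below by 1/(n_perms+1).

Metric screening discards features with more than 30 % of values at their
fit ceiling (the µAD/AD failure mode) or with a coefficient of variation
below 0.01 (constants), and reports ceiling fractions plus the feature
correlation matrix.  Feature-set selection scores candidate subsets
(default: all subsets of size 3–5 of the retained metrics) and accepts a
set only if its averaged prediction strength exceeds 0.8 overall and in
every evaluated stratum; passing sets are ranked by overall value, ties
to the smaller set.  The B/A label convention (B = lower f_in centroid,
lower FA as tie-break) makes labels comparable across runs.

## Clinical inference

Freedman–Lane: fit the nuisance-only model y ~ [1, age, sex], permute its
residuals, add them back to the nuisance fit, refit the full model and
collect the t-statistic of the burden predictor; two-sided add-one
p-value.  The permutation refits are vectorized over all permutations
(one pseudoinverse, matrix of permuted outcomes), which is what makes the
1,000-simulation type-I calibration test affordable.  Exact fits are
handled explicitly: zero residual variance with a non-negligible predictor
coefficient gives |t| = ∞, with a negligible one t = 0 — so a constant
outcome yields p = 1 and a noiseless strong effect yields the minimum
attainable p.  With many permutations the p-value agrees with the
classical t-test on Gaussian data (tested at 10,000 permutations within
0.01).

For binary outcomes no additive residual decomposition exists, so the
package adopts predictor-residual permutation as the Freedman–Lane
analogue: residualize the predictor on the nuisance design, permute those
residuals, refit the logistic model, and compare likelihood-ratio
statistics.  The logistic solver is a ridge-stabilized Newton/IRLS with
step halving (checked against statsmodels' Logit); possible separation is
flagged on the result rather than raised, since the permutation p-value
remains valid.  Missing values are dropped casewise per test with counts
recorded.  Bonferroni correction takes the family size as an explicit
argument — it is analysis-dependent and never inferred from the input.

## Synthetic study conditions

The generator defaults encode the reference study: 59 patients; Poisson
lesion counts per location with rates (357, 343, 44, 60, 432)/59 for
periventricular, juxtacortical, brainstem, cerebellum and deep white
matter (≈1236 lesions in expectation); latent B-type probabilities per
location (0.54, 0.60, 0.50, 0.53, 0.46; 0.52 pooled); pooled per-metric
means/SDs equal to the reference whole-brain lesion row; and between-type
differences (B−A) of −0.15 (FA), +0.17 (RD), −0.12 (µFA), −0.20 (f_in),
zero for the other metrics.  Within-type SDs come from the variance
decomposition `var_within = var_pooled − p(1−p)Δ²` (an error if negative —
which is why whole-brain moments, not the per-location rows, drive the
feature model: some per-location SD/Δ combinations printed in the
reference tables are mutually inconsistent).  Draws are independent
Gaussians per type, clipped to physical bounds ([0,1] for FA/µFA/f_in,
[0, 3.0] for diffusivities); an optional correlation matrix and an
optional per-patient random intercept (default off — no published
magnitude exists) are provided.  Clipping reproduces the µAD ceiling
pile-up that screening must catch, at the cost of slightly distorting the
moments of boundary-hugging metrics (µAD, µRD); the moment-fidelity test
therefore covers the metrics whose bounds are far from the bulk of the
mass.

Lesion volumes are lognormal (σ_log = 1) with type means 400 mm³ (A) and
656 mm³ (B): the 1.64 ratio converts the 52 % B count share into a ≈64 %
B volume share, and the pooled mean of ≈0.54 cm³ gives ≈11.4 cm³ total
lesion volume per patient — all matching the reference cohort.  Clinical
outcomes are linear in the true B-type count with age/sex nuisance and
Gaussian noise scaled to give moderate-to-strong burden correlations; the
binary therapy outcome uses a logistic link with intercept logit(0.23)
on the centered burden so its prevalence matches the reference 23 %.

What the generator does **not** emulate: real lesion morphology and
spatial structure, registration artifacts, partial volume, within-patient
feature correlation of unknown size, non-Gaussian feature distributions,
and the coupling between metric identities (per-lesion FA/MD/RD/AD draws
are statistically faithful to the table moments but are not derived from
one underlying tensor).  Consequently, passing tests demonstrate the
correctness and calibration of the *procedures* under the stated
conditions — not that real MS lesions form two Gaussian clusters.  On this
idealized mixture the averaged prediction strength (~0.99) naturally
exceeds the value observed on real data; the acceptance check is the 0.8
replication threshold, not a point match.

Phantom label volumes place box lesions against simple geometric region
masks so that overlap/contact fractions are exact by construction
(e.g. a 16-deep box abutting the ventricle face has contact fraction
1/16 = 6.25 %), with sub-threshold (< 27 mm³) lesions flagged in the
ground truth.

## Problem sizes

The default test and acceptance runs use 1,000-lesion cohorts with 500
splits for replication, 200 repetitions × 19 permutations for null
calibration, 1,000 simulations × 199 permutations for type-I calibration,
and 500 voxels for the noise regression — sizes chosen so the full suite
completes in a couple of minutes on one CPU while keeping Monte-Carlo
error well inside the asserted tolerances.

## Known limitations

- No kurtosis/non-monoexponential modelling; the MC-SMT model cannot
  separate exchange or dispersion effects.
- No preprocessing (motion/eddy/susceptibility correction, registration);
  inputs must share a voxel grid.
- The logistic permutation scheme is an analogue, not a derivation; a Wald
  fallback is deliberately not the default.
- Noise-level estimation for the Rician debiasing is the caller's
  responsibility.
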