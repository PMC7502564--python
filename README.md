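# mslesions

Quantitative diffusion-MRI characterization and data-driven typing of
multiple sclerosis (MS) white-matter lesions.

MS plaques are pathologically heterogeneous: demyelination, axonal loss and
repair vary from lesion to lesion, and conventional MRI sees little of it.
This package implements an analysis pipeline that (i) quantifies each
lesion with macroscopic diffusion-tensor metrics and microscopic
spherical-mean-technique metrics, (ii) classifies lesion topography with
rule-based location criteria, (iii) splits lesions into two severity types
(A/B) by k-means clustering that is accepted only when it *replicates* —
measured by the prediction strength over repeated random half-splits, with
a permutation null — and (iv) tests whether a patient's B-type lesion
burden is associated with disability and cognition using covariate-adjusted
permutation inference.  Because clinical MRI data of this kind are not
openly deposited, the package ships first-class synthetic generators that
emulate the study conditions with known ground truth, so every stage is
testable end to end.

It is aimed at neuroimaging methodologists and MS researchers who want a
tested, reusable implementation of these procedures for their own data or
for simulation studies.

## Models and statistics

**DTI.** The low-b shell (b ≤ 1000 s/mm², plus b = 0) is fitted by
log-linear least squares to `S = S0·exp(−b gᵀDg)`; the eigenvalues
λ₁ ≥ λ₂ ≥ λ₃ of `D` give FA, MD = (λ₁+λ₂+λ₃)/3, AD = λ₁, RD = (λ₂+λ₃)/2.

**Spherical-mean microstructure.** The per-shell direction average ε(b) of
the normalized signal is orientation-free.  A single axially symmetric
micro-tensor gives the microscopic coefficients (µAD = λ∥, µRD = λ⊥, µMD,
µFA) through

    ε(b; λ∥, λ⊥) = exp(−b λ⊥) · √π · erf(√(b(λ∥−λ⊥))) / (2√(b(λ∥−λ⊥))),

and the two-compartment extension (MC-SMT) models intra-neurite sticks plus
a tortuosity-constrained extra-neurite zeppelin sharing one intrinsic
diffusivity:

    ε(b) = f_in·ε_stick(b; λ_diff) + (1−f_in)·ε_zeppelin(b; λ_diff, (1−f_in)λ_diff),

yielding f_in, λ_diff and the derived v_AD = (1−f_in)·λ_diff,
v_MD = (λ_diff + 2 v_AD)/3.  All fits are bounded multi-start least squares
with λ ≤ 3.0×10⁻³ mm²/s (free water).

**Lesion typing.** Features are z-scored and clustered with k-means (k=2).
For a random half-split into halves D₁, D₂, the prediction strength is

    ps = min_j  (1 / n_j(n_j−1)) · Σ_{i≠i′ ∈ cluster j of D₂} 1[C(D₁) co-assigns i, i′],

i.e. the worst-case fraction of test-half within-cluster pairs kept
together by the training-half centroids; it is averaged over both role
assignments and 500 random splits.  A feature set is accepted when the
averaged prediction strength exceeds 0.8 in every lesion-location stratum;
significance comes from a null built by independently shuffling each
feature column.  B-type is the cluster with the lower f_in centroid (more
severe damage: lower FA, µFA, f_in; higher RD).

**Clinical associations.** Linear models `outcome ~ burden + age + sex` are
tested with the Freedman–Lane permutation procedure (permute nuisance-model
residuals, refit, collect the predictor t-statistic); binary outcomes use a
logistic likelihood-ratio statistic with predictor-residual permutation.
Families of tests are Bonferroni-controlled with an explicit family size.

## Worked example

```python
from mslesions import synthetic, clustering

cfg = synthetic.CohortConfig(seed=42)          # defaults = study conditions
patients, lesions, truth = synthetic.gen_cohort(cfg)
feats = ["FA", "RD", "uFA", "f_in"]
model = clustering.kmeans2(lesions[feats], seed=0)
lesions["type"] = clustering.assign_types(lesions[feats], model)
ps = clustering.prediction_strength(lesions[feats], n_splits=500, seed=1,
                                    strata=lesions["location"])
```

Output for this run:

```
59 patients, 1255 lesions
mean prediction strength: 0.993
  periventricular: 0.997
  juxtacortical: 0.986
  cerebellum: 1.000
  deep_wm: 0.992
  brainstem: 0.997
B-type share: 53% of lesions, 63% of lesion volume
```

The cohort size and per-location lesion rates reproduce the reference
cohort (59 patients, ≈1236 lesions in expectation); the prediction strength
is far above the 0.8 replication threshold because the generated two-type
mixture is exactly Gaussian; and the B-type count/volume shares land near
the configured 52% / 64%.  The same analysis is available from the shell:

```
mslesions simulate cohort --seed 42 --out sim/
mslesions cluster --features sim/lesions.tsv --splits 500 --seed 1 --out typed/
mslesions associate --patients sim/patients.tsv --burden typed/burden.tsv \
    --predictor count --perms 5000 --seed 2 --out associations.tsv
mslesions run-all --config analysis.yaml    # everything in one step
```

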