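# Methods

## Dose model

Physical dose grids are converted to EQD2 per voxel under the
linear-quadratic model, `EQD2 = D·(d + α/β)/(2 + α/β)`, with the voxel's
fraction dose taken as `d_v = D_v / n_fractions` for a uniform fraction
count over the course. This is the natural reading for simultaneous
integrated-boost IMRT, where every voxel is irradiated in every fraction at
a voxel-specific dose; non-uniform per-voxel fractionation schedules are out
of scope. The default α/β is 3 Gy (late-reacting thyroid tissue); it is a
parameter everywhere it appears. At exactly 2 Gy/fraction the conversion is
the identity for any α/β, which the tests exploit as an exact oracle.

Dose-volume metrics are computed on the raw masked voxel values, never from
the binned DVH, so Dmin/Dmax/Dmean carry no binning bias. Vx uses the
inclusive convention (dose ≥ x Gy); on a continuous dose distribution the
difference from a strict inequality has measure zero, and the inclusive form
matches the usual cumulative-DVH definition (first bin = 100%). The DVH bin
width defaults to 0.1 Gy and only affects the exported curve. The
"fractionated dose" summary is defined as the mean *physical* structure
dose divided by the fraction count; it cannot be recovered from an
EQD2-converted grid, so for such grids it is reported only when the
physical mean is supplied. Masks must already be sampled on the dose
lattice (no contour resampling); voxel indices are 0-based and physical
coordinates refer to voxel centers.

## Logistic engine

The binary-outcome fits use an in-house Newton–Raphson (IRLS) maximiser of
the logistic likelihood: convergence when the log-likelihood changes by
less than 1e-8, at most 100 iterations, with step-halving so the likelihood
is non-decreasing. Wald standard errors come from the inverse information
matrix at the optimum. Complete or quasi-complete separation is detected by
coefficient divergence (|β| > 15) or a singular information matrix and
raised as an explicit error rather than returned as a spurious fit; a
non-converged fit is flagged, never silently reported as converged. The
engine is cross-checked in the test suite against statsmodels' `Logit` and
against a coarse-to-fine grid search of the likelihood on one-covariate
problems (agreement to 4 decimals).

## Selection pipeline

1. **Univariate screening** fits each candidate factor alone and reports
   the per-unit odds ratio, 95% Wald CI, and Wald p. Per-factor failures
   (constant column, separation) are recorded and do not abort the screen.
2. **Collinearity clustering** links two factors when their Spearman |ρ|
   exceeds 0.8 (midranks for ties, via scipy); connected components of this
   graph are clusters, and each cluster is represented by its member with
   the smallest univariate p (ties broken by larger |Wald z|). Singletons
   represent themselves. An undefined correlation (constant vector)
   contributes no edge and emits a warning.
3. **Forward selection** starts from the intercept-only model and adds, at
   each step, the candidate with the smallest likelihood-ratio p-value
   against the current model, while that p is below `p_enter = 0.05`. The
   likelihood-ratio criterion was chosen over Wald entry as the more robust
   of the standard variants. If no candidate enters, the intercept-only
   model is returned with an empty trace. Stage variables are treated as
   ordinal scores (T1–T4 → 1–4).

No multiple-testing correction is applied at any stage: the pipeline
reproduces a conventional clinical modelling workflow, and users should
treat the univariate p-values accordingly.

The full pipeline (`run_pipeline`) clusters the univariately significant
factors and forwards their representatives. The exported NTCP equation is
always the two-covariate dose/volume logistic model — that is the model
family this package implements — and a warning is emitted when the
forward-selected set differs, which happens regularly at small sample
sizes where collinear proxies of Dmean can win the univariate race.

## NTCP model

`NTCPModel` holds the intercept, the per-Gy log-odds of mean thyroid EQD2
dose, and the per-cc log-odds of thyroid volume; the published coefficients
(−1.385, 0.093, −0.188) ship as the packaged default. NTCP = (1+e^(−S))^(−1)
is used throughout: with the published signs this is the only orientation
under which risk increases with dose (odds ratio > 1/Gy) and the
volume-stratified curves are increasing. Tolerance doses invert the
logistic in closed form and round-trip through the forward evaluation to
better than 1e-12; a negative tolerance dose (small gland, low target risk)
is returned with an extrapolation warning. Evaluation outside the dose
range 10.31–51.46 Gy or volume range 8.19–42.00 cc — the region the
published model was fitted on — warns but returns values, since the curve
family is routinely drawn across the full dose axis.

Calibration uses the Hosmer–Lemeshow deciles-of-risk test: equal-count
groups by predicted probability (ties kept together; fewer distinct values
reduce the group count with a warning, and fewer than 3 groups is an
error), χ² = Σ (O−E)²/(E(1−E/n_g)), df = groups − 2. The df correction
presumes the predictions come from a model fitted to the same data; the
package therefore applies the test to fitted probabilities. Applying it to
externally fixed probabilities makes the statistic approximately χ² with
*g* degrees of freedom and the test anti-conservative.

## Synthetic cohorts

The generator draws thyroid volume from a truncated normal
(16.60 ± 6.38 cc on [8.19, 42.00]) and mean EQD2 dose from a truncated
normal (41.79 ± 11.02 Gy on [10.31, 51.46]); truncation (rather than
clipping) makes the stated ranges hard bounds, treating them as data
extremes. Dose and volume are drawn independently — their joint
distribution in the study population is unknown, and independence is the
neutral default. Outcomes are Bernoulli under the configured true model
(published coefficients by default); over the default covariate
distribution the mean true risk is ≈ 0.29, consistent with the ~35%
12-month incidence the model was built on once truncation shifts the mean
dose down to ≈ 38 Gy.

The collinear dose-metric cluster is constructed, not assumed: each
patient's cumulative DVH is a logistic curve in dose with latent midpoint
D50 = Dmean + N(0, σ) and width ≈ 12 ± 1.5 Gy, from which V20–V50 are read
off (plus N(0, σ) jitter in percentage points, re-sorted to keep the
per-patient curve monotone); Dmin = Dmean − 20.45 + N(0, σ), clipped to
[0.05, Dmean]. With the default σ = 2.5 every pairwise Spearman |ρ| within
{Dmean, Dmin, V20–V50} exceeds 0.8. Dmax, V10, V60, V70, the fractionated
dose, age (uniform 11–64), gender (16/69 female), chemotherapy (58/69) and
the stage variables are drawn independently at the study's frequencies,
with V10/V60/V70 clipped against their neighbours so each patient's Vx
remains monotone in x. The fractionated dose is an independent truncated
normal (1.37 ± 0.35 Gy on [0.34, 1.83]) rather than Dmean/n: in the study
population it was neither prognostic nor part of the collinear cluster,
and a deterministic Dmean/n would wrongly tie it to Dmean with ρ = 1.

What the generator does **not** emulate: any dependence between dose and
volume, realistic 3-D dose texture (phantom fields are uniform, linear, or
two-level), longitudinal hormone trajectories, censoring or missingness.
Passing tests therefore demonstrate correctness of the *methods* under the
stated distributional structure, not performance on arbitrary clinical
data.

`recovery_experiment` is the Monte-Carlo harness: per replicate it refits
the generating model (bias and 95% CI coverage per coefficient) and
optionally runs clustering plus forward selection over the representative
candidate set {age, Dmean, volume}, reporting how often exactly
{Dmean, volume} is selected and how often {Dmean, Dmin, V20–V50} form one
cluster. Replicate seeds are spawned from a single `SeedSequence`, so the
experiment is reproducible and no global random state is touched.

## Problem sizes and numerical choices

The Monte-Carlo checks use 200 replicates of n = 2000 for coverage/bias,
100 replicates for cluster/selection frequencies, and 500 replicates of
n = 500 for the Hosmer–Lemeshow type-I error — sizes at which the binomial
Monte-Carlo error is comfortably inside the asserted bands while the whole
suite runs in well under a minute on one core. Brute-force oracle
comparisons use random grids up to 12³ voxels, where exhaustive per-voxel
enumeration is exact and fast: Vx values and DVH ordinates are asserted
bit-identical (pure counting), means to 1e-12 relative (summation order).

## Known limitations

- The final NTCP equation form is fixed at dose + volume; the pipeline
  reports, but does not refit around, a differing forward-selected set.
- Wald inference throughout (no profile-likelihood or Firth correction);
  at n ≈ 69 with ~35% incidence, Wald CIs for the volume coefficient are
  noticeably asymmetric on the OR scale but adequate, as the coverage
  experiments confirm at larger n.
- The DICOM-RT reader is a convenience adapter for RT Dose grids only;
  structure-set rasterisation and contour resampling are out of scope.
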