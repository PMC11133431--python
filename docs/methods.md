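# Methods

This note records the models, conventions, parameter choices and known
limitations behind `parcelcorr`, in the order the pipeline runs.

## Parcellations and maps

A parcellation is an ordered list of parcels, each with a hemisphere
label and a unit-vector centroid on the sphere (RAS axes: +x right, so
the sagittal plane is x = 0). Parcel maps carry one real value per
parcel plus an explicit missing mask; missing parcels are dropped from
whatever statistic touches them, never imputed. Single-hemisphere
parcellations are first-class, because expression atlases are often
left-hemisphere only, and sparse coverage (e.g. an 11-region
developmental atlas) is handled by the same masking path.

The bundled `dkt62_centroids_synthetic.tsv` uses the 62
Desikan–Killiany–Tourville parcel names with **synthetic** centroid
coordinates from the package's own hemisphere-spiral construction; it
is a geometric stand-in, not FreeSurfer fsaverage geometry.

## Obesity maps

Cohort inclusion removes subjects with BMI < 10 or > 50 kg/m² (skipped,
with a logged notice, when the BMI column is a precomputed standardized
score — standard-deviation-score conversion itself needs external
growth-chart tables and is out of scope). Each parcel is fitted by OLS
with an intercept, the BMI term, and a shared covariate roster; sex and
site enter as indicator terms, age/education/SES/scan-date as numeric
columns (the linear-numeric treatment of ordinal covariates is a
documented choice). Single-level factors are dropped with a notice;
rank-deficient designs raise an error naming the collinear terms; a
parcel whose fit fails is masked rather than aborting the map. The
t-map, betas, two-sided p and BH q across parcels are returned
together. The t-map is invariant to affine rescaling of covariates
(tested), and maps fitted with and without an inert SES covariate
correlate > 0.99 (the robustness check the analysis design calls for).

## Spin permutation nulls

Rotations are sampled uniformly over SO(3) by QR-orthonormalizing a
standard-normal 3×3 matrix, fixing signs by the R diagonal, and
flipping one column when the determinant is −1. The left hemisphere
receives R, the right its sagittal mirror M R M with M = diag(−1,1,1),
preserving contralateral structure. Each target parcel takes the value
of the source parcel whose rotated centroid is nearest by great-circle
distance; exact ties break to the lowest source index, and duplicate
assignments are allowed (the centroid nearest-neighbour variant; a
bijective reassignment is deliberately not implemented). Empirical
p-values use the +1-corrected formula, so p ∈ [1/(n_perm+1), 1] and is
never zero. The observed correlation is computed through the same code
path as the nulls so exact ties (an identity assignment) count as
exceedances. Which side is spun is configurable; by default the target
(phenotype) map is spun and annotations held fixed.

**Known limitation — mild anticonservativeness.** Value reassignment
by nearest rotated centroid quantizes the rotation at parcel scale,
which makes spun maps slightly rougher than the original. On strongly
smoothed maps (smoothing lengthscale 0.5 rad at 62 parcels) the
two-sided spin test's type-I error at α = 0.05 measures ≈ 0.07–0.09
(recomputed by `scripts/acceptance.py`), against ≈ 0.5 for the naive
unconstrained shuffle on the same pairs. The effect compounds in the
PLS component test below. Under a true permutation null on white maps
the machinery is exact (≈ 0.05).

## PLS correspondence

Columns of X and y are z-scored (ddof = 1) over the jointly usable
parcels, so weights are scale-free and the first direction has the
closed form w₁ ∝ Xᵀy. Components are extracted by single-response
NIPALS with X-deflation; for one response this needs no iteration, and
the implementation agrees with scikit-learn's `PLSRegression` weights
to machine precision (cross-checked in the tests, not used as the
implementation). Scores are the deflated-X projections (the NIPALS
x-scores; identical to X·w for component 1). Each component is
sign-oriented so its score–response correlation r_obs is non-negative,
with the flip recorded. Variance explained is 100·r_obs² — the
definition is validated against the printed (r, %) pairs it must
reproduce: 0.654→42.77, 0.869→75.52, 0.601→36.12, 0.697→48.58, each
within rounding of the printed correlation. Captured covariance
‖X_kᵀy‖/(n−1) is nonincreasing across components on standardized data
(tested as a seeded property; it is not a theorem for adversarial
unstandardized designs).

**Component significance.** The response is spun through the ensemble,
re-standardized (duplicate assignments change its mean and SD), the
model refit, and the k-th observed captured covariance compared to the
null distribution of k-th components with the +1-corrected p. No
axis realignment between observed and null components is attempted.
Because the statistic aggregates chance correlations across all
features, it amplifies the spin null's slight variance deficit: with
200 smooth annotation columns against a smooth response (both at
lengthscale 0.5, 62 parcels) the component-1 type-I error at α = 0.05
measures ≈ 0.13–0.17 rather than 0.05 (recomputed by
`scripts/acceptance.py`). Interpret borderline component p-values
accordingly; with white or weakly smoothed annotation columns the test
is well calibrated (≈ 0.06).

**Bootstrap ratios.** Parcel rows of (X, y) are resampled jointly with
replacement; each refitted weight vector is sign-aligned to the
original by dot product before accumulating spread — without this, the
sign indeterminacy of PLS inflates the SE, the classic pitfall.
BR = original weight / bootstrap SD; a zero SD yields a flagged
infinite ratio (never a crash), and resamples with fewer than three
distinct parcels are redrawn with bounded retries. Selection is strict
|BR| > 3 into disjoint positive/negative sets.

**What BR does and does not test.** BR measures the stability of the
*observed* weight under parcel resampling, not whether the population
loading is zero. A null feature that is spatially smooth can carry a
large chance correlation with a smooth response that is perfectly
stable under resampling — such features are flagged at high rates
(~40% measured at lengthscale 0.5 on 31 parcels). The recovery
experiment in the tests and acceptance script therefore uses white
null columns, isolating estimator performance; the spatial-null
stress test is the spin-test calibration above. The same experiment
uses fixed-magnitude loadings (|loading| = 1, i.e. per-feature signal
SD equal to the unit noise SD): with N(0,1) loadings many planted
features are undetectable in principle (P(|l| > 3/√29) ≈ 0.57), which
would measure the loading distribution, not the estimator.

**Recovery ceiling.** The correlation between fitted first-component
weights and planted loadings is bounded by chance-correlation noise
from the null columns: each of the 180 null features contributes weight
noise of SD ≈ 1/√(n−1) ≈ 0.183 at 31 parcels, capping the correlation
near 0.88 even with noiseless informative columns; at unit SNR it
measures ≈ 0.79–0.81. More parcels, fewer null features, or selection
by BR before comparison would raise it; the acceptance script reports
the raw-weight value.

## Overrepresentation

Hypergeometric upper tail P[overlap ≥ observed] per set (enrichment
direction only; depletion is out of scope), against a caller-supplied
universe — for PLS output, the full analysed feature list. Sets are
intersected with the universe at load; configurable size filters
(defaults 5–2000) are applied and logged; BH-FDR across tested sets;
positive and negative feature lists run independently; a top-10 view
mirrors the usual reporting convention. GMT is the input format; no
hosted annotation database is bundled or queried.

## Synthetic data

Every generator is a pure function of (config, seed), byte-identical
on repetition, and returns its ground truth (planted effect maps,
planted loadings) alongside the data.

* **Parcellations**: golden-ratio spirals per hemisphere with small
  seeded angular jitter; hemispheres split at x = 0.
* **Autocorrelated maps**: white noise smoothed by a Gaussian kernel
  exp(−d²/2ℓ²) over great-circle distances, re-standardized to mean 0,
  SD 1. ℓ = 0 gives standardized white noise; ℓ = 0.5 rad (default)
  gives clearly smooth maps at 62 parcels (mean inverse-distance
  Moran's I ≈ 0.19 vs ≈ 0 for white noise).
* **Cohorts**: BMI lognormal (median 26 kg/m², σ = 0.17 — an adult-like
  distribution), clipped to [10, 50] with clip counts recorded; age
  N(55, 7.5) years; sex Bernoulli(0.5); site uniform over 3 sites with
  N(0, 0.02) mm offsets; education N(14, 3) years; SES N(0, 1).
  Thickness per parcel = baseline N(2.5, 0.1) mm + planted
  beta·BMI + covariate effects (defaults: −0.005 mm/year age,
  +0.02 mm sex, +0.001 mm/unit education and SES) + N(0, 0.1) mm noise.
* **Annotation matrices**: informative columns = loading·target +
  N(0, 1) with loadings N(0, loading_sd) or fixed ±loading_sd; null
  columns independent autocorrelated maps at `feature_lengthscale`
  (defaults to the map lengthscale; 0 gives white columns); column
  order shuffled by seed. Default width 200 features (20 informative)
  — desk-scale, configurable.

What the generator does **not** emulate: scanner- or sequence-specific
noise, site effects beyond additive offsets, growth-chart BMI
standardization, the covariance structure of real gene expression
(co-expression modules), or realistic PET tracer noise. Passing tests
demonstrate the statistical machinery under known ground truth, not
performance on any particular real dataset.

## Numerical and design choices

* Empirical p-values always use the (1 + count)/(n + 1) form.
* Geodesic nearest-neighbour search is done via maximal dot product;
  `argmax` gives deterministic lowest-index tie-breaking.
* BH-FDR is delegated to `statsmodels.multipletests(fdr_bh)` behind
  `bh_fdr` (the tests compare it against brute-force step-up
  enumeration); the hypergeometric tail to `scipy.stats.hypergeom`
  (tests compare against exact combinatorial enumeration).
* OLS is delegated to `statsmodels.OLS` behind `fit_parcel_regression`
  (tests compare against the normal-equations closed form to 1e-8).
* Constant annotation columns are dropped at construction with logged
  names; z-scoring guards zero-SD columns inside bootstrap resamples by
  leaving them at zero weight.
* Rotation sampling, the spin ensemble, cohorts, matrices and the full
  pipeline are deterministic under their seeds; pipeline TSVs are
  written with a fixed float format so reruns are byte-identical.
* Defaults: n_perm = 10,000, n_boot = 20,000, 5 components, BR
  threshold 3, α = 0.05. Tests and the acceptance script run reduced
  scales chosen to keep a full pass inside a few minutes on one CPU:
  1,000 spins, 2,000 bootstrap resamples, 500 simulation replicates;
  the type-I bands quoted above are what those scales resolve.

## Known limitations

* The parcel-spin null is mildly anticonservative on strongly smoothed
  maps, and markedly so for the aggregate PLS component statistic (see
  above); a variogram-matched surrogate or bijective-spin null family
  is out of scope here.
* Mass-univariate maps use fixed-effect site indicators, not
  harmonization or mixed models; no vertex-wise or longitudinal
  modelling.
* PLS is single-response; two-block symmetric PLS and CCA are not
  implemented.
* The enrichment stage consumes whatever GMT the user supplies; it
  ships no curated pathway database.
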