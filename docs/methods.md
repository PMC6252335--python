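# Methods

This note documents the statistical model, the numerical choices, and
what the synthetic validation does and does not establish.

## Estimand and estimator

Narrow-sense heritability h² is the fraction of phenotypic variance
attributable to additive genetic variance. In a one-parent
one-offspring design the regression coefficient of offspring on parent
estimates h²/2 (the parent transmits half its additive value), so
h² = 2b. For multivariate shape, b is obtained indirectly:

* PLSR predicts offspring shape from father shape. PLSR is used instead
  of multivariate OLS because shape blocks are high-dimensional and
  collinear (p, q up to 3K ≫ n). Our implementation is NIPALS on the
  cross-covariance: each component's predictor weight is the dominant
  left singular vector of XᵀY (computed by dense SVD for small blocks,
  power iteration for large ones), followed by rank-one deflation of
  both blocks. Regression coefficients for any leading subset of
  components come from one fit (PᵀW is unit upper triangular), which
  makes cross-validation over the component count cheap and permutation
  loops fast.
* The fit is summarized by the multivariate shape R²
  (1 − residual/total squared deviation in the aligned shape space),
  transformed as b = √(R² · SS_offspring / SS_parent) — the unique form
  that reduces to b = r·s_y/s_x in one dimension — and doubled.

**Component count.** Chosen per fit as the minimizer of 5-fold
cross-validated prediction MSE with contiguous folds, candidates 0..15
(further capped by p and the training-fold size). Zero components (mean
predictor) is admissible: without it every null fit would produce a
strictly positive R² (training overfit) which the square root inflates
badly; with it, a structureless pairing collapses to h² = 0 and the
broken-pairing null mean is ≈ 0. Pairwise landmark fits (3 predictors)
skip CV and use the full 3 components, where the PLSR fit equals the
least-squares projection; this is what makes the K² matrix computable
as a vectorized normal-equations solve.

**Reporting convention.** h² is reported raw: values may exceed 1
(sampling noise) or reach 2 exactly in the degenerate offspring≡father
limit. No truncation is applied; the sign of b is fixed positive, which
is the only consistent convention because the first PLS latent pair has
tᵀu = σ₁ ≥ 0 by construction — a multivariate "sign of the
relationship" does not exist.

**Negative R².** Predictions worse than the mean are clipped to R² = 0
with a logged warning before the b transform.

## Alignment and symmetry

GPA centers, optionally scales to unit centroid size, and iteratively
rotates to the evolving consensus (SVD orthogonal Procrustes with
determinant correction, so reflections never enter the rotation
solver). Convergence: RMS consensus displacement < 1e-10, max 100
iterations; the rotation gauge is fixed against the first subject.

Symmetrization runs GPA on the 2n set {originals ∪ reflections}, where
reflection negates x and swaps bilateral landmark pairs. Because the
set is closed under reflection, the consensus is symmetric up to a
rotation gauge; we solve for the frame explicitly (the −1 eigenvector
of diag(−1,1,1)·Q, with Q the rotation aligning the reflected consensus
to the consensus, is the symmetry-plane normal), rotate the plane onto
x = 0, and run three refinement sweeps against the reflection-averaged
consensus. The symmetric component is then reflection-invariant to
≈ 1e-9 and symmetric + asymmetric reconstructs each aligned original
exactly (identity by construction).

The full (scale-included) Procrustes distance sin ρ is used throughout,
consistent with scale removal in GPA; it is computed via the residual
norm rather than √(1−cos²ρ), which loses half the significant digits
near zero.

**Outlier QC.** Per-subject score = Procrustes distance to the
consensus, standardized; flag at z ≥ 2 (default). The z-score
construction for faces is not uniquely defined in the literature we
follow; distance-to-consensus standardization is our choice.

## Covariate adjustment

Vectorized shape is regressed on standardized age, sex (0/1), BMI by
PLSR with as many components as covariates — full rank, hence identical
to multivariate OLS, idempotent, and exactly orthogonalizing shape
against the covariates. Zero-variance covariates (sex in the all-male
father cohort or in single-sex strata) are dropped with a warning.
Fathers and offspring are adjusted separately.

## Segmentation

Affinities are the symmetrized co-heritability matrix with negative
entries clipped to 0 (spectral clustering needs non-negative weights).
Each segment is split by the symmetric normalized Laplacian's second
eigenvector; candidate bipartitions (sign pattern, 2-means on the 2-dim
spectral embedding with a fixed seed, and every sweep cut along the
second eigenvector's ordering) are scored by normalized cut and the
best is kept — the sweep-cut family is what makes the split agree with
the exhaustive minimum-Ncut oracle on small matrices. Disconnected
affinity graphs split by connected components. Five levels give 2^l
segments per level, 63 total; segments with < 2 landmarks are carried
down unchanged and flagged so the registry stays well-defined. NMI uses
mean-entropy normalization, with the identical single-cluster case
defined as 1 (this makes the level-0 comparison of any two
segmentations equal 1 by convention).

## Module shape spaces and parallel analysis

Each module is re-GPA'd independently of the rest of the face (modules
with < 3 landmarks use centered raw coordinates), then decomposed by
PCA. The retained PC count is Horn's parallel analysis: 100
column-permutations of the aligned coordinate matrix, 95th percentile
threshold per rank, leading-run retention, minimum 1.

One correction matters here: aligned coordinates live in the shape
subspace (7 similarity dimensions are removed by GPA), while a
column-permuted matrix does not. Comparing against raw permuted
eigenvalues makes PA retain *every* direction even for isotropic noise,
because the permuted variance is spread over more dimensions than the
data can occupy. Each permuted matrix is therefore projected onto the
shape subspace (orthogonal complement of the similarity tangent at the
module consensus) and rescaled to preserve its total variance. With
this null, isotropic-noise modules retain ≤ 1 PC and planted factors
are counted exactly (both verified in tests).

Parallel analysis runs on fathers and offspring pooled, matching the
pooled construction of the module shape spaces.

## Permutation tests and multiple testing

Significance of each module/cohort h² comes from randomizing the
father–offspring pairing: p = (1 + #{h2_perm ≥ h2_obs}) / (1 + n_perm),
so p ≥ 1/(n_perm+1). The test statistic uses a *pairing-independent*
component count, min(15, p, n−1), for the observed and all permuted
fits; choosing the count by CV on the observed pairing breaks
exchangeability and measurably inflates type-I error, while a CV choice
of 0 would freeze the statistic at 0. The reported point estimate
remains the cross-validated one; the permutation p refers to the
full-component statistic. Default n_perm is 9,999 at desk scale, with
the count configurable upward for production runs.

M_eff is Li–Ji: with λ the eigenvalues of the module correlation
matrix, M_eff = Σ [I(λᵢ ≥ 1) + (λᵢ − ⌊λᵢ⌋)]; eigenvalues within 1e-9 of
an integer are snapped to it (the fractional part is discontinuous
there and float noise otherwise corrupts exact cases like the 63×63
identity). The adjusted threshold divides the FWER by round(M_eff),
matching the integer reporting convention. The "multivariate
correlation" between two modules is the RV coefficient of their
retained-PC score blocks — rotation-invariant, hence well-defined
across shape spaces of different dimension; pooled subjects are the
default, with a row subset switch.

## Synthetic cohorts

The generator emulates what the pipeline assumes about real data:

* a bilaterally symmetric template (paraboloid grid) with bilateral
  pair map and midline;
* planted modules, each with latent factors displacing its landmarks
  along smooth, mirror-symmetric loading fields (Gaussian bumps along
  surface normals, projected off the module's similarity tangent so the
  planted variance is genuine shape variation, then orthonormalized);
* additive genetics: father score ~ N(0, Va), offspring score
  = ½·father + √(¾Va)·ξ (so cov = Va/2), independent environmental
  scores ~ N(0, Ve) per individual;
* optionally, shared factors spanning module pairs, giving *nested*
  co-inheritance — the structure the binary hierarchy assumes; without
  them a normalized cut may legitimately isolate one module at level 1,
  and a flat 4-module plant is then not recoverable as a level-2
  quartet;
* linear age/sex/BMI effects through fixed smooth fields, iid
  coordinate noise, and per-subject rigid motion + scale (default 10°
  rotation, 0.05 log-scale SD) applied last so GPA is genuinely
  exercised.

Defaults: per-factor shape variance Va + Ve = 0.1 against a template of
centroid size ≈ 8, i.e. deformations a few percent of size, like real
inter-individual facial variation — large enough to dominate 1%
coordinate noise, small enough that Procrustes linearization holds
(large-amplitude plants visibly attenuate recovered h²). Randomness:
one master seed; per-subject nuisance draws come from counter-keyed
substreams, so cohorts are bit-identical per seed and independent of
iteration order.

The planted truth is h² = Va/(Va + Ve + noise_sd²) along any generating
direction. Exact-truth recovery designs set noise_sd = 0, because iid
coordinate noise enters the symmetric component at half variance and
would shift the attainable truth away from the closed form.

**What passing tests show — and don't.** Recovery of planted h² within
±0.08 (n = 800, 20 cohorts) shows the estimator chain (GPA →
symmetrization → adjustment → module PCA → PLSR → 2b) is consistent and
approximately unbiased under the generator's assumptions: additive
genetics, linear covariate effects, mirror-symmetric smooth loadings,
Gaussian noise, small rigid nuisance. Real faces violate several of
these (common environment inflates parent-offspring covariance;
loadings are not orthonormalized anatomy; registration error is not
iid), so synthetic recovery does not certify unbiasedness on real
cohorts — notably, estimates from relatives remain upper bounds in the
presence of shared environment.

## Numerical details and degenerate inputs

* Rotation solver: batched 3×3 SVD with sign correction; coincident
  (zero-size) configurations are a hard error.
* Midline landmarks have ≈ zero x-variance after symmetrization; the
  pairwise co-heritability solve uses a pseudoinverse (rcond 1e-12),
  matching PLSR's behaviour of ignoring rank-deficient directions.
* CV folds are contiguous, so all estimates are deterministic without
  an RNG; 2-means tie-breaks label the lowest-index landmark's cluster
  0.
* Pipeline substreams are derived from the master seed via
  `SeedSequence([seed, tags…])`, keeping every derived seed below 2³¹.

## Problem sizes

The test-suite and acceptance studies run at K = 42–242 landmarks and
n = 120–800 pairs, with 100–200 replicate cohorts where a distribution
is being checked; the analysis drivers use K = 242, n = 762 pairs.
These sizes were chosen so each study carries enough Monte-Carlo
precision for its stated tolerance band.

## Known limitations

* The asymmetric component is computed but not analyzed (the symmetric
  component is the analysis target); no sliding semi-landmarks, no
  weighted GPA.
* Heritability from a single-parent design cannot separate additive
  variance from shared-environment covariance.
* Landmark-level maps inherit superimposition effects: densely sampled
  regions drive the global alignment, and midline x-coordinates lose
  variance by construction — module-level estimates (separate GPA per
  module) are the more interpretable quantity.
* The non-genetic, shape-covariance-based segmentation used for NMI
  comparisons is accepted as an external label file, not re-derived.
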