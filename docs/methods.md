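# Methods

## Model and preconditioning

The data model is a linear mixed model with a single structured random
effect: `y = Xβ + u + ε` with `u ~ N(0, σ²ₛK)`, `ε ~ N(0, σ²εI)` and
`K = (1/p)XXᵀ` computed from the standardized **penalized** feature columns
(fixed-effect covariates such as sex or recruitment site are excluded from K:
they model mean structure, not relatedness).  Because fitted coefficients are
invariant to the overall scale of the outcome covariance, the package works
with the unit-total-variance form `Σ_unit = ηK + (1−η)I`, leaving a single
structure parameter `η = σ²ₛ/(σ²ₛ+σ²ε) ∈ [0,1]`; the total variance is kept
only for reporting.

Whitening is performed through the eigendecomposition `K = U diag(s) Uᵀ`:
`F = diag(w) Uᵀ` with `w_i = (η s_i + 1 − η)^{−1/2}` satisfies
`F Σ_unit Fᵀ = I` by construction.  The rotation acts on rows, so feature
coefficients retain their interpretation; it destroys the implicit intercept,
so an explicit all-ones column is appended before rotating and treated as an
unpenalized column thereafter.  The eigendecomposition is full and dense
(`scipy.linalg.eigh` on the n × n matrix), which is exact and practical up to
n of roughly 10⁴; approximate or sparse eigensolvers are deliberately out of
scope.

## Standardization conventions

Columns are centered and scaled to **mean square one** (the 1/n population
convention), which makes `trace(K) = n` exactly — used as an analytic test.
Missing dosages are imputed to the column mean computed from observed entries
(hence exactly 0 after standardization); minor allele frequencies for QC
filtering are computed from observed alleles only, before imputation.
Constant columns are dropped with reason `zero_variance`, sub-threshold MAF
columns with reason `maf`.  Unpenalized covariates are standardized exactly
like penalized columns for numerical uniformity; the format step returns all
coefficients on the raw data scale.

## Variance-component estimation

η̂ maximizes the **restricted** profile Gaussian likelihood of the null model
(intercept + unpenalized covariates) in the eigenbasis of K, where the
covariance is diagonal (`d_i = η s_i + 1 − η`) and each evaluation is O(n·q²);
both the GLS coefficients and the total variance profile out in closed form.
The restriction term `log det(WᵀD⁻¹W)` is essential rather than cosmetic:
column standardization gives K an exact null eigenvector along the all-ones
direction, which the intercept absorbs, so the unrestricted likelihood
contains a spurious `−½·log(1−η)` term and is attracted to the η = 1
boundary; the restricted form cancels that degeneracy exactly.  Optimization
is a deterministic 100-point grid scan on [0, 0.999] followed by bounded
Brent refinement (xatol 1e-10).  The cap at 0.999 keeps the whitening weights
finite when K is singular (always the case after centering, or when p < n).
At the study sizes used in the tests (n = 200, p = 1000) the Cramér–Rao bound
puts sd(η̂) at roughly 0.10–0.13, so recovery accuracy near 0.1 mean absolute
error is the information-theoretic floor, not an implementation limit.

## Penalized path solver

The objective on the rotated scale is `(1/2n)‖ỹ − X̃β‖² + Σⱼ pfⱼ Pλ(βⱼ)` with
penalty families lasso, MCP (γ > 1, default 3.0) and SCAD (γ > 2, default
3.7), each optionally mixed with a ridge term through the elastic-net
fraction α ∈ (0,1] (default 1, i.e. no ridge).  Rotated columns are **not**
re-standardized — that would change the estimand; instead every coordinate
update uses the column curvature `vⱼ = (1/n)x̃ⱼᵀx̃ⱼ` and the closed-form
one-dimensional minimizer of `(v/2)β² − zβ + penalty`.

The λ path is log-spaced over `n_lambda = 100` values from
`λ_max = maxⱼ |(1/n)x̃ⱼᵀr₀|/(α·pfⱼ)` (r₀ = rotated outcome residualized on the
unpenalized block) down to `λ_max·ratio`, ratio defaulting to 0.01 for n > p
and 0.05 otherwise.  At any λ ≥ λ_max the exact solution — unpenalized block
by least squares, penalized block zero — is assigned analytically, which
makes the "all penalized coefficients are exactly zero at λ_max" invariant
hold without floating-point ambiguity.  Below λ_max the solver warm-starts
each λ from the previous solution and alternates sweeps restricted to the
active set with full sweeps that admit new violators; convergence is declared
when the largest curvature-weighted coefficient change in a full sweep falls
below `tol · RMS(ỹ)` (tol default 1e-4, max 10 000 sweeps; non-convergence is
recorded per λ, not fatal).  For the convex families the returned solutions
are KKT-certified in tests to 1e-6 and match an independent FISTA oracle's
objective to 1e-7.  The inner sweep is a numba-compiled kernel operating on
column blocks; the in-memory and file-backed paths execute identical
per-column operations in identical order, so they agree to machine precision.

## Prediction

The BLUP for new samples is `ŷ₂ = X₂β̂ + Σ̂₂₁Σ̂₁₁⁻¹(y₁ − X₁β̂)`, with
`Σ̂₁₁⁻¹` applied through the training eigendecomposition and
`K₂₁ = (1/p)X₂X₁ᵀ` over standardized penalized features — new samples are
always standardized with training centers and scales.  The cross-covariance
is `Σ̂₂₁ = η̂K₂₁`, plus a `(1−η̂)` term on any entry whose new sample *is* a
training sample (matched by sample ID): the covariance of an observation with
itself includes its noise.  For disjoint samples this reduces to the plain
η̂-scaled cross-relatedness; when the "new" data are exactly the training
data it makes `Σ̂₂₁ = Σ̂₁₁` and BLUP reproduces y₁ identically — the
algebraic identity used as a test.  With η̂ = 0 the adjustment vanishes and
BLUP equals the linear predictor.

## Cross-validation

`cv_plmm` shares a single λ sequence computed from the full data (so CVE is
comparable per λ) but redoes **everything else** inside each training fold:
standardization, K, η̂, whitening, and the path fit use training rows only,
and held-out outcomes are predicted by BLUP (default) from the training-fold
context.  Folds are balanced (sizes differ by at most one), deterministic
given the seed, and may be computed in parallel (joblib) with results
combined in fold order so serial and parallel runs are identical.  The error
metric is mean squared prediction error on the raw outcome scale, reported
alongside its square root (RMSPE); λ is selected at the CVE minimum (first
index on ties), with a one-standard-error index also reported.  k defaults to
5; k = n gives leave-one-out for small expression-style designs.  A guard
worth noting: a training fold's own λ_max can exceed the shared λ_max, in
which case the fold model at the head of the path is legitimately non-null;
the null-model identity of the CVE head is therefore only exact at a λ that
dominates every fold's λ_max.

## Synthetic data

The generator emulates the data regimes the model targets: per-feature allele
frequencies drawn in a MAF window, per-population Balding–Nichols-style beta
perturbation with divergence knob F, family blocks built from two
pseudo-parent haplotype pairs with children as Mendelian draws (within-family
relatedness ≈ 0.5), uniform missingness, sparse causal effects on the
standardized scale, and a structured random effect drawn exactly from the
realized K in its eigenbasis so that η_true is the actual proportion of
structural variance.  Defaults (families of ~4, two ancestry groups,
F = 0.1) describe a moderately structured multi-site family cohort.  The
`confounded` flag strongly stratifies a random 10% of *null* features while
restricting causal features to the weakly stratified remainder, reproducing
the false-positive trap for independence-assuming regressions.

What the generator does **not** emulate: linkage disequilibrium along a map
(features are exchangeable given their frequencies), case/control
ascertainment, sex chromosomes, genotyping-batch artifacts in the features
themselves.  Passing tests therefore demonstrate correctness of the
estimator, solver, predictor, and CV machinery under the assumed model — not
robustness to LD structure or ascertainment in real cohorts.

## Study sizes used by the test suite

Simulation-backed checks run at deliberately modest sizes chosen to exercise
the asymptotics that matter while keeping the suite fast: whitening and
solver certification on dozens of random instances up to n = 100; η recovery
at n = 200, p = 1000 with 20 phenotype replicates per η ∈ {0.2, 0.5, 0.8}
over a fixed genotype draw (the fixed-design reading of the generative
model); confounding mitigation on ten replicates of a 450-sample cohort
(training 300, related test split 150, p = 2000), where the mixed model
averages ~3× fewer false positives than the naive lasso at matched
cross-validated λ selection with no worse held-out RMSPE.

## Numerical choices and edge cases

- Eigenvalues in [−1e-10, 0) are clipped to zero; larger asymmetry than 1e-8
  in K is an error, not a warning.
- Dosage decoding follows the 2-bit SNP-major layout exactly; the A1-count
  orientation is the default with an `A2` flip available (orientation only
  changes coefficient signs).  Individual-major files are rejected
  explicitly rather than transposed.
- The backing store is a flat float64 file in column-major order plus a JSON
  sidecar (shape, identifiers); column blocks are the unit of all out-of-core
  access.
- Ties in the CVE minimum resolve to the largest λ (smallest index).
- All-missing and constant columns are dropped before fitting; an empty
  sample-ID intersection, duplicate IDs, and non-numeric outcomes are hard
  errors.
- `assign_folds` requires 2 ≤ k ≤ n and rejects folds whose training part has
  fewer rows than the unpenalized column count plus two.

## Known limitations

Linear (Gaussian) loss only — binary outcomes must be coded numerically.
The dense n × n eigendecomposition bounds practical cohort size at n ≈ 10⁴.
K is the empirical (1/p)XXᵀ estimator; sparse/thresholded relatedness and
externally supplied kinship are not supported.  Fold assignment is uniform,
not family-aware, so relatives of held-out samples may appear in training —
realistic for prediction, but worth remembering when interpreting CVE as a
generalization estimate for unrelated cohorts.
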