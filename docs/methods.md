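# Methods

`relmc` evaluates internal-consistency reliability indices with a
confusion-matrix-style Monte Carlo design.  This note records the
models, the estimators as actually computed, the evaluation criteria,
the numerical choices, and the limits of what the simulations show.

## Populations

All populations have unit item variances, so covariance and
correlation matrices coincide and items can be generated as standard
normals.

* **Null** — k mutually independent N(0,1) items.  Every inter-item
  covariance and factor loading is zero, so the true internal
  consistency is exactly 0.  This is the null distribution of the
  reliability statistics.
* **Tau-equivalent** — one common factor with equal loadings, which at
  unit variance is an equicorrelated matrix.  For a target alpha the
  off-diagonal solves the closed form `r = alpha / (k - (k-1) alpha)`;
  the population Cronbach alpha then equals the target to machine
  precision.  Defaults used in the studies: alpha = 0.731 at k = 6 and
  0.845 at k = 12 (the acceptable-level conditions), and 0.3 / 0.5 for
  the weak-reliability extension.
* **Congeneric** — one factor with unequal loadings.  The loading
  *pattern* is configuration (default: an arithmetic sequence from 0.3
  to 0.8 across the k items, a conventional monotone design); a scalar
  multiplier is solved by Brent root-finding so the one-factor
  composite reliability `omega = (sum lam)^2 / ((sum lam)^2 +
  sum(1 - lam^2))` hits the target within ~1e-12.  The original
  evaluation's exact congeneric matrices were never published, so
  congeneric cells reproduce trends, not printed values; the pattern
  can be replaced by a user's own.

Samples are multivariate normal via a Cholesky factor of the
population matrix (eigenvalue factor as fallback).  A large-sample
check (`verify_null_large_sample`, n >= 10,000) computes all four
indices on one null draw and should return values near zero; it is the
recommended validation that a null design really excludes the effect
the statistic measures.

## Estimators

All indices are computed from the sample Pearson correlation matrix R
(the populations are standardized, and the reference routines
standardize by default).

* **Cronbach's alpha**: `k/(k-1) * (1 - k / sum(R))`.  May be negative;
  not truncated.
* **Minres EFA**: uniquenesses minimize the sum of squared
  off-diagonal residuals of `R - Lambda Lambda'`, with loadings from
  the truncated eigendecomposition of the reduced matrix.  L-BFGS-B on
  `psi in [0.005, 1]^k`, started at 1 − squared multiple correlations,
  up to three jittered restarts; the gradient is a forward difference
  evaluated through one batched eigendecomposition per iteration.
  Communalities above 1 (Heywood) are flagged; uniquenesses are
  clipped to [0,1] for the plain estimators but enter the
  omega pipeline unclipped (below), matching the reference routine.
* **Omega-total** (`omega_total`): `1 - sum(u2) / sum(R)` with u2 from
  the m-factor minres fit; m defaults to 3 (the reference default),
  reduced to the largest identified m when `(k-m)^2 - k - m < 0`.
* **Reference omega pipeline** (`omega_reliability`): minres(3) →
  oblique quartimin rotation (gradient-projection algorithm) → one
  factor fitted to the 3×3 factor-correlation matrix → Schmid–Leiman
  general-factor loadings `g = L f_g`.  **Reverse-keying**: items with
  negative g-loadings are sign-flipped and the analysis redone on the
  flipped matrix (the refit is mathematically a row-sign change, so
  communalities carry over).  Alpha and omega-total are then computed
  on the *flipped* matrix.  This emulates the default behaviour of the
  standard omega routine in the field's reference software.  Because
  the flip is chosen from the sample, under a null population it
  aligns noise: both indices acquire a positive bias of order
  `1/sqrt(n)` and heavier upper tails.  The simulation engine uses
  this pipeline for alpha and omega by default (`reverse_key=True`)
  because it is what published evaluations of these indices measure;
  set `reverse_key=False` for the keying-free estimators.
* **Factor-based GLB** (`glb_factor`): replace the diagonal of R with
  m-factor communalities; `glb = (sum(R) - k + sum(h2)) / sum(R)`.
  m defaults to floor(k/2) (capped at identifiability), the reference
  routine's default.  With that many factors the communalities absorb
  most observed covariation; on noisy matrices they can exceed the
  exact algebraic optimum, so no ordering between the two GLB variants
  is guaranteed (for m = 1 the factor version is conservative).
* **Algebraic GLB** (`glb_algebraic`): the exact bound — maximize
  `sum(y)` subject to `R - diag(y)` positive semidefinite and
  `0 <= y_i <= 1`, then `glb = 1 - sum(y*) / sum(R)`.  Solved by SLSQP
  with the eigenvalues of `R - diag(y)` as constraints and their
  analytic gradients (`d lambda_j / d y_i = -v_ij^2`), from the
  feasible start y = 0; a bisection pull-back guarantees feasibility
  of the returned point.  Verified in the tests against the 2×2 closed
  form `2r/(1+r)` and a brute-force oracle on 3×3 matrices.

Non-PSD sample matrices (possible only numerically) are smoothed by
eigenvalue clipping before the semidefinite program; alpha and minres
operate on the raw matrix.  Estimator failures are recorded per
replication and excluded from that estimator's aggregates only — the
failure count is always reported, never silently dropped.

## Criteria

For replication estimates p-hat of a true value p:

* `RMSE = sqrt(mean((p-hat − p)^2))`
* `%bias = mean(deviation) × 100` under three conventions:
  estimate−true, true−estimate, and absolute.  True-negative tables
  report the absolute mode by default (the signed conventions are also
  computed and stored); with a null population and sign-symmetric
  estimators the signed mean is near zero and uninformative.
* `FPm = P(estimate >= 0.7 | null population)` — inclusive cut-off.
* `FNm = P(estimate <= 0 | population at an acceptable level)` —
  inclusive floor.

FPm refuses non-null replication sets unless explicitly relabelled
(`as_null`), which is how the dummy-index counterfactual and the
weak-reliability study pose their questions.  The dummy indices — the
constant 0.78 and uniform draws on [0.711, 0.751] — are first-class
`ReplicationSet` constructors used to demonstrate that RMSE/%bias
cannot separate a valid estimator from noise pinned near the target.

## Study grids and seeding

Four studies: `tn` (null, RMSE/%bias; k ∈ {6,12} × n ∈ {250,500,1000}),
`fpm` (null, FPm; n ∈ {20,25,30,35,40,45,50,250,500,1000}), `fnm`
(tau-equivalent and congeneric at 0.731/0.845, FNm; same n grid), and
`fpm_weak` (6-item TE at 0.3 and 12-item CG at 0.5, FPm).  Default
10,000 replications per condition, overridable.  Each replication's
generator derives from `SeedSequence(master_seed, spawn_key=(study, k,
n, model, replication))`: streams never collide, results are
byte-identical regardless of execution order, and all estimators see
the same sample within a replication (paired comparison).

The test suite runs reduced replication counts (300–2,500 for most
stochastic checks, 10,000 where a zero-event or sub-percent rate is
asserted), chosen so Monte Carlo error is small against each check's
tolerance; the acceptance script uses 10,000 throughout.

## What the synthetic data does and does not show

The generator produces exactly the stated population structures under
multivariate normality.  It does not emulate Likert-type discreteness,
non-normal item distributions, missing data, or multidimensional
structure — so passing results certify estimator behaviour under the
stated ideal conditions, not robustness on real questionnaire data.
Within those conditions the qualitative findings (omega-total and the
GLB variants report acceptable reliability on pure noise at small n;
alpha's false-positive rate stays near zero; false negatives are
negligible for all indices) are structural, driven by the [0,1] range
restriction and the data-driven reverse-keying, and should transfer.

## Known limitations

* The congeneric population matrices are reconstructions; cells that
  depend on them are trend-level only.
* The reference omega pipeline is re-implemented (rotation, general
  factor, keying); small implementation differences from the original
  software are possible in degenerate small-sample fits, within about
  one percentage point in the rates reported here.
* The algebraic GLB solver targets k ≤ ~20; it is exact but not tuned
  for large item counts.
* Rates below ~0.1% need more than 10,000 replications to pin down;
  such cells are compared only at coarse tolerance.
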