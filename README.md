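# relmc

Confusion-matrix Monte Carlo evaluation of internal-consistency
reliability indices.

## The problem

Simulation studies that compare reliability coefficients — Cronbach's
alpha, McDonald's omega-total, and the greatest lower bound (GLB) in
its factor-based and algebraic forms — usually score estimators by how
closely they track a population with *acceptable* reliability (RMSE
and %bias against a true value like 0.731).  Those two criteria cannot
tell a valid estimator from a dummy: a constant "index" C = 0.78 has
RMSE 0.049 and %bias −4.9% against p = 0.731, rivalling the best real
estimator, while being pure nonsense.  What exposes it is the missing
half of the confusion matrix: how a statistic behaves when the effect
it measures is *absent*.

`relmc` implements that design for internal consistency.  It
simulates

* **null populations** — k mutually independent N(0,1) items, where
  the true internal consistency is exactly 0;
* **tau-equivalent populations** — equicorrelated, with population
  alpha solving `r = α/(k−(k−1)α)` for targets such as 0.731 (k=6),
  0.845 (k=12), or weak levels 0.3/0.5;
* **congeneric populations** — one factor with unequal loadings,
  scaled so the composite reliability `ω = (Σλ)²/((Σλ)² + Σ(1−λ²))`
  hits the target;

computes the four indices from first principles on every replication
(closed-form alpha; minres exploratory factor analysis behind
omega-total and the factor GLB; a semidefinite program for the
algebraic GLB), and aggregates four criteria:

* `RMSE` and `%bias` (three sign conventions) for true-negative runs;
* `FPm = P(estimate ≥ 0.7 | null population)` — the modified false
  positive rate at the field's acceptability cut-off;
* `FNm = P(estimate ≤ 0 | acceptable population)` — the modified
  false negative rate.

The alpha/omega path reproduces the reference software's full omega
pipeline, including its default *reverse-keying*: items with negative
general-factor loadings are sign-flipped before the indices are
computed.  Because the flip is chosen from the sample, it aligns noise
under a null population — the mechanism behind omega's striking
false-positive rates at small n.  It can be disabled
(`reverse_key=False`) to study the keying-free estimators.

## A worked example

```
python examples/false_positive_small_samples.py
```

prints (800 replications per cell, fixed seed):

```
FPm = P(index >= 0.7 | null population), 6 items:
 k  n Alpha  Omega   GLB   GLBa
 6 20 0.38% 48.00% 7.75% 12.50%
 6 30 0.00% 17.25% 2.25%  2.75%
 6 40 0.00%  4.00% 0.38%  0.62%
 6 50 0.00%  1.50% 0.00%  0.00%
```

Read: with six items and twenty respondents of *pure noise*,
omega-total certifies "acceptable reliability" in about half the
samples; alpha almost never does.  By n = 250 every index's rate is
zero.  `examples/` contains similar narrative scripts for the dummy
indices, the large-sample null verification, one-off index
computation, and the true-negative study.

The same runs are available from a shell:

```
relmc run --study fpm --reps 10000 --seed 1 --out results/
relmc indices --input data.csv
relmc dummy-demo
```

`run` writes a tidy CSV (one row per condition × estimator ×
criterion), wide tables shaped like the conventional result tables,
and a JSON manifest with seeds and failure counts; a run is exactly
reproducible from its manifest.

## Library surface

`relmc.populations` builds population structures and samples;
`relmc.indices` has the estimators (`cronbach_alpha`, `efa_minres`,
`omega_total`, `omega_reliability`, `glb_factor`, `glb_algebraic`);
`relmc.criteria` the criteria and dummy indices; `relmc.engine` the
study grids with hierarchical, collision-free seeding;
`relmc.reporting` the table layouts.

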