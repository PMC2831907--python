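# Methods

## Statistical model and assumptions

The pipeline treats a patient × category table of dichotomized ICF
qualifiers as a sample from a causal system represented by a DAG over the
categories.  The working assumptions are the standard ones for
constraint-based causal discovery:

* **Causal sufficiency** — no unmeasured confounders and no selection
  variables.
* **Faithfulness** — every conditional independence in the distribution is
  implied by d-separation in the DAG.
* **Acyclicity** — no feedback loops.
* **Interaction-free linear-probability structural equations** — each
  binary category satisfies `P(X_j = 1 | parents) = a_j + Σ_k w_jk X_k`
  (main effects only), and the continuous outcome is a main-effects linear
  function of a subset of categories plus Gaussian noise.

The last assumption is what licenses the binary extension of intervention
calculus used here: in a linear-probability system the covariance matrix
obeys the same path (trek) rules as a linear Gaussian structural model, so
the coefficient of X in the least-squares regression of the outcome on X
and any valid parent set of X equals the total causal effect
`E[Y | do(X=1)] − E[Y | do(X=0)]` under the DAG that has that parent set.
The synthetic generator uses the linear-probability form (not logistic)
precisely so that this estimator is exactly, not approximately, consistent
with the data mechanism, making parameter-recovery tests sharp.

## Pipeline stages and tunable parameters

| parameter | default | meaning |
|---|---|---|
| `missing_threshold` | 0.20 | drop a category iff its missing fraction is **strictly greater** (a column at the threshold is kept) |
| `m` | 10 | imputations per dataset |
| `iterations` | 10 | chained-equations cycles (0 = initial random fill only) |
| `method` | logistic | imputation draw: ridge-logistic Bernoulli or predictive mean matching (donor pool k = 5) |
| `B` | 10 | bootstrap replicates per imputation; the collection holds m·B datasets |
| `alpha` | 0.05 | significance level of the PC independence tests |
| `max_cond_size` | 3 | largest conditioning set; 2^|S| strata on ~10³ rows starve beyond that |
| `n_perm` | 499 | permutations in the conditional test (add-one p-value) |
| `summary_fraction` | 0.20 | summary-graph inclusion threshold as ceil(fraction·N) |
| `comparison_quantile` | 0.95 | within-SHD quantile the between-SHD median must exceed |
| `characteristic_high/low` | 0.5 / 0.2 | reliability bounds for characteristic edges |

Dichotomization maps b/d/s qualifiers 1–4 to 1 and 0 to 0; environmental
(e) qualifiers 1–4 (facilitator) to 1 and −4..0 (barrier or neutral) to 0.
Qualifier values outside the legal ranges are an error, never silently
recoded.  The ghp outcome is resampled jointly with its row in the
bootstrap, is excluded from imputation and from the PC node set, and enters
only through the effect regressions.

## Numerical and algorithmic choices

* **Conditional independence test.**  The statistic is the sum over the
  2^|S| conditioning strata of the Pearson chi-square of the stratum's 2×2
  table; strata with a zero row or column margin carry no information and
  contribute 0.  The null permutes x within each stratum.  Because the
  stratum statistic depends on the table only through its (1,1) cell, and
  uniform within-stratum permutation makes that cell hypergeometric given
  the margins, the permutation null is simulated by vectorised
  hypergeometric draws — an exact equivalence, not an approximation.  The
  add-one rule `(1 + #{null ≥ obs}) / (n_perm + 1)` keeps p-values strictly
  positive.
* **PC search order.**  Edges are scanned in lexicographic order;
  conditioning subsets at each size are enumerated lexicographically, first
  within adj(X)\{Y}, then adj(Y)\{X}, stopping at the first separating set.
  This fixes the (well-known) order dependence of plain PC and makes runs
  reproducible; the order-independent PC-stable variant is out of scope.
* **Orientation conflicts.**  With sampled sepsets two colliders can demand
  opposite directions for one edge; such edges degrade to undirected and
  are logged, as is any directed cycle left by Meek propagation (broken at
  its lexicographically smallest edge).  Skeleton-level results are
  unaffected.
* **Imputation robustness.**  The logistic imputation model carries a small
  ridge penalty (inverse strength C = 10) so that complete separation —
  near-certain in wide sparse binary tables — cannot crash or produce
  infinite weights; a column whose observed values are constant imputes
  that constant.  PMM operates on the 0/1 data as numeric with a
  least-squares index and k = 5 donors.
* **Effect regressions.**  Ordinary least squares via `numpy.linalg.lstsq`;
  a rank-deficient (collinear) adjustment set falls back to the
  minimum-norm solution with a logged warning; a zero-variance category
  yields an empty effect multiset with a warning rather than a fabricated 0.
* **Parent-set enumeration.**  Local IDA: candidate sets are
  pa(X) ∪ T over subsets T of the undirected neighbours such that orienting
  T→X creates no new unshielded collider at X (every member of T adjacent
  to every other candidate parent).  The test suite proves this equal to
  brute-force enumeration of all consistent DAG extensions on p ≤ 6.
* **Aggregation.**  Each effect estimate carries equal weight in the pooled
  mean ("mean over all estimates"), so datasets with more ambiguous
  orientations contribute more estimates than others — a deliberate,
  documented property, not per-dataset means of means.  Ranking is by
  ascending signed mean: category value 1 codes impairment and higher ghp
  codes better health, so the most negative mean marks the most promising
  intervention target; the convention is printed in every report header.
* **Sub-seeding.**  Every stochastic stage derives its seed as a CRC-32 /
  SeedSequence hash of the master seed and the stage's name and indices, so
  any replicate is independently reproducible.

## The synthetic generator — what it emulates and what it does not

`synthetic` produces random DAGs (each ordered pair under a random
topological order receives an edge with probability `expected_degree /
(p−1)`), parent weights drawn uniformly and *rescaled* (never rejected) so
that the structural probability is valid for all 2^|parents|
configurations, a linear ghp equation (default baseline 60, noise sd 10 —
a realistic spread for a 0–100 health score in a patient cohort), and MCAR
missingness per column.  Exact ground-truth intervention effects come from
truncated-factorization enumeration (p ≤ 16), cross-checked in tests
against the sum-of-path-products closed form.

It does **not** emulate: informative missingness (only MCAR, matching the
noninformative-missingness assumption), ordinal qualifier structure
(generation is directly binary), latent confounders, selection effects, or
interactions.  Passing tests therefore certify the machinery under the
method's own assumptions; they say nothing about robustness to violations
of those assumptions in clinical data.

## Known limitations

* The subpopulation decision rule is a heuristic, not a calibrated test.
  Between-collection SHDs include dataset-level sampling variation that
  within-collection SHDs (bootstrap + imputation on one sample) do not, so
  with small ensembles the null "different" rate is noticeably above zero
  (roughly 10–15% at m=B=2, n=2000 in our simulations) and depends on the
  ensemble size.  A formally calibrated two-sample graph test is out of
  scope.
* Plain PC with sampled tests is order-dependent and its skeleton is only
  consistent, not exact, at finite n; reliability thresholds exist to
  absorb exactly this instability.
* Effect multisets bound, but do not identify, causal effects; the mean is
  one defensible aggregate of an ambiguous set, and min/max are always
  reported alongside it.
* Imputation runs after dichotomization; on data whose raw qualifiers carry
  information beyond the binary split this loses efficiency.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run everything on synthetic
data at sizes chosen to make the Monte-Carlo assertions sharp yet quick on
one core: 100 random DAGs (p ≤ 8) for oracle skeleton/CPDAG recovery with
equivalence-class enumeration cross-checks at p ≤ 5; 50 models at
n = 50 000 for effect containment (3-standard-error criterion per category);
200 null simulations at n = 500 for permutation-test calibration;
exhaustive Fisher-vs-enumeration agreement over all 2×2 tables up to
n = 40 (tests) / n = 30 (script); 500 random triples for the SHD metric
axioms; 50 same-model and 50 four-edge-difference comparison runs at
n = 2000 with m = B = 2; and 30 ranking-recovery pipeline runs at p = 12,
n = 3000, m = B = 2.
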