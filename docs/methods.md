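# Methods

## Problem setting

Clinical repositories store facts in the Entity–Attribute–Value (EAV)
layout: one row per (clinical event, parameter name, value) triple.
Building a risk-prediction model from such data requires (1) pivoting the
parameters of interest into a wide table with one column per parameter,
(2) optionally deriving features with SQL, and (3) choosing a learning
algorithm and its hyper-parameter values — the combined algorithm
selection and hyper-parameter optimization (CASH) problem — before fitting
and evaluating the final model. The package implements this loop for
binary outcomes scored by AUC, together with synthetic generators that
make the whole pipeline testable at desk scale, and power analyses for
two-group comparisons of modelling workflows.

## EAV pivoting

Pivoting follows a map/reduce contract. The map step turns each EAV tuple
into a key–value pair (key = entity, value = (attribute, value)) *only if*
the attribute is wanted, so tuples for unneeded parameters are discarded
before any grouping work. The reduce step combines all pairs sharing an
entity — possibly drawn from several source tables — into one relational
row, with wanted attributes never observed coming out as nulls. A batch
of queries over the same sources shares a single scan, and each batch
output is identical to the standalone pivot. The contract is a
specification, not an execution mandate: the implementation is a
single-machine streaming engine, with an optional hash-partitioned
external mode (`n_partitions`) for sources larger than memory.

Decisions where the layout leaves room:

* **Duplicate (entity, attribute) measurements** are resolved by a
  configurable policy {first, last, error}, default `last` under the
  declared ordering (source index, row index) — repeated measurements are
  common in EMR extracts and latest-wins is the usual convention.
* **Entity scope**: by default only entities observed with at least one
  wanted tuple appear (a consequence of early filtering); a roster can be
  supplied when a full cohort with nulls is needed.
* **Values stay text** through pivoting; numeric coercion happens at
  modelling time, so extraction is lossless. Output CSV is RFC 4180,
  UTF-8, header row, empty string for null.
* The entity is an opaque join key; no structure (patient id, timestamp)
  is imposed on it computationally.
* When the same attribute appears in several source tables with
  conflicting values, the clash is treated as an ordinary duplicate under
  the configured policy rather than an error.

## The search space

Each algorithm is described by a spec: hyper-parameters of kind
categorical / integer / continuous / log-continuous, with defaults and
optional condition edges (a parameter is relevant only for certain values
of a parent — e.g. second-layer units only when a network has two
layers). Condition edges form a DAG, so combinations are built root to
leaf and carry exactly the active parameters. Distinct SVM kernels are
distinct algorithms. The choice of feature-selection technique is a
root-level hyper-parameter of every combination, with `none` always
available; the shipped selector is univariate top-k (ANOVA F) with the
kept fraction as its own parameter, and it never drops forced-inclusion
features.

For the surrogate model a combination is encoded as a fixed-length
vector over *all* of the spec's parameters: inactive conditionals are
imputed with their defaults, categoricals are integer-coded by domain
order, and log-continuous values are encoded on the log scale. This
integer/default encoding was chosen for compatibility with tree-ensemble
surrogates, which split on thresholds and need no one-hot expansion.

The default registry holds eight base algorithms (logistic regression,
decision tree, k-nearest-neighbour, Gaussian naive Bayes, linear- and
RBF-kernel SVM, random forest, MLP — the MLP carrying the canonical
conditional parameter), one meta algorithm (bagging) and one ensemble
(soft voting), with decision tree, k-NN and logistic regression flagged
interpretable. The pool is representative, not canonical; it is
extensible through a YAML declaration without code changes, and user
allowlists / interpretable-only mode are applied as registry filters
before round 1. Voting members are drawn from the probability-capable
bases, since soft voting needs class probabilities.

## Sampling schedule

One uniform random sort key is drawn per instance; instances sorted by
the key form a fixed permutation (ties broken by original index for
determinism). The first `n_test` (default 3000) instances are the test
sample in every round; the next `n_k` are round k's training sample.
The initial training size is max(1000, 10 × number of features) and
doubles each round, capped by the data. Training samples are therefore
prefix-nested and always disjoint from the test sample.

Small-data fallback: when the data cannot host the configured test sample
plus the initial training sample, `n_test` shrinks to at most a third of
the data and training is capped at the remainder — this keeps a
relatively large disjoint held-out sample while making the procedure
runnable on small fixtures.

## The progressive search

Round 1 evaluates, for every base algorithm, its default combination plus
`n_random_init` (default 10) random ones. Every evaluation trains on the
round's training sample only and scores the fixed test sample; a backend
training failure is penalized with AUC 0 rather than aborting. A
combination trailing the algorithm's round best by at least the accuracy
difference threshold τ becomes *unpromising*; an algorithm trailing the
global round best by at least τ is *eliminated*. τ starts at 0.4 and
falls by 0.07 per round to a floor of 0.05 — with these defaults the
floor is reached at round 6, which is the last filtering round. A single
τ serves both filtering levels by default, with optional separate
overrides.

In each later round, promising combinations are re-measured on the
doubled training sample, giving the ratio r = E2/E1 per combination and
its mean avg_r over survivors. Unpromising combinations are not
retrained; their estimate is rolled forward as previous estimate × avg_r,
capped at 1, and flagged *extrapolated*. Extrapolated values feed only
the per-algorithm surrogate — never an elimination comparison and never
the final selection (the audit trace records the kind of every estimate
so this is checkable).

Per surviving algorithm, a random-forest surrogate is fitted from encoded
combinations to their current estimates (all combinations tested so far,
measured or extrapolated; unavailable below two points) and
`smbo_iters_per_round` (default 8) propose/evaluate/update cycles run.
Odd iterations propose the expected-improvement maximizer over a random
candidate pool of 500 valid combinations, with EI uncertainty taken from
the per-tree prediction spread and ties broken uniformly at random; even
iterations propose uniformly at random, keeping exploration robust when
the surrogate is misdirected. An already-evaluated combination is never
re-proposed (bounded resampling; a finite space can signal exhaustion).

Meta and ensemble algorithms enter at round `base_only_rounds + 1`
(default 5). Their base-selection domains are frozen at entry to the base
algorithms never eliminated *before* entry, and members keep their
eligibility even if later eliminated as standalone candidates. Their
searched parameters are base-selection and combination-control only; the
wrapped bases' own hyper-parameters are pinned to the best values found
for those bases so far. Within such rounds base algorithms are evaluated
before meta/ensemble ones.

After the last filtering round the promising pair with the highest
measured accuracy wins. The final round either trains it on everything
outside the test sample (`full-data`, default) or keeps doubling the
training sample until the relative accuracy gain over one doubling falls
below `convergence_tol` (`convergence` mode). If the final AUC falls
below 0.8 the result carries an advisory flag suggesting that more
clinical parameters be extracted.

Seed discipline: one master seed drives the sampling permutation,
per-algorithm proposal streams, surrogate seeds and per-evaluation model
seeds through a stable hash derivation, so a search trace is exactly
reproducible.

Open points resolved here: the "pre-determined number of rounds (e.g.,
5)" is read as five *decrements* (the only reading under which
0.4 − 5 × 0.07 = 0.05), exposed as `n_decrements`; the surrogate
iteration budget is per algorithm, not global; extrapolations stop
updating once an algorithm is eliminated (moot for selection either way).

## Model evaluation and reporting

AUC is the Mann–Whitney probability that a random positive outscores a
random negative, ties half-credited (computed via scikit-learn; the test
suite cross-checks against brute-force pair counting). ROC points are
produced per distinct threshold and their trapezoidal area equals the
AUC. Backward feature elimination retrains the winning combination,
repeatedly dropping the non-forced feature whose removal least reduces
test-sample AUC; the ranking is the reverse removal order with forced
features at the head, and the reported cumulative accuracy for prefix k
is the test AUC of the model retrained on the top-k features. Scoring
uses the single held-out test sample rather than cross-validation,
consistent with the search's train-on-one-sample/test-on-another
protocol and far cheaper. Non-numeric feature columns are one-hot
expanded for numeric backends, with the expansion recorded so rankings
report original clinical parameters. Feature-construction SQL runs on an
embedded SQLite engine over registered wide tables.

## Synthetic data

`generate_eav` draws a wide ground-truth table (patient-visit entities,
lab-test attributes, values as fixed-precision decimal strings so CSV
round trips are byte-exact), melts it to EAV, then applies per-cell
missingness and injects duplicate measurements. An injected duplicate is
a perturbed copy placed *before* the true value, so policy `last`
provably recovers the ground truth and policy `first` provably differs —
duplicate behaviour is fully predictable in tests. Optionally the records
are split across two tables by attribute parity to exercise the
multi-table pivot.

`generate_gaussian_task` draws two spherical Gaussian classes N(0, I) and
N(m, I) with equal priors; the Bayes-optimal AUC has the closed form
Φ(‖m‖/√2), giving an absolute quality target (‖m‖ = 2 ⇒ AUC ≈ 0.921).
`generate_xor_task` labels instances by sign disagreement of the first
two coordinates with 5% label noise: every linear score tends to AUC 0.5
in large samples while axis-aligned partitioning reaches ≥ 0.9, which
separates model families by design. All generators are deterministic
under their seed.

These generators emulate structure, not clinical realism: values are
Gaussian rather than coded (no ICD codes or dispensing patterns),
missingness is completely at random, and entities carry one visit each.
Passing tests therefore demonstrate the mechanics of pivoting, filtering
and search on data with known geometry — not performance on real EMR
extracts.

## Power analyses

Both computations live on the scale of a standardized mean difference
(Cohen's d) between two independent groups of per-analyst AUC outcomes,
treating per-participant AUCs as independent measures. The one-sided
two-sample t-test power uses the noncentral t with df = 2n − 2 and
noncentrality d·√(n/2). TOST equivalence power — both one-sided tests at
level α within limits (L, U) on the d scale — is computed exactly by
integrating the normal probability of the rejection window over the
scaled-chi distribution of the pooled standard deviation, and is
cross-checked by Monte-Carlo simulation of the tests (analytic and
100k-replicate simulated values agree within 0.01). With n = 25 per
group, α = 0.05: d = 0.7 gives one-sided power 0.787, and d = 1.29 with
limits ±2 gives TOST power 0.797 — both design points round to the
conventional 80%.

## Problem sizes and numerical choices

The verification suite exercises the search at desk scale as the
package's own choice of test conditions: enumerable-space oracle
comparisons at n = 3000 (five seeds), Bayes-AUC recovery at n = 20 000
with a three-algorithm pool (logistic regression, decision tree,
Gaussian naive Bayes — a pool containing the Bayes-optimal family, so the
closed-form target is attainable), and XOR elimination at n = 6000 with a
two-linear-plus-tree pool. Tolerances follow the generators' stochastic
nature: 0.02 AUC regret against the exhaustive oracle, 0.03 against the
closed-form Bayes AUC. Numerical details: r is defined as 1 when E1 = 0;
extrapolations are capped at 1; EI tie-breaks are uniform; the degenerate
zero-spread EI reduces to plain improvement; standardization precedes
every backend fit.

## Known limitations

* The pivot's external mode partitions by entity hash but still assumes a
  single partition's groups fit in memory.
* Greedy CART needs depth ≥ 4 to reliably find the XOR structure (the
  first split carries no marginal gain), so elimination claims are about
  linear *scores*, not about any specific tree depth.
* Predicting from a fitted search on new data assumes the same feature
  columns (and, for categorical features, the same category set) as at
  fit time.
* No stratification of the test sample by outcome; rare outcomes may need
  a larger test sample than the default.
* Background continuation of fine-tuning after a result is returned,
  distributed execution, and warm-starting from prior problems are out of
  scope.
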