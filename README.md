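# pivotml

Tools for iterative machine learning on clinical data stored in the
Entity–Attribute–Value (EAV) format: a map/reduce-style pivot engine that
turns tall (entity, attribute, value) tables into wide relational tables,
and an efficient automatic search for the best machine-learning algorithm
and hyper-parameter values — the combined algorithm selection and
hyper-parameter optimization (CASH) problem — built on progressive
sampling, an accuracy-difference elimination threshold, and per-algorithm
model-based optimization. It is aimed at risk-prediction work on
binary-outcome clinical tables where training candidates on the full data
set is too expensive to do exhaustively.

## The method in brief

**Pivoting.** A map step emits one key–value pair (entity → (attribute,
value)) per EAV tuple *only* when the attribute is wanted, filtering
unneeded clinical parameters before any grouping; a reduce step combines
all pairs per entity, possibly across several source tables, into one
relational row. Several queries over the same sources share a single
scan, and an external hash-partitioned mode handles sources larger than
memory.

**Search.** A fixed random permutation of the data yields a held-out test
sample (n_test = 3000) and nested training samples starting at
max(1000, 10·p) instances (p = number of features) and doubling each
round. In round k every surviving combination is trained on the round's
sample and scored by AUC on the test sample; a combination trailing its
algorithm's best by ≥ τ is marked unpromising, and an algorithm trailing
the global best by ≥ τ is eliminated, with τ = max(0.05, 0.4 − 0.07(k−1)).
Discarded combinations are never retrained — their accuracy is
extrapolated by the survivors' mean accuracy ratio avg_r = mean(E2/E1)
and feeds only the per-algorithm random-forest surrogate that proposes
new combinations (expected-improvement maximizer over a random candidate
pool, every second proposal purely random). Meta (bagging) and ensemble
(voting) algorithms enter after four base-only rounds, selecting among
the surviving bases with the bases' own hyper-parameters pinned to the
best values found. After τ reaches its floor, the best measured pair is
retrained on all non-test data and reported with its held-out AUC, ROC
points and a backward-elimination feature ranking.

**Study design support.** Power of a one-sided two-sample t-test and of
the TOST equivalence procedure on the standardized-difference (Cohen's d)
scale, computed from the noncentral t distribution.

See `docs/methods.md` for assumptions, defaults and design decisions.

## Worked example

Pivot a small synthetic EAV table (three lab tests per patient visit):

```python
import pivotml as pm
from pivotml.eav import EAVSource, PivotQuery, pivot

tables, truth = pm.generate_eav(pm.SyntheticSpec(n_patients=4, seed=0))
wide = pivot(PivotQuery([EAVSource(tables[0])], ["test 1", "test 2", "test 3"]))
print(wide.to_string(index=False))
```

```
  entity test 1 test 2 test 3
p0001-t1 101.89  98.02 109.61
p0002-t1 101.57  91.96 105.42
p0003-t1 119.56 114.21  89.44
p0004-t1  81.02  90.65 100.62
```

Search for the best algorithm and hyper-parameters on a Gaussian task
whose Bayes-optimal AUC is known in closed form (Φ(‖m‖/√2) ≈ 0.9214 at
separation ‖m‖ = 2):

```python
data = pm.Dataset(pm.generate_gaussian_task(pm.SyntheticSpec(
    n_instances=5000, n_features=3, class_separation=2.0, seed=11)))
pool = pm.default_registry().filtered(
    algorithms=["logistic", "decision_tree", "gaussian_nb"])
result = pm.search(data, pm.SearchConfig(seed=11), pool)
print("best:", result.best_combination.label())
print("final AUC: %.4f" % result.final_auc)
```

```
best: logistic(C=91.89) | sel=kbest
final AUC: 0.9185
```

The winner is a logistic regression (the Bayes-optimal family for this
task) with a univariate feature selector, and its held-out AUC is within
0.003 of the theoretical optimum. `result.trace` holds the full audit
trail — per round: τ, sample sizes, every evaluation with its kind
(measured vs extrapolated), and eliminations. The same search is
available as a scikit-learn classifier
(`pm.ProgressiveSearchClassifier(...).fit(X, y)`) and from the shell:

```bash
pivotml simulate gaussian --out data --n 5000 --features 3 --seed 11
pivotml search --data data/gaussian.csv --algorithms logistic,decision_tree,gaussian_nb --out run
pivotml power tost --n 25 --d 1.29 --limits -2 2   # prints 0.7967
```

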