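"""Progressive-sampling automatic algorithm and hyper-parameter search.

The search answers the combined algorithm-selection / hyper-parameter
question (CASH) for a binary-outcome table without ever paying full-data
training cost for weak candidates.  It proceeds in rounds over a nested
sequence of random training samples (doubling each round) with one fixed
disjoint test sample:

* Round 1 evaluates, for every applicable base algorithm, its default
  hyper-parameter combination plus a handful of random ones, then
  eliminates algorithms and marks combinations unpromising when they trail
  the best by at least the accuracy-difference threshold tau.
* Each later round re-evaluates the surviving (promising) combinations on
  the enlarged training sample, runs a few iterations of sequential
  model-based optimization per surviving algorithm — a random-forest
  surrogate over encoded combinations proposes expected-improvement
  maximizers, every second proposal drawn at random instead — and filters
  again with a linearly decreasing tau.
* Combinations marked unpromising are never retrained; their accuracy is
  extrapolated by the surviving combinations' average accuracy ratio
  avg_r = mean(E2/E1) so they can still inform the surrogate (never an
  elimination or the final selection).
* Meta (bagging) and ensemble (voting) algorithms enter only after a few
  base-only rounds, selecting among the bases alive at entry, with the
  wrapped bases' own hyper-parameters pinned to the best values found;
  a base eliminated as a standalone candidate may live on inside them.
* Once tau has reached its floor the best measured pair wins, and a final
  round trains it on the whole non-test data (or grows the sample until
  the learning curve flattens) and reports held-out AUC.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.utils.validation import check_is_fitted

from .metrics import Dataset, accuracy_prompt, compute_auc, roc_points
from .modeling import build_estimator, decision_scores, evaluate_on_split
from .sampling import SampleSchedule, ScheduleConfig, build_schedule
from .space import (
    AlgorithmSpec,
    Combination,
    Registry,
    default_combination,
    default_registry,
    encode_for_surrogate,
    sample_random_combination,
)

__all__ = [
    "SearchConfig",
    "CombinationRecord",
    "AlgorithmState",
    "SearchResult",
    "tau_at_round",
    "evaluate_combination",
    "filter_combinations",
    "filter_algorithms",
    "extrapolate_unpromising",
    "fit_surrogate",
    "propose_next",
    "search",
    "ProgressiveSearchClassifier",
]

MEASURED = "measured"
EXTRAPOLATED = "extrapolated"


@dataclass
class SearchConfig:
    """Tunable knobs of the search; defaults follow the published protocol."""

    tau_init: float = 0.4
    tau_decrement: float = 0.07
    tau_min: float = 0.05
    tau_algorithms: float | None = None  # optional separate thresholds
    tau_combinations: float | None = None
    n_random_init: int = 10
    smbo_iters_per_round: int = 8
    base_only_rounds: int = 4
    n_decrements: int = 5
    metric: str = "auc"
    auc_prompt_threshold: float = 0.8
    candidate_pool_size: int = 500
    final_mode: str = "full-data"  # or "convergence"
    convergence_tol: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.tau_min <= self.tau_init <= 1:
            raise ValueError("need 0 < tau_min <= tau_init <= 1")
        if self.tau_decrement <= 0:
            raise ValueError("tau_decrement must be positive")
        for name in ("n_random_init", "smbo_iters_per_round", "n_decrements",
                     "candidate_pool_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.base_only_rounds < 0:
            raise ValueError("base_only_rounds must be >= 0")
        if self.final_mode not in ("full-data", "convergence"):
            raise ValueError(f"unknown final_mode {self.final_mode!r}")

    @property
    def n_rounds(self) -> int:
        """Rounds of filtering: the first round plus one per decrement."""
        return self.n_decrements + 1


def tau_at_round(config: SearchConfig, round_k: int) -> float:
    """Linearly decreasing threshold, floored at tau_min; round 1 = tau_init."""
    if round_k < 1:
        raise ValueError("round_k must be >= 1")
    return max(config.tau_min,
               config.tau_init - config.tau_decrement * (round_k - 1))


@dataclass
class CombinationRecord:
    """Per-combination accuracy history across rounds."""

    combination: Combination
    status: str = "promising"  # or "unpromising"
    history: list[tuple[int, float, str]] = field(default_factory=list)
    E1: float | None = None  # previous-round measured estimate
    E2: float | None = None  # current measured estimate
    r: float | None = None  # accuracy ratio E2/E1

    @property
    def current_estimate(self) -> float | None:
        return self.history[-1][1] if self.history else None

    @property
    def current_kind(self) -> str | None:
        return self.history[-1][2] if self.history else None

    def measured_at(self, round_k: int) -> float | None:
        for rk, est, kind in reversed(self.history):
            if rk == round_k and kind == MEASURED:
                return est
        return None

    def record_measured(self, round_k: int, accuracy: float) -> None:
        self.E1, self.E2 = self.E2, accuracy
        if self.E1 is not None:
            self.r = 1.0 if self.E1 == 0 else self.E2 / self.E1
        self.history.append((round_k, accuracy, MEASURED))


@dataclass
class AlgorithmState:
    """Per-algorithm search status, records, surrogate, and RNG stream."""

    spec: AlgorithmSpec
    status: str = "active"  # or "eliminated"
    records: list[CombinationRecord] = field(default_factory=list)
    avg_r: float | None = None
    surrogate: RandomForestRegressor | None = None
    entered_round: int = 1
    rng: np.random.Generator | None = None
    _evaluated: set[Combination] = field(default_factory=set)

    def promising(self) -> list[CombinationRecord]:
        return [rec for rec in self.records if rec.status == "promising"]

    def best_measured(self, round_k: int) -> tuple[CombinationRecord | None, float]:
        """Best combination measured in the given round (never extrapolated)."""
        best, best_acc = None, -np.inf
        for rec in self.records:
            est = rec.measured_at(round_k)
            if est is not None and est > best_acc:
                best, best_acc = rec, est
        return best, best_acc

    def add_record(self, round_k: int, combo: Combination, accuracy: float) -> CombinationRecord:
        rec = CombinationRecord(combo)
        rec.record_measured(round_k, accuracy)
        self.records.append(rec)
        self._evaluated.add(combo)
        return rec


@dataclass
class SearchResult:
    """Winning combination, final model, held-out accuracy and audit trace."""

    best_combination: Combination
    model: Any
    final_auc: float
    trace: list[dict]
    advisory_low_accuracy: bool
    roc: list[tuple[float, float, float]] = field(default_factory=list)
    n_rounds: int = 0
    final_train_size: int = 0


def _stable_seed(*parts: Any) -> int:
    digest = hashlib.md5("|".join(map(str, parts)).encode()).hexdigest()
    return int(digest[:8], 16) % (2**31 - 1)


def evaluate_combination(
    combo: Combination,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    data: Dataset,
    registry: Registry,
    seed: int = 0,
    make_base: Callable | None = None,
) -> float:
    """Train on the training rows only and score the disjoint test rows.

    A backend training failure is penalized with the metric minimum (0.0)
    rather than aborting the search.
    """
    model_seed = _stable_seed(seed, combo)
    try:
        return evaluate_on_split(
            data, combo, registry, train_idx, test_idx,
            random_state=model_seed, make_base=make_base,
        )
    except Exception:
        return 0.0


def filter_combinations(state: AlgorithmState, tau: float, round_k: int) -> list[Combination]:
    """Mark combinations trailing the algorithm's round best by >= tau.

    Only estimates measured this round participate; the best record always
    stays promising.  Returns the newly unpromising combinations.
    """
    best_rec, best_acc = state.best_measured(round_k)
    if best_rec is None:
        return []
    newly: list[Combination] = []
    for rec in state.records:
        if rec.status != "promising":
            continue
        est = rec.measured_at(round_k)
        if est is None:
            continue
        if rec is not best_rec and best_acc - est >= tau:
            rec.status = "unpromising"
            newly.append(rec.combination)
    assert best_rec.status == "promising"  # incumbent safety
    return newly


def filter_algorithms(
    states: Sequence[AlgorithmState], tau: float, round_k: int
) -> list[str]:
    """Eliminate algorithms whose round best trails the global best by >= tau."""
    active = [s for s in states if s.status == "active"]
    bests = {s.spec.id: s.best_measured(round_k)[1] for s in active}
    scored = {k: v for k, v in bests.items() if np.isfinite(v)}
    if not scored:
        return []
    global_best = max(scored.values())
    leader = max(scored, key=lambda k: scored[k])
    eliminated: list[str] = []
    for state in active:
        acc = bests[state.spec.id]
        if state.spec.id != leader and np.isfinite(acc) and global_best - acc >= tau:
            state.status = "eliminated"
            eliminated.append(state.spec.id)
    assert any(s.status == "active" for s in states)  # best always survives
    return eliminated


def extrapolate_unpromising(
    record: CombinationRecord, avg_r: float, round_k: int
) -> float:
    """Rough estimate for a discarded combination: previous estimate x avg_r.

    Capped at 1; flagged extrapolated, so it feeds only the surrogate and
    never an elimination or the final selection.
    """
    prior = record.current_estimate
    if prior is None:
        raise ValueError("no prior estimate to extrapolate from")
    rough = min(1.0, prior * avg_r)
    record.history.append((round_k, rough, EXTRAPOLATED))
    return rough


def fit_surrogate(
    state: AlgorithmState, registry: Registry, seed: int = 0
) -> RandomForestRegressor | None:
    """Tree-ensemble regressor from encoded combinations to accuracy.

    Trained on every combination tested for the algorithm so far, using
    the current estimate (measured where available, extrapolated
    otherwise); unavailable with fewer than two records.
    """
    records = [rec for rec in state.records if rec.current_estimate is not None]
    if len(records) < 2:
        state.surrogate = None
        return None
    X = np.vstack([
        encode_for_surrogate(rec.combination, state.spec, registry.selector_pool)
        for rec in records
    ])
    y = np.array([rec.current_estimate for rec in records])
    model = RandomForestRegressor(
        n_estimators=30, random_state=_stable_seed(seed, state.spec.id, "surrogate"),
        n_jobs=1,
    )
    model.fit(X, y)
    state.surrogate = model
    return model


def _expected_improvement(
    surrogate: RandomForestRegressor, X: np.ndarray, best: float
) -> np.ndarray:
    per_tree = np.stack([tree.predict(X) for tree in surrogate.estimators_])
    mu = per_tree.mean(axis=0)
    sigma = per_tree.std(axis=0)
    ei = np.maximum(0.0, mu - best)  # degenerate spread: plain improvement
    spread = sigma > 0
    z = (mu[spread] - best) / sigma[spread]
    ei[spread] = (mu[spread] - best) * stats.norm.cdf(z) + sigma[spread] * stats.norm.pdf(z)
    return ei


def propose_next(
    state: AlgorithmState,
    iteration_index: int,
    registry: Registry,
    config: SearchConfig,
    round_best: float,
    max_tries: int = 50,
) -> Combination | None:
    """Next combination to test: EI maximizer on odd iterations, random on even.

    Candidates come from a random pool of valid combinations; already
    evaluated combinations are never re-proposed (None signals an
    exhausted space).  Without a surrogate the proposal falls back to
    random regardless of parity.
    """
    rng = state.rng or np.random.default_rng(0)
    use_surrogate = iteration_index % 2 == 1 and state.surrogate is not None
    if use_surrogate:
        pool: list[Combination] = []
        seen: set[Combination] = set()
        for _ in range(config.candidate_pool_size):
            c = sample_random_combination(state.spec, rng, registry.selector_pool)
            if c not in state._evaluated and c not in seen:
                pool.append(c)
                seen.add(c)
        if not pool:
            return None
        X = np.vstack([
            encode_for_surrogate(c, state.spec, registry.selector_pool) for c in pool
        ])
        ei = _expected_improvement(state.surrogate, X, round_best)
        winners = np.flatnonzero(ei == ei.max())
        return pool[int(rng.choice(winners))]
    for _ in range(max_tries):
        c = sample_random_combination(state.spec, rng, registry.selector_pool)
        if c not in state._evaluated:
            return c
    return None


# ---------------------------------------------------------------------------
# The round engine.
# ---------------------------------------------------------------------------


class _Engine:
    def __init__(
        self,
        data: Dataset,
        registry: Registry,
        config: SearchConfig,
        schedule: SampleSchedule,
    ):
        self.data = data
        self.registry = registry
        self.config = config
        self.schedule = schedule
        self.test_idx = schedule.test_sample()
        self.states: list[AlgorithmState] = []
        self.trace: list[dict] = []
        # Best measured combination per base algorithm, for pinning the
        # base-passthrough hyper-parameters of meta/ensemble algorithms.
        self.best_base: dict[str, tuple[float, Combination]] = {}
        self._round_evals: list[dict] = []

    # -- plumbing ----------------------------------------------------------

    def _state_for(self, spec: AlgorithmSpec, round_k: int) -> AlgorithmState:
        rng = np.random.default_rng(_stable_seed(self.config.seed, spec.id, "proposals"))
        return AlgorithmState(spec=spec, entered_round=round_k, rng=rng)

    def make_base(self, base_id: str):
        """Fresh base estimator with its best hyper-parameters found so far."""
        spec = self.registry[base_id]
        if base_id in self.best_base:
            combo = self.best_base[base_id][1]
        else:
            combo = default_combination(spec)
        seed = _stable_seed(self.config.seed, base_id, "as-member")
        return spec.backend(combo.param_dict, seed)

    def _evaluate(
        self, state: AlgorithmState, combo: Combination, round_k: int,
        train_idx: np.ndarray,
    ) -> float:
        acc = evaluate_combination(
            combo, train_idx, self.test_idx, self.data, self.registry,
            seed=self.config.seed,
            make_base=self.make_base if state.spec.category != "base" else None,
        )
        self._round_evals.append({
            "algorithm": state.spec.id, "combination": combo.label(),
            "accuracy": acc, "kind": MEASURED, "n_train": len(train_idx),
        })
        if state.spec.category == "base":
            if base := self.best_base.get(state.spec.id):
                if acc > base[0]:
                    self.best_base[state.spec.id] = (acc, combo)
            else:
                self.best_base[state.spec.id] = (acc, combo)
        return acc

    # -- round phases ------------------------------------------------------

    def _enter_algorithms(self, round_k: int) -> None:
        """Instantiate states for algorithms entering this round."""
        entry_meta = round_k == self.config.base_only_rounds + 1
        for spec in self.registry.algorithms.values():
            if spec.category == "base" and round_k == 1:
                self.states.append(self._state_for(spec, round_k))
            elif spec.category != "base" and entry_meta:
                frozen = self._freeze_selection(spec)
                if frozen is not None:
                    self.states.append(self._state_for(frozen, round_k))

    def _freeze_selection(self, spec: AlgorithmSpec) -> AlgorithmSpec | None:
        """Restrict base-selection domains to the bases alive at entry."""
        alive = {
            s.spec.id for s in self.states
            if s.spec.category == "base" and s.status == "active"
        }
        for p in spec.hyperparameters:
            if spec.roles.get(p.name) != "base-selection":
                continue
            keep_none = "none" in p.domain
            domain = tuple(b for b in p.domain if b in alive)
            if not domain:
                return None
            if keep_none:
                domain = domain + ("none",)
            default = p.default if p.default in domain else domain[0]
            spec = spec.with_domain(p.name, domain, default)
        return spec

    def _initial_evaluations(self, state: AlgorithmState, round_k: int,
                             train_idx: np.ndarray) -> None:
        """Default combination plus n_random_init random ones, deduplicated."""
        combos = [default_combination(state.spec)]
        rng = state.rng
        for _ in range(self.config.n_random_init):
            for _ in range(50):
                c = sample_random_combination(state.spec, rng, self.registry.selector_pool)
                if c not in state._evaluated and c not in combos:
                    combos.append(c)
                    break
        for combo in combos:
            if combo in state._evaluated:
                continue
            acc = self._evaluate(state, combo, round_k, train_idx)
            state.add_record(round_k, combo, acc)

    def _reevaluate_promising(self, state: AlgorithmState, round_k: int,
                              train_idx: np.ndarray) -> None:
        ratios = []
        for rec in state.promising():
            acc = self._evaluate(state, rec.combination, round_k, train_idx)
            rec.record_measured(round_k, acc)
            if rec.r is not None:
                ratios.append(rec.r)
        state.avg_r = float(np.mean(ratios)) if ratios else None

    def _refresh_extrapolations(self, state: AlgorithmState, round_k: int) -> None:
        if state.avg_r is None:
            return
        for rec in state.records:
            if rec.status == "unpromising":
                extrapolate_unpromising(rec, state.avg_r, round_k)
                self._round_evals.append({
                    "algorithm": state.spec.id, "combination": rec.combination.label(),
                    "accuracy": rec.current_estimate, "kind": EXTRAPOLATED,
                    "n_train": 0,
                })

    def _smbo(self, state: AlgorithmState, round_k: int, train_idx: np.ndarray) -> None:
        fit_surrogate(state, self.registry, seed=self.config.seed)
        for iteration in range(1, self.config.smbo_iters_per_round + 1):
            _, round_best = state.best_measured(round_k)
            if not np.isfinite(round_best):
                round_best = 0.0
            combo = propose_next(state, iteration, self.registry, self.config, round_best)
            if combo is None:
                break  # space exhausted
            acc = self._evaluate(state, combo, round_k, train_idx)
            state.add_record(round_k, combo, acc)
            fit_surrogate(state, self.registry, seed=self.config.seed)

    # -- rounds ------------------------------------------------------------

    def run_round(self, round_k: int) -> None:
        config = self.config
        tau = tau_at_round(config, round_k)
        tau_alg = config.tau_algorithms if config.tau_algorithms is not None else tau
        tau_comb = config.tau_combinations if config.tau_combinations is not None else tau
        train_idx = self.schedule.training_sample(round_k)
        self._round_evals = []
        self._enter_algorithms(round_k)

        # Base algorithms are evaluated before meta/ensemble ones.
        ordered = sorted(
            (s for s in self.states if s.status == "active"),
            key=lambda s: s.spec.category != "base",
        )
        for state in ordered:
            if state.entered_round == round_k:
                self._initial_evaluations(state, round_k, train_idx)
            else:
                self._reevaluate_promising(state, round_k, train_idx)
                self._refresh_extrapolations(state, round_k)
                self._smbo(state, round_k, train_idx)

        newly_unpromising: dict[str, list[str]] = {}
        for state in ordered:
            dropped = filter_combinations(state, tau_comb, round_k)
            if dropped:
                newly_unpromising[state.spec.id] = [c.label() for c in dropped]
        eliminated = filter_algorithms(self.states, tau_alg, round_k)

        best_state, best_rec, best_acc = self._overall_best(round_k)
        self.trace.append({
            "round": round_k,
            "tau": tau,
            "n_train": len(train_idx),
            "n_test": len(self.test_idx),
            "evaluations": self._round_evals,
            "newly_unpromising": newly_unpromising,
            "eliminated_algorithms": eliminated,
            "active_algorithms": [s.spec.id for s in self.states if s.status == "active"],
            "best": {
                "algorithm": best_state.spec.id if best_state else None,
                "combination": best_rec.combination.label() if best_rec else None,
                "accuracy": best_acc if np.isfinite(best_acc) else None,
                "kind": MEASURED,
            },
        })

    def _overall_best(self, round_k: int):
        best_state, best_rec, best_acc = None, None, -np.inf
        for state in self.states:
            if state.status != "active":
                continue
            rec, acc = state.best_measured(round_k)
            if rec is not None and acc > best_acc:
                best_state, best_rec, best_acc = state, rec, acc
        return best_state, best_rec, best_acc

    def run_final_round(self, best_state: AlgorithmState, best_rec: CombinationRecord):
        """Train the winning pair on (a large part of) the whole data set."""
        config = self.config
        combo = best_rec.combination
        make_base = self.make_base if best_state.spec.category != "base" else None
        model_seed = _stable_seed(config.seed, combo)

        if config.final_mode == "full-data":
            train_idx = self.schedule.full_training_sample()
        else:
            last_round = config.n_rounds
            n = self.schedule.training_size(last_round)
            prev_acc = None
            while True:
                train_idx = self.schedule.permutation[
                    self.schedule.n_test : self.schedule.n_test + n
                ]
                acc = evaluate_combination(
                    combo, train_idx, self.test_idx, self.data, self.registry,
                    seed=config.seed, make_base=make_base,
                )
                if prev_acc is not None:
                    denom = prev_acc if prev_acc > 0 else 1.0
                    if (acc - prev_acc) / denom < config.convergence_tol:
                        break
                prev_acc = acc
                if n >= self.schedule.max_training:
                    break
                n = min(int(n * self.schedule.growth_factor), self.schedule.max_training)

        X, _, groups = self.data.encode()
        y = self.data.y
        forced_idx = tuple(
            i for f in self.data.forced_include for i in groups.get(f, [])
        )
        model = build_estimator(
            combo, self.registry, random_state=model_seed,
            make_base=make_base, forced_idx=forced_idx,
        )
        model.fit(X[train_idx], y[train_idx])
        scores = decision_scores(model, X[self.test_idx])
        final_auc = compute_auc(scores, y[self.test_idx])
        roc = roc_points(scores, y[self.test_idx])
        self.trace.append({
            "round": "final",
            "mode": config.final_mode,
            "n_train": len(train_idx),
            "combination": combo.label(),
            "accuracy": final_auc,
            "kind": MEASURED,
        })
        return model, final_auc, roc, len(train_idx)

    def run(self) -> SearchResult:
        config = self.config
        for round_k in range(1, config.n_rounds + 1):
            self.run_round(round_k)
        best_state, best_rec, _ = self._overall_best(config.n_rounds)
        if best_rec is None:
            raise RuntimeError("search produced no measured evaluations")
        model, final_auc, roc, n_train = self.run_final_round(best_state, best_rec)
        return SearchResult(
            best_combination=best_rec.combination,
            model=model,
            final_auc=final_auc,
            trace=self.trace,
            advisory_low_accuracy=accuracy_prompt(final_auc, config.auc_prompt_threshold),
            roc=roc,
            n_rounds=config.n_rounds,
            final_train_size=n_train,
        )


def search(
    data: Dataset,
    config: SearchConfig | None = None,
    registry: Registry | None = None,
    schedule_config: ScheduleConfig | None = None,
) -> SearchResult:
    """Run the full progressive search on a dataset; see the module docstring."""
    config = config or SearchConfig()
    registry = registry or default_registry()
    schedule = build_schedule(
        len(data.frame), data.n_features, schedule_config, seed=config.seed
    )
    engine = _Engine(data, registry, config, schedule)
    result = engine.run()
    return result


class ProgressiveSearchClassifier(ClassifierMixin, BaseEstimator):
    """Automatic algorithm + hyper-parameter selection as a classifier.

    Fitting runs the progressive-sampling search over the configured
    algorithm registry and refits the winning combination; the fitted
    object then predicts like any scikit-learn classifier.

    Parameters
    ----------
    config : SearchConfig, optional
        Search thresholds, budgets and seed (defaults follow the protocol:
        tau 0.4 decreasing by 0.07 to a floor of 0.05, 10 random initial
        combinations, 8 surrogate iterations per round, 4 base-only rounds).
    registry : Registry, optional
        Algorithm/selector pool; defaults to the built-in pool.
    algorithms : list of str, optional
        Allowlist of algorithm ids to explore.
    selectors : list of str, optional
        Allowlist of feature-selection techniques ('none' always kept).
    interpretable_only : bool
        Restrict the pool to interpretable model families.
    forced_include : sequence of str, optional
        Feature names that must appear in every model.
    schedule_config : ScheduleConfig, optional
        Test-sample size and training-sample growth rules.

    Attributes
    ----------
    best_combination_ : Combination
        The winning algorithm + hyper-parameter assignment.
    best_estimator_ : sklearn estimator
        The final model, trained in the final round.
    best_score_ : float
        Held-out test-sample AUC of the final model.
    result_ : SearchResult
        Full audit trace (per-round tau, evaluations, eliminations).
    advisory_low_accuracy_ : bool
        Set when the final AUC falls below the acceptability threshold,
        suggesting that more clinical parameters be extracted.
    """

    def __init__(
        self,
        config: SearchConfig | None = None,
        registry: Registry | None = None,
        algorithms: Sequence[str] | None = None,
        selectors: Sequence[str] | None = None,
        interpretable_only: bool = False,
        forced_include: Sequence[str] | None = None,
        schedule_config: ScheduleConfig | None = None,
    ):
        self.config = config
        self.registry = registry
        self.algorithms = algorithms
        self.selectors = selectors
        self.interpretable_only = interpretable_only
        self.forced_include = forced_include
        self.schedule_config = schedule_config

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            frame = X.copy()
            if y is not None:
                frame["outcome"] = np.asarray(y)
            data = Dataset(frame, outcome="outcome",
                           forced_include=frozenset(self.forced_include or ()))
        else:
            X = np.asarray(X)
            frame = pd.DataFrame(X, columns=[f"x{j + 1}" for j in range(X.shape[1])])
            frame["outcome"] = np.asarray(y)
            data = Dataset(frame, outcome="outcome",
                           forced_include=frozenset(self.forced_include or ()))
        registry = (self.registry or default_registry()).filtered(
            algorithms=self.algorithms,
            selectors=self.selectors,
            interpretable_only=self.interpretable_only,
        )
        result = search(
            data, config=self.config, registry=registry,
            schedule_config=self.schedule_config,
        )
        self.data_ = data
        self.classes_ = np.unique(data.y)
        self.n_features_in_ = data.n_features
        self.result_ = result
        self.best_combination_ = result.best_combination
        self.best_estimator_ = result.model
        self.best_score_ = result.final_auc
        self.trace_ = result.trace
        self.advisory_low_accuracy_ = result.advisory_low_accuracy
        return self

    def _encode_new(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            probe = Dataset(
                X.assign(outcome=np.zeros(len(X), dtype=int) if len(X) else []),
                outcome="outcome",
            )
            # align on the training feature set
            probe.feature_names = self.data_.feature_names
            return probe.encode()[0]
        return np.asarray(X, dtype=float)

    def predict(self, X):
        check_is_fitted(self, "best_estimator_")
        return self.best_estimator_.predict(self._encode_new(X))

    def predict_proba(self, X):
        check_is_fitted(self, "best_estimator_")
        return self.best_estimator_.predict_proba(self._encode_new(X))

    def decision_function(self, X):
        check_is_fitted(self, "best_estimator_")
        return decision_scores(self.best_estimator_, self._encode_new(X))
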