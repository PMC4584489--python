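"""Progressive search: thresholds, filtering, surrogate guidance, rounds."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pivotml.datasets import SyntheticSpec, generate_gaussian_task
from pivotml.metrics import Dataset
from pivotml.modeling import build_estimator, decision_scores
from pivotml.sampling import ScheduleConfig, build_schedule
from pivotml.search import (
    AlgorithmState,
    CombinationRecord,
    SearchConfig,
    _stable_seed,
    evaluate_combination,
    extrapolate_unpromising,
    filter_algorithms,
    filter_combinations,
    fit_surrogate,
    propose_next,
    search,
    tau_at_round,
)
from pivotml.space import (
    AlgorithmSpec,
    Combination,
    FeatureSelectorSpec,
    Registry,
    default_combination,
)
from pivotml.space import _hp as hp


def _toy_backend(params, random_state):
    from sklearn.naive_bayes import GaussianNB
    return GaussianNB()


def quick_config(**kw):
    kw.setdefault("n_random_init", 3)
    kw.setdefault("smbo_iters_per_round", 2)
    kw.setdefault("n_decrements", 2)
    kw.setdefault("candidate_pool_size", 40)
    kw.setdefault("seed", 0)
    return SearchConfig(**kw)


def quick_schedule_config(**kw):
    kw.setdefault("n_test", 150)
    kw.setdefault("initial_const", 150)
    return ScheduleConfig(**kw)


def gaussian_dataset(n=900, separation=2.0, seed=0, n_features=2):
    return Dataset(generate_gaussian_task(SyntheticSpec(
        n_instances=n, n_features=n_features, class_separation=separation, seed=seed)))


def state_with_accuracies(accuracies, round_k=1, name="toy"):
    spec = AlgorithmSpec(name, "base",
                         (hp("p", "continuous", (0.0, 1e6), 1.0),), _toy_backend)
    state = AlgorithmState(spec=spec, rng=np.random.default_rng(0))
    for i, acc in enumerate(accuracies):
        state.add_record(round_k, Combination.make(name, {"p": float(i)}), acc)
    return state


class TestTauSchedule:
    def test_first_round_uses_initial_threshold(self):
        assert tau_at_round(SearchConfig(), 1) == 0.4

    def test_floor_reached_after_five_decrements(self):
        config = SearchConfig()
        assert tau_at_round(config, 6) == pytest.approx(0.05)
        # exactly ceil((0.4 - 0.05) / 0.07) = 5 decrements with the defaults
        assert tau_at_round(config, 5) > 0.05

    def test_far_rounds_stay_floored(self):
        assert tau_at_round(SearchConfig(), 100) == 0.05

    def test_schedule_non_increasing(self):
        config = SearchConfig()
        taus = [tau_at_round(config, k) for k in range(1, 12)]
        assert all(a >= b for a, b in zip(taus, taus[1:]))


class TestFilterCombinations:
    def test_margin_rule(self):
        state = state_with_accuracies([0.90, 0.60, 0.85])
        dropped = filter_combinations(state, 0.26, round_k=1)
        statuses = [rec.status for rec in state.records]
        assert statuses == ["promising", "unpromising", "promising"]
        assert len(dropped) == 1

    def test_boundary_margin_counts_as_unpromising(self):
        state = state_with_accuracies([0.90, 0.85])
        filter_combinations(state, 0.05, round_k=1)
        assert state.records[1].status == "unpromising"

    def test_threshold_above_max_margin_keeps_all(self):
        state = state_with_accuracies([0.90, 0.60, 0.10])
        assert filter_combinations(state, 1.1, round_k=1) == []

    def test_best_record_always_survives(self):
        state = state_with_accuracies([0.5, 0.5, 0.5])
        filter_combinations(state, 0.0001, round_k=1)
        assert any(rec.status == "promising" for rec in state.records)


class TestFilterAlgorithms:
    @staticmethod
    def states(bests):
        return [state_with_accuracies([b], name=f"toy{i}")
                for i, b in enumerate(bests)]

    def test_trailing_algorithm_eliminated(self):
        states = self.states([0.9, 0.45, 0.88])
        gone = filter_algorithms(states, 0.4, round_k=1)
        assert [s.status for s in states] == ["active", "eliminated", "active"]
        assert gone == ["toy1"]

    def test_single_algorithm_never_eliminated(self):
        states = self.states([0.3])
        assert filter_algorithms(states, 0.05, round_k=1) == []

    def test_equal_bests_all_survive(self):
        states = self.states([0.7, 0.7, 0.7])
        filter_algorithms(states, 0.01, round_k=1)
        assert all(s.status == "active" for s in states)


class TestExtrapolation:
    def test_avg_ratio_extrapolation(self):
        rec = CombinationRecord(Combination.make("toy", {"p": 1.0}))
        rec.history.append((1, 0.50, "measured"))
        rec.status = "unpromising"
        rough = extrapolate_unpromising(rec, np.mean([1.10, 1.20]), round_k=2)
        assert rough == pytest.approx(0.575)
        assert rec.history[-1][2] == "extrapolated"

    def test_capped_at_one(self):
        rec = CombinationRecord(Combination.make("toy", {"p": 1.0}))
        rec.history.append((1, 0.95, "measured"))
        assert extrapolate_unpromising(rec, 1.2, round_k=2) == 1.0

    def test_single_ratio_is_its_own_mean(self):
        rec = CombinationRecord(Combination.make("toy", {"p": 1.0}))
        rec.history.append((1, 0.60, "measured"))
        assert extrapolate_unpromising(rec, 1.05, round_k=2) == pytest.approx(0.63)


class TestSurrogate:
    @staticmethod
    def toy_registry():
        spec = AlgorithmSpec("toy", "base",
                             (hp("p", "integer", (1, 30), 1),), _toy_backend)
        return Registry([spec], [FeatureSelectorSpec("none")])

    def test_constant_accuracies_predict_constant(self):
        registry = self.toy_registry()
        state = AlgorithmState(spec=registry["toy"], rng=np.random.default_rng(0))
        for p in (1, 5, 9):
            state.add_record(1, Combination.make("toy", {"p": p}), 0.7)
        model = fit_surrogate(state, registry)
        grid = np.vstack([
            __import__("pivotml.space", fromlist=["encode_for_surrogate"]).encode_for_surrogate(
                Combination.make("toy", {"p": p}), registry["toy"], registry.selector_pool)
            for p in range(1, 30)
        ])
        assert np.allclose(model.predict(grid), 0.7)

    def test_recovers_monotone_signal(self):
        registry = self.toy_registry()
        state = AlgorithmState(spec=registry["toy"], rng=np.random.default_rng(0))
        for p in range(1, 31):
            state.add_record(1, Combination.make("toy", {"p": p}), p / 30.0)
        model = fit_surrogate(state, registry)
        from pivotml.space import encode_for_surrogate
        grid = np.vstack([
            encode_for_surrogate(Combination.make("toy", {"p": p}),
                                 registry["toy"], registry.selector_pool)
            for p in range(1, 31)
        ])
        preds = model.predict(grid)
        rho = stats.spearmanr(preds, np.arange(1, 31)).statistic
        assert rho >= 0.9

    def test_single_record_unavailable(self):
        registry = self.toy_registry()
        state = AlgorithmState(spec=registry["toy"], rng=np.random.default_rng(0))
        state.add_record(1, Combination.make("toy", {"p": 3}), 0.6)
        assert fit_surrogate(state, registry) is None


class TestProposals:
    @staticmethod
    def discrete_registry(n_values=10):
        spec = AlgorithmSpec(
            "toy", "base",
            (hp("p", "categorical", tuple(range(1, n_values + 1)), 1),), _toy_backend)
        return Registry([spec], [FeatureSelectorSpec("none")])

    def test_even_iterations_random_regardless_of_surrogate(self):
        registry = self.discrete_registry()
        state = AlgorithmState(spec=registry["toy"], rng=np.random.default_rng(1))
        for p in range(1, 11):
            rec = CombinationRecord(Combination.make("toy", {"p": p}))
            rec.history.append((1, 1.0 if p == 3 else 0.0, "measured"))
            state.records.append(rec)
        fit_surrogate(state, registry)
        config = quick_config()
        draws = {propose_next(state, 2, registry, config, round_best=0.5).param_dict["p"]
                 for _ in range(40)}
        assert len(draws) > 3  # a surrogate argmax would collapse to one value

    def test_odd_iteration_returns_surrogate_argmax(self):
        registry = self.discrete_registry()
        state = AlgorithmState(spec=registry["toy"], rng=np.random.default_rng(2))
        for p in range(1, 11):
            rec = CombinationRecord(Combination.make("toy", {"p": p}))
            rec.history.append((1, 1.0 if p == 3 else 0.0, "measured"))
            state.records.append(rec)
        fit_surrogate(state, registry)
        combo = propose_next(state, 1, registry, quick_config(), round_best=0.5)
        assert combo.param_dict["p"] == 3

    def test_exhausted_space_signals_none(self):
        registry = self.discrete_registry(n_values=3)
        state = AlgorithmState(spec=registry["toy"], rng=np.random.default_rng(3))
        for p in (1, 2, 3):
            state.add_record(1, Combination.make("toy", {"p": p}), 0.5)
        fit_surrogate(state, registry)
        assert propose_next(state, 1, registry, quick_config(), 0.5) is None
        assert propose_next(state, 2, registry, quick_config(), 0.5) is None

    def test_never_reproposes_evaluated_combination(self):
        registry = self.discrete_registry(n_values=5)
        state = AlgorithmState(spec=registry["toy"], rng=np.random.default_rng(4))
        for p in (1, 2, 3, 4):
            state.add_record(1, Combination.make("toy", {"p": p}), 0.5)
        fit_surrogate(state, registry)
        for iteration in (1, 2, 3, 4):
            combo = propose_next(state, iteration, registry, quick_config(), 0.5)
            assert combo.param_dict["p"] == 5


class TestEvaluateCombination:
    def test_separable_concept_reaches_perfect_auc(self, linear_and_tree_registry):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 700)
        x = np.where(y == 1, rng.uniform(1, 2, 700), rng.uniform(-2, -1, 700))
        data = Dataset(pd.DataFrame({"x": x, "outcome": y}))
        schedule = build_schedule(700, 1, quick_schedule_config(), seed=0)
        combo = default_combination(linear_and_tree_registry["decision_tree"])
        acc = evaluate_combination(combo, schedule.training_sample(1),
                                   schedule.test_sample(), data,
                                   linear_and_tree_registry)
        assert acc == 1.0

    def test_constant_feature_scores_chance(self, linear_and_tree_registry):
        rng = np.random.default_rng(1)
        data = Dataset(pd.DataFrame({"x": np.ones(400),
                                     "outcome": rng.integers(0, 2, 400)}))
        schedule = build_schedule(400, 1, quick_schedule_config(n_test=100,
                                                               initial_const=100), seed=0)
        combo = default_combination(linear_and_tree_registry["logistic"])
        acc = evaluate_combination(combo, schedule.training_sample(1),
                                   schedule.test_sample(), data,
                                   linear_and_tree_registry)
        assert acc == 0.5

    def test_matches_standalone_metric_oracle(self, linear_and_tree_registry):
        """Pipeline accuracy equals hand-computed pair-counting AUC."""
        import itertools

        def mann_whitney_auc(scores, labels):
            pos = [s for s, y in zip(scores, labels) if y == 1]
            neg = [s for s, y in zip(scores, labels) if y == 0]
            wins = sum(1.0 if a > b else 0.5 if a == b else 0.0
                       for a, b in itertools.product(pos, neg))
            return wins / (len(pos) * len(neg))

        rng = np.random.default_rng(2)
        frame = pd.DataFrame({"x1": rng.normal(size=20), "x2": rng.normal(size=20),
                              "outcome": rng.integers(0, 2, 20)})
        frame.loc[:1, "outcome"] = [0, 1]
        data = Dataset(frame)
        train = np.arange(12)
        test = np.arange(12, 20)
        combo = default_combination(linear_and_tree_registry["decision_tree"])
        got = evaluate_combination(combo, train, test, data,
                                   linear_and_tree_registry, seed=7)
        X, _, _ = data.encode()
        est = build_estimator(combo, linear_and_tree_registry,
                              random_state=_stable_seed(7, combo))
        est.fit(X[train], data.y[train])
        scores = decision_scores(est, X[test])
        assert got == pytest.approx(mann_whitney_auc(scores, data.y[test]))

    def test_training_failure_penalized_not_raised(self, registry):
        rng = np.random.default_rng(3)
        data = Dataset(pd.DataFrame({"x": rng.normal(size=400),
                                     "outcome": rng.integers(0, 2, 400)}))
        combo = Combination.make("knn", {"n_neighbors": 50, "weights": "uniform"})
        acc = evaluate_combination(combo, np.arange(10), np.arange(10, 40),
                                   data, registry)
        assert acc == 0.0  # 50 neighbors > 10 training rows

    def test_deterministic_under_seed(self, linear_and_tree_registry):
        data = gaussian_dataset(n=600, seed=4)
        schedule = build_schedule(600, 2, quick_schedule_config(), seed=0)
        combo = default_combination(linear_and_tree_registry["decision_tree"])
        args = (combo, schedule.training_sample(1), schedule.test_sample(),
                data, linear_and_tree_registry)
        assert evaluate_combination(*args, seed=5) == evaluate_combination(*args, seed=5)


class TestRounds:
    def test_first_round_evaluation_count(self, linear_and_tree_registry):
        """3 base algorithms, default + 10 random each = 33 evaluations."""
        data = gaussian_dataset(n=800, seed=1)
        config = SearchConfig(n_random_init=10, n_decrements=1,
                              smbo_iters_per_round=1, candidate_pool_size=20, seed=2)
        result = search(data, config, linear_and_tree_registry,
                        quick_schedule_config())
        round1 = result.trace[0]
        measured = [e for e in round1["evaluations"] if e["kind"] == "measured"]
        assert len(measured) == 33

    def test_meta_and_ensemble_enter_after_base_only_rounds(self, registry):
        data = gaussian_dataset(n=900, seed=2, n_features=2)
        small = registry.filtered(algorithms=["logistic", "decision_tree",
                                              "gaussian_nb", "bagging", "voting"])
        config = quick_config(base_only_rounds=2, n_decrements=3, seed=3)
        result = search(data, config, small, quick_schedule_config())
        per_round_algos = {
            t["round"]: {e["algorithm"] for e in t["evaluations"]
                         if e["kind"] == "measured"}
            for t in result.trace if t["round"] != "final"
        }
        for k in (1, 2):
            assert not per_round_algos[k] & {"bagging", "voting"}
        entered = set().union(*(per_round_algos[k] for k in per_round_algos if k >= 3))
        assert entered & {"bagging", "voting"}

    def test_base_algorithms_evaluated_before_meta_within_round(self, registry):
        data = gaussian_dataset(n=900, seed=5)
        small = registry.filtered(algorithms=["logistic", "decision_tree", "bagging"])
        config = quick_config(base_only_rounds=1, n_decrements=2, seed=4)
        result = search(data, config, small, quick_schedule_config())
        round2 = next(t for t in result.trace if t["round"] == 2)
        kinds = [small[e["algorithm"]].category for e in round2["evaluations"]
                 if e["kind"] == "measured"]
        first_meta = kinds.index("meta") if "meta" in kinds else len(kinds)
        assert "base" not in kinds[first_meta:]

    def test_degenerate_tau_never_shrinks_candidate_sets(self, linear_and_tree_registry):
        data = gaussian_dataset(n=900, seed=6)
        config = quick_config(tau_init=1.0, tau_min=1.0, tau_decrement=0.07, seed=7)
        result = search(data, config, linear_and_tree_registry, quick_schedule_config())
        for t in result.trace:
            if t["round"] == "final":
                continue
            assert t["eliminated_algorithms"] == []
            assert t["newly_unpromising"] == {}

    def test_trivial_space_returns_its_only_combination(self):
        spec = AlgorithmSpec("toy", "base",
                             (hp("p", "categorical", ("only",), "only"),), _toy_backend)
        registry = Registry([spec], [FeatureSelectorSpec("none")])
        data = gaussian_dataset(n=600, seed=8)
        result = search(data, quick_config(seed=9), registry, quick_schedule_config())
        assert result.best_combination.param_dict == {"p": "only"}

    def test_low_accuracy_sets_advisory_flag(self, linear_and_tree_registry):
        data = gaussian_dataset(n=900, separation=0.3, seed=10)  # Bayes ~0.58
        result = search(data, quick_config(seed=11), linear_and_tree_registry,
                        quick_schedule_config())
        assert result.final_auc < 0.8
        assert result.advisory_low_accuracy


class TestFinalRound:
    def test_full_data_mode_trains_on_everything_outside_test(self, linear_and_tree_registry):
        data = gaussian_dataset(n=900, seed=12)
        result = search(data, quick_config(seed=13), linear_and_tree_registry,
                        quick_schedule_config())
        assert result.final_train_size == 900 - 150

    def test_convergence_mode_close_to_full_data_on_saturating_task(self, registry):
        data = gaussian_dataset(n=3000, seed=14)
        small = registry.filtered(algorithms=["logistic"])
        aucs = {}
        for mode in ("full-data", "convergence"):
            config = quick_config(final_mode=mode, seed=15)
            result = search(data, config, small,
                            quick_schedule_config(n_test=500, initial_const=500))
            aucs[mode] = result.final_auc
        assert abs(aucs["full-data"] - aucs["convergence"]) < 0.02


@pytest.fixture(scope="module")
def traced_result(linear_and_tree_registry):
    data = gaussian_dataset(n=1200, seed=16)
    config = SearchConfig(n_random_init=4, smbo_iters_per_round=4,
                          n_decrements=3, candidate_pool_size=40, seed=17)
    return search(data, config, linear_and_tree_registry,
                  quick_schedule_config(n_test=200, initial_const=200))


class TestTraceInvariants:

    def test_round_best_is_always_measured(self, traced_result):
        for t in traced_result.trace:
            if t["round"] == "final":
                assert t["kind"] == "measured"
            else:
                assert t["best"]["kind"] == "measured"

    def test_incumbent_never_eliminated(self, traced_result):
        for t in traced_result.trace:
            if t["round"] == "final":
                continue
            assert t["best"]["algorithm"] not in t["eliminated_algorithms"]
            dropped = t["newly_unpromising"].get(t["best"]["algorithm"], [])
            assert t["best"]["combination"] not in dropped

    def test_active_algorithms_monotone_non_increasing(self, traced_result):
        rounds = [t for t in traced_result.trace if t["round"] != "final"]
        for prev, cur in zip(rounds, rounds[1:]):
            assert set(cur["active_algorithms"]) <= set(prev["active_algorithms"])

    def test_extrapolated_estimates_never_selected(self, traced_result):
        for t in traced_result.trace:
            if t["round"] == "final":
                continue
            extrapolated = {e["combination"] for e in t["evaluations"]
                            if e["kind"] == "extrapolated"}
            assert t["best"]["combination"] not in extrapolated

    def test_same_seed_reproduces_trace(self, linear_and_tree_registry, traced_result):
        data = gaussian_dataset(n=1200, seed=16)
        config = SearchConfig(n_random_init=4, smbo_iters_per_round=4,
                              n_decrements=3, candidate_pool_size=40, seed=17)
        again = search(data, config, linear_and_tree_registry,
                       quick_schedule_config(n_test=200, initial_const=200))
        assert again.best_combination == traced_result.best_combination
        assert again.final_auc == traced_result.final_auc
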