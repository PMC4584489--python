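"""Shared fixtures: small algorithm pools and synthetic tasks."""

import pytest

from pivotml.space import (
    AlgorithmSpec,
    FeatureSelectorSpec,
    Registry,
    default_registry,
)
from pivotml.space import _decision_tree, _gaussian_nb, _logistic, _svm_linear
from pivotml.space import _hp as hp


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def tiny_enumerable_registry():
    """2 algorithms x 3 combinations each, selector fixed to 'none'.

    Categorical numeric domains make the space fully enumerable, so
    exhaustive evaluation can serve as an oracle for the search.
    """
    logistic = AlgorithmSpec(
        "logistic", "base",
        (hp("C", "categorical", (0.01, 1.0, 100.0), 1.0),),
        _logistic, interpretable=True,
    )
    tree = AlgorithmSpec(
        "decision_tree", "base",
        (
            hp("max_depth", "categorical", (2, 5, 10), 5),
            hp("min_samples_leaf", "categorical", (1,), 1),
            hp("criterion", "categorical", ("gini",), "gini"),
        ),
        _decision_tree, interpretable=True,
    )
    return Registry([logistic, tree], [FeatureSelectorSpec("none")])


@pytest.fixture(scope="session")
def linear_and_tree_registry():
    """Linear-only algorithms plus one axis-aligned partitioner."""
    logistic = AlgorithmSpec(
        "logistic", "base",
        (hp("C", "log-continuous", (1e-3, 1e3), 1.0),),
        _logistic, interpretable=True,
    )
    svm_linear = AlgorithmSpec(
        "svm_linear", "base",
        (hp("C", "log-continuous", (1e-3, 1e3), 1.0),),
        _svm_linear,
    )
    tree = AlgorithmSpec(
        "decision_tree", "base",
        (
            hp("max_depth", "integer", (1, 20), 5),
            hp("min_samples_leaf", "integer", (1, 50), 1),
            hp("criterion", "categorical", ("gini", "entropy"), "gini"),
        ),
        _decision_tree, interpretable=True,
    )
    return Registry([logistic, svm_linear, tree], [FeatureSelectorSpec("none")])


@pytest.fixture
def conditional_spec():
    """Neural-net-like DAG: second-layer units only when layers >= 2."""
    return AlgorithmSpec(
        "net", "base",
        (
            hp("layers", "integer", (1, 2), 1),
            hp("units_2", "integer", (4, 64), 16, condition=("layers", (2,))),
            hp("lr", "log-continuous", (1e-4, 1e-1), 1e-3),
        ),
        _gaussian_nb,
    )
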