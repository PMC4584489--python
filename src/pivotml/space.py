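"""Algorithm and hyper-parameter search space.

Each learning algorithm is described by an :class:`AlgorithmSpec`: its
hyper-parameters (categorical, integer, continuous or log-continuous),
their defaults, and condition edges making some parameters relevant only
for certain values of a parent (e.g. second-layer units only when a neural
network has two layers).  The condition edges form a DAG, so parameters
are processed root-to-leaf: a concrete :class:`Combination` carries exactly
the active parameters.

Algorithms come in three categories.  A *base* algorithm stands alone; a
*meta* algorithm (bagging) wraps one base algorithm; an *ensemble*
algorithm (voting) combines several.  For meta/ensemble specs each
parameter is tagged with a role: base-selection (which base algorithm),
combination-control (how members are combined), while the wrapped bases'
own hyper-parameters (base-passthrough) are pinned by the search to the
best values found for those bases.

The choice of feature-selection technique is itself a root-level
hyper-parameter: every combination names a selector ('none' always
available) with its own parameters.

For the tree-ensemble surrogate used by the search, a combination is
encoded as a fixed-length numeric vector over ALL of the spec's
parameters, with inactive conditional parameters imputed at their
defaults, categoricals integer-coded by domain order, and log-continuous
values on the log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any, Callable, Iterable, Mapping, Sequence

import numpy as np
import yaml
from sklearn.ensemble import BaggingClassifier, RandomForestClassifier, VotingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC, LinearSVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "HyperParameter",
    "AlgorithmSpec",
    "FeatureSelectorSpec",
    "Combination",
    "Registry",
    "default_combination",
    "sample_random_combination",
    "encode_for_surrogate",
    "validate_combination",
    "default_registry",
    "load_registry",
]

KINDS = ("categorical", "integer", "continuous", "log-continuous")
ROLES = ("base-selection", "combination-control", "base-passthrough")


@dataclass(frozen=True)
class HyperParameter:
    """One hyper-parameter: kind, domain, default, optional condition edge.

    ``domain`` is a tuple of values for categoricals, or (low, high) bounds
    for numeric kinds.  ``condition`` = (parent name, activating values):
    the parameter is active only when its parent is active and takes one of
    those values.
    """

    name: str
    kind: str
    domain: tuple
    default: Any
    condition: tuple[str, frozenset] | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown parameter kind {self.kind!r}")
        if self.kind == "categorical":
            if not self.domain:
                raise ValueError(f"{self.name}: empty categorical domain")
            if self.default not in self.domain:
                raise ValueError(f"{self.name}: default outside domain")
        else:
            low, high = self.domain
            if not low <= self.default <= high:
                raise ValueError(f"{self.name}: default outside bounds")
            if self.kind == "log-continuous" and low <= 0:
                raise ValueError(f"{self.name}: log-continuous bounds must be > 0")

    def contains(self, value: Any) -> bool:
        if self.kind == "categorical":
            return value in self.domain
        low, high = self.domain
        if self.kind == "integer" and value != int(value):
            return False
        return low <= value <= high


@dataclass(frozen=True)
class AlgorithmSpec:
    """A learning algorithm with its conditional hyper-parameter DAG.

    ``backend`` builds an unfitted scikit-learn estimator from an active
    parameter mapping; meta/ensemble backends additionally receive a
    ``make_base(base_id)`` factory producing pinned base estimators.
    """

    id: str
    category: str  # base | meta | ensemble
    hyperparameters: tuple[HyperParameter, ...]
    backend: Callable[..., Any]
    interpretable: bool = False
    roles: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in ("base", "meta", "ensemble"):
            raise ValueError(f"unknown category {self.category!r}")
        names = [p.name for p in self.hyperparameters]
        if len(set(names)) != len(names):
            raise ValueError(f"{self.id}: duplicate parameter names")
        for p in self.hyperparameters:
            if p.condition is not None and p.condition[0] not in names:
                raise ValueError(f"{self.id}: condition parent {p.condition[0]!r} missing")
        self._topological()  # raises on cycles
        if self.category != "base":
            for name, role in self.roles.items():
                if role not in ROLES:
                    raise ValueError(f"{self.id}: unknown role {role!r} for {name}")
            if "base-selection" not in self.roles.values():
                raise ValueError(f"{self.id}: meta/ensemble needs a base-selection parameter")

    def parameter(self, name: str) -> HyperParameter:
        for p in self.hyperparameters:
            if p.name == name:
                return p
        raise KeyError(name)

    def _topological(self) -> tuple[HyperParameter, ...]:
        by_name = {p.name: p for p in self.hyperparameters}
        order: list[HyperParameter] = []
        state: dict[str, int] = {}

        def visit(p: HyperParameter) -> None:
            if state.get(p.name) == 2:
                return
            if state.get(p.name) == 1:
                raise ValueError(f"{self.id}: condition cycle through {p.name!r}")
            state[p.name] = 1
            if p.condition is not None:
                visit(by_name[p.condition[0]])
            state[p.name] = 2
            order.append(p)

        for p in self.hyperparameters:
            visit(p)
        return tuple(order)

    @property
    def topological_parameters(self) -> tuple[HyperParameter, ...]:
        """Parameters ordered so every condition parent precedes its children."""
        return self._topological()

    def with_domain(self, name: str, domain: tuple, default: Any | None = None) -> "AlgorithmSpec":
        """Copy of this spec with one parameter's domain (and default) replaced."""
        params = tuple(
            replace(p, domain=tuple(domain),
                    default=(default if default is not None else
                             (p.default if p.contains(p.default) and p.default in domain
                              else domain[0])))
            if p.name == name else p
            for p in self.hyperparameters
        )
        return replace(self, hyperparameters=params)


@dataclass(frozen=True)
class FeatureSelectorSpec:
    """A feature-selection technique exposed as a root hyper-parameter."""

    id: str
    hyperparameters: tuple[HyperParameter, ...] = ()


@dataclass(frozen=True)
class Combination:
    """One concrete assignment: algorithm + selector + active parameter values."""

    algorithm: str
    params: tuple[tuple[str, Any], ...]
    selector: str = "none"
    selector_params: tuple[tuple[str, Any], ...] = ()

    @classmethod
    def make(
        cls,
        algorithm: str,
        params: Mapping[str, Any],
        selector: str = "none",
        selector_params: Mapping[str, Any] | None = None,
    ) -> "Combination":
        return cls(
            algorithm,
            tuple(sorted(params.items())),
            selector,
            tuple(sorted((selector_params or {}).items())),
        )

    @property
    def param_dict(self) -> dict[str, Any]:
        return dict(self.params)

    @property
    def selector_param_dict(self) -> dict[str, Any]:
        return dict(self.selector_params)

    def label(self) -> str:
        parts = [f"{k}={v:.4g}" if isinstance(v, float) else f"{k}={v}"
                 for k, v in self.params]
        sel = "" if self.selector == "none" else f" | sel={self.selector}"
        return f"{self.algorithm}({', '.join(parts)}){sel}"


def _active_parameters(
    spec_params: Sequence[HyperParameter], values: Mapping[str, Any]
) -> list[HyperParameter]:
    """Active parameters given an assignment, walking the DAG root-to-leaf."""
    active: list[HyperParameter] = []
    active_names: set[str] = set()
    for p in spec_params:
        if p.condition is None:
            is_active = True
        else:
            parent, activating = p.condition
            is_active = parent in active_names and values.get(parent) in activating
        if is_active:
            active.append(p)
            active_names.add(p.name)
    return active


def default_combination(
    spec: AlgorithmSpec, selector: FeatureSelectorSpec | None = None
) -> Combination:
    """The combination of the spec's default hyper-parameter values.

    Defaults are assigned walking the condition DAG from the roots, so a
    conditional parameter whose parent's default does not activate it is
    absent from the result.
    """
    values: dict[str, Any] = {}
    for p in _walk_defaults(spec.topological_parameters):
        values[p.name] = p.default
    sel = selector or FeatureSelectorSpec("none")
    sel_values = {p.name: p.default for p in _walk_defaults(sel.hyperparameters)}
    return Combination.make(spec.id, values, sel.id, sel_values)


def _walk_defaults(params: Sequence[HyperParameter]) -> Iterable[HyperParameter]:
    values: dict[str, Any] = {}
    for p in params:
        if p.condition is None or values.get(p.condition[0]) in p.condition[1]:
            values[p.name] = p.default
            yield p


def _sample_value(p: HyperParameter, rng: np.random.Generator) -> Any:
    if p.kind == "categorical":
        return p.domain[int(rng.integers(len(p.domain)))]
    low, high = p.domain
    if p.kind == "integer":
        return int(rng.integers(low, high + 1))
    if p.kind == "continuous":
        return float(rng.uniform(low, high))
    return float(math.exp(rng.uniform(math.log(low), math.log(high))))


def sample_random_combination(
    spec: AlgorithmSpec,
    rng: np.random.Generator,
    selector_pool: Sequence[FeatureSelectorSpec] | None = None,
) -> Combination:
    """Draw a uniformly random valid combination, root-to-leaf.

    Only parameters activated by the values drawn for their parents are
    sampled; log-continuous kinds are sampled uniformly on the log scale.
    The selector (if a pool is given) is drawn uniformly as well.
    """
    values: dict[str, Any] = {}
    for p in spec.topological_parameters:
        if p.condition is None or values.get(p.condition[0]) in p.condition[1]:
            values[p.name] = _sample_value(p, rng)
    sel = FeatureSelectorSpec("none")
    if selector_pool:
        sel = selector_pool[int(rng.integers(len(selector_pool)))]
    sel_values: dict[str, Any] = {}
    for p in sel.hyperparameters:
        if p.condition is None or sel_values.get(p.condition[0]) in p.condition[1]:
            sel_values[p.name] = _sample_value(p, rng)
    return Combination.make(spec.id, values, sel.id, sel_values)


def _encode_value(p: HyperParameter, value: Any) -> float:
    if p.kind == "categorical":
        return float(p.domain.index(value))
    if p.kind == "log-continuous":
        return float(math.log(value))
    return float(value)


def encode_for_surrogate(
    combo: Combination,
    spec: AlgorithmSpec,
    selector_pool: Sequence[FeatureSelectorSpec] | None = None,
) -> np.ndarray:
    """Fixed-length numeric encoding of a combination for the surrogate.

    One slot per spec parameter (inactive conditionals imputed with their
    defaults), plus — when a selector pool is given — one slot for the
    selector choice and one per selector parameter.
    """
    values = combo.param_dict
    vec = [
        _encode_value(p, values.get(p.name, p.default))
        for p in spec.hyperparameters
    ]
    if selector_pool:
        ids = [s.id for s in selector_pool]
        vec.append(float(ids.index(combo.selector)))
        sel_values = combo.selector_param_dict
        for s in selector_pool:
            for p in s.hyperparameters:
                if s.id == combo.selector and p.name in sel_values:
                    vec.append(_encode_value(p, sel_values[p.name]))
                else:
                    vec.append(_encode_value(p, p.default))
    return np.asarray(vec, dtype=float)


def validate_combination(combo: Combination, spec: AlgorithmSpec) -> list[str]:
    """Domain and condition violations (empty list = valid)."""
    violations: list[str] = []
    if combo.algorithm != spec.id:
        violations.append(f"algorithm {combo.algorithm!r} does not match spec {spec.id!r}")
        return violations
    values = combo.param_dict
    known = {p.name for p in spec.hyperparameters}
    for name in values:
        if name not in known:
            violations.append(f"unknown parameter {name!r}")
    expected_active = {p.name for p in _active_parameters(spec.topological_parameters, values)}
    for name in values.keys() & known:
        p = spec.parameter(name)
        if not p.contains(values[name]):
            violations.append(f"{name}={values[name]!r} outside domain")
        if name not in expected_active:
            violations.append(f"{name} active despite non-activating parent value")
    for name in expected_active - values.keys():
        violations.append(f"active parameter {name!r} missing")
    return violations


# ---------------------------------------------------------------------------
# Default registry: scikit-learn backends.
# ---------------------------------------------------------------------------


def _logistic(params, random_state):
    return LogisticRegression(C=params["C"], max_iter=2000, random_state=random_state)


def _decision_tree(params, random_state):
    return DecisionTreeClassifier(
        max_depth=params["max_depth"],
        min_samples_leaf=params["min_samples_leaf"],
        criterion=params["criterion"],
        random_state=random_state,
    )


def _knn(params, random_state):
    return KNeighborsClassifier(
        n_neighbors=params["n_neighbors"], weights=params["weights"]
    )


def _gaussian_nb(params, random_state):
    return GaussianNB(var_smoothing=params["var_smoothing"])


def _svm_linear(params, random_state):
    return LinearSVC(C=params["C"], random_state=random_state)


def _svm_rbf(params, random_state):
    return SVC(
        kernel="rbf", C=params["C"], gamma=params["gamma"], random_state=random_state
    )


def _random_forest(params, random_state):
    return RandomForestClassifier(
        n_estimators=params["n_estimators"],
        max_features=params["max_features"],
        min_samples_leaf=params["min_samples_leaf"],
        random_state=random_state,
        n_jobs=1,
    )


def _mlp(params, random_state):
    if params["hidden_layers"] == 2:
        sizes = (params["units_1"], params["units_2"])
    else:
        sizes = (params["units_1"],)
    return MLPClassifier(
        hidden_layer_sizes=sizes,
        alpha=params["alpha"],
        max_iter=300,
        random_state=random_state,
    )


def _bagging(params, random_state, make_base):
    return BaggingClassifier(
        estimator=make_base(params["base_algorithm"]),
        n_estimators=params["n_estimators"],
        random_state=random_state,
        n_jobs=1,
    )


def _voting(params, random_state, make_base):
    members = [params["member_1"], params["member_2"]]
    if params.get("member_3", "none") != "none":
        members.append(params["member_3"])
    estimators = [(f"m{i}_{b}", make_base(b)) for i, b in enumerate(members)]
    return VotingClassifier(estimators=estimators, voting="soft", n_jobs=1)


def _hp(name, kind, domain, default, condition=None):
    cond = None if condition is None else (condition[0], frozenset(condition[1]))
    return HyperParameter(name, kind, tuple(domain), default, cond)


#: Base algorithms able to emit class probabilities (voting members).
PROBABILISTIC_BASES = (
    "logistic", "decision_tree", "knn", "gaussian_nb", "random_forest", "mlp",
)


class Registry:
    """The pool of algorithm and selector specs the search explores."""

    def __init__(
        self,
        algorithms: Sequence[AlgorithmSpec],
        selectors: Sequence[FeatureSelectorSpec] | None = None,
    ):
        self.algorithms = {a.id: a for a in algorithms}
        sels = list(selectors) if selectors is not None else [FeatureSelectorSpec("none")]
        if not any(s.id == "none" for s in sels):
            sels.insert(0, FeatureSelectorSpec("none"))
        self.selectors = {s.id: s for s in sels}

    def __getitem__(self, algorithm_id: str) -> AlgorithmSpec:
        return self.algorithms[algorithm_id]

    @property
    def selector_pool(self) -> list[FeatureSelectorSpec]:
        return list(self.selectors.values())

    def base_ids(self) -> list[str]:
        return [a.id for a in self.algorithms.values() if a.category == "base"]

    def filtered(
        self,
        algorithms: Sequence[str] | None = None,
        selectors: Sequence[str] | None = None,
        interpretable_only: bool = False,
    ) -> "Registry":
        """Apply user allowlists / interpretable-only mode before round 1."""
        algos = list(self.algorithms.values())
        if algorithms is not None:
            unknown = set(algorithms) - set(self.algorithms)
            if unknown:
                raise KeyError(f"unknown algorithms {sorted(unknown)}")
            algos = [a for a in algos if a.id in set(algorithms)]
        if interpretable_only:
            algos = [a for a in algos if a.interpretable or a.category != "base"]
            base_left = {a.id for a in algos if a.category == "base"}
            algos = [
                a for a in algos
                if a.category == "base" or _selection_feasible(a, base_left)
            ]
        sels = self.selector_pool
        if selectors is not None:
            sels = [s for s in sels if s.id in set(selectors) | {"none"}]
        if not algos:
            raise ValueError("registry filter left no algorithms")
        return Registry(algos, sels)


def _selection_feasible(spec: AlgorithmSpec, base_left: set[str]) -> bool:
    for p in spec.hyperparameters:
        if spec.roles.get(p.name) == "base-selection":
            if not (set(p.domain) - {"none"}) & base_left:
                return False
    return True


def default_registry() -> Registry:
    """Representative pool: 8 base + 1 meta + 1 ensemble algorithm.

    Distinct SVM kernels are distinct algorithms.  The MLP spec carries the
    canonical conditional parameter (second-layer units active only when
    hidden_layers = 2).
    """
    base = [
        AlgorithmSpec(
            "logistic", "base",
            (_hp("C", "log-continuous", (1e-3, 1e3), 1.0),),
            _logistic, interpretable=True,
        ),
        AlgorithmSpec(
            "decision_tree", "base",
            (
                _hp("max_depth", "integer", (1, 20), 5),
                _hp("min_samples_leaf", "integer", (1, 50), 1),
                _hp("criterion", "categorical", ("gini", "entropy"), "gini"),
            ),
            _decision_tree, interpretable=True,
        ),
        AlgorithmSpec(
            "knn", "base",
            (
                _hp("n_neighbors", "integer", (1, 50), 5),
                _hp("weights", "categorical", ("uniform", "distance"), "uniform"),
            ),
            _knn, interpretable=True,
        ),
        AlgorithmSpec(
            "gaussian_nb", "base",
            (_hp("var_smoothing", "log-continuous", (1e-12, 1e-6), 1e-9),),
            _gaussian_nb,
        ),
        AlgorithmSpec(
            "svm_linear", "base",
            (_hp("C", "log-continuous", (1e-3, 1e3), 1.0),),
            _svm_linear,
        ),
        AlgorithmSpec(
            "svm_rbf", "base",
            (
                _hp("C", "log-continuous", (1e-3, 1e3), 1.0),
                _hp("gamma", "log-continuous", (1e-4, 10.0), 0.1),
            ),
            _svm_rbf,
        ),
        AlgorithmSpec(
            "random_forest", "base",
            (
                _hp("n_estimators", "integer", (10, 100), 50),
                _hp("max_features", "continuous", (0.1, 1.0), 0.5),
                _hp("min_samples_leaf", "integer", (1, 20), 1),
            ),
            _random_forest,
        ),
        AlgorithmSpec(
            "mlp", "base",
            (
                _hp("hidden_layers", "integer", (1, 2), 1),
                _hp("units_1", "integer", (4, 64), 16),
                _hp("units_2", "integer", (4, 64), 16, condition=("hidden_layers", (2,))),
                _hp("alpha", "log-continuous", (1e-6, 1e-1), 1e-4),
            ),
            _mlp,
        ),
    ]
    base_ids = tuple(a.id for a in base)
    meta = AlgorithmSpec(
        "bagging", "meta",
        (
            _hp("base_algorithm", "categorical", base_ids, "decision_tree"),
            _hp("n_estimators", "integer", (5, 30), 10),
        ),
        _bagging,
        roles={"base_algorithm": "base-selection", "n_estimators": "combination-control"},
    )
    ensemble = AlgorithmSpec(
        "voting", "ensemble",
        (
            _hp("member_1", "categorical", PROBABILISTIC_BASES, "logistic"),
            _hp("member_2", "categorical", PROBABILISTIC_BASES, "decision_tree"),
            _hp("member_3", "categorical", PROBABILISTIC_BASES + ("none",), "none"),
        ),
        _voting,
        roles={"member_1": "base-selection", "member_2": "base-selection",
               "member_3": "base-selection"},
    )
    selectors = [
        FeatureSelectorSpec("none"),
        FeatureSelectorSpec(
            "kbest", (_hp("k_frac", "continuous", (0.05, 1.0), 0.5),)
        ),
    ]
    return Registry(base + [meta, ensemble], selectors)


_BACKENDS = {
    "logistic": _logistic,
    "decision_tree": _decision_tree,
    "knn": _knn,
    "gaussian_nb": _gaussian_nb,
    "svm_linear": _svm_linear,
    "svm_rbf": _svm_rbf,
    "random_forest": _random_forest,
    "mlp": _mlp,
    "bagging": _bagging,
    "voting": _voting,
}


def load_registry(path: str) -> Registry:
    """Load a registry from a YAML declaration.

    Each algorithm entry gives id, category, interpretable flag, backend
    name (a registered builder), parameter declarations
    (name/kind/domain/default/condition) and, for meta/ensemble, roles —
    so the pool is extensible without code changes.
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    algorithms = []
    for entry in doc.get("algorithms", []):
        params = tuple(
            _hp(
                p["name"], p["kind"], tuple(p["domain"]), p["default"],
                condition=(
                    (p["condition"]["parent"], tuple(p["condition"]["values"]))
                    if "condition" in p else None
                ),
            )
            for p in entry.get("hyperparameters", [])
        )
        algorithms.append(
            AlgorithmSpec(
                entry["id"],
                entry.get("category", "base"),
                params,
                _BACKENDS[entry.get("backend", entry["id"])],
                interpretable=bool(entry.get("interpretable", False)),
                roles=entry.get("roles", {}),
            )
        )
    selectors = [FeatureSelectorSpec("none")]
    for entry in doc.get("selectors", []):
        if entry["id"] == "none":
            continue
        params = tuple(
            _hp(p["name"], p["kind"], tuple(p["domain"]), p["default"])
            for p in entry.get("hyperparameters", [])
        )
        selectors.append(FeatureSelectorSpec(entry["id"], params))
    return Registry(algorithms, selectors)
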