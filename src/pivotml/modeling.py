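"""Building and scoring concrete models from combinations.

Bridges the abstract search space and scikit-learn: a Combination plus the
registry yields an unfitted pipeline (standardization, optional feature
selection honoring forced-inclusion variables, then the backend
estimator), and an evaluation helper fits on training rows only and scores
held-out rows by AUC.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin, clone
from sklearn.feature_selection import f_classif
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .metrics import Dataset, compute_auc
from .space import Combination, Registry

__all__ = ["ForcedKBest", "build_estimator", "decision_scores", "evaluate_on_split"]


class ForcedKBest(TransformerMixin, BaseEstimator):
    """Univariate top-k selection that never drops forced columns.

    Scores non-forced columns with the ANOVA F statistic and keeps the top
    ceil(k_frac * n_selectable) of them; forced columns always pass
    through, so selection applies only to the other input variables.
    """

    def __init__(self, k_frac: float = 0.5, forced_idx: tuple[int, ...] = ()):
        self.k_frac = k_frac
        self.forced_idx = forced_idx

    def fit(self, X, y):
        X = np.asarray(X)
        n_cols = X.shape[1]
        forced = [i for i in self.forced_idx if i < n_cols]
        selectable = [i for i in range(n_cols) if i not in forced]
        if selectable:
            scores, _ = f_classif(X[:, selectable], y)
            scores = np.nan_to_num(scores, nan=0.0)
            k = max(1, int(np.ceil(self.k_frac * len(selectable))))
            top = np.argsort(-scores, kind="stable")[:k]
            kept = sorted(forced + [selectable[i] for i in top])
        else:
            kept = forced
        self.support_ = np.array(kept, dtype=int)
        self.n_features_in_ = n_cols
        return self

    def transform(self, X):
        return np.asarray(X)[:, self.support_]


def _make_selector(combo: Combination, forced_idx: tuple[int, ...]):
    if combo.selector == "none":
        return None
    if combo.selector == "kbest":
        params = combo.selector_param_dict
        return ForcedKBest(k_frac=params.get("k_frac", 0.5), forced_idx=forced_idx)
    raise ValueError(f"unknown feature selector {combo.selector!r}")


def build_estimator(
    combo: Combination,
    registry: Registry,
    random_state: int | None = None,
    make_base: Callable[[str], BaseEstimator] | None = None,
    forced_idx: tuple[int, ...] = (),
) -> Pipeline:
    """Unfitted pipeline for a combination: scale -> (select) -> model."""
    spec = registry[combo.algorithm]
    params = combo.param_dict
    if spec.category == "base":
        model = spec.backend(params, random_state)
    else:
        if make_base is None:
            raise ValueError(f"{spec.id}: meta/ensemble spec needs a base factory")
        model = spec.backend(params, random_state, make_base)
    steps = [("scale", StandardScaler())]
    selector = _make_selector(combo, forced_idx)
    if selector is not None:
        steps.append(("select", selector))
    steps.append(("model", model))
    return Pipeline(steps)


def decision_scores(estimator, X) -> np.ndarray:
    """Continuous scores for ranking: P(class 1) or the decision function."""
    if hasattr(estimator, "predict_proba"):
        return np.asarray(estimator.predict_proba(X))[:, 1]
    return np.asarray(estimator.decision_function(X))


def evaluate_on_split(
    data: Dataset,
    combo: Combination,
    registry: Registry,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    features: list[str] | None = None,
    random_state: int | None = None,
    make_base: Callable[[str], BaseEstimator] | None = None,
) -> float:
    """Fit on the training rows only, return AUC on the disjoint test rows."""
    X, _, groups = data.encode(features)
    y = data.y
    feats = features if features is not None else data.feature_names
    forced_idx = tuple(
        i for f in data.forced_include if f in groups for i in groups[f]
    ) if feats else ()
    est = build_estimator(
        combo, registry, random_state=random_state,
        make_base=make_base, forced_idx=forced_idx,
    )
    est = clone(est)
    est.fit(X[train_idx], y[train_idx])
    scores = decision_scores(est, X[test_idx])
    return compute_auc(scores, y[test_idx])
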