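"""Metrics, final-model reporting, and the SQL feature-construction hook.

The accuracy measure throughout is the AUC — the probability that a random
positive instance outscores a random negative one, ties half-credited
(the Mann-Whitney formulation).  ROC points expose the
sensitivity/specificity trade-off; the trapezoidal area over them equals
the AUC.  Backward feature elimination orders the input variables by
importance on the held-out test sample, with medically forced variables
never removed, and reports per-prefix cumulative accuracy so a user can
see how few clinical parameters suffice.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "Dataset",
    "EvaluationReport",
    "MetricError",
    "compute_auc",
    "roc_points",
    "accuracy_prompt",
    "run_feature_queries",
    "rank_features_backward",
]


class MetricError(ValueError):
    """Metric undefined for the given inputs (e.g. single-class labels)."""


@dataclass
class Dataset:
    """A wide feature table with a binary outcome.

    Non-numeric feature columns are one-hot expanded for numeric backends;
    the expansion is recorded so rankings report the original clinical
    parameters rather than indicator columns.  ``forced_include`` names
    features that medical knowledge requires in every model.
    """

    frame: pd.DataFrame
    outcome: str = "outcome"
    forced_include: frozenset[str] = frozenset()
    entity_col: str | None = None

    feature_names: list[str] = field(init=False)

    def __post_init__(self) -> None:
        if self.outcome not in self.frame.columns:
            raise ValueError(f"outcome column {self.outcome!r} missing")
        drop = {self.outcome} | ({self.entity_col} if self.entity_col else set())
        self.feature_names = [c for c in self.frame.columns if c not in drop]
        if not self.feature_names:
            raise ValueError("dataset has no feature columns")
        y = pd.to_numeric(self.frame[self.outcome])
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("outcome must be binary 0/1")
        self.forced_include = frozenset(self.forced_include)
        unknown = self.forced_include - set(self.feature_names)
        if unknown:
            raise ValueError(f"forced features not in data: {sorted(unknown)}")

    @property
    def y(self) -> np.ndarray:
        return pd.to_numeric(self.frame[self.outcome]).to_numpy()

    def encode(self, features: list[str] | None = None):
        """Numeric design matrix for a feature subset.

        Returns (X, columns, groups) where groups maps each original
        feature to its column indices in X (one-hot expansion for
        non-numeric columns).
        """
        features = features if features is not None else self.feature_names
        blocks: list[np.ndarray] = []
        columns: list[str] = []
        groups: dict[str, list[int]] = {}
        for name in features:
            col = self.frame[name]
            numeric = pd.to_numeric(col, errors="coerce")
            start = len(columns)
            if numeric.notna().all():
                blocks.append(numeric.to_numpy(dtype=float)[:, None])
                columns.append(name)
            else:
                dummies = pd.get_dummies(col.astype(str), prefix=name)
                blocks.append(dummies.to_numpy(dtype=float))
                columns.extend(dummies.columns)
            groups[name] = list(range(start, len(columns)))
        X = np.hstack(blocks) if blocks else np.empty((len(self.frame), 0))
        return X, columns, groups

    @property
    def n_features(self) -> int:
        return len(self.feature_names)


@dataclass
class EvaluationReport:
    """Final-model report: metric, ROC points, ranked features."""

    auc: float
    roc: list[tuple[float, float, float]]
    ranking: list[str] = field(default_factory=list)
    cumulative_auc: list[float] = field(default_factory=list)
    low_accuracy_flag: bool = False


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise MetricError("AUC needs both outcome classes present")
    return labels


def compute_auc(scores, labels) -> float:
    """AUC = P(score_pos > score_neg) + 0.5 P(score_pos = score_neg)."""
    labels = _check_labels(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def roc_points(scores, labels) -> list[tuple[float, float, float]]:
    """(false-positive rate, true-positive rate, threshold) per distinct cut.

    The trapezoidal area over the returned points equals :func:`compute_auc`.
    """
    labels = _check_labels(labels)
    fpr, tpr, thresholds = roc_curve(labels, np.asarray(scores, dtype=float))
    return list(zip(fpr.tolist(), tpr.tolist(), thresholds.tolist()))


def accuracy_prompt(value: float, threshold: float = 0.8) -> bool:
    """Advisory flag: model accuracy strictly below the acceptability bar.

    A set flag suggests returning to parameter extraction to add more
    clinical parameters.
    """
    return value < threshold


def run_feature_queries(
    tables: dict[str, pd.DataFrame], statements: str | list[str]
) -> pd.DataFrame:
    """Execute feature-construction SQL over named wide tables.

    Tables are registered in an in-memory SQLite database; statements run
    in order and the last row-returning statement's result is materialized
    as the constructed feature table.
    """
    if isinstance(statements, str):
        statements = [s.strip() for s in statements.split(";") if s.strip()]
    if not statements:
        raise ValueError("no SQL statements given")
    conn = sqlite3.connect(":memory:")
    try:
        for name, frame in tables.items():
            frame.to_sql(name, conn, index=False)
        result: pd.DataFrame | None = None
        for stmt in statements:
            try:
                cursor = conn.execute(stmt)
            except sqlite3.Error as exc:
                raise ValueError(f"SQL error in {stmt!r}: {exc}") from exc
            if cursor.description is not None:
                columns = [c[0] for c in cursor.description]
                result = pd.DataFrame(cursor.fetchall(), columns=columns)
        if result is None:
            raise ValueError("no statement returned rows")
        return result
    finally:
        conn.close()


def rank_features_backward(
    data: Dataset,
    combo,
    schedule,
    registry,
    random_state: int | None = None,
    make_base=None,
) -> tuple[list[str], list[float]]:
    """Backward feature elimination on the held-out test sample.

    Starting from all features, repeatedly retrain without each removable
    (non-forced) feature and drop the one whose absence least reduces test
    AUC.  The ranking is the reverse removal order (most important first);
    forced features are ordered by the same hypothetical-removal criterion
    but are present in every evaluated model.  Cumulative accuracy for
    prefix k is the test AUC of the model retrained on the top-k features.
    """
    from .modeling import evaluate_on_split  # local import, avoids a cycle

    train_idx = schedule.full_training_sample()
    test_idx = schedule.test_sample()

    def score(features: list[str]) -> float:
        return evaluate_on_split(
            data, combo, registry, train_idx, test_idx,
            features=features, random_state=random_state, make_base=make_base,
        )

    remaining = list(data.feature_names)
    removal_order: list[str] = []
    while True:
        removable = [f for f in remaining if f not in data.forced_include]
        if not removable or len(remaining) == 1:
            break
        drops = {f: score([g for g in remaining if g != f]) for f in removable}
        worst = max(drops, key=lambda f: (drops[f], f))  # least accuracy loss
        remaining.remove(worst)
        removal_order.append(worst)

    # Order forced survivors by the same criterion, without removing them.
    forced_left = list(remaining)
    forced_order: list[str] = []
    while len(forced_left) > 1:
        drops = {f: score([g for g in forced_left if g != f]) for f in forced_left}
        worst = max(drops, key=lambda f: (drops[f], f))
        forced_left.remove(worst)
        forced_order.append(worst)
    ranking = forced_left + list(reversed(forced_order)) + list(reversed(removal_order))
    cumulative = [score(ranking[: k + 1]) for k in range(len(ranking))]
    return ranking, cumulative
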