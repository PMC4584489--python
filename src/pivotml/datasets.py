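"""Synthetic data generators.

Two families of inputs are needed to exercise the pipeline end to end:

* EAV clinical tables with a known wide-format ground truth — a wide table
  of patient lab-test values is drawn first and then melted into the tall
  (entity, attribute, value) layout, with configurable per-cell missingness
  and injected duplicate measurements, optionally scattered across two
  source tables;
* binary-outcome classification tasks with known structure — a Gaussian
  location-shift task whose Bayes-optimal AUC has the closed form
  Phi(||m|| / sqrt(2)), and an XOR (interaction-only) task on which any
  linear score is uninformative while axis-aligned partitioning succeeds.

All generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SyntheticSpec",
    "generate_eav",
    "generate_gaussian_task",
    "generate_xor_task",
    "gaussian_bayes_auc",
]


@dataclass
class SyntheticSpec:
    """Knobs for the generators; rates are per-cell probabilities in [0, 1]."""

    n_patients: int = 100
    n_parameters: int = 3
    missing_rate: float = 0.0
    duplicate_rate: float = 0.0
    split_tables: bool = False
    n_instances: int = 1000
    n_features: int = 2
    class_separation: float = 2.0  # ||m|| of the Gaussian task
    label_noise: float = 0.05  # XOR task flip rate
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.missing_rate <= 1.0 and 0.0 <= self.duplicate_rate <= 1.0):
            raise ValueError("rates must lie in [0, 1]")
        if min(self.n_patients, self.n_parameters, self.n_instances) < 1:
            raise ValueError("counts must be >= 1")


def generate_eav(spec: SyntheticSpec) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """EAV table(s) plus the wide ground truth they were melted from.

    Entities are patient-visit keys ('p0001-t1'); attributes are the lab
    tests 'test 1' ... 'test k'; values are decimal strings with fixed
    precision so CSV round trips are byte-exact.  Missing cells are dropped
    from the EAV output; a duplicate measurement is injected by placing a
    perturbed copy of a cell *before* the true one, so duplicate_policy
    'last' recovers the ground truth while 'first' picks the perturbed
    value.  With split_tables the records are split by attribute parity
    into two tables to exercise the multi-table pivot case.
    """
    rng = np.random.default_rng(spec.seed)
    attributes = [f"test {j + 1}" for j in range(spec.n_parameters)]
    entities = [f"p{i + 1:04d}-t1" for i in range(spec.n_patients)]
    values = rng.normal(100.0, 15.0, size=(spec.n_patients, spec.n_parameters))
    wide = pd.DataFrame(
        [[f"{v:.2f}" for v in row] for row in values],
        columns=attributes, dtype=object,
    )
    wide.insert(0, "entity", entities)

    missing = rng.random((spec.n_patients, spec.n_parameters)) < spec.missing_rate
    duplicate = rng.random((spec.n_patients, spec.n_parameters)) < spec.duplicate_rate

    rows: list[tuple[str, str, str]] = []
    for i, entity in enumerate(entities):
        for j, attribute in enumerate(attributes):
            if missing[i, j]:
                wide.iat[i, j + 1] = None
                continue
            true_value = wide.iat[i, j + 1]
            if duplicate[i, j]:  # stale measurement first, truth last
                stale = f"{float(true_value) + rng.normal(0.0, 5.0):.2f}"
                rows.append((entity, attribute, stale))
            rows.append((entity, attribute, true_value))

    eav = pd.DataFrame(rows, columns=["entity", "attribute", "value"], dtype=object)
    if spec.split_tables:
        odd = eav["attribute"].isin(attributes[0::2])
        tables = [eav[odd].reset_index(drop=True), eav[~odd].reset_index(drop=True)]
    else:
        tables = [eav]
    return tables, wide


def gaussian_bayes_auc(separation: float) -> float:
    """Bayes-optimal AUC of the equal-covariance Gaussian task, Phi(||m||/sqrt 2)."""
    return float(stats.norm.cdf(separation / np.sqrt(2.0)))


def generate_gaussian_task(spec: SyntheticSpec) -> pd.DataFrame:
    """Two spherical Gaussian classes N(0, I) vs N(m, I), equal priors.

    The separation vector m points along the first axis with norm
    ``class_separation``; any extra features are pure noise dimensions of
    the same spherical covariance, so the optimal score stays linear and
    the Bayes AUC keeps its closed form.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_instances, spec.n_features
    y = rng.integers(0, 2, size=n)
    x = rng.normal(0.0, 1.0, size=(n, p))
    x[:, 0] += spec.class_separation * y
    frame = pd.DataFrame(x, columns=[f"x{j + 1}" for j in range(p)])
    frame["outcome"] = y
    return frame


def generate_xor_task(spec: SyntheticSpec) -> pd.DataFrame:
    """Interaction-only signal: outcome = [sign(x1) != sign(x2)], noisy.

    Labels are flipped with probability ``label_noise``.  In large samples
    every linear score has AUC near 0.5 while a two-split axis-aligned
    partition separates the classes.
    """
    if spec.n_instances < 100:
        raise ValueError("XOR task needs n_instances >= 100")
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_instances, max(2, spec.n_features)
    x = rng.normal(0.0, 1.0, size=(n, p))
    y = (np.sign(x[:, 0]) != np.sign(x[:, 1])).astype(int)
    flip = rng.random(n) < spec.label_noise
    y[flip] = 1 - y[flip]
    frame = pd.DataFrame(x, columns=[f"x{j + 1}" for j in range(p)])
    frame["outcome"] = y
    return frame
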