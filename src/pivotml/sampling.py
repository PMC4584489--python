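"""Nested training samples and the fixed disjoint test sample.

A single random sort key is drawn per data instance; instances sorted by
that key form a fixed random permutation.  The first n_test instances are
the test sample for every round; the following n_k instances are round k's
training sample, with n_k doubling each round from an initial size of
max(1000, 10 x n_features).  Training samples are therefore prefix-nested
(each round's sample contains the previous round's) and always disjoint
from the test sample, and the whole schedule is deterministic under its
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ScheduleConfig", "SampleSchedule", "build_schedule"]


@dataclass(frozen=True)
class ScheduleConfig:
    """Sizing rules; defaults follow the progressive-sampling protocol."""

    n_test: int = 3000
    initial_const: int = 1000
    per_feature_const: int = 10
    growth_factor: float = 2.0

    def __post_init__(self) -> None:
        if self.n_test < 1:
            raise ValueError("test sample must be non-empty")
        if self.initial_const < 1 or self.per_feature_const < 0:
            raise ValueError("size constants must be positive")
        if self.growth_factor <= 1.0:
            raise ValueError("growth_factor must exceed 1")


@dataclass
class SampleSchedule:
    n_instances: int
    n_features: int
    n_test: int
    initial_size: int
    growth_factor: float
    permutation: np.ndarray = field(repr=False)

    @property
    def max_training(self) -> int:
        return self.n_instances - self.n_test

    def test_sample(self) -> np.ndarray:
        """Indices of the fixed test sample (identical across rounds)."""
        return self.permutation[: self.n_test]

    def training_size(self, round_k: int) -> int:
        if round_k < 1:
            raise ValueError("round_k must be >= 1")
        size = self.initial_size * self.growth_factor ** (round_k - 1)
        return int(min(size, self.max_training))

    def training_sample(self, round_k: int) -> np.ndarray:
        """Indices of round k's training sample, nested within round k+1's."""
        n_k = self.training_size(round_k)
        return self.permutation[self.n_test : self.n_test + n_k]

    def full_training_sample(self) -> np.ndarray:
        """Everything outside the test block (the final round's training set)."""
        return self.permutation[self.n_test :]


def build_schedule(
    n_instances: int,
    n_features: int,
    config: ScheduleConfig | None = None,
    seed: int | None = None,
) -> SampleSchedule:
    """Draw the random permutation and size the sample sequence.

    The permutation is the argsort of one seeded uniform draw per instance
    (ties broken by original index).  Initial training size is
    max(initial_const, per_feature_const * n_features).  Small-data
    fallback: when the data cannot host the configured test sample plus the
    initial training sample, n_test shrinks to at most a third of the data
    and training is capped at the remainder, preserving a disjoint
    held-out sample on small fixtures.
    """
    config = config or ScheduleConfig()
    if n_instances < 10:
        raise ValueError("need at least 10 data instances")
    rng = np.random.default_rng(seed)
    keys = rng.random(n_instances)
    permutation = np.argsort(keys, kind="stable")

    initial = max(config.initial_const, config.per_feature_const * n_features)
    n_test = config.n_test
    if n_test + initial > n_instances:
        n_test = min(config.n_test, n_instances // 3)
    initial = min(initial, n_instances - n_test)
    return SampleSchedule(
        n_instances=n_instances,
        n_features=n_features,
        n_test=n_test,
        initial_size=initial,
        growth_factor=config.growth_factor,
        permutation=permutation,
    )
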