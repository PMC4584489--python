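"""Power computations for two-group model-comparison designs.

Two designs are covered, both on the scale of a standardized difference
(Cohen's d) between two independent groups of per-analyst AUC outcomes:

* a one-sided two-sample t-test of superiority, and
* the TOST (two one-sided tests) procedure for equivalence within
  pre-specified limits on the d scale.

Powers are computed analytically from the noncentral t distribution
(TOST by exact quadrature over the pooled-SD distribution) and can be
cross-checked by Monte-Carlo simulation of the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

__all__ = [
    "PowerQuery",
    "power_two_sample_t",
    "power_tost",
    "simulate_tost_power",
    "simulate_two_sample_t_power",
]


@dataclass(frozen=True)
class PowerQuery:
    """A power question: per-group size, true effect, level, TOST limits.

    Parameters
    ----------
    n_per_group : int
        Number of independent observations in each group (>= 2).
    d : float
        True standardized mean difference between the groups.
    alpha : float
        One-sided significance level of each test, in (0, 1).
    lower, upper : float
        Equivalence limits on the d scale (TOST only); lower < upper.
    """

    n_per_group: int
    d: float
    alpha: float = 0.05
    lower: float = -2.0
    upper: float = 2.0

    def validate(self, *, tost: bool = False) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if tost and not self.lower < self.upper:
            raise ValueError("equivalence limits must satisfy lower < upper")


def power_two_sample_t(query: PowerQuery) -> float:
    """Power of the one-sided two-sample t-test (H1: group 1 > group 2).

    With n per group and true standardized difference d, the t statistic
    follows a noncentral t with df = 2n - 2 and noncentrality d * sqrt(n/2).
    """
    query.validate()
    n, d, alpha = query.n_per_group, query.d, query.alpha
    df = 2 * n - 2
    t_crit = stats.t.ppf(1.0 - alpha, df)
    ncp = d * np.sqrt(n / 2.0)
    return float(1.0 - stats.nct.cdf(t_crit, df, ncp))


def power_tost(query: PowerQuery) -> float:
    """Exact power of the TOST equivalence procedure on the d scale.

    Both one-sided tests must reject at level alpha: the observed mean
    difference must exceed lower + t_crit*SE and fall below
    upper - t_crit*SE, where SE = S_pooled * sqrt(2/n).  Power is obtained
    by integrating the normal probability of that window over the exact
    (scaled-chi) distribution of the pooled standard deviation.
    """
    query.validate(tost=True)
    if np.isinf(query.lower) and np.isinf(query.upper):
        return 1.0
    n, d, alpha = query.n_per_group, query.d, query.alpha
    lower, upper = query.lower, query.upper
    df = 2 * n - 2
    t_crit = stats.t.ppf(1.0 - alpha, df)
    se0 = np.sqrt(2.0 / n)  # SE of the mean difference at sigma = 1

    def integrand(s: float) -> float:
        lo = (lower + t_crit * s * se0 - d) / se0
        hi = (upper - t_crit * s * se0 - d) / se0
        window = max(0.0, stats.norm.cdf(hi) - stats.norm.cdf(lo))
        # density of S_pooled: sqrt(df)*S ~ chi(df)
        return window * stats.chi.pdf(s * np.sqrt(df), df) * np.sqrt(df)

    value, _ = integrate.quad(integrand, 0.0, 10.0, limit=200)
    return float(min(1.0, value))


def simulate_two_sample_t_power(
    query: PowerQuery, n_rep: int = 100_000, seed: int | None = None
) -> float:
    """Monte-Carlo estimate of :func:`power_two_sample_t`."""
    query.validate()
    rng = np.random.default_rng(seed)
    n, d = query.n_per_group, query.d
    df = 2 * n - 2
    t_crit = stats.t.ppf(1.0 - query.alpha, df)
    x = rng.normal(d, 1.0, size=(n_rep, n))
    y = rng.normal(0.0, 1.0, size=(n_rep, n))
    se = np.sqrt((x.var(axis=1, ddof=1) + y.var(axis=1, ddof=1)) / 2) * np.sqrt(2.0 / n)
    t = (x.mean(axis=1) - y.mean(axis=1)) / se
    return float(np.mean(t > t_crit))


def simulate_tost_power(
    query: PowerQuery, n_rep: int = 100_000, seed: int | None = None
) -> float:
    """Monte-Carlo estimate of :func:`power_tost` by simulating both tests."""
    query.validate(tost=True)
    rng = np.random.default_rng(seed)
    n, d = query.n_per_group, query.d
    df = 2 * n - 2
    t_crit = stats.t.ppf(1.0 - query.alpha, df)
    x = rng.normal(d, 1.0, size=(n_rep, n))
    y = rng.normal(0.0, 1.0, size=(n_rep, n))
    diff = x.mean(axis=1) - y.mean(axis=1)
    se = np.sqrt((x.var(axis=1, ddof=1) + y.var(axis=1, ddof=1)) / 2) * np.sqrt(2.0 / n)
    reject_low = (diff - query.lower) / se > t_crit
    reject_high = (diff - query.upper) / se < -t_crit
    return float(np.mean(reject_low & reject_high))
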