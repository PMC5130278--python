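"""Mendelian-randomisation design calculations.

Required sample size and power for detecting a causal odds ratio on a binary
outcome through a polygenic-score instrument that explains a fraction r2 of
the exposure's variance.  Standard non-centrality/Wald design formula: the
instrument-outcome log-OR test has non-centrality

    lambda = n * r2 * (ln OR)^2 * phi * (1 - phi),

with phi the case fraction, so the total sample size for two-sided level
alpha and target power is

    n = (z_{1-alpha/2} + z_{power})^2 / (r2 (ln OR)^2 phi (1 - phi)).

Reported design sizes are rounded UP to a granularity of 100 individuals by
default (conservative design numbers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

__all__ = ["PowerQuery", "required_n_binary", "power_binary",
           "required_n_continuous"]


@dataclass(frozen=True)
class PowerQuery:
    """Design query for a binary-outcome MR analysis."""

    odds_ratio: float
    r2: float
    alpha: float = 0.05
    power: float = 0.80
    case_fraction: float = 0.5

    def __post_init__(self):
        if self.odds_ratio <= 0:
            raise ValueError("odds_ratio must be > 0")
        if not 0 < self.r2 < 1:
            raise ValueError("r2 must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must lie in (0, 1)")
        if not 0 < self.case_fraction < 1:
            raise ValueError("case_fraction must lie in (0, 1)")


def required_n_binary(q: PowerQuery, granularity: int = 100):
    """Total sample size for the binary-outcome MR design.

    Returns ``(n_raw, n_reported)`` with ``n_reported`` the raw size rounded
    up to the next multiple of ``granularity``.
    """
    if q.odds_ratio == 1:
        raise ValueError("odds_ratio = 1 implies no effect: required n is infinite")
    if granularity < 1:
        raise ValueError("granularity must be >= 1")
    z_a = stats.norm.ppf(1 - q.alpha / 2)
    z_b = stats.norm.ppf(q.power)
    phi = q.case_fraction
    n_raw = (z_a + z_b) ** 2 / (q.r2 * math.log(q.odds_ratio) ** 2 * phi * (1 - phi))
    n_reported = int(math.ceil(n_raw / granularity) * granularity)
    return n_raw, n_reported


def power_binary(n: float, q: PowerQuery) -> float:
    """Power at total sample size n (exact inverse of required_n_binary)."""
    if n <= 0:
        raise ValueError("n must be > 0")
    z_a = stats.norm.ppf(1 - q.alpha / 2)
    phi = q.case_fraction
    lam = n * q.r2 * math.log(q.odds_ratio) ** 2 * phi * (1 - phi)
    return float(stats.norm.cdf(math.sqrt(lam) - z_a))


def required_n_continuous(beta: float, r2: float, alpha: float = 0.05,
                          power: float = 0.80) -> float:
    """Sample size for a continuous outcome: causal effect in SD units."""
    if beta == 0:
        raise ValueError("beta = 0 implies no effect: required n is infinite")
    if not 0 < r2 < 1:
        raise ValueError("r2 must lie in (0, 1)")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie in (0, 1)")
    z_a = stats.norm.ppf(1 - alpha / 2)
    z_b = stats.norm.ppf(power)
    return (z_a + z_b) ** 2 / (r2 * beta ** 2)
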