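"""Statistical power for two-sample MR with a binary outcome.

The asymptotic approximation treats the IVW estimate of the causal log
odds ratio as normal with standard error
``1 / sqrt(n * r2 * K * (1 - K))``, where n is the outcome sample size, r2
the exposure variance explained by the instruments, and K the case
fraction.  The two-sided test's non-centrality is therefore
``|log OR| * sqrt(n * r2 * K * (1-K))`` and

    power = Phi(ncp - z_{1-alpha/2}) + Phi(-ncp - z_{1-alpha/2}).

Power is exactly alpha at OR = 1 and strictly increasing in |log OR|,
n and r2.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigurationError


@dataclasses.dataclass(frozen=True)
class PowerQuery:
    """One power evaluation: outcome study size and composition, instrument
    strength, test level and the hypothesized true OR per SD of exposure."""

    n_outcome: int
    case_fraction: float
    r2_instruments: float
    detectable_or: float
    alpha: float = 0.05

    def __post_init__(self):
        if not 0 < self.case_fraction < 1:
            raise ConfigurationError("case_fraction must lie in (0, 1)")
        if not 0 < self.r2_instruments < 1:
            raise ConfigurationError("r2_instruments must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.n_outcome <= 0 or self.detectable_or <= 0:
            raise ConfigurationError("n_outcome and detectable_or must be positive")


def mr_power_binary(q: PowerQuery) -> float:
    """Asymptotic power of the two-sided IVW test at level alpha."""
    k = q.case_fraction
    ncp = abs(math.log(q.detectable_or)) * math.sqrt(
        q.n_outcome * q.r2_instruments * k * (1 - k)
    )
    z = stats.norm.ppf(1 - q.alpha / 2)
    return float(stats.norm.cdf(ncp - z) + stats.norm.cdf(-ncp - z))


def detectable_or(
    n_outcome: int,
    case_fraction: float,
    r2_instruments: float,
    power: float = 0.8,
    alpha: float = 0.05,
) -> float:
    """Smallest OR > 1 detectable with the requested power (the inverse
    query; by symmetry 1/OR is detectable on the protective side)."""
    if not alpha < power < 1:
        raise ConfigurationError("power must lie in (alpha, 1)")

    def gap(log_or: float) -> float:
        q = PowerQuery(n_outcome, case_fraction, r2_instruments,
                       math.exp(log_or), alpha)
        return mr_power_binary(q) - power

    return float(math.exp(optimize.brentq(gap, 1e-9, 10.0)))


def power_curve(
    or_grid,
    n_outcome: int,
    case_fraction: float,
    r2_instruments: float,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Power across a grid of hypothesized ORs, as a two-column table."""
    rows = [
        {"or": float(o),
         "power": mr_power_binary(PowerQuery(n_outcome, case_fraction,
                                             r2_instruments, float(o), alpha))}
        for o in np.asarray(or_grid, dtype=float)
    ]
    return pd.DataFrame(rows)
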