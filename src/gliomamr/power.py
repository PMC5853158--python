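"""A priori power and instrument-strength calculations for two-sample MR.

Power for a binary-outcome MR study is approximated from the outcome GWAS
size, the case fraction, the proportion of exposure variance explained by
the instruments (R^2), and the causal OR to detect:

    power = Phi(d - z_{1-a/2}) + Phi(-d - z_{1-a/2}),
    d = sqrt(n * R^2 * ratio * (1 - ratio)) * |ln OR|

with ``n`` the total outcome GWAS size and ``ratio`` the case fraction.
Both rejection tails are counted, so the power tends to the significance
level exactly as R^2 -> 0 or OR -> 1, and is symmetric in OR <-> 1/OR.

Instrument strength is summarised by the first-stage F statistic
``F = (n - k - 1)/k * R^2/(1 - R^2)``; F > 10 is the usual rule of thumb for
negligible weak-instrument bias.

R^2 is an input here (published heritability estimates differ by trait and
source); :func:`snp_r_squared` provides the standard single-SNP
approximation ``2 p (1-p) beta^2`` for user-supplied instruments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

from scipy import stats

__all__ = ["PowerInput", "approx_power", "f_statistic", "snp_r_squared", "power_grid"]


@dataclass
class PowerInput:
    """Design parameters of a two-sample MR power calculation."""

    n_cases: int
    n_controls: int
    r_squared: float     # exposure variance explained by the IV set
    target_or: float     # hypothesised causal OR (per doubling for binary exposures)
    alpha: float = 0.05
    k_instruments: int = 1

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("case and control counts must be positive")
        if not 0 <= self.r_squared < 1:
            raise ValueError(f"r_squared must be in [0, 1), got {self.r_squared}")
        if self.target_or <= 0:
            raise ValueError("target_or must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.k_instruments < 1:
            raise ValueError("k_instruments must be >= 1")


def approx_power(inp: PowerInput) -> float:
    """Two-sided a priori power of the MR design in [0, 1]."""
    n = inp.n_cases + inp.n_controls
    ratio = inp.n_cases / n
    z = stats.norm.ppf(1 - inp.alpha / 2)
    d = math.sqrt(n * inp.r_squared * ratio * (1 - ratio)) * abs(math.log(inp.target_or))
    return float(stats.norm.cdf(d - z) + stats.norm.cdf(-d - z))


def f_statistic(r_squared: float, n_sample: int, k_instruments: int) -> float:
    """First-stage F statistic of the exposure GWAS.

    ``F = (n - k - 1)/k * R^2/(1 - R^2)``.
    """
    if not 0 <= r_squared < 1:
        raise ValueError(f"r_squared must be in [0, 1), got {r_squared}")
    if k_instruments < 1 or n_sample <= k_instruments + 1:
        raise ValueError(
            f"need n_sample > k_instruments + 1 (got n={n_sample}, k={k_instruments})"
        )
    return (n_sample - k_instruments - 1) / k_instruments * r_squared / (1 - r_squared)


def snp_r_squared(beta: float, eaf: float) -> float:
    """Variance in a standardised trait explained by one SNP: 2 p (1-p) beta^2."""
    if not 0 < eaf < 1:
        raise ValueError(f"eaf must be in (0, 1), got {eaf}")
    return 2 * eaf * (1 - eaf) * beta**2


def power_grid(
    n_cases: int,
    n_controls: int,
    r_squared: float,
    or_grid: Iterable[float],
    alpha: float = 0.05,
    k_instruments: int = 1,
):
    """Power over a grid of target ORs; returns a list of (OR, power) pairs."""
    out = []
    for orr in or_grid:
        inp = PowerInput(n_cases, n_controls, r_squared, orr, alpha, k_instruments)
        out.append((float(orr), approx_power(inp)))
    return out
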