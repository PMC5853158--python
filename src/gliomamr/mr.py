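"""Causal-effect estimators for two-sample Mendelian randomisation.

All estimators consume harmonised instruments: per-SNP exposure effects
``X_k`` (log-OR per effect allele, or per-SD effect for continuous
exposures) with SE ``sigma_Xk``, and outcome effects ``Y_k`` (log-OR) with
SE ``sigma_Yk``, both aligned to the same effect allele.

Implemented methods:

* **Wald ratio** per SNP: ``theta_k = Y_k / X_k``.
* **IVW** (inverse-variance weighting):
  ``beta = sum(X Y / sigma_Y^2) / sum(X^2 / sigma_Y^2)``,
  ``se = sqrt(1 / sum(X^2 / sigma_Y^2))``; algebraically identical to a
  weighted least-squares fit of Y on X through the origin with weights
  ``sigma_Y^-2`` and to a fixed-effect meta-analysis of the Wald ratios.
* **MLE**: joint bivariate-normal likelihood over the causal slope and the
  per-SNP true exposure effects, optionally with a non-zero correlation
  ``rho`` between the errors of X_k and Y_k; SE from observed information.
* **Weighted median**: interpolated 50th weight-percentile of the ordered
  Wald ratios; robust when at least half the weight is on valid instruments.
* **Mode-based estimate**: argmax of an inverse-variance-weighted kernel
  density of the Wald ratios; robust when the largest cluster is valid.
* **MR-Egger**: weighted regression of Y on X with a free intercept after
  orienting instruments to positive exposure effect; the intercept measures
  average directional pleiotropy.

For binary exposures, estimates on the log-odds-of-exposure scale are
rescaled by ln 2 (:func:`per_doubling`) so that ``exp(beta)`` is the outcome
OR per doubling in odds of the exposure.

Significance conventions follow the source analysis: 0.05 nominal, 0.0125
Bonferroni across four traits, 0.00625 across four traits x two subtypes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .sumstats import HarmonisedInstrument

__all__ = [
    "MREstimate",
    "RatioEstimate",
    "EggerResult",
    "ConvergenceError",
    "wald_ratio",
    "ivw",
    "mle",
    "rho_sensitivity",
    "weighted_median",
    "mode_based",
    "egger",
    "per_doubling",
    "SIGNIFICANCE_TIERS",
]

LN2 = math.log(2.0)

#: P-value ledger: nominal / Bonferroni over 4 traits / 4 traits x 2 subtypes
SIGNIFICANCE_TIERS = {"nominal": 0.05, "bonferroni": 0.0125, "subtype": 0.00625}


class ConvergenceError(RuntimeError):
    """Likelihood optimisation failed; message carries diagnostics."""


@dataclass
class RatioEstimate:
    """Single-SNP Wald ratio estimate ``theta = Y/X``."""

    snp_id: str
    theta: float
    se_theta: float

    def __post_init__(self) -> None:
        if not self.se_theta > 0:
            raise ValueError(f"{self.snp_id}: se_theta must be > 0")


@dataclass
class MREstimate:
    """A causal-effect estimate from one MR method.

    ``beta`` is the causal log-OR of the outcome per unit increase in the
    log odds of the exposure (per SD for continuous exposures), or per
    doubling of exposure odds when ``scale == "per-doubling"``.
    """

    method: str
    beta: float
    se: float
    p_value: float
    n_snps: int
    scale: str = "per-log-odds"
    level: float = 0.95

    @property
    def _z(self) -> float:
        return stats.norm.ppf(0.5 + self.level / 2)

    @property
    def ci_lower(self) -> float:
        return self.beta - self._z * self.se

    @property
    def ci_upper(self) -> float:
        return self.beta + self._z * self.se

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    @property
    def or_ci(self) -> tuple[float, float]:
        return math.exp(self.ci_lower), math.exp(self.ci_upper)

    def __str__(self) -> str:
        lo, hi = self.or_ci
        return (
            f"{self.method}: OR {self.odds_ratio:.3f} "
            f"({lo:.3f}-{hi:.3f}), P = {self.p_value:.3g} "
            f"[{self.n_snps} SNPs, {self.scale}]"
        )


@dataclass
class EggerResult:
    slope: MREstimate
    intercept: MREstimate


def _arrays(
    instruments: Sequence[HarmonisedInstrument],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    x = np.array([i.x for i in instruments], dtype=float)
    sx = np.array([i.sigma_x for i in instruments], dtype=float)
    y = np.array([i.y for i in instruments], dtype=float)
    sy = np.array([i.sigma_y for i in instruments], dtype=float)
    return x, sx, y, sy


def _normal_p(beta: float, se: float) -> float:
    return 2 * stats.norm.sf(abs(beta / se))


def wald_ratio(inst: HarmonisedInstrument, second_order: bool = False) -> RatioEstimate:
    """Single-SNP causal estimate ``Y/X`` with a delta-method SE.

    The default first-order SE, ``sigma_Y / |X|``, ignores exposure-side
    uncertainty and matches the IVW weighting; ``second_order=True`` adds
    the exposure-side term ``Y^2 sigma_X^2 / X^4``.
    """
    if inst.x == 0:
        raise ZeroDivisionError(f"{inst.snp_id}: zero exposure effect")
    theta = inst.y / inst.x
    var = inst.sigma_y**2 / inst.x**2
    if second_order:
        var += inst.y**2 * inst.sigma_x**2 / inst.x**4
    return RatioEstimate(inst.snp_id, theta, math.sqrt(var))


def ivw(instruments: Sequence[HarmonisedInstrument]) -> MREstimate:
    """Inverse-variance-weighted estimate over all instruments."""
    if len(instruments) < 2:
        raise ValueError("IVW requires at least 2 instruments")
    x, _, y, sy = _arrays(instruments)
    if np.any(x == 0):
        raise ZeroDivisionError("zero exposure effect among instruments")
    w = sy**-2.0
    denom = np.sum(x**2 * w)
    beta = float(np.sum(x * y * w) / denom)
    se = float(np.sqrt(1.0 / denom))
    return MREstimate("ivw", beta, se, _normal_p(beta, se), len(instruments))


def _profiled_xi(x, sx, y, sy, beta: float, rho: float) -> np.ndarray:
    # closed-form minimiser over the per-SNP true effects xi_k
    a = 1 / sx**2 - 2 * rho * beta / (sx * sy) + beta**2 / sy**2
    b = -x / sx**2 + rho * (y + beta * x) / (sx * sy) - beta * y / sy**2
    return -b / a


def _joint_nll(x, sx, y, sy, beta: float, xi: np.ndarray, rho: float) -> float:
    u = (x - xi) / sx
    v = (y - beta * xi) / sy
    return float(0.5 / (1 - rho**2) * np.sum(u**2 - 2 * rho * u * v + v**2))


def mle(
    instruments: Sequence[HarmonisedInstrument],
    rho: float = 0.0,
) -> MREstimate:
    """Maximum-likelihood estimate under a bivariate-normal error model.

    ``(X_k, Y_k)`` is modelled as bivariate normal with mean
    ``(xi_k, beta xi_k)``, marginal SDs ``(sigma_Xk, sigma_Yk)`` and error
    correlation ``rho`` (0 for non-overlapping samples).  The nuisance
    ``xi_k`` are profiled out analytically; the SE comes from the observed
    information (numerical Hessian of the joint negative log-likelihood at
    the optimum).
    """
    if len(instruments) < 2:
        raise ValueError("MLE requires at least 2 instruments")
    if not -1 < rho < 1:
        raise ValueError(f"rho must be in (-1, 1), got {rho}")
    x, sx, y, sy = _arrays(instruments)

    def profile_nll(beta: float) -> float:
        xi = _profiled_xi(x, sx, y, sy, beta, rho)
        return _joint_nll(x, sx, y, sy, beta, xi, rho)

    start = ivw(instruments).beta
    res = optimize.minimize_scalar(
        profile_nll, bracket=(start - 1.0, start, start + 1.0), method="brent",
        options={"xtol": 1e-10},
    )
    if not res.success or not np.isfinite(res.x):
        raise ConvergenceError(
            f"MLE optimiser failed (rho={rho}): {getattr(res, 'message', res)}"
        )
    beta = float(res.x)
    xi = _profiled_xi(x, sx, y, sy, beta, rho)

    theta0 = np.concatenate([[beta], xi])

    def full(theta: np.ndarray) -> float:
        return _joint_nll(x, sx, y, sy, theta[0], theta[1:], rho)

    n = theta0.size
    h = 1e-5 * np.maximum(np.abs(theta0), 1.0)
    hess = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            hess[i, j] = hess[j, i] = (
                full(theta0 + ei + ej) - full(theta0 + ei - ej)
                - full(theta0 - ei + ej) + full(theta0 - ei - ej)
            ) / (4 * h[i] * h[j])
    try:
        cov_bb = float(np.linalg.inv(hess)[0, 0])
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError(f"singular observed information at beta={beta}") from exc
    if cov_bb <= 0:
        raise ConvergenceError(
            f"observed information not positive definite at beta={beta}"
        )
    se = math.sqrt(cov_bb)
    return MREstimate("mle", beta, se, _normal_p(beta, se), len(instruments))


def rho_sensitivity(
    instruments: Sequence[HarmonisedInstrument],
    rho_grid: Sequence[float],
) -> pd.DataFrame:
    """Re-fit the MLE over a grid of error correlations.

    Returns a DataFrame ordered by ``rho`` with columns
    ``rho, beta, se, p_value``.
    """
    grid = sorted(float(r) for r in rho_grid)
    if not grid:
        raise ValueError("rho grid is empty")
    rows = []
    for r in grid:
        est = mle(instruments, rho=r)
        rows.append({"rho": r, "beta": est.beta, "se": est.se, "p_value": est.p_value})
    return pd.DataFrame(rows)


def _weighted_median_point(theta: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(theta)
    t, w = theta[order], weights[order]
    cum = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, cum, t))


def weighted_median(
    instruments: Sequence[HarmonisedInstrument],
    n_boot: int = 10_000,
    seed: int = 1,
) -> MREstimate:
    """Weighted median of Wald ratios with a parametric-bootstrap SE.

    The point estimate interpolates the 50th percentile of the cumulative
    inverse-variance weights of the ordered per-SNP ratios and is
    deterministic; SE and p-value come from ``n_boot`` parametric bootstrap
    resamples of ``(X_k, Y_k)`` from normals at their observed values.
    """
    if len(instruments) < 3:
        raise ValueError("weighted median requires at least 3 instruments")
    x, sx, y, sy = _arrays(instruments)
    theta = y / x
    w = (sy / np.abs(x)) ** -2.0
    beta = _weighted_median_point(theta, w)

    rng = np.random.default_rng(seed)
    xb = rng.normal(x, sx, size=(n_boot, x.size))
    yb = rng.normal(y, sy, size=(n_boot, x.size))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        tb = yb[b] / xb[b]
        wb = (sy / np.abs(xb[b])) ** -2.0
        boots[b] = _weighted_median_point(tb, wb)
    se = float(np.std(boots, ddof=1))
    return MREstimate("wme", beta, se, _normal_p(beta, se), len(instruments))


def _mbe_bandwidth(theta: np.ndarray, phi: float) -> float:
    # modified Silverman rule: 0.9 min(sd, normalised MAD) n^(-1/5)
    sd = float(np.std(theta, ddof=1))
    mad = float(stats.median_abs_deviation(theta, scale="normal"))
    s = min(sd, mad) if mad > 0 else sd
    return phi * 0.9 * s * theta.size ** (-1 / 5)


def _mbe_point(theta: np.ndarray, weights: np.ndarray, h: float) -> float:
    if h <= 0 or np.ptp(theta) == 0:
        return float(theta[np.argmax(weights)])
    w = weights / weights.sum()
    grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h, 4001)
    dens = np.exp(-0.5 * ((grid[:, None] - theta[None, :]) / h) ** 2) @ w
    k = int(np.argmax(dens))
    lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, grid.size - 1)]

    def negdens(t: float) -> float:
        return -float(np.exp(-0.5 * ((t - theta) / h) ** 2) @ w)

    res = optimize.minimize_scalar(negdens, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    return float(res.x)


def mode_based(
    instruments: Sequence[HarmonisedInstrument],
    phi: float = 1.0,
    n_boot: int = 10_000,
    seed: int = 1,
) -> MREstimate:
    """Weighted mode-based estimate: argmax of a kernel-smoothed density of
    the Wald ratios with inverse-variance weights.

    The Gaussian kernel bandwidth is ``phi`` times the modified Silverman
    rule.  Point estimate is deterministic for fixed ``phi``; SE and
    p-value come from a seeded parametric bootstrap.
    """
    if len(instruments) < 3:
        raise ValueError("mode-based estimate requires at least 3 instruments")
    if phi <= 0:
        raise ValueError(f"bandwidth multiplier phi must be > 0, got {phi}")
    x, sx, y, sy = _arrays(instruments)
    theta = y / x
    w = (sy / np.abs(x)) ** -2.0
    beta = _mbe_point(theta, w, _mbe_bandwidth(theta, phi))

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        xb = rng.normal(x, sx)
        yb = rng.normal(y, sy)
        tb = yb / xb
        wb = (sy / np.abs(xb)) ** -2.0
        boots[b] = _mbe_point_fast(tb, wb, _mbe_bandwidth(tb, phi))
    se = float(np.std(boots, ddof=1))
    return MREstimate("mbe", beta, se, _normal_p(beta, se), len(instruments))


def _mbe_point_fast(theta: np.ndarray, weights: np.ndarray, h: float) -> float:
    # coarser grid without local refinement, for bootstrap replicates
    if h <= 0 or np.ptp(theta) == 0:
        return float(theta[np.argmax(weights)])
    w = weights / weights.sum()
    grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h, 512)
    dens = np.exp(-0.5 * ((grid[:, None] - theta[None, :]) / h) ** 2) @ w
    return float(grid[np.argmax(dens)])


def egger(
    instruments: Sequence[HarmonisedInstrument],
    normal_p: bool = False,
) -> EggerResult:
    """MR-Egger regression: weighted fit of Y on X with a free intercept.

    Instruments are first oriented so every exposure effect is positive;
    weights are ``sigma_Y^-2``.  The slope is the pleiotropy-adjusted causal
    estimate and the intercept the average directional pleiotropy per
    instrument.  P-values use the t distribution with K-2 df (regression
    convention) unless ``normal_p`` is set.
    """
    if len(instruments) < 3:
        raise ValueError("MR-Egger requires at least 3 instruments")
    x, _, y, sy = _arrays(instruments)
    sign = np.where(x < 0, -1.0, 1.0)
    xo, yo = x * sign, y * sign
    if np.ptp(xo) == 0:
        raise ValueError("zero variance in exposure effects after orientation")
    design = sm.add_constant(xo)
    fit = sm.WLS(yo, design, weights=sy**-2.0).fit()
    k = len(instruments)

    def _p(beta: float, se: float) -> float:
        if normal_p:
            return _normal_p(beta, se)
        return 2 * stats.t.sf(abs(beta / se), df=k - 2)

    intercept = MREstimate(
        "egger_intercept", float(fit.params[0]), float(fit.bse[0]),
        _p(float(fit.params[0]), float(fit.bse[0])), k,
    )
    slope = MREstimate(
        "egger_slope", float(fit.params[1]), float(fit.bse[1]),
        _p(float(fit.params[1]), float(fit.bse[1])), k,
    )
    return EggerResult(slope=slope, intercept=intercept)


def per_doubling(estimate: MREstimate) -> MREstimate:
    """Rescale a binary-exposure estimate to 'per doubling of exposure odds'.

    Multiplies beta and SE by ln 2 (z-score and p-value are unchanged).
    Apply only to binary exposures; continuous ones are already per SD.
    """
    if estimate.scale == "per-doubling":
        return estimate
    return replace(
        estimate, beta=estimate.beta * LN2, se=estimate.se * LN2, scale="per-doubling"
    )
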