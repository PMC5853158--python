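"""Binary-exposure / binary-outcome generative model and two-sample GWAS
sampling.

The generator produces a cohort of individuals with independent bi-allelic
variants in Hardy-Weinberg equilibrium, a multiplicative-odds exposure
disease, and an outcome disease whose odds respond to the exposure odds:

* genotypes ``g_ij ~ Binomial(2, p_i)`` with ``p_i ~ Uniform(0.1, 0.9)``;
* exposure odds ``x_j = x0 * prod_i w_i ** g_ij`` with per-allele odds
  ratios ``w_i`` drawn from a pool of published GWAS effect sizes;
* outcome odds ``y_j = y0 * 2 ** (log2(x_j) * log2(v))``, where ``v`` is the
  outcome OR per doubling of exposure odds (v = 1 is the causal null);
* disease statuses ``a_j ~ Bernoulli(x_j / (1 + x_j))`` and
  ``b_j ~ Bernoulli(y_j / (1 + y_j))``.

The cohort is split at random into two halves; per-variant case-control
association statistics are computed by additive logistic regression of the
exposure status on allele count in one half and of the outcome status in the
other, mimicking two non-overlapping GWAS.  The resulting instrument sets
feed the same estimators as real summary statistics, which makes the
generator both the evaluation harness for the MR methods and the package's
synthetic-data source.

Baselines ``x0 = 0.0005`` and ``y0 = 0.01`` keep disease prevalences in the
range of atopy-related traits and glioma.  The desk-scale default profile is
100,000 individuals and 20 replicates per scenario; the full-scale profile
(1,000,000 individuals, 100 replicates) is available as a preset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import mr
from .sumstats import InstrumentSet, VariantAssociation, load_fixture, harmonise_sets

__all__ = [
    "SimScenario",
    "SimCohort",
    "SimResult",
    "simulate_cohort",
    "two_sample_gwas",
    "run_scenarios",
    "scenario_for_trait",
    "logistic_regression_counts",
    "PROFILES",
]

#: Named problem-size profiles: (n_individuals, n_reps)
PROFILES = {"desk": (100_000, 20), "full": (1_000_000, 100)}


@dataclass
class SimScenario:
    """Generative parameters for one simulation scenario."""

    n_variants: int
    or_pool: tuple[float, ...]
    v: float = 1.0                      # outcome OR per doubling of exposure odds
    allele_freq_range: tuple[float, float] = (0.1, 0.9)
    x0: float = 0.0005                  # baseline exposure odds
    y0: float = 0.01                    # baseline outcome odds
    n_individuals: int = 100_000
    n_cases_exp: int | None = None      # None: use every case in the half
    n_controls_exp: int | None = None
    n_cases_out: int | None = None
    n_controls_out: int | None = None
    n_reps: int = 20
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if not self.or_pool or any(w <= 0 for w in self.or_pool):
            raise ValueError("or_pool must be non-empty with positive ORs")
        if self.v <= 0 or self.x0 <= 0 or self.y0 <= 0:
            raise ValueError("odds and odds ratios must be > 0")
        lo, hi = self.allele_freq_range
        if not 0 < lo < hi < 1:
            raise ValueError(f"invalid allele_freq_range {self.allele_freq_range}")
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        for name in ("n_cases_exp", "n_controls_exp", "n_cases_out", "n_controls_out"):
            val = getattr(self, name)
            if val is not None and not 0 < val <= self.n_individuals // 2:
                raise ValueError(f"{name}={val} exceeds half-cohort size")


@dataclass
class SimCohort:
    """One simulated cohort: genotypes, disease odds and statuses."""

    genotypes: np.ndarray        # (n, N) allele counts in {0, 1, 2}
    allele_freqs: np.ndarray     # drawn p_i
    or_draws: np.ndarray         # drawn w_i
    exposure_odds: np.ndarray
    outcome_odds: np.ndarray
    exposure_status: np.ndarray  # a_j in {0, 1}
    outcome_status: np.ndarray   # b_j in {0, 1}
    half: np.ndarray             # True: exposure-GWAS half, False: outcome half


@dataclass
class SimResult:
    """Per-replicate estimator outputs plus scenario echo."""

    estimates: pd.DataFrame  # label, v, rep, method, beta, se (per doubling)
    scenarios: list[SimScenario]
    seed: int

    def summary(self) -> pd.DataFrame:
        """Per-(scenario, method) mean estimate, Monte-Carlo SE, empirical
        95% coverage of the true per-doubling effect ln(v), and the fraction
        of positive replicates."""
        rows = []
        truth = {s.label: math.log(s.v) for s in self.scenarios}
        for (label, method), grp in self.estimates.groupby(["label", "method"]):
            b = grp["beta"].to_numpy()
            se = grp["se"].to_numpy()
            t = truth[label]
            cover = np.mean(
                (b - 1.959964 * se <= t) & (t <= b + 1.959964 * se)
            ) if np.all(np.isfinite(se)) else np.nan
            rows.append(
                {
                    "label": label,
                    "method": method,
                    "n_reps": len(grp),
                    "true_beta": t,
                    "mean_beta": b.mean(),
                    "mc_se": b.std(ddof=1) / math.sqrt(len(b)),
                    "bias": b.mean() - t,
                    "coverage_95": cover,
                    "frac_positive": float(np.mean(b > 0)),
                }
            )
        return pd.DataFrame(rows)


def scenario_for_trait(
    trait_name: str,
    v: float = 1.0,
    profile: str = "desk",
    **overrides,
) -> SimScenario:
    """Scenario mirroring one packaged trait: same number of variants, and
    per-allele ORs drawn from that trait's published exposure effect sizes."""
    exposure, _ = load_fixture(trait_name)
    pool = tuple(round(math.exp(a.beta), 6) for a in exposure)
    n_ind, n_reps = PROFILES[profile]
    params = dict(
        n_variants=len(exposure),
        or_pool=pool,
        v=v,
        n_individuals=n_ind,
        n_reps=n_reps,
        label=f"{trait_name}_v{v:g}",
    )
    params.update(overrides)
    return SimScenario(**params)


def simulate_cohort(scenario: SimScenario, seed: int) -> SimCohort:
    """Generate one cohort under the multiplicative-odds disease model.

    Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    n, nv = scenario.n_individuals, scenario.n_variants
    p = rng.uniform(*scenario.allele_freq_range, size=nv)
    w = rng.choice(np.asarray(scenario.or_pool, dtype=float), size=nv, replace=True)
    g = rng.binomial(2, p, size=(n, nv)).astype(np.int8)
    # x_j = x0 * prod_i w_i^g_ij, computed in log space
    log_x = math.log(scenario.x0) + g @ np.log(w)
    x = np.exp(log_x)
    # y_j = y0 * 2^(log2 x_j * log2 v)  <=>  ln y = ln y0 + ln x * log2 v
    y = scenario.y0 * np.exp(log_x * math.log2(scenario.v))
    a = rng.binomial(1, x / (1 + x)).astype(np.int8)
    b = rng.binomial(1, y / (1 + y)).astype(np.int8)
    half = np.zeros(n, dtype=bool)
    half[rng.permutation(n)[: n // 2]] = True
    return SimCohort(
        genotypes=g, allele_freqs=p, or_draws=w,
        exposure_odds=x, outcome_odds=y,
        exposure_status=a, outcome_status=b, half=half,
    )


def logistic_regression_counts(
    case_counts: np.ndarray, control_counts: np.ndarray, tol: float = 1e-8
) -> tuple[float, float] | None:
    """Additive logistic regression of case status on allele count (0/1/2).

    Fitted by iteratively reweighted least squares on the genotype-aggregated
    3x2 table (the same MLE as the individual-level fit).  Returns
    ``(beta, se)`` per allele, or ``None`` when the effect is unestimable
    (perfect separation, empty margins, or non-convergence).
    """
    g = np.array([0.0, 1.0, 2.0])
    cases = np.asarray(case_counts, dtype=float)
    ctrls = np.asarray(control_counts, dtype=float)
    n = cases + ctrls
    keep = n > 0
    if keep.sum() < 2 or cases.sum() == 0 or ctrls.sum() == 0:
        return None
    gk, yk, nk = g[keep], cases[keep], n[keep]
    design = np.column_stack([np.ones_like(gk), gk])
    beta = np.zeros(2)
    for _ in range(100):
        mu = 1.0 / (1.0 + np.exp(-(design @ beta)))
        wgt = nk * mu * (1 - mu)
        grad = design.T @ (yk - nk * mu)
        hess = (design * wgt[:, None]).T @ design
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return None
        beta += step
        if np.max(np.abs(step)) < tol:
            break
    else:
        return None
    if abs(beta[1]) > 15:  # drifting towards separation
        return None
    mu = 1.0 / (1.0 + np.exp(-(design @ beta)))
    wgt = nk * mu * (1 - mu)
    hess = (design * wgt[:, None]).T @ design
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return None
    if cov[1, 1] <= 0:
        return None
    return float(beta[1]), float(math.sqrt(cov[1, 1]))


def _sample_case_control(
    status: np.ndarray, n_cases: int | None, n_controls: int | None, rng
) -> np.ndarray:
    """Row indices of the sampled cases and controls (without replacement)."""
    cases = np.flatnonzero(status == 1)
    ctrls = np.flatnonzero(status == 0)
    if n_cases is not None:
        if n_cases > cases.size:
            raise ValueError(
                f"requested {n_cases} cases but only {cases.size} available; "
                "scenario prevalence and sampling sizes are inconsistent"
            )
        cases = rng.choice(cases, size=n_cases, replace=False)
    if n_controls is not None:
        if n_controls > ctrls.size:
            raise ValueError(
                f"requested {n_controls} controls but only {ctrls.size} available"
            )
        ctrls = rng.choice(ctrls, size=n_controls, replace=False)
    return np.concatenate([cases, ctrls])


def two_sample_gwas(
    cohort: SimCohort, scenario: SimScenario, seed: int
) -> tuple[InstrumentSet, InstrumentSet]:
    """Per-variant case-control association statistics from the two halves.

    The exposure GWAS uses the first half and the exposure status, the
    outcome GWAS the second half and the outcome status.  Variants that are
    unestimable in either GWAS are reported absent from that set (and hence
    excluded downstream when the sets are joined by variant id).
    """
    rng = np.random.default_rng(seed)
    sets = []
    specs = [
        ("exposure", cohort.exposure_status, cohort.half,
         scenario.n_cases_exp, scenario.n_controls_exp),
        ("outcome", cohort.outcome_status, ~cohort.half,
         scenario.n_cases_out, scenario.n_controls_out),
    ]
    for name, status, in_half, n_ca, n_co in specs:
        rows = np.flatnonzero(in_half)
        rows = rows[_sample_case_control(status[rows], n_ca, n_co, rng).astype(int)] \
            if (n_ca is not None or n_co is not None) else rows
        st = status[rows]
        geno = cohort.genotypes[rows]
        assocs = []
        for i in range(scenario.n_variants):
            gi = geno[:, i]
            fit = logistic_regression_counts(
                np.bincount(gi[st == 1], minlength=3),
                np.bincount(gi[st == 0], minlength=3),
            )
            if fit is None:
                continue
            beta, se = fit
            assocs.append(
                VariantAssociation(
                    snp_id=f"var{i:04d}",
                    effect_allele="A",
                    other_allele="G",
                    beta=beta,
                    se=se,
                    eaf=float(np.clip(gi.mean() / 2, 1e-6, 1 - 1e-6)),
                )
            )
        sets.append(
            InstrumentSet(
                trait_name=f"sim_{name}",
                exposure_type="binary",
                associations=assocs,
                provenance=f"simulated {name} GWAS ({scenario.label or 'scenario'})",
            )
        )
    return sets[0], sets[1]


_METHODS = ("ivw", "mle", "wme", "mbe", "egger")


def _estimate_all(
    instruments, methods: Sequence[str], n_boot: int, seed: int
) -> dict[str, mr.MREstimate]:
    out = {}
    for m in methods:
        if m == "ivw":
            out[m] = mr.ivw(instruments)
        elif m == "mle":
            out[m] = mr.mle(instruments)
        elif m == "wme":
            out[m] = mr.weighted_median(instruments, n_boot=n_boot, seed=seed)
        elif m == "mbe":
            out[m] = mr.mode_based(instruments, n_boot=n_boot, seed=seed)
        elif m == "egger":
            out[m] = mr.egger(instruments).slope
        else:
            raise ValueError(f"unknown method {m!r}")
    return out


def run_scenarios(
    scenarios: Iterable[SimScenario],
    methods: Sequence[str] = _METHODS,
    seed: int = 1,
    n_boot: int = 200,
) -> SimResult:
    """Full loop: simulate -> two-sample GWAS -> harmonise -> estimate.

    Estimates are returned on the per-doubling scale (true value ln v).
    Replicate seeds are spawned deterministically from ``seed``; running
    twice with the same arguments yields identical results.
    """
    scenarios = list(scenarios)
    unknown = set(methods) - set(_METHODS)
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}")
    root = np.random.SeedSequence(seed)
    rows = []
    for scen, scen_ss in zip(scenarios, root.spawn(len(scenarios))):
        for rep, rep_ss in enumerate(scen_ss.spawn(scen.n_reps)):
            s_cohort, s_gwas, s_boot = rep_ss.generate_state(3) >> np.uint32(1)
            cohort = simulate_cohort(scen, int(s_cohort))
            exp_set, out_set = two_sample_gwas(cohort, scen, int(s_gwas))
            instruments = harmonise_sets(exp_set, out_set)
            ests = _estimate_all(instruments, methods, n_boot, int(s_boot))
            for m, est in ests.items():
                est = mr.per_doubling(est)
                rows.append(
                    {
                        "label": scen.label or f"scenario{scenarios.index(scen)}",
                        "v": scen.v,
                        "rep": rep,
                        "method": m,
                        "beta": est.beta,
                        "se": est.se,
                        "n_snps": est.n_snps,
                    }
                )
    return SimResult(pd.DataFrame(rows), scenarios, seed)
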