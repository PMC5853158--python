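"""Instrument-validity diagnostics: Cochran's Q / I-squared heterogeneity and
HEIDI-outlier screening.

A valid instrument set should produce mutually consistent Wald ratios; excess
spread indicates horizontal pleiotropy.  Cochran's Q measures that spread
against the IVW pooled ratio.  The HEIDI (heterogeneity in dependent
instruments) outlier test compares each SNP's ratio against the ratio of the
reference instrument (the SNP with the strongest exposure association) and
flags SNPs whose deviation is improbable under the null of a shared causal
effect, at the advocated threshold P <= 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mr import RatioEstimate
from .sumstats import HarmonisedInstrument

__all__ = ["HeterogeneityResult", "HeidiReport", "cochran_q", "heidi_outlier"]


@dataclass
class HeterogeneityResult:
    """Cochran's Q heterogeneity across single-SNP Wald ratios."""

    q: float
    df: int
    p_het: float
    i_squared: float  # max(0, (Q - df)/Q), in [0, 1]

    @property
    def i_squared_pct(self) -> int:
        """I-squared as an integer percentage, the usual printed form."""
        return round(100 * self.i_squared)


@dataclass
class HeidiReport:
    """Per-SNP deviation from the reference instrument's Wald ratio."""

    top_snp: str
    table: pd.DataFrame  # snp_id, theta, d, se_d, chi2, p_heidi
    threshold: float
    flagged: list[str] = field(default_factory=list)


def cochran_q(ratios: Sequence[RatioEstimate]) -> HeterogeneityResult:
    """Cochran's Q of the Wald ratios against their IVW pooled mean.

    ``Q = sum w_k (theta_k - theta_ivw)^2`` with ``w_k = se_k^-2``, referred
    to a chi-square distribution with K-1 degrees of freedom.
    """
    if len(ratios) < 2:
        raise ValueError("heterogeneity requires at least 2 ratios")
    theta = np.array([r.theta for r in ratios], dtype=float)
    w = np.array([r.se_theta for r in ratios], dtype=float) ** -2.0
    pooled = np.sum(w * theta) / np.sum(w)
    q = float(np.sum(w * (theta - pooled) ** 2))
    df = len(ratios) - 1
    p_het = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return HeterogeneityResult(q=q, df=df, p_het=p_het, i_squared=i2)


def _heidi_pass(inst: list[HarmonisedInstrument]) -> tuple[str, pd.DataFrame]:
    # reference: strongest exposure association; ties by smaller sigma_x,
    # then rsID, so the choice is reproducible
    top = min(inst, key=lambda i: (-abs(i.x / i.sigma_x), i.sigma_x, i.snp_id))
    x = np.array([i.x for i in inst])
    sx = np.array([i.sigma_x for i in inst])
    y = np.array([i.y for i in inst])
    sy = np.array([i.sigma_y for i in inst])
    theta = y / x
    # second-order delta variance: outlier detection is sensitive to the
    # exposure-side uncertainty, so it is included here (unlike the Q test)
    var = sy**2 / x**2 + y**2 * sx**2 / x**4
    k_top = inst.index(top)
    d = theta - theta[k_top]
    var_d = var + var[k_top]
    chi2 = d**2 / var_d
    p = stats.chi2.sf(chi2, df=1)
    tbl = pd.DataFrame(
        {
            "snp_id": [i.snp_id for i in inst],
            "theta": theta,
            "d": d,
            "se_d": np.sqrt(var_d),
            "chi2": chi2,
            "p_heidi": p,
        }
    )
    tbl.loc[k_top, ["d", "chi2"]] = 0.0
    tbl.loc[k_top, "p_heidi"] = 1.0  # reference never flagged
    return top.snp_id, tbl


def heidi_outlier(
    instruments: Sequence[HarmonisedInstrument],
    p_threshold: float = 0.01,
    iterate: bool = False,
) -> HeidiReport:
    """HEIDI-outlier screen for pleiotropic instruments.

    Each SNP's Wald ratio is compared with the reference instrument's ratio;
    the squared deviation over its delta-method variance is tested against
    chi-square with 1 df.  SNPs with ``p < p_threshold`` are flagged.  With
    ``iterate=True`` the single worst SNP is removed and the test repeated
    until no SNP is below the threshold (the reference is re-chosen each
    round); the default is a single pass.
    """
    if len(instruments) < 3:
        raise ValueError("HEIDI-outlier requires at least 3 instruments")
    inst = list(instruments)
    flagged: list[str] = []
    top_snp, table = _heidi_pass(inst)
    if not iterate:
        flagged = table.loc[table["p_heidi"] < p_threshold, "snp_id"].tolist()
        return HeidiReport(top_snp, table, p_threshold, flagged)

    while True:
        top_snp, table = _heidi_pass(inst)
        bad = table[table["p_heidi"] < p_threshold]
        if bad.empty or len(inst) == 3:
            break
        worst = bad.sort_values(["p_heidi", "snp_id"]).iloc[0]["snp_id"]
        flagged.append(worst)
        inst = [i for i in inst if i.snp_id != worst]
    return HeidiReport(top_snp, table, p_threshold, flagged)
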