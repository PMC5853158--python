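"""Forest and scatter plots for MR analyses (vector output)."""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .mr import EggerResult, MREstimate, RatioEstimate
from .sumstats import HarmonisedInstrument

__all__ = ["forest_plot", "scatter_plot"]

_Z = 1.959964


def forest_plot(
    ratios: Sequence[RatioEstimate],
    pooled: MREstimate,
    out_path,
    title: str = "",
) -> Path:
    """Forest plot of single-SNP Wald ORs with the pooled IVW diamond.

    SNPs are ordered by effect magnitude; bars are 95% CIs on the OR scale.
    """
    if not ratios:
        raise ValueError("need at least one ratio")
    out_path = Path(out_path)
    ordered = sorted(ratios, key=lambda r: r.theta)
    ors = np.array([math.exp(r.theta) for r in ordered])
    lo = np.array([math.exp(r.theta - _Z * r.se_theta) for r in ordered])
    hi = np.array([math.exp(r.theta + _Z * r.se_theta) for r in ordered])

    fig, ax = plt.subplots(figsize=(6, 0.35 * len(ordered) + 1.6))
    ypos = np.arange(len(ordered), 0, -1)
    ax.errorbar(
        ors, ypos, xerr=[ors - lo, hi - ors],
        fmt="s", color="black", ecolor="black", ms=4, lw=1, capsize=2,
    )
    plo, phi_ = pooled.or_ci
    centre = pooled.odds_ratio
    ax.fill(
        [plo, centre, phi_, centre], [0, 0.25, 0, -0.25],
        color="darkred", lw=0,
    )
    ax.axvline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(list(ypos) + [0])
    ax.set_yticklabels([r.snp_id for r in ordered] + [f"pooled ({pooled.method})"])
    ax.set_xscale("log")
    ax.set_xlabel("OR (95% CI)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path)
    plt.close(fig)
    return out_path


def scatter_plot(
    instruments: Sequence[HarmonisedInstrument],
    ivw_fit: MREstimate,
    egger_fit: EggerResult,
    out_path,
    title: str = "",
) -> Path:
    """Scatter of outcome vs exposure effects with IVW and MR-Egger lines.

    Instruments are oriented to positive exposure effect, matching the
    orientation used by the MR-Egger fit.
    """
    if not instruments:
        raise ValueError("need at least one instrument")
    out_path = Path(out_path)
    x = np.array([i.x for i in instruments])
    y = np.array([i.y for i in instruments])
    sx = np.array([i.sigma_x for i in instruments])
    sy = np.array([i.sigma_y for i in instruments])
    sign = np.where(x < 0, -1.0, 1.0)
    x, y = x * sign, y * sign

    # lines are drawn on the raw (per unit log-odds) scale
    ivw_slope = ivw_fit.beta / (math.log(2) if ivw_fit.scale == "per-doubling" else 1.0)
    eg_slope = egger_fit.slope.beta / (
        math.log(2) if egger_fit.slope.scale == "per-doubling" else 1.0
    )
    eg_int = egger_fit.intercept.beta

    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    ax.errorbar(x, y, xerr=_Z * sx, yerr=_Z * sy, fmt="o", ms=4,
                color="black", ecolor="0.6", lw=0.8, capsize=0)
    grid = np.linspace(0, float(x.max()) * 1.05, 50)
    ax.plot(grid, ivw_slope * grid, color="darkred", label="IVW")
    ax.plot(grid, eg_int + eg_slope * grid, color="navy", ls="--", label="MR-Egger")
    ax.axhline(0, color="grey", lw=0.6)
    ax.set_xlabel("SNP effect on exposure (log OR)")
    ax.set_ylabel("SNP effect on outcome (log OR)")
    ax.legend(frameon=False)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path)
    plt.close(fig)
    return out_path
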