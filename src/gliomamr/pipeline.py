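"""End-to-end analysis pipeline: prune, harmonise, screen, estimate, report.

For each trait the pipeline loads an instrument set (packaged fixture or
user-supplied TSVs), optionally LD-prunes it, harmonises exposure and
outcome records, screens instruments with the HEIDI-outlier test, runs all
five MR estimators plus the MR-Egger intercept, quantifies heterogeneity,
applies the per-doubling conversion for binary exposures, and assigns each
association a significance tier (none / potential P < 0.05 / significant
P < 0.0125).  Results serialise deterministically to TSV and JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import mr, pleiotropy, sumstats

__all__ = ["AnalysisReport", "TraitResult", "run_pipeline", "DEFAULT_CONFIG"]

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict[str, Any] = {
    "traits": list(sumstats.FIXTURE_TRAITS),
    "heidi_enabled": True,
    "heidi_threshold": 0.01,
    "heidi_iterate": False,
    "freq_tolerance": 0.08,
    "trust_alignment": True,  # published tables are printed on a common effect allele
    "ld_threshold": 0.001,
    "n_boot": 10_000,
    "seed": 1,
    "rho": 0.0,
    "phi": 1.0,
    "significance_nominal": 0.05,
    "significance_bonferroni": 0.0125,
    "significance_subtype": 0.00625,
}


def _tier(p: float, cfg: Mapping[str, Any]) -> str:
    if p < cfg["significance_bonferroni"]:
        return "significant"
    if p < cfg["significance_nominal"]:
        return "potential"
    return "none"


@dataclass
class TraitResult:
    """All outputs of the pipeline for one exposure trait."""

    trait: str
    exposure_type: str
    n_snps_loaded: int
    n_snps_used: int
    excluded: list[str]
    heidi: pleiotropy.HeidiReport | None
    heterogeneity: pleiotropy.HeterogeneityResult
    estimates: dict[str, mr.MREstimate]     # ivw, mle, wme, mbe, egger_slope
    egger_intercept: mr.MREstimate
    ratios: list[mr.RatioEstimate]
    tiers: dict[str, str]
    instruments: list = field(default_factory=list, repr=False)


@dataclass
class AnalysisReport:
    """Pipeline output across traits, with run metadata."""

    traits: dict[str, TraitResult]
    metadata: dict[str, Any]

    def estimates_frame(self) -> pd.DataFrame:
        rows = []
        for name, tr in self.traits.items():
            ests = dict(tr.estimates)
            ests["egger_intercept"] = tr.egger_intercept
            for method, est in ests.items():
                lo, hi = est.or_ci
                rows.append(
                    {
                        "trait": name,
                        "method": method,
                        "n_snps": est.n_snps,
                        "scale": est.scale,
                        "beta": est.beta,
                        "se": est.se,
                        "or": est.odds_ratio,
                        "or_ci_lower": lo,
                        "or_ci_upper": hi,
                        "p_value": est.p_value,
                        "tier": tr.tiers[method],
                    }
                )
        return pd.DataFrame(rows)

    def heterogeneity_frame(self) -> pd.DataFrame:
        rows = []
        for name, tr in self.traits.items():
            rows.append(
                {
                    "trait": name,
                    "n_snps": tr.n_snps_used,
                    "q": tr.heterogeneity.q,
                    "df": tr.heterogeneity.df,
                    "p_het": tr.heterogeneity.p_het,
                    "i_squared_pct": tr.heterogeneity.i_squared_pct,
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, out_dir) -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []
        for name, frame in (
            ("estimates.tsv", self.estimates_frame()),
            ("heterogeneity.tsv", self.heterogeneity_frame()),
        ):
            path = out_dir / name
            frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
            written.append(path)
        heidi_frames = [
            tr.heidi.table.assign(trait=name)
            for name, tr in self.traits.items()
            if tr.heidi is not None
        ]
        if heidi_frames:
            path = out_dir / "heidi.tsv"
            pd.concat(heidi_frames, ignore_index=True).to_csv(
                path, sep="\t", index=False, float_format="%.10g"
            )
            written.append(path)
        return written

    def to_json(self, path) -> Path:
        path = Path(path)
        payload = {
            "metadata": self.metadata,
            "estimates": self.estimates_frame().to_dict("records"),
            "heterogeneity": self.heterogeneity_frame().to_dict("records"),
            "heidi": {
                name: {
                    "top_snp": tr.heidi.top_snp,
                    "flagged": tr.heidi.flagged,
                    "threshold": tr.heidi.threshold,
                }
                for name, tr in self.traits.items()
                if tr.heidi is not None
            },
        }
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        return path


def _load_config(config) -> dict[str, Any]:
    cfg = dict(DEFAULT_CONFIG)
    if config is None:
        return cfg
    if isinstance(config, (str, Path)):
        loaded = yaml.safe_load(Path(config).read_text()) or {}
    else:
        loaded = dict(config)
    unknown = set(loaded) - set(DEFAULT_CONFIG) - {"ld_matrix", "exposure_tsv", "outcome_tsv"}
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg.update(loaded)
    if isinstance(cfg["traits"], str):
        cfg["traits"] = [t.strip() for t in cfg["traits"].split(",") if t.strip()]
    return cfg


def analyse_trait(
    exposure: sumstats.InstrumentSet,
    outcome: sumstats.InstrumentSet,
    cfg: Mapping[str, Any] | None = None,
    ld_matrix: pd.DataFrame | None = None,
) -> TraitResult:
    """Run the per-trait stage chain on one exposure/outcome pair."""
    cfg = {**DEFAULT_CONFIG, **(cfg or {})}
    t0 = time.perf_counter()
    n_loaded = len(exposure)
    if ld_matrix is not None:
        exposure = sumstats.ld_prune(exposure, ld_matrix, cfg["ld_threshold"])
    instruments = sumstats.harmonise_sets(
        exposure, outcome, freq_tolerance=cfg["freq_tolerance"],
        trust_labels=bool(cfg["trust_alignment"]),
    )

    heidi = None
    excluded: list[str] = []
    if cfg["heidi_enabled"] and len(instruments) >= 3:
        heidi = pleiotropy.heidi_outlier(
            instruments, cfg["heidi_threshold"], iterate=cfg["heidi_iterate"]
        )
        excluded = list(heidi.flagged)
        instruments = [i for i in instruments if i.snp_id not in set(excluded)]

    ratios = [mr.wald_ratio(i) for i in instruments]
    het = pleiotropy.cochran_q(ratios)

    seed = int(cfg["seed"])
    estimates = {
        "ivw": mr.ivw(instruments),
        "mle": mr.mle(instruments, rho=cfg["rho"]),
        "wme": mr.weighted_median(instruments, n_boot=cfg["n_boot"], seed=seed),
        "mbe": mr.mode_based(
            instruments, phi=cfg["phi"], n_boot=cfg["n_boot"], seed=seed
        ),
    }
    egger_fit = mr.egger(instruments)
    estimates["egger_slope"] = egger_fit.slope

    if exposure.exposure_type == "binary":
        estimates = {k: mr.per_doubling(v) for k, v in estimates.items()}
    tiers = {k: _tier(v.p_value, cfg) for k, v in estimates.items()}
    tiers["egger_intercept"] = _tier(egger_fit.intercept.p_value, cfg)

    log.info(
        "trait %s: %d/%d SNPs used, %.2fs",
        exposure.trait_name, len(instruments), n_loaded, time.perf_counter() - t0,
    )
    return TraitResult(
        trait=exposure.trait_name,
        exposure_type=exposure.exposure_type,
        n_snps_loaded=n_loaded,
        n_snps_used=len(instruments),
        excluded=excluded,
        heidi=heidi,
        heterogeneity=het,
        estimates=estimates,
        egger_intercept=egger_fit.intercept,
        ratios=ratios,
        tiers=tiers,
        instruments=instruments,
    )


def run_pipeline(config=None, seed: int | None = None) -> AnalysisReport:
    """Run the full multi-trait analysis.

    ``config`` may be a mapping or a path to a flat YAML key-value file;
    ``seed`` overrides the config seed.  Deterministic for fixed inputs.
    """
    cfg = _load_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]

    results: dict[str, TraitResult] = {}
    for trait in cfg["traits"]:
        exposure, outcome = sumstats.load_fixture(trait)
        ld = None
        if cfg.get("ld_matrix"):
            ld = sumstats.read_ld_matrix(cfg["ld_matrix"])
        results[trait] = analyse_trait(exposure, outcome, cfg, ld_matrix=ld)

    try:
        pkg_version = _pkg_version("gliomamr")
    except Exception:  # pragma: no cover - not installed
        pkg_version = "unknown"
    metadata = {
        "seed": cfg["seed"],
        "config_hash": cfg_hash,
        "version": pkg_version,
        "traits": list(cfg["traits"]),
        "heidi_enabled": bool(cfg["heidi_enabled"]),
        "n_boot": int(cfg["n_boot"]),
    }
    return AnalysisReport(traits=results, metadata=metadata)
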