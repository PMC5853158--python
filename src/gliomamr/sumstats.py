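"""Reading, validation, harmonisation and LD pruning of GWAS summary statistics.

Instrument sets are per-SNP association tables for one trait: rsID, alleles,
effect-allele frequency, and an effect size stored as a log odds ratio (or a
per-SD effect for continuous traits) with its standard error.  Published
tables usually print the effect as ``OR (95% CI)``; :func:`parse_or_ci`
recovers ``(beta, se)`` from that representation.

Harmonisation aligns an outcome record onto the exposure record's effect
allele, flipping the sign of the outcome effect where the alleles are
reported the other way around (possibly on the opposite strand), and using
effect-allele frequencies to resolve strand-ambiguous (A/T, C/G) variants.

The four instrument sets used in the atopy -> glioma analysis (atopic
dermatitis, asthma & hay fever, serum IgE level, self-reported allergy; 46
SNPs in total, with per-SNP glioma associations from a 12,488-case /
18,169-control GWAS meta-analysis) ship as packaged TSV fixtures and are
returned by :func:`load_fixture`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VariantAssociation",
    "InstrumentSet",
    "HarmonisedInstrument",
    "HarmonisationError",
    "AlleleMismatchError",
    "UnresolvablePalindromeError",
    "parse_or_ci",
    "align_outcome",
    "harmonise",
    "harmonise_sets",
    "ld_prune",
    "load_fixture",
    "read_instruments",
    "read_ld_matrix",
    "FIXTURE_TRAITS",
]

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Traits with packaged fixtures, mapping to exposure type.
FIXTURE_TRAITS = {
    "atopic_dermatitis": "binary",
    "asthma_hayfever": "binary",
    "ige": "continuous",
    "self_reported_allergy": "binary",
}


class HarmonisationError(ValueError):
    """Exposure and outcome records cannot be placed on a common allele."""


class AlleleMismatchError(HarmonisationError):
    """Allele sets are incompatible even after strand complementation."""


class UnresolvablePalindromeError(HarmonisationError):
    """A/T or C/G variant whose orientation cannot be inferred from EAFs."""


def parse_or_ci(
    or_point: float,
    ci_lower: float,
    ci_upper: float,
    level: float = 0.95,
) -> tuple[float, float]:
    """Convert an odds ratio with a symmetric-on-log-scale CI to (beta, se).

    ``beta = ln(OR)`` and ``se = (ln(upper) - ln(lower)) / (2 z)`` with ``z``
    the standard-normal quantile of the confidence level (1.959964 at 0.95).
    """
    if or_point <= 0 or ci_lower <= 0 or ci_upper <= 0:
        raise ValueError("odds ratio and CI bounds must be positive")
    if not (ci_lower <= or_point <= ci_upper):
        raise ValueError(
            f"point estimate {or_point} outside CI ({ci_lower}, {ci_upper})"
        )
    if ci_lower == ci_upper:
        raise ValueError("degenerate CI of zero width")
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2)
    beta = math.log(or_point)
    se = (math.log(ci_upper) - math.log(ci_lower)) / (2 * z)
    return beta, se


@dataclass
class VariantAssociation:
    """One SNP's association with one trait.

    ``beta`` is the log odds ratio per effect allele for binary traits, or
    the per-SD effect for continuous traits; ``se`` its standard error.
    Positions are 1-based GRCh37 coordinates stored verbatim from the source.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: float | None = None
    position: int | None = None
    region: str | None = None
    p_value: float | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in _VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in _VALID_ALLELES:
            raise ValueError(f"{self.snp_id}: invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele identical")
        if not self.se > 0:
            raise ValueError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if self.eaf is not None and not 0 < self.eaf < 1:
            raise ValueError(f"{self.snp_id}: eaf must be in (0, 1), got {self.eaf}")
        if self.p_value is not None and not 0 < self.p_value <= 1:
            raise ValueError(f"{self.snp_id}: p_value must be in (0, 1]")

    @classmethod
    def from_or_ci(
        cls,
        snp_id: str,
        effect_allele: str,
        other_allele: str,
        or_point: float,
        ci_lower: float,
        ci_upper: float,
        level: float = 0.95,
        **kwargs,
    ) -> "VariantAssociation":
        beta, se = parse_or_ci(or_point, ci_lower, ci_upper, level)
        return cls(snp_id, effect_allele, other_allele, beta, se, **kwargs)

    @property
    def z(self) -> float:
        return self.beta / self.se

    @property
    def is_palindromic(self) -> bool:
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


@dataclass
class InstrumentSet:
    """An ordered collection of variant associations for one trait."""

    trait_name: str
    exposure_type: str  # "binary" or "continuous"
    associations: list[VariantAssociation] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.exposure_type not in ("binary", "continuous"):
            raise ValueError(f"exposure_type must be binary/continuous, got {self.exposure_type}")
        ids = [a.snp_id for a in self.associations]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"{self.trait_name}: duplicate snp_ids {dup}")

    def __len__(self) -> int:
        return len(self.associations)

    def __iter__(self) -> Iterator[VariantAssociation]:
        return iter(self.associations)

    def __getitem__(self, snp_id: str) -> VariantAssociation:
        for a in self.associations:
            if a.snp_id == snp_id:
                return a
        raise KeyError(snp_id)

    @property
    def snp_ids(self) -> list[str]:
        return [a.snp_id for a in self.associations]

    def drop(self, snp_ids: Iterable[str]) -> "InstrumentSet":
        """New set without the named SNPs."""
        drop = set(snp_ids)
        return replace(
            self, associations=[a for a in self.associations if a.snp_id not in drop]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": [a.snp_id for a in self.associations],
                "effect_allele": [a.effect_allele for a in self.associations],
                "other_allele": [a.other_allele for a in self.associations],
                "eaf": [a.eaf for a in self.associations],
                "beta": [a.beta for a in self.associations],
                "se": [a.se for a in self.associations],
            }
        )


@dataclass
class HarmonisedInstrument:
    """A SNP's paired exposure/outcome effects on a common effect allele."""

    snp_id: str
    x: float          # exposure beta
    sigma_x: float
    y: float          # outcome beta, aligned to the exposure effect allele
    sigma_y: float
    flipped: bool = False
    palindromic: bool = False

    def __post_init__(self) -> None:
        if not (self.sigma_x > 0 and self.sigma_y > 0):
            raise ValueError(f"{self.snp_id}: standard errors must be > 0")


def align_outcome(
    exposure: VariantAssociation,
    outcome: VariantAssociation,
    freq_tolerance: float = 0.08,
    trust_labels: bool = False,
) -> tuple[VariantAssociation, bool]:
    """Re-express ``outcome`` on the exposure's effect allele.

    Returns the aligned outcome record and whether its sign was flipped.
    Alignment tries the alleles as reported, then their strand complements.
    Palindromic variants are resolved by comparing effect-allele frequencies
    and rejected when either frequency is missing or both lie within
    ``freq_tolerance`` of 0.5; with ``trust_labels`` the reported allele
    labels of palindromic variants are taken at face value instead (for
    sources known to publish both sides on a common strand and allele).
    Aligning an already-aligned record is a no-op, so the operation is
    idempotent.
    """
    if exposure.snp_id != outcome.snp_id:
        raise ValueError(f"snp_id mismatch: {exposure.snp_id} vs {outcome.snp_id}")
    ea, oa = exposure.effect_allele, exposure.other_allele
    oea, ooa = outcome.effect_allele, outcome.other_allele

    if exposure.is_palindromic:
        if {oea, ooa} != {ea, oa}:
            raise AlleleMismatchError(
                f"{exposure.snp_id}: outcome alleles {oea}/{ooa} incompatible "
                f"with palindromic exposure alleles {ea}/{oa}"
            )
        if trust_labels:
            flip = oea != ea
        else:
            if exposure.eaf is None or outcome.eaf is None:
                raise UnresolvablePalindromeError(
                    f"{exposure.snp_id}: palindromic variant without both EAFs"
                )
            lo, hi = 0.5 - freq_tolerance, 0.5 + freq_tolerance
            if lo <= exposure.eaf <= hi and lo <= outcome.eaf <= hi:
                raise UnresolvablePalindromeError(
                    f"{exposure.snp_id}: palindromic variant with EAFs near 0.5 "
                    f"({exposure.eaf:.3f}, {outcome.eaf:.3f})"
                )
            # frequency of the exposure effect allele in the outcome study,
            # as labelled; a label swap inverts it
            freq = outcome.eaf if oea == ea else 1 - outcome.eaf
            label_flip = oea != ea
            # strand ambiguity: trust frequency concordance, not the labels
            strand_flip = (freq < 0.5) != (exposure.eaf < 0.5)
            flip = label_flip ^ strand_flip
    else:
        pair = (oea, ooa)
        comp = (_COMPLEMENT[oea], _COMPLEMENT[ooa])
        if pair == (ea, oa):
            flip = False
        elif pair == (oa, ea):
            flip = True
        elif comp == (ea, oa):
            flip = False
        elif comp == (oa, ea):
            flip = True
        else:
            raise AlleleMismatchError(
                f"{exposure.snp_id}: outcome alleles {oea}/{ooa} incompatible "
                f"with exposure alleles {ea}/{oa} on either strand"
            )

    aligned = replace(
        outcome,
        effect_allele=ea,
        other_allele=oa,
        beta=-outcome.beta if flip else outcome.beta,
        eaf=None if outcome.eaf is None else (1 - outcome.eaf if flip else outcome.eaf),
    )
    return aligned, flip


def harmonise(
    exposure: VariantAssociation,
    outcome: VariantAssociation,
    freq_tolerance: float = 0.08,
    trust_labels: bool = False,
) -> HarmonisedInstrument:
    """Pair one SNP's exposure and outcome effects on a common effect allele."""
    aligned, flipped = align_outcome(exposure, outcome, freq_tolerance, trust_labels)
    return HarmonisedInstrument(
        snp_id=exposure.snp_id,
        x=exposure.beta,
        sigma_x=exposure.se,
        y=aligned.beta,
        sigma_y=aligned.se,
        flipped=flipped,
        palindromic=exposure.is_palindromic,
    )


def harmonise_sets(
    exposure: InstrumentSet,
    outcome: InstrumentSet,
    freq_tolerance: float = 0.08,
    on_error: str = "raise",
    trust_labels: bool = False,
) -> list[HarmonisedInstrument]:
    """Harmonise all SNPs shared between two instrument sets, in exposure order.

    ``on_error="skip"`` drops SNPs that fail harmonisation instead of raising.
    """
    if on_error not in ("raise", "skip"):
        raise ValueError("on_error must be 'raise' or 'skip'")
    out_ids = set(outcome.snp_ids)
    result = []
    for exp in exposure:
        if exp.snp_id not in out_ids:
            continue
        try:
            result.append(harmonise(exp, outcome[exp.snp_id], freq_tolerance, trust_labels))
        except HarmonisationError:
            if on_error == "raise":
                raise
    return result


def ld_prune(
    iset: InstrumentSet,
    r2: pd.DataFrame | None = None,
    threshold: float = 0.001,
) -> InstrumentSet:
    """Greedy LD pruning: within each correlated cluster keep the SNP with
    the strongest exposure association (largest |beta|/se).

    ``r2`` is a symmetric matrix of pairwise LD r-squared values indexed by
    rsID on both axes; ``None`` means the set is already independent.  The
    returned set contains no pair with r-squared >= ``threshold``.
    """
    if r2 is None:
        return replace(iset, associations=list(iset.associations))
    ids = iset.snp_ids
    missing = [s for s in ids if s not in r2.index or s not in r2.columns]
    if missing:
        raise ValueError(f"LD matrix missing entries for {missing}")
    sub = r2.loc[ids, ids].astype(float)
    if sub.isna().to_numpy().any():
        raise ValueError("LD matrix contains missing values")
    if not np.allclose(sub.to_numpy(), sub.to_numpy().T, atol=1e-12):
        raise ValueError("LD matrix is not symmetric")
    if not np.allclose(np.diag(sub.to_numpy()), 1.0, atol=1e-9):
        raise ValueError("LD matrix diagonal must be 1")

    # strongest first; ties broken by smaller se, then rsID, so the result
    # does not depend on input row order
    ranked = sorted(
        iset.associations, key=lambda a: (-abs(a.z), a.se, a.snp_id)
    )
    kept: list[VariantAssociation] = []
    for cand in ranked:
        if all(sub.loc[cand.snp_id, k.snp_id] < threshold for k in kept):
            kept.append(cand)
    keep_ids = {a.snp_id for a in kept}
    return replace(
        iset, associations=[a for a in iset.associations if a.snp_id in keep_ids]
    )


def _read_tsv(path_or_buf, trait_name: str, exposure_type: str, provenance: str) -> InstrumentSet:
    df = pd.read_csv(path_or_buf, sep="\t", comment="#", dtype={"snp_id": str})
    assocs = []
    for row in df.to_dict("records"):
        def _opt(key, cast):
            val = row.get(key)
            return None if val is None or pd.isna(val) else cast(val)

        common = dict(
            snp_id=row["snp_id"],
            effect_allele=row["effect_allele"],
            other_allele=row["other_allele"],
            eaf=_opt("eaf", float),
            position=_opt("position", int),
            region=row.get("region"),
        )
        if row.get("beta") is not None and not pd.isna(row.get("beta")):
            assocs.append(
                VariantAssociation(beta=float(row["beta"]), se=float(row["se"]), **common)
            )
        else:
            beta, se = parse_or_ci(
                float(row["or"]), float(row["ci_lower"]), float(row["ci_upper"])
            )
            assocs.append(VariantAssociation(beta=beta, se=se, **common))
    return InstrumentSet(trait_name, exposure_type, assocs, provenance)


def read_instruments(
    path, trait_name: str, exposure_type: str = "binary", provenance: str = ""
) -> InstrumentSet:
    """Read an instrument set from a TSV file.

    Columns: ``snp_id, region, position, effect_allele, other_allele, eaf``
    plus either ``or, ci_lower, ci_upper`` or ``beta, se``.  Lines starting
    with ``#`` are comments.
    """
    return _read_tsv(path, trait_name, exposure_type, provenance or str(path))


def load_fixture(trait_name: str) -> tuple[InstrumentSet, InstrumentSet]:
    """Load the packaged per-SNP exposure and glioma associations for a trait.

    Betas and SEs are recomputed from the stored ORs/CIs on every load, so
    the conversion path is always exercised.  Returns ``(exposure, outcome)``.
    """
    if trait_name not in FIXTURE_TRAITS:
        raise KeyError(
            f"unknown trait {trait_name!r}; available: {sorted(FIXTURE_TRAITS)}"
        )
    pkg = resources.files(__package__) / "fixtures"
    sets = []
    for role in ("exposure", "glioma"):
        with (pkg / f"{trait_name}.{role}.tsv").open() as fh:
            sets.append(
                _read_tsv(
                    fh,
                    trait_name if role == "exposure" else "glioma",
                    FIXTURE_TRAITS[trait_name] if role == "exposure" else "binary",
                    f"packaged fixture {trait_name}.{role}.tsv",
                )
            )
    return sets[0], sets[1]


def read_ld_matrix(path) -> pd.DataFrame:
    """Read a square LD r-squared matrix (TSV, rsID header row and column)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df
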