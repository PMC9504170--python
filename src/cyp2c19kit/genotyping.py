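"""Genotype calling from band patterns and CYP2C19 diplotype assembly.

The three diagnostic SNPs and the star alleles they define:

    rs4244285  -> CYP2C19*2   (no function)
    rs4986893  -> CYP2C19*3   (no function)
    rs12248560 -> CYP2C19*17  (increased function)

A chromosome carrying none of the three variants is CYP2C19*1.  Because
allele-specific PCR yields unphased genotypes, heterozygous variants at
different SNPs are placed on opposite haplotypes (the *trans* assumption,
the standard interpretation for e.g. *2/*17) and the resulting diplotype is
flagged ``phased=False``.  Three simultaneously heterozygous variants
cannot be placed on two haplotypes without an arbitrary cis pairing and
raise an explicit ambiguity error.  When homozygosity forces two variants
onto one haplotype, the loss-of-function variant names the star allele
(precedence *2 > *3 > *17).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from .insilico_pcr import BandPattern

__all__ = [
    "GenotypeCall",
    "SnpGenotypeCall",
    "Diplotype",
    "IncompletePanelError",
    "AmbiguousPhaseError",
    "PANEL_RSIDS",
    "RSID_TO_STAR",
    "call_snp_genotype",
    "assign_diplotype",
    "call_panel",
    "PanelResult",
]

PANEL_RSIDS = ("rs4244285", "rs4986893", "rs12248560")
RSID_TO_STAR = {"rs4244285": "*2", "rs4986893": "*3", "rs12248560": "*17"}

# loss-of-function first: the variant that names a multi-variant haplotype
STAR_PRECEDENCE = ("*2", "*3", "*17")


class GenotypeCall(str, Enum):
    """Per-SNP diploid genotype call (no-call is a value, not an error)."""

    HOMOZYGOUS_MAJOR = "homozygous-major"
    HETEROZYGOUS = "heterozygous"
    HOMOZYGOUS_MINOR = "homozygous-minor"
    NO_CALL = "no-call"


@dataclass(frozen=True)
class SnpGenotypeCall:
    rsid: str
    call: GenotypeCall


class IncompletePanelError(ValueError):
    """Raised when one of the three panel SNPs is missing or no-call."""


class AmbiguousPhaseError(ValueError):
    """Raised when heterozygous variants cannot be phased onto two haplotypes."""


def _star_sort_key(star: str) -> int:
    return int(star.lstrip("*"))


@dataclass(frozen=True)
class Diplotype:
    """Unordered pair of star alleles; equality is order-insensitive."""

    alleles: tuple[str, str]
    phased: bool = field(default=True, compare=False)

    def __post_init__(self) -> None:
        if len(self.alleles) != 2:
            raise ValueError("a diplotype is a pair of star alleles")
        normalised = tuple(sorted((a.strip() for a in self.alleles), key=_star_sort_key))
        object.__setattr__(self, "alleles", normalised)

    def __str__(self) -> str:
        return "/".join(self.alleles)

    @classmethod
    def from_string(cls, text: str, phased: bool = True) -> "Diplotype":
        parts = [p.strip() for p in text.split("/")]
        if len(parts) != 2 or not all(p.startswith("*") for p in parts):
            raise ValueError(f"cannot parse diplotype {text!r}; expected '*X/*Y'")
        return cls(alleles=(parts[0], parts[1]), phased=phased)


def call_snp_genotype(pattern: BandPattern) -> GenotypeCall:
    """Map a two-reaction band pattern to a diploid genotype call."""
    table = {
        (True, False): GenotypeCall.HOMOZYGOUS_MAJOR,
        (True, True): GenotypeCall.HETEROZYGOUS,
        (False, True): GenotypeCall.HOMOZYGOUS_MINOR,
        (False, False): GenotypeCall.NO_CALL,
    }
    return table[(pattern.major_reaction_amplified, pattern.minor_reaction_amplified)]


def assign_diplotype(calls: dict[str, GenotypeCall]) -> Diplotype:
    """Assemble a CYP2C19 diplotype from the three per-SNP genotype calls.

    ``calls`` maps rsID -> genotype call and must cover all three panel
    SNPs with no no-calls.
    """
    missing = [r for r in PANEL_RSIDS if r not in calls or calls[r] is GenotypeCall.NO_CALL]
    if missing:
        raise IncompletePanelError(
            f"panel incomplete: missing or no-call at {', '.join(missing)}"
        )
    unknown = set(calls) - set(PANEL_RSIDS)
    if unknown:
        raise ValueError(f"unexpected rsIDs {sorted(unknown)}; panel is {PANEL_RSIDS}")

    hom_variants = [RSID_TO_STAR[r] for r in PANEL_RSIDS
                    if calls[r] is GenotypeCall.HOMOZYGOUS_MINOR]
    het_variants = [RSID_TO_STAR[r] for r in PANEL_RSIDS
                    if calls[r] is GenotypeCall.HETEROZYGOUS]

    if len(het_variants) == 3:
        raise AmbiguousPhaseError(
            "three heterozygous variants cannot be placed on two haplotypes "
            "without an arbitrary cis pairing; unphased assay data cannot "
            "resolve this diplotype"
        )

    # haplotypes as sets of variant star alleles; homozygous variants on both
    hap_a: list[str] = list(hom_variants)
    hap_b: list[str] = list(hom_variants)
    # heterozygous variants in trans: one per haplotype
    phased = True
    if het_variants:
        hap_a.append(het_variants[0])
        if len(het_variants) == 2:
            hap_b.append(het_variants[1])
            phased = False  # trans placement is an assumption, not an observation

    def name(hap: list[str]) -> str:
        if not hap:
            return "*1"
        for star in STAR_PRECEDENCE:
            if star in hap:
                return star
        raise AssertionError("unreachable")

    return Diplotype(alleles=(name(hap_a), name(hap_b)), phased=phased)


@dataclass
class PanelResult:
    """Batch genotyping result: per-sample diplotypes, errors, and a summary."""

    diplotypes: dict[str, Diplotype] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        counts = Counter(str(d) for d in self.diplotypes.values())
        rows = [{"diplotype": k, "count": v} for k, v in sorted(counts.items())]
        if self.errors:
            rows.append({"diplotype": "<error>", "count": len(self.errors)})
        return pd.DataFrame(rows, columns=["diplotype", "count"])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sample, d in self.diplotypes.items():
            rows.append({"sample": sample, "diplotype": str(d), "phased": d.phased})
        for sample, err in self.errors.items():
            rows.append({"sample": sample, "diplotype": None, "phased": None, "error": err})
        return pd.DataFrame(rows)


def call_panel(samples: dict[str, dict[str, BandPattern]]) -> PanelResult:
    """Call diplotypes for a batch of samples from their per-locus band patterns.

    Per-sample failures (incomplete panel, phase ambiguity) are collected in
    ``PanelResult.errors`` and do not abort the batch.
    """
    result = PanelResult()
    for sample, patterns in samples.items():
        try:
            calls = {rsid: call_snp_genotype(p) for rsid, p in patterns.items()}
            result.diplotypes[sample] = assign_diplotype(calls)
        except (IncompletePanelError, AmbiguousPhaseError, ValueError) as exc:
            result.errors[sample] = str(exc)
    return result
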