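"""In-silico PCR: predict per-reaction amplification from mismatch structure.

The discrimination principle of mismatch-augmented allele-specific PCR is
that a primer/template duplex carrying two mismatches (the 3'-terminal
diagnostic mismatch plus the internal artificial one) is refractory to
amplification, whereas a single internal artificial mismatch still
amplifies.  This module encodes that principle as a binary rule:

    amplify  <=>  no 3'-terminal mismatch  AND  total mismatches <= 1

which reproduces the presence/absence banding readout of a gel for each of
the two parallel reactions, without modelling quantitative efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass

from .asp_design import AlleleSpecificPrimer, AspAssay, SnpLocus, allele_template
from .seq_core import mismatch_profile

__all__ = [
    "DiploidGenotypeAtLocus",
    "BandPattern",
    "predict_amplification",
    "simulate_assay",
    "genotype_truth_table",
    "GENOTYPE_NAMES",
]

GENOTYPE_NAMES = ("major/major", "major/minor", "minor/minor")


@dataclass(frozen=True)
class DiploidGenotypeAtLocus:
    """The unordered pair of allele copies a diploid sample carries at one locus."""

    locus: SnpLocus
    alleles: tuple[str, str]

    def __post_init__(self) -> None:
        if len(self.alleles) != 2 or any(a not in ("major", "minor") for a in self.alleles):
            raise ValueError("alleles must be a pair drawn from {'major','minor'}")
        object.__setattr__(self, "alleles", tuple(sorted(self.alleles)))


@dataclass(frozen=True)
class BandPattern:
    """Gel readout of the two parallel reactions for one sample/locus."""

    major_reaction_amplified: bool
    minor_reaction_amplified: bool
    product_length_bp: int | None = None

    def __post_init__(self) -> None:
        amplified = self.major_reaction_amplified or self.minor_reaction_amplified
        if amplified != (self.product_length_bp is not None):
            raise ValueError("product length must be present iff at least one reaction amplified")


def predict_amplification(
    primer: AlleleSpecificPrimer, locus: SnpLocus, template_allele: str
) -> bool:
    """True iff the primer extends on the template carrying ``template_allele``.

    The primer is compared position-wise to the forward-strand template
    window ending at the diagnostic base; amplification requires a matched
    3' terminus and at most one mismatch in total.
    """
    window = allele_template(locus, template_allele, len(primer.sequence))
    profile = mismatch_profile(primer.sequence, window)
    return not profile.has_terminal_mismatch and profile.total <= 1


def simulate_assay(assay: AspAssay, genotype: DiploidGenotypeAtLocus) -> BandPattern:
    """Band pattern of the two reactions for a diploid genotype.

    Each reaction amplifies iff its allele-specific primer extends on at
    least one of the two template copies.
    """
    if genotype.locus.rsid != assay.locus.rsid:
        raise ValueError(
            f"genotype locus {genotype.locus.rsid} does not match assay locus {assay.locus.rsid}"
        )
    major_band = any(
        predict_amplification(assay.primer_major, assay.locus, a) for a in genotype.alleles
    )
    minor_band = any(
        predict_amplification(assay.primer_minor, assay.locus, a) for a in genotype.alleles
    )
    product = assay.product_length_bp if (major_band or minor_band) else None
    return BandPattern(major_band, minor_band, product)


def genotype_truth_table(assay: AspAssay) -> dict[str, BandPattern]:
    """Band pattern for each of the three diploid genotypes at the assay's locus."""
    pairs = {
        "major/major": ("major", "major"),
        "major/minor": ("major", "minor"),
        "minor/minor": ("minor", "minor"),
    }
    return {
        name: simulate_assay(assay, DiploidGenotypeAtLocus(assay.locus, alleles))
        for name, alleles in pairs.items()
    }
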