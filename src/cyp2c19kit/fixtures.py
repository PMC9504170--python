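"""Built-in CYP2C19 loci and seeded synthetic data for every pipeline stage.

``table5_loci`` reconstructs the three diagnostic CYP2C19 SNP loci
(rs4244285/*2, rs4986893/*3, rs12248560/*17) from the published assay
oligonucleotides: the upstream flank is the published forward primer with
the artificial destabilizing substitution reverted to its complement, and
the downstream flank embeds the reverse complement of the published common
reverse primer behind a committed spacer, so that re-running the design on
these loci reproduces the published primers.  The spacer is synthetic: the
true intervening genomic sequence and product sizes are not part of the
published assay description.

``synth_locus``/``synth_panel`` generate seeded random loci and diploid
sample panels with retained ground truth, standing in for a reference-DNA
validation panel (e.g. Coriell lymphoblastoid lines) so that end-to-end
genotype recovery can be scored without any external data.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .asp_design import DEFAULT_PARAMS, DesignParams, SnpLocus
from .genotyping import PANEL_RSIDS, GenotypeCall
from .seq_core import complement, reverse_complement

__all__ = [
    "PUBLISHED_ASSAYS",
    "SPACER_150",
    "table5_loci",
    "synth_locus",
    "SyntheticPanel",
    "synth_panel",
]

#: Published assay oligos: forward primer core (major-allele form, with the
#: artificial substitution in place), the two allele bases (major/minor),
#: and the common reverse primer.
PUBLISHED_ASSAYS = {
    "rs4244285": {
        "allele_name": "CYP2C19*2",
        "position_label": "681",
        "forward_major": "CACTATCATTGATTATTACCCG",
        "minor_allele": "A",
        "reverse": "CTCCATTTTGATCAGGAAGC",
    },
    "rs4986893": {
        "allele_name": "CYP2C19*3",
        "position_label": "636",
        "forward_major": "GGATTGTAAGCACCCGCTGG",
        "minor_allele": "A",
        "reverse": "AGAACTTTGCCATCTTTTCCAG",
    },
    "rs12248560": {
        "allele_name": "CYP2C19*17",
        "position_label": "806",
        "forward_major": "GTGTCTTCTGTTCTCTAAGC",
        "minor_allele": "T",
        "reverse": "CAAATGGGAAAAGGGAGAC",
    },
}

#: Committed synthetic 150 bp spacer placed between the diagnostic base and
#: the reverse-primer binding site.  Deliberately A/T-only so no spacer
#: window can out-score the embedded reverse-primer site under the GC
#: constraints of the reverse-primer search.
SPACER_150 = (
    "ATTATAATTTATATTAATTATTTAATATTATTAATATTTATATTAATTAT"
    "TTAATATATTATTAAATTTATATTATTAATTTATAATATTATTAATATTT"
    "ATATTAATTATTTAATATATTATTAAATTTATATTATTAATTTATAATAT"
)


def _reconstruct_locus(rsid: str, mismatch_offset: int = DEFAULT_PARAMS.mismatch_offset) -> SnpLocus:
    spec = PUBLISHED_ASSAYS[rsid]
    fwd = spec["forward_major"]
    # revert the artificial substitution (5th base from the 3' end for offset 4)
    idx = len(fwd) - mismatch_offset - 1
    template = fwd[:idx] + complement(fwd[idx]) + fwd[idx + 1 :]
    upstream, major = template[:-1], template[-1]
    downstream = SPACER_150 + reverse_complement(spec["reverse"])
    return SnpLocus(
        rsid=rsid,
        allele_name=spec["allele_name"],
        position_label=spec["position_label"],
        upstream=upstream,
        major_allele=major,
        minor_allele=spec["minor_allele"],
        downstream=downstream,
    )


def table5_loci() -> list[SnpLocus]:
    """The three reconstructed CYP2C19 diagnostic loci, in panel order."""
    return [_reconstruct_locus(rsid) for rsid in PANEL_RSIDS]


def synth_locus(
    seed: int,
    upstream_len: int = 30,
    downstream_len: int = 260,
    params: DesignParams = DEFAULT_PARAMS,
) -> SnpLocus:
    """A seeded random biallelic locus with uniform-random flanks.

    Reproducible: the same seed yields the identical locus.  Lengths must
    support at least the minimum primer length upstream and a minimal
    reverse-primer window downstream.
    """
    min_len = params.primer_length_range[0]
    if upstream_len < min_len - 1:
        raise ValueError(f"upstream_len must be >= {min_len - 1}")
    if downstream_len < min_len:
        raise ValueError(f"downstream_len must be >= {min_len}")
    rng = random.Random(seed)
    bases = "ACGT"
    upstream = "".join(rng.choice(bases) for _ in range(upstream_len))
    downstream = "".join(rng.choice(bases) for _ in range(downstream_len))
    major, minor = rng.sample(bases, 2)
    return SnpLocus(
        rsid=f"rs_synth_{seed}",
        allele_name=f"SYNTH*{seed}",
        position_label=str(upstream_len + 1),
        upstream=upstream,
        major_allele=major,
        minor_allele=minor,
        downstream=downstream,
    )


_GENOTYPES = (
    GenotypeCall.HOMOZYGOUS_MAJOR,
    GenotypeCall.HETEROZYGOUS,
    GenotypeCall.HOMOZYGOUS_MINOR,
)


@dataclass
class SyntheticPanel:
    """A seeded panel of diploid samples with planted per-locus genotypes."""

    loci: list[SnpLocus]
    samples: dict[str, dict[str, GenotypeCall]]
    seed: int
    genotype_frequencies: dict[str, tuple[float, float, float]] = field(default_factory=dict)


def synth_panel(
    seed: int,
    n_samples: int = 21,
    genotype_frequencies: dict[str, tuple[float, float, float]] | None = None,
    loci: list[SnpLocus] | None = None,
) -> SyntheticPanel:
    """Generate a seeded diploid sample panel over the three-SNP CYP2C19 panel.

    ``genotype_frequencies`` maps rsID to the (hom-major, het, hom-minor)
    sampling probabilities; the default is uniform thirds at every locus.
    Ground-truth genotypes are retained for concordance scoring.
    """
    panel_loci = loci if loci is not None else table5_loci()
    freqs: dict[str, tuple[float, float, float]] = {}
    for locus in panel_loci:
        f = (
            genotype_frequencies.get(locus.rsid, (1 / 3, 1 / 3, 1 / 3))
            if genotype_frequencies
            else (1 / 3, 1 / 3, 1 / 3)
        )
        if len(f) != 3 or any(p < 0 for p in f) or abs(sum(f) - 1.0) > 1e-9:
            raise ValueError(f"{locus.rsid}: genotype frequencies must be 3 non-negatives summing to 1")
        freqs[locus.rsid] = tuple(float(p) for p in f)
    rng = random.Random(seed)
    samples: dict[str, dict[str, GenotypeCall]] = {}
    width = len(str(n_samples))
    for i in range(1, n_samples + 1):
        name = f"S{i:0{width}d}"
        samples[name] = {
            locus.rsid: rng.choices(_GENOTYPES, weights=freqs[locus.rsid])[0]
            for locus in panel_loci
        }
    return SyntheticPanel(
        loci=panel_loci, samples=samples, seed=seed, genotype_frequencies=freqs
    )
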