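import pytest

from cyp2c19kit import design_assay, table5_loci
from cyp2c19kit.genotyping import GenotypeCall

#: genotype call -> the diploid allele pair it denotes
ALLELE_PAIRS = {
    GenotypeCall.HOMOZYGOUS_MAJOR: ("major", "major"),
    GenotypeCall.HETEROZYGOUS: ("major", "minor"),
    GenotypeCall.HOMOZYGOUS_MINOR: ("minor", "minor"),
}


@pytest.fixture(scope="session")
def cyp2c19_loci():
    """The three reconstructed CYP2C19 diagnostic loci, keyed by rsID."""
    return {locus.rsid: locus for locus in table5_loci()}


@pytest.fixture(scope="session")
def cyp2c19_assays(cyp2c19_loci):
    """Designed two-reaction assays for the three CYP2C19 loci."""
    return {rsid: design_assay(locus) for rsid, locus in cyp2c19_loci.items()}
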