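"""Assay design: artificial-mismatch placement, primer assembly, Tm, reverse search."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cyp2c19kit.asp_design import (
    DEFAULT_PARAMS,
    DesignError,
    DesignParams,
    SnpLocus,
    allele_template,
    apply_artificial_mismatch,
    design_allele_specific_primer,
    design_assay,
    design_common_reverse_primer,
    melting_temperature,
    reverse_primer_candidates,
)
from cyp2c19kit.seq_core import mismatch_profile

dna = st.text(alphabet="ACGT", min_size=8, max_size=40)


# --- artificial mismatch ---------------------------------------------------


@pytest.mark.parametrize(
    "core,expected",
    [
        # published forward primers, reconstructed by reverting the substitution
        ("CACTATCATTGATTATTTCCCG", "CACTATCATTGATTATTACCCG"),
        ("GGATTGTAAGCACCCCCTGG", "GGATTGTAAGCACCCGCTGG"),
        ("GTGTCTTCTGTTCTCAAAGC", "GTGTCTTCTGTTCTCTAAGC"),
    ],
)
def test_artificial_mismatch_substitutes_fifth_base_from_3prime(core, expected):
    assert apply_artificial_mismatch(core) == expected


@settings(derandomize=True, max_examples=100)
@given(dna)
def test_artificial_mismatch_is_self_inverse_and_local(core):
    once = apply_artificial_mismatch(core)
    assert apply_artificial_mismatch(once) == core
    profile = mismatch_profile(once, core)
    assert profile.total == 1
    assert profile.positions_from_3prime == (DEFAULT_PARAMS.mismatch_offset + 1,)


def test_artificial_mismatch_requires_long_enough_core():
    with pytest.raises(DesignError):
        apply_artificial_mismatch("ACGT")


# --- melting temperature ---------------------------------------------------


def test_wallace_fallback_rule():
    # 2 degC per A/T + 4 degC per G/C, computed by hand
    params = DesignParams(tm_model="wallace")
    assert melting_temperature("ACGT", params) == pytest.approx(12.0)
    assert melting_temperature("AAAA", params) == pytest.approx(8.0)
    # sequences shorter than 8 nt fall back automatically
    assert melting_temperature("ACGT") == pytest.approx(12.0)


# Independently-typed unified nearest-neighbor parameters
# (Allawi & SantaLucia 1997): (dH kcal/mol, dS cal/mol/K) per stack.
_NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_INIT = {"A": (2.3, 4.1), "T": (2.3, 4.1), "G": (0.1, -2.8), "C": (0.1, -2.8)}


def _oracle_nn_tm(seq: str, na_molar=0.05, primer_molar=250e-9) -> float:
    """Independent nearest-neighbor Tm: stack sums + terminal initiation +
    SantaLucia entropy salt correction, two-state hybridisation of excess primer."""
    dh = _INIT[seq[0]][0] + _INIT[seq[-1]][0]
    ds = _INIT[seq[0]][1] + _INIT[seq[-1]][1]
    for i in range(len(seq) - 1):
        h, s = _NN[seq[i : i + 2]]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(na_molar)
    return (1000 * dh) / (ds + 1.987 * math.log(primer_molar)) - 273.15


@pytest.mark.parametrize(
    "seq",
    [
        "CTCCATTTTGATCAGGAAGC",
        "AGAACTTTGCCATCTTTTCCAG",
        "CACTATCATTGATTATTACCCG",
        "GTGTCTTCTGTTCTCTAAGC",
    ],
)
def test_nearest_neighbor_tm_matches_independent_oracle(seq):
    tm = melting_temperature(seq)
    assert tm == pytest.approx(_oracle_nn_tm(seq), abs=0.3)
    assert 45.0 <= tm <= 65.0


def test_common_reverse_primer_tm_in_annealing_compatible_range():
    assert 50.0 <= melting_temperature("CTCCATTTTGATCAGGAAGC") <= 65.0


# --- allele-specific primer design ----------------------------------------


def test_published_minor_primer_for_rs4244285(cyp2c19_loci):
    primer = design_allele_specific_primer(cyp2c19_loci["rs4244285"], "minor", 22)
    assert primer.sequence == "CACTATCATTGATTATTACCCA"
    assert primer.target_allele == "A"
    assert primer.substituted_base == "A" and primer.template_base == "T"


def test_published_major_primer_for_rs12248560(cyp2c19_loci):
    primer = design_allele_specific_primer(cyp2c19_loci["rs12248560"], "major", 20)
    assert primer.sequence == "GTGTCTTCTGTTCTCTAAGC"


def test_primer_mismatch_structure_against_both_templates(cyp2c19_loci):
    """One internal mismatch vs the targeted allele; terminal + internal vs the other."""
    for locus in cyp2c19_loci.values():
        for allele, other in (("major", "minor"), ("minor", "major")):
            primer = design_allele_specific_primer(locus, allele, 20)
            own = mismatch_profile(primer.sequence, allele_template(locus, allele, 20))
            assert own.positions_from_3prime == (5,)
            cross = mismatch_profile(primer.sequence, allele_template(locus, other, 20))
            assert cross.positions_from_3prime == (1, 5)


def test_major_and_minor_primers_differ_only_at_terminus(cyp2c19_loci):
    for locus in cyp2c19_loci.values():
        a = design_allele_specific_primer(locus, "major", 20).sequence
        b = design_allele_specific_primer(locus, "minor", 20).sequence
        assert a[:-1] == b[:-1] and a[-1] != b[-1]


def test_primer_design_errors_and_flags(cyp2c19_loci):
    locus = cyp2c19_loci["rs4244285"]
    with pytest.raises(DesignError):
        design_allele_specific_primer(locus, "major", 30)  # outside length range
    with pytest.raises(DesignError):
        design_allele_specific_primer(locus, "major", 25)  # upstream too short
    # published 22-mer has Tm below the default [55,65] window: flagged, not fatal
    primer = design_allele_specific_primer(locus, "major", 22)
    assert primer.flags and "Tm" in primer.flags[0]


# --- common reverse primer -------------------------------------------------


def test_published_reverse_primers_are_selected(cyp2c19_loci):
    assert (
        design_common_reverse_primer(cyp2c19_loci["rs4244285"]).sequence
        == "CTCCATTTTGATCAGGAAGC"
    )
    assert (
        design_common_reverse_primer(cyp2c19_loci["rs4986893"]).sequence
        == "AGAACTTTGCCATCTTTTCCAG"
    )


def test_published_reverse_primers_are_valid_candidates(cyp2c19_loci):
    published = {
        "rs4244285": "CTCCATTTTGATCAGGAAGC",
        "rs4986893": "AGAACTTTGCCATCTTTTCCAG",
        "rs12248560": "CAAATGGGAAAAGGGAGAC",
    }
    for rsid, locus in cyp2c19_loci.items():
        sequences = {c[1].sequence for c in reverse_primer_candidates(locus)}
        assert published[rsid] in sequences


def test_reverse_design_error_when_downstream_too_short(cyp2c19_loci):
    locus = cyp2c19_loci["rs4244285"]
    short = SnpLocus(
        rsid=locus.rsid,
        allele_name=locus.allele_name,
        position_label=locus.position_label,
        upstream=locus.upstream,
        major_allele=locus.major_allele,
        minor_allele=locus.minor_allele,
        downstream="ACGTACGTAC",
    )
    with pytest.raises(DesignError):
        design_common_reverse_primer(short)


# --- full assay ------------------------------------------------------------


def test_table5_roundtrip_regression(cyp2c19_assays):
    """Designing on the reconstructed loci recovers all published primer strings."""
    expected = {
        "rs4244285": ("CACTATCATTGATTATTACCCG", "CACTATCATTGATTATTACCCA", "CTCCATTTTGATCAGGAAGC"),
        "rs4986893": ("GGATTGTAAGCACCCGCTGG", "GGATTGTAAGCACCCGCTGA", "AGAACTTTGCCATCTTTTCCAG"),
        "rs12248560": ("GTGTCTTCTGTTCTCTAAGC", "GTGTCTTCTGTTCTCTAAGT", "CAAATGGGAAAAGGGAGAC"),
    }
    for rsid, (fwd_major, fwd_minor, reverse) in expected.items():
        assay = cyp2c19_assays[rsid]
        assert assay.primer_major.sequence == fwd_major
        assert assay.primer_minor.sequence == fwd_minor
        assert assay.common_reverse.sequence == reverse


def test_assay_invariants(cyp2c19_assays):
    for assay in cyp2c19_assays.values():
        lo, hi = DEFAULT_PARAMS.product_length_range
        assert lo <= assay.product_length_bp <= hi
        assert assay.cycling.denature_celsius == 94.0
        assert assay.cycling.anneal_celsius == 60.0
        assert assay.cycling.extend_celsius == 72.0
        assert assay.cycling.cycles == 35
        assert (
            assay.primer_major.artificial_mismatch_offset
            == assay.primer_minor.artificial_mismatch_offset
            == DEFAULT_PARAMS.mismatch_offset
        )


def test_design_params_validation():
    with pytest.raises(ValueError):
        DesignParams(mismatch_offset=1)
    with pytest.raises(ValueError):
        DesignParams(mismatch_offset=20)  # >= min primer length
    with pytest.raises(ValueError):
        DesignParams(primer_length_range=(25, 18))
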