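"""Design of mismatch-augmented allele-specific PCR (ARMS-style) assays.

For a biallelic SNP, a two-reaction allele-specific PCR assay consists of

* two forward allele-specific primers whose 3'-terminal base is the
  diagnostic (allele-discriminating) nucleotide, each additionally carrying
  an artificial destabilizing mismatch -- the template base four positions
  5' of the diagnostic base replaced by its Watson-Crick complement -- so
  that the primer/wrong-allele duplex carries two mismatches (terminal
  diagnostic + internal artificial) and fails to extend, while the
  primer/right-allele duplex carries only the single internal artificial
  mismatch and amplifies; and
* one conventional common reverse primer shared by both reactions.

Melting temperatures use the nearest-neighbor thermodynamic model
(unified Allawi & SantaLucia 1997 parameter set, via Biopython) at 50 mM
monovalent salt and 250 nM primer, with the additive Wallace rule
(2 degC per A/T + 4 degC per G/C) as a fallback for very short oligos.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.SeqUtils import MeltingTemp as _mt

from .seq_core import (
    clean_sequence,
    complement,
    mismatch_profile,
    reverse_complement,
)

__all__ = [
    "DesignError",
    "SnpLocus",
    "DesignParams",
    "AlleleSpecificPrimer",
    "ReversePrimer",
    "CyclingConditions",
    "AspAssay",
    "DEFAULT_PARAMS",
    "melting_temperature",
    "apply_artificial_mismatch",
    "allele_template",
    "design_allele_specific_primer",
    "reverse_primer_candidates",
    "design_common_reverse_primer",
    "design_assay",
]


class DesignError(ValueError):
    """A locus/parameter combination for which no valid design exists."""


@dataclass(frozen=True)
class SnpLocus:
    """A biallelic diagnostic site with forward-strand flanking sequence.

    ``upstream`` ends immediately 5' of the diagnostic base; ``downstream``
    starts immediately 3' of it.  Both are given on the forward strand.
    """

    rsid: str
    allele_name: str
    position_label: str
    upstream: str
    major_allele: str
    minor_allele: str
    downstream: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "upstream", clean_sequence(self.upstream))
        object.__setattr__(self, "downstream", clean_sequence(self.downstream))
        object.__setattr__(self, "major_allele", complement(complement(self.major_allele.upper())))
        object.__setattr__(self, "minor_allele", complement(complement(self.minor_allele.upper())))
        if self.major_allele == self.minor_allele:
            raise ValueError(f"{self.rsid}: major and minor alleles must differ")

    def allele_base(self, allele: str) -> str:
        if allele == "major":
            return self.major_allele
        if allele == "minor":
            return self.minor_allele
        raise ValueError(f"allele must be 'major' or 'minor', got {allele!r}")


@dataclass(frozen=True)
class DesignParams:
    """Tunable assay-design parameters.

    ``mismatch_offset`` is the distance of the artificial substitution from
    the 3'-terminal diagnostic base: 4 means the substituted base is the
    5th base from the 3' terminus (counting the terminus as 1).
    """

    mismatch_offset: int = 4
    primer_length_range: tuple[int, int] = (18, 25)
    tm_window_celsius: tuple[float, float] = (55.0, 65.0)
    annealing_temp_celsius: float = 60.0
    product_length_range: tuple[int, int] = (80, 400)
    tm_model: str = "nn-unified-1997"
    monovalent_mM: float = 50.0
    primer_nM: float = 250.0
    gc_fraction_range: tuple[float, float] = (0.30, 0.70)
    require_gc_clamp: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.primer_length_range
        if not (0 < lo <= hi):
            raise ValueError("primer_length_range must be ordered and positive")
        if not (2 <= self.mismatch_offset < lo):
            raise ValueError("mismatch_offset must be >= 2 and < min primer length")
        plo, phi = self.product_length_range
        if not (0 < plo <= phi):
            raise ValueError("product_length_range must be ordered and positive")
        tlo, thi = self.tm_window_celsius
        if not tlo < thi:
            raise ValueError("tm_window_celsius must be ordered")


DEFAULT_PARAMS = DesignParams()

_NN_TABLES = {
    "nn-unified-1997": _mt.DNA_NN3,  # Allawi & SantaLucia 1997 unified set
    "nn-santalucia-2004": _mt.DNA_NN4,
    "wallace": None,
}


def melting_temperature(seq: str, params: DesignParams = DEFAULT_PARAMS) -> float:
    """Melting temperature in degC.

    Nearest-neighbor estimate for sequences of length >= 8; the additive
    Wallace rule (2 degC per A/T + 4 degC per G/C) for shorter oligos or
    when ``params.tm_model == 'wallace'``.
    """
    s = clean_sequence(seq)
    if params.tm_model == "wallace" or len(s) < 8:
        return float(_mt.Tm_Wallace(s))
    try:
        table = _NN_TABLES[params.tm_model]
    except KeyError:
        raise DesignError(f"unknown tm_model {params.tm_model!r}") from None
    return float(
        _mt.Tm_NN(
            s,
            nn_table=table,
            Na=params.monovalent_mM,
            dnac1=params.primer_nM,
            dnac2=0,
        )
    )


def apply_artificial_mismatch(core: str, params: DesignParams = DEFAULT_PARAMS) -> str:
    """Replace the base ``mismatch_offset`` positions 5' of the 3' terminus by its complement.

    With the default offset 4 the substituted base is the 5th from the 3'
    end.  Self-inverse (complementation is an involution).
    """
    s = clean_sequence(core)
    if len(s) <= params.mismatch_offset:
        raise DesignError(
            f"core length {len(s)} too short for mismatch offset {params.mismatch_offset}"
        )
    idx = len(s) - params.mismatch_offset - 1
    return s[:idx] + complement(s[idx]) + s[idx + 1 :]


def allele_template(locus: SnpLocus, allele: str, length: int) -> str:
    """Forward-strand template window of ``length`` ending at the diagnostic base."""
    if length - 1 > len(locus.upstream):
        raise DesignError(
            f"{locus.rsid}: upstream length {len(locus.upstream)} too short for "
            f"primer length {length}"
        )
    return locus.upstream[-(length - 1):] + locus.allele_base(allele)


@dataclass(frozen=True)
class AlleleSpecificPrimer:
    """A designed forward allele-specific primer (5'->3').

    The 3'-terminal base targets one allele; ``artificial_mismatch_offset``
    records how far 5' of that terminus the destabilizing substitution sits
    (offset counted with the terminus as position 1 excluded, i.e. offset 4
    = 5th base from the 3' end).
    """

    sequence: str
    target_allele: str
    artificial_mismatch_offset: int
    template_base: str
    substituted_base: str
    melting_temp_celsius: float
    diagnostic_offset: int = 1
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", clean_sequence(self.sequence))
        if self.substituted_base != complement(self.template_base):
            raise ValueError("substituted base must be the complement of the template base")


def design_allele_specific_primer(
    locus: SnpLocus,
    allele: str,
    length: int,
    params: DesignParams = DEFAULT_PARAMS,
) -> AlleleSpecificPrimer:
    """Build the forward allele-specific primer of a given length.

    The primer is the last ``length - 1`` upstream bases followed by the
    allele base, with the artificial destabilizing substitution applied.
    A melting temperature outside ``params.tm_window_celsius`` is flagged
    (non-fatal) on the returned record.
    """
    lo, hi = params.primer_length_range
    if not (lo <= length <= hi):
        raise DesignError(f"primer length {length} outside range {params.primer_length_range}")
    core = allele_template(locus, allele, length)
    seq = apply_artificial_mismatch(core, params)
    idx = length - params.mismatch_offset - 1
    tm = melting_temperature(seq, params)
    flags: tuple[str, ...] = ()
    if not (params.tm_window_celsius[0] <= tm <= params.tm_window_celsius[1]):
        flags = (f"Tm {tm:.1f} C outside window {params.tm_window_celsius}",)
    return AlleleSpecificPrimer(
        sequence=seq,
        target_allele=locus.allele_base(allele),
        artificial_mismatch_offset=params.mismatch_offset,
        template_base=core[idx],
        substituted_base=seq[idx],
        melting_temp_celsius=tm,
        flags=flags,
    )


@dataclass(frozen=True)
class ReversePrimer:
    """Common reverse primer (5'->3' on the reverse strand)."""

    sequence: str
    melting_temp_celsius: float
    start_offset_in_downstream: int  # 0-based start of the binding window on the forward strand
    strand: str = "reverse"

    @property
    def length(self) -> int:
        return len(self.sequence)


def _gc_fraction(s: str) -> float:
    return (s.count("G") + s.count("C")) / len(s)


def reverse_primer_candidates(
    locus: SnpLocus,
    params: DesignParams = DEFAULT_PARAMS,
    forward_length: int | None = None,
) -> list[tuple[float, ReversePrimer]]:
    """All constraint-satisfying reverse-primer windows with their scores.

    A candidate window lies on the forward strand within ``downstream``
    (so it can never overlap the diagnostic or substituted positions); the
    primer is its reverse complement.  Constraints: primer length within
    ``primer_length_range``, GC fraction within ``gc_fraction_range``,
    3'-terminal G/C clamp (if enabled), and amplicon length within
    ``product_length_range`` for the longest forward primer the locus
    supports.  Score = |Tm - annealing target| (smaller is better).
    """
    lo, hi = params.primer_length_range
    fwd_len = forward_length if forward_length is not None else min(hi, len(locus.upstream) + 1)
    out: list[tuple[float, ReversePrimer]] = []
    down = locus.downstream
    for length in range(lo, hi + 1):
        for start in range(0, len(down) - length + 1):
            window = down[start : start + length]
            primer = reverse_complement(window)
            if params.require_gc_clamp and primer[-1] not in "GC":
                continue
            gc = _gc_fraction(primer)
            if not (params.gc_fraction_range[0] <= gc <= params.gc_fraction_range[1]):
                continue
            product = fwd_len + start + length
            if not (params.product_length_range[0] <= product <= params.product_length_range[1]):
                continue
            tm = melting_temperature(primer, params)
            score = abs(tm - params.annealing_temp_celsius)
            out.append((score, ReversePrimer(primer, tm, start)))
    return out


def design_common_reverse_primer(
    locus: SnpLocus,
    params: DesignParams = DEFAULT_PARAMS,
    forward_length: int | None = None,
) -> ReversePrimer:
    """Pick the reverse-primer window whose Tm is nearest the annealing target.

    Ties break to the shortest primer, then the smallest product (most
    5'-proximal window), so the search is deterministic.
    """
    if len(locus.downstream) < params.primer_length_range[0]:
        raise DesignError(
            f"{locus.rsid}: downstream ({len(locus.downstream)} nt) shorter than the "
            f"minimum primer length; no reverse-primer window exists"
        )
    candidates = reverse_primer_candidates(locus, params, forward_length=forward_length)
    if not candidates:
        raise DesignError(
            f"{locus.rsid}: no downstream window satisfies the reverse-primer "
            f"constraints (length {params.primer_length_range}, GC "
            f"{params.gc_fraction_range}, 3' G/C clamp, product "
            f"{params.product_length_range})"
        )
    return min(
        candidates,
        key=lambda c: (round(c[0], 9), c[1].length, c[1].start_offset_in_downstream),
    )[1]


@dataclass(frozen=True)
class CyclingConditions:
    """Thermocycling constants shared by both reactions."""

    denature_celsius: float = 94.0
    anneal_celsius: float = 60.0
    extend_celsius: float = 72.0
    step_seconds: int = 30
    cycles: int = 35


@dataclass(frozen=True)
class AspAssay:
    """A complete two-reaction allele-specific PCR assay for one SNP."""

    locus: SnpLocus
    primer_major: AlleleSpecificPrimer
    primer_minor: AlleleSpecificPrimer
    common_reverse: ReversePrimer
    product_length_bp: int
    cycling: CyclingConditions = field(default_factory=CyclingConditions)

    def __post_init__(self) -> None:
        a, b = self.primer_major.sequence, self.primer_minor.sequence
        if len(a) != len(b) or a[:-1] != b[:-1] or a[-1] == b[-1]:
            raise ValueError("allele-specific primers must differ only at the 3'-terminal base")

    def primer(self, allele: str) -> AlleleSpecificPrimer:
        return self.primer_major if allele == "major" else self.primer_minor


def design_assay(locus: SnpLocus, params: DesignParams = DEFAULT_PARAMS) -> AspAssay:
    """Design the full two-reaction assay for a locus.

    Both forward primers share one length, chosen (within the allowed range
    and the available upstream context) to put the pair's mean melting
    temperature nearest the annealing target; ties break to the shorter
    primer.  The common reverse primer is optimised independently.
    """
    lo, hi = params.primer_length_range
    max_len = min(hi, len(locus.upstream) + 1)
    if max_len < lo:
        raise DesignError(
            f"{locus.rsid}: upstream ({len(locus.upstream)} nt) cannot support the "
            f"minimum primer length {lo}"
        )
    best: tuple[float, int] | None = None
    for length in range(lo, max_len + 1):
        pm = design_allele_specific_primer(locus, "major", length, params)
        pn = design_allele_specific_primer(locus, "minor", length, params)
        score = abs(
            (pm.melting_temp_celsius + pn.melting_temp_celsius) / 2.0
            - params.annealing_temp_celsius
        )
        if best is None or (round(score, 9), length) < best:
            best = (round(score, 9), length)
    assert best is not None
    length = best[1]
    primer_major = design_allele_specific_primer(locus, "major", length, params)
    primer_minor = design_allele_specific_primer(locus, "minor", length, params)
    reverse = design_common_reverse_primer(locus, params, forward_length=length)
    product = length + reverse.start_offset_in_downstream + reverse.length
    return AspAssay(
        locus=locus,
        primer_major=primer_major,
        primer_minor=primer_minor,
        common_reverse=reverse,
        product_length_bp=product,
        cycling=CyclingConditions(anneal_celsius=params.annealing_temp_celsius),
    )
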