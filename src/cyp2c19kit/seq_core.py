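"""Nucleotide-sequence primitives shared by the assay-design and simulation layers.

Sequences are plain Python strings over the DNA alphabet {A, C, G, T},
written 5'->3'.  This layer deliberately rejects IUPAC ambiguity codes and
RNA (U): every downstream consumer (primer design, in-silico PCR) assumes an
unambiguous template strand.  Lowercase input is tolerated and upper-cased
on ingest.

Mismatch bookkeeping between a primer and the template window it anneals to
uses 1-based offsets counted from the primer's 3' terminus (offset 1 = the
3'-terminal base), because allele-specific PCR discrimination is governed by
how close a mismatch sits to the extending 3' end.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

__all__ = [
    "DNA_ALPHABET",
    "AlphabetError",
    "AlignmentError",
    "MismatchProfile",
    "clean_sequence",
    "complement",
    "reverse_complement",
    "mismatch_profile",
]

DNA_ALPHABET = frozenset("ACGT")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class AlphabetError(ValueError):
    """Raised for characters outside the unambiguous DNA alphabet."""


class AlignmentError(ValueError):
    """Raised when two sequences that must be compared position-wise differ in length."""


def clean_sequence(seq: str) -> str:
    """Validate and normalise a DNA sequence.

    Upper-cases the input and checks that it is non-empty and restricted to
    A/C/G/T.  U is rejected explicitly (DNA-only tool); IUPAC ambiguity
    codes (N, R, Y, ...) are rejected like any other foreign character.
    """
    if not isinstance(seq, str):
        raise AlphabetError(f"expected a string sequence, got {type(seq).__name__}")
    s = seq.upper()
    if not s:
        raise AlphabetError("empty sequence")
    bad = set(s) - DNA_ALPHABET
    if bad:
        if "U" in bad:
            raise AlphabetError("U found: RNA is not accepted, supply DNA (A/C/G/T)")
        raise AlphabetError(f"non-DNA characters {sorted(bad)} in sequence")
    return s


def complement(base: str) -> str:
    """Watson-Crick partner of a single nucleotide (involutive)."""
    b = base.upper()
    if len(b) != 1 or b not in DNA_ALPHABET:
        raise AlphabetError(f"{base!r} is not a single A/C/G/T nucleotide")
    return _COMPLEMENT[b]


def reverse_complement(seq: str) -> str:
    """Opposite strand of ``seq``, read 5'->3'.  Length-preserving involution."""
    s = clean_sequence(seq)
    return str(Seq(s).reverse_complement())


@dataclass(frozen=True)
class MismatchProfile:
    """Per-position comparison of a primer against an equal-length template window.

    ``positions_from_3prime`` are 1-based offsets of mismatching positions,
    counted from the primer's 3' terminus (offset 1 = 3'-terminal base).
    """

    total: int
    positions_from_3prime: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.total != len(self.positions_from_3prime):
            raise ValueError("total must equal the number of listed positions")
        if len(set(self.positions_from_3prime)) != len(self.positions_from_3prime):
            raise ValueError("mismatch positions must be unique")

    @property
    def has_terminal_mismatch(self) -> bool:
        """True if the 3'-terminal primer base mismatches the template."""
        return 1 in self.positions_from_3prime


def mismatch_profile(primer: str, template_window: str) -> MismatchProfile:
    """Compare a primer to the equal-length template window it anneals over.

    Both sequences are given 5'->3' on the same strand sense, aligned at the
    3' end (which for equal lengths is a full positional alignment).
    """
    p = clean_sequence(primer)
    t = clean_sequence(template_window)
    if len(p) != len(t):
        raise AlignmentError(
            f"primer length {len(p)} != template window length {len(t)}"
        )
    n = len(p)
    positions = tuple(
        n - i for i in range(n) if p[i] != t[i]
    )
    return MismatchProfile(total=len(positions), positions_from_3prime=tuple(sorted(positions)))
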