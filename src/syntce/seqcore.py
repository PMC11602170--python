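"""Validated RNA sequences, reading-frame arithmetic and motif scanning.

Everything downstream (thermodynamic scoring, cassette design, operon
assembly) is built on the small vocabulary defined here: an immutable RNA
sequence type (:class:`NucSeq`), half-open annotation coordinates
(:class:`Region`), IUPAC degenerate patterns (:class:`IUPACPattern`), and
scanners for stop codons and the 5'-URAUG-3' overlapping stop-start motif
that places a downstream start codon one nucleotide inside an upstream stop
codon.

Conventions
-----------
* Coordinates are 0-based, half-open, 5'->3' on the transcript.
* The internal alphabet is RNA (A, C, G, U); DNA input is accepted at the
  boundary (:func:`to_rna`) and transcribed.  Ambiguity codes are allowed in
  patterns but never in concrete sequences.
* The stop-codon set is the standard bacterial {UAA, UAG, UGA}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, List, Sequence, Union

__all__ = [
    "NucSeq",
    "Region",
    "IUPACPattern",
    "SeqValidationError",
    "RNA_ALPHABET",
    "STOP_CODONS",
    "IUPAC_RNA",
    "to_rna",
    "revcomp",
    "match_iupac",
    "scan_stop_codons",
    "find_overlap_motif",
    "junction_frame",
]

RNA_ALPHABET = frozenset("ACGU")
STOP_CODONS = frozenset({"UAA", "UAG", "UGA"})

_COMPLEMENT = str.maketrans("ACGU", "UGCA")

#: IUPAC degenerate nucleotide codes, RNA reading (T -> U).
IUPAC_RNA = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "U": frozenset("U"),
    "R": frozenset("AG"),
    "Y": frozenset("CU"),
    "S": frozenset("CG"),
    "W": frozenset("AU"),
    "K": frozenset("GU"),
    "M": frozenset("AC"),
    "B": frozenset("CGU"),
    "D": frozenset("AGU"),
    "H": frozenset("ACU"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGU"),
}


class SeqValidationError(ValueError):
    """Raised when a sequence, pattern or coordinate fails validation."""


@dataclass(frozen=True)
class NucSeq:
    """An immutable, validated RNA sequence (5'->3').

    Construct directly only from already-normalized residues; use
    :func:`to_rna` for arbitrary user input (case folding, T->U).
    """

    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise SeqValidationError("NucSeq must contain at least one residue")
        for i, ch in enumerate(self.residues):
            if ch not in RNA_ALPHABET:
                raise SeqValidationError(
                    f"invalid residue {ch!r} at position {i}; expected one of A, C, G, U"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues

    def __iter__(self) -> Iterator[str]:
        return iter(self.residues)

    def __getitem__(self, item: Union[int, slice]) -> str:
        # Slicing returns a plain string: sub-windows (possibly empty) are
        # working material, not new validated molecules.
        return self.residues[item]

    def __add__(self, other: "NucSeq | str") -> "NucSeq":
        return NucSeq(self.residues + str(other))


@dataclass(frozen=True)
class Region:
    """Half-open annotation interval on a transcript.

    ``frame`` is the reading-frame offset (0, 1 or 2) of ``start`` relative
    to transcript position 0; it is only meaningful for coding annotations.
    """

    start: int
    end: int
    frame: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise SeqValidationError(
                f"invalid region [{self.start}, {self.end}): need 0 <= start <= end"
            )
        if self.frame not in (0, 1, 2):
            raise SeqValidationError(f"frame must be 0, 1 or 2, got {self.frame}")

    def __len__(self) -> int:
        return self.end - self.start

    def shift(self, offset: int, label: str | None = None) -> "Region":
        return Region(self.start + offset, self.end + offset,
                      (self.start + offset) % 3 if self.frame else self.frame,
                      self.label if label is None else label)

    def overlaps(self, other: "Region") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class IUPACPattern:
    """A degenerate nucleotide pattern such as ``RRRRRR`` or ``URAUG``."""

    symbols: str

    def __post_init__(self) -> None:
        if not self.symbols:
            raise SeqValidationError("empty IUPAC pattern")
        for i, ch in enumerate(self.symbols):
            if ch not in IUPAC_RNA:
                raise SeqValidationError(
                    f"invalid IUPAC symbol {ch!r} at position {i}"
                )

    def __len__(self) -> int:
        return len(self.symbols)

    def matches_at(self, residues: str, pos: int) -> bool:
        if pos < 0 or pos + len(self.symbols) > len(residues):
            return False
        return all(
            residues[pos + i] in IUPAC_RNA[sym]
            for i, sym in enumerate(self.symbols)
        )


def to_rna(raw: str) -> NucSeq:
    """Normalize arbitrary nucleotide text to a validated RNA sequence.

    Whitespace is stripped, case is folded, and T is transcribed to U.
    Ambiguity codes are rejected: concrete sequences must be concrete.
    """
    cleaned = "".join(raw.split()).upper()
    if not cleaned:
        raise SeqValidationError("empty sequence")
    for i, ch in enumerate(cleaned):
        if ch not in "ACGTU":
            raise SeqValidationError(
                f"invalid character {ch!r} at position {i}; expected A, C, G, T or U"
            )
    return NucSeq(cleaned.replace("T", "U"))


def revcomp(seq: NucSeq | str) -> NucSeq:
    """Reverse complement under A-U / C-G (an involution)."""
    s = str(seq)
    return NucSeq(s.translate(_COMPLEMENT)[::-1])


def match_iupac(seq: NucSeq | str, pattern: IUPACPattern | str) -> List[int]:
    """All 0-based start positions where *pattern* matches, ascending.

    Overlapping matches are all reported.  A pattern longer than the
    sequence yields an empty list.
    """
    if isinstance(pattern, str):
        pattern = IUPACPattern(pattern)
    s = str(seq)
    return [p for p in range(len(s) - len(pattern) + 1) if pattern.matches_at(s, p)]


def scan_stop_codons(seq: NucSeq | str, frame: int) -> List[int]:
    """Positions of every stop codon read in *frame* (p == frame mod 3)."""
    if frame not in (0, 1, 2):
        raise SeqValidationError(f"frame must be 0, 1 or 2, got {frame}")
    s = str(seq)
    return [
        p for p in range(frame, len(s) - 2, 3) if s[p:p + 3] in STOP_CODONS
    ]


_URAUG = IUPACPattern("URAUG")


def find_overlap_motif(seq: NucSeq | str) -> List[int]:
    """Positions of the 5'-URAUG-3' overlapping stop-start motif.

    At a reported position p the stop codon (UAA or UGA) occupies p..p+2 and
    the start codon AUG occupies p+2..p+4, sharing one nucleotide — the
    configuration giving intergenic distance -1.
    """
    return match_iupac(seq, _URAUG)


def junction_frame(upstream_frame: int) -> int:
    """Reading frame of the start codon at a URAUG junction.

    The AUG begins two nucleotides into the upstream-frame stop codon, so
    the coupled downstream ORF reads in frame ``(upstream_frame + 2) % 3``.
    """
    if upstream_frame not in (0, 1, 2):
        raise SeqValidationError(
            f"frame must be 0, 1 or 2, got {upstream_frame}"
        )
    return (upstream_frame + 2) % 3


def translate_frame(seq: NucSeq | str, start: int) -> List[str]:
    """Codons read from *start* to the end of the sequence (partial tail dropped)."""
    s = str(seq)
    return [s[p:p + 3] for p in range(start, len(s) - 2, 3)]
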