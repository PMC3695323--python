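"""Core DNA sequence types and IUPAC utilities.

Coordinates are 0-based half-open throughout the package; converters at the
I/O boundary produce 1-based formats (GFF3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

#: IUPAC degenerate code -> set of concrete bases it stands for.
IUPAC_EXPAND: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: set of concrete bases -> IUPAC code (inverse of IUPAC_EXPAND).
IUPAC_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_EXPAND.items()}


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware (R<->Y, etc.)."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_match(code: str, base: str) -> bool:
    """Does a degenerate motif character match a concrete subject base?

    An N in the subject matches nothing (unknown bases never satisfy a motif).
    """
    if base == "N":
        return False
    return base in IUPAC_EXPAND[code]


def iupac_consensus_code(bases: set[str] | frozenset[str]) -> str:
    """IUPAC code covering a set of concrete bases (e.g. {A,G} -> R)."""
    key = frozenset(bases)
    if key not in IUPAC_CODE:
        raise ValueError(f"not a valid base set: {sorted(bases)}")
    return IUPAC_CODE[key]


@dataclass
class GenomicSequence:
    """A named DNA sequence over {A,C,G,T,N} (genomic record, BAC clone,
    BAC-end read or locus haplotype)."""

    id: str
    residues: str
    description: str = field(default="")

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r}: residues must be non-empty")
        bad = set(self.residues) - DNA_ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(self.residues) if c in bad)
            raise ValueError(
                f"sequence {self.id!r}: illegal character {self.residues[pos]!r} "
                f"at offset {pos}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def subseq(self, start: int, end: int, sub_id: str | None = None) -> "GenomicSequence":
        return GenomicSequence(sub_id or f"{self.id}:{start}-{end}", self.residues[start:end])
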