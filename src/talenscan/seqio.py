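"""Sequence records, coordinate conventions, FASTA I/O and base-level utilities.

Conventions used throughout the package:

* Internal coordinates are 0-based, half-open (``start`` inclusive, ``end``
  exclusive). All user-facing reports are 1-based inclusive, matching the
  locus notation conventional in the genome-editing literature
  (e.g. ``Chr.3: 36,197,357-36,197,403``). :func:`to_one_based` is the single
  conversion point.
* Residues are uppercase ``A/C/G/T/N``. Lowercase (soft-masked) input is
  uppercased on read; masking is never used to exclude matches.
* In mismatch counting a genomic ``N`` counts as a mismatch against any
  binding-element base (conservative). In IUPAC motif matching a genomic
  ``N`` fails every pattern code except ``N`` itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FastaFormatError",
    "NucleotideSequence",
    "GenomicInterval",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "iupac_matches",
    "iupac_reverse_complement",
    "to_one_based",
    "from_one_based",
    "IUPAC_SETS",
]

VALID_RESIDUES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Degenerate nucleotide codes, each expanded to its set of concrete bases.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

# Complement of every IUPAC code (W and S are self-complementary).
_IUPAC_COMPLEMENT = str.maketrans("ACGTURYSWKMBDHVN", "TGCAAYRSWMKVHDBN")


class FastaFormatError(ValueError):
    """Raised for malformed FASTA content or residues outside A/C/G/T/N."""


@dataclass(frozen=True)
class NucleotideSequence:
    """A named DNA sequence over the alphabet ``{A,C,G,T,N}``.

    Residues are uppercase-normalized at construction; any other character
    raises :class:`FastaFormatError` naming the record and offset.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        normalized = self.residues.upper()
        for offset, ch in enumerate(normalized):
            if ch not in VALID_RESIDUES:
                raise FastaFormatError(
                    f"record {self.id!r}: invalid residue {ch!r} at offset {offset}"
                )
        object.__setattr__(self, "residues", normalized)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    def slice(self, start: int, end: int) -> str:
        if not (0 <= start < end <= len(self.residues)):
            raise ValueError(f"slice [{start}, {end}) out of bounds for {self.id!r}")
        return self.residues[start:end]


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-aware interval on a named sequence, 0-based half-open."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id!r}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def to_one_based(self) -> tuple[int, int]:
        return to_one_based(self.start, self.end)


def to_one_based(start: int, end: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval to 1-based inclusive coordinates."""
    return start + 1, end


def from_one_based(start: int, end: int) -> tuple[int, int]:
    """Convert 1-based inclusive coordinates to a 0-based half-open interval."""
    return start - 1, end


def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    """Read a (multi-record) FASTA file into :class:`NucleotideSequence` records.

    Record ids are the header up to the first whitespace. Lowercase residues
    are uppercased; anything outside ``{A,C,G,T,N}`` raises
    :class:`FastaFormatError` naming the record and offset.
    """
    path = Path(path)
    records = []
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            records.append(NucleotideSequence(id=rec.id, residues=str(rec.seq)))
    return records


def write_fasta(
    sequences: Iterable[NucleotideSequence], path: str | Path, width: int = 60
) -> None:
    """Write records as FASTA, wrapping residue lines at ``width`` columns."""
    with open(path, "w") as handle:
        for seq in sequences:
            handle.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), width):
                handle.write(seq.residues[i : i + width] + "\n")


def reverse_complement(residues: str) -> str:
    """Watson-Crick reverse complement over ``{A,C,G,T,N}`` (N maps to N)."""
    upper = residues.upper()
    bad = set(upper) - VALID_RESIDUES
    if bad:
        raise ValueError(f"invalid residue(s) {sorted(bad)} in sequence")
    return upper.translate(_COMPLEMENT)[::-1]


def iupac_reverse_complement(pattern: str) -> str:
    """Reverse complement of an IUPAC pattern (code-wise complement, reversed)."""
    upper = pattern.upper()
    bad = set(upper) - set(IUPAC_SETS)
    if bad:
        raise ValueError(f"invalid IUPAC code(s) {sorted(bad)} in pattern")
    return upper.translate(_IUPAC_COMPLEMENT)[::-1]


def iupac_matches(pattern_char: str, base: str) -> bool:
    """True iff ``base`` is in the degenerate set of ``pattern_char``.

    A genomic ``N`` matches only the pattern code ``N``; every concrete base
    matches per the IUPAC degeneracy table.
    """
    code = pattern_char.upper()
    if code not in IUPAC_SETS:
        raise ValueError(f"unknown IUPAC code {pattern_char!r}")
    b = base.upper()
    if b not in VALID_RESIDUES:
        raise ValueError(f"invalid residue {base!r}")
    if b == "N":
        return code == "N"
    return b in IUPAC_SETS[code]
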