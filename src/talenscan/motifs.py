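"""Transcription-factor binding-site scanning of upstream regions.

Scans sequences (typically promoter/upstream windows extracted by the
caller) for an IUPAC consensus motif on one or both strands, reporting every
match position including overlapping ones. The shipped default is the
canonical SRY core consensus ``WAACAAW`` ((A/T)AACAA(A/T)); it is fully
user-overridable. Presence/absence counting only — no position-weight-matrix
scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional

import pandas as pd

from .seqio import (
    IUPAC_SETS,
    GenomicInterval,
    NucleotideSequence,
    iupac_matches,
    iupac_reverse_complement,
)

__all__ = ["MotifSpec", "MotifHitReport", "MotifSummary", "scan_motif",
           "summarize_gene_sites", "DEFAULT_SRY_MOTIF"]


@dataclass(frozen=True)
class MotifSpec:
    """An IUPAC consensus motif; scanned on both strands by default."""

    name: str
    pattern: str
    both_strands: bool = True

    def __post_init__(self) -> None:
        pattern = self.pattern.upper()
        if len(pattern) < 4:
            raise ValueError("motif pattern must be at least 4 characters")
        bad = set(pattern) - set(IUPAC_SETS)
        if bad:
            raise ValueError(f"invalid IUPAC code(s) in pattern: {sorted(bad)}")
        object.__setattr__(self, "pattern", pattern)


DEFAULT_SRY_MOTIF = MotifSpec(name="SRY", pattern="WAACAAW")


@dataclass(frozen=True)
class MotifHitReport:
    """All motif matches in one sequence; positions are 0-based window starts."""

    seq_id: str
    window: Optional[GenomicInterval]
    hits: tuple[tuple[int, str], ...]
    count: int


class MotifSummary(NamedTuple):
    table: pd.DataFrame  # columns: seq_id, count
    n_flagged: int       # sequences with count >= min_sites


def _match_at(seq: str, pattern: str, i: int) -> bool:
    return all(iupac_matches(pattern[j], seq[i + j]) for j in range(len(pattern)))


def scan_motif(seq: NucleotideSequence, motif: MotifSpec) -> MotifHitReport:
    """Report every offset where the motif matches (overlaps included).

    Minus-strand matches are windows whose minus-strand 5'->3' read matches
    the pattern, i.e. plus-strand windows matching the pattern's IUPAC
    reverse complement; their reported position is the plus-strand window
    start. A genomic N fails every pattern code except N.
    """
    s = seq.residues
    m = len(motif.pattern)
    hits: list[tuple[int, str]] = []
    patterns = [(motif.pattern, "+")]
    if motif.both_strands:
        patterns.append((iupac_reverse_complement(motif.pattern), "-"))
    for pattern, strand in patterns:
        for i in range(len(s) - m + 1):
            if _match_at(s, pattern, i):
                hits.append((i, strand))
    hits.sort(key=lambda h: (h[0], h[1]))
    return MotifHitReport(
        seq_id=seq.id,
        window=GenomicInterval(seq.id, 0, len(s)) if len(s) else None,
        hits=tuple(hits),
        count=len(hits),
    )


def summarize_gene_sites(
    upstreams: Iterable[NucleotideSequence], motif: MotifSpec, min_sites: int = 1
) -> MotifSummary:
    """Per-sequence motif counts plus how many sequences reach ``min_sites``."""
    if min_sites < 1:
        raise ValueError("min_sites must be >= 1")
    rows = []
    for seq in upstreams:
        report = scan_motif(seq, motif)
        rows.append({"seq_id": seq.id, "count": report.count})
    table = pd.DataFrame(rows, columns=["seq_id", "count"])
    n_flagged = int((table["count"] >= min_sites).sum()) if len(table) else 0
    return MotifSummary(table=table, n_flagged=n_flagged)
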