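"""Genome-wide paired-EBE off-target scanning for TALEN pairs.

A potential off-target site is a pair of genomic windows resembling the two
effector binding elements (EBEs) of a TALEN: position 0 of each EBE must
align to a T on the match strand (required exact, outside the mismatch
budget), the total number of mismatches across the two EBEs lies in a
configurable band (default 1-10, so the perfect on-target itself is
excluded), and the spacer between the footprints is below 100 bp because
longer spacers interfere with FokI dimerization.

Spacer length also classifies expected activity: spacers shorter than 10 bp
or longer than 24 bp give the TALEN scaffold lower disrupting activity, so
hits are labelled ``likely_active`` only inside the closed interval
[10, 24] (all bounds configurable).

Arrangements: ``LR`` is the canonical heterodimeric geometry (left EBE on
the plus strand upstream, right EBE on the minus strand downstream); ``RL``
swaps the two EBEs; ``LL``/``RR`` are homodimeric and disabled by default
since obligate-heterodimer FokI variants (ELD/KKR) cut only as an L+R pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .seqio import GenomicInterval, NucleotideSequence, to_one_based

__all__ = [
    "OffTargetCriteria",
    "ArmMatch",
    "OffTargetHit",
    "scan_arm",
    "pair_arms",
    "classify_activity",
    "scan_offtargets",
    "hits_to_dataframe",
    "write_hits_tsv",
    "write_hits_bed",
]

LIKELY_ACTIVE = "likely_active"
LOW_ACTIVITY = "low_activity"

VALID_ARRANGEMENTS = ("LR", "RL", "LL", "RR")


@dataclass(frozen=True)
class OffTargetCriteria:
    """Filter and classification parameters for the off-target scan.

    Defaults encode the published screening rule: 1-10 total mismatches over
    the pair of EBEs, spacer strictly below 100 bp, heterodimeric
    arrangements only, and the 10-24 bp activity-permissive spacer window.
    ``max_arm_mismatch`` optionally caps mismatches per individual arm
    (off by default: the published rule is pair-level).
    """

    min_total_mismatch: int = 1
    max_total_mismatch: int = 10
    min_spacer: int = 1
    max_spacer: int = 99
    active_spacer_low: int = 10
    active_spacer_high: int = 24
    arrangements: tuple[str, ...] = ("LR", "RL")
    max_arm_mismatch: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0 <= self.min_total_mismatch <= self.max_total_mismatch):
            raise ValueError("require 0 <= min_total_mismatch <= max_total_mismatch")
        if self.min_spacer < 1:
            raise ValueError("min_spacer must be >= 1")
        if not (self.active_spacer_low <= self.active_spacer_high <= self.max_spacer):
            raise ValueError(
                "require active_spacer_low <= active_spacer_high <= max_spacer"
            )
        bad = set(self.arrangements) - set(VALID_ARRANGEMENTS)
        if bad:
            raise ValueError(f"unknown arrangement(s): {sorted(bad)}")


@dataclass(frozen=True)
class ArmMatch:
    """One EBE matched to a genomic window.

    ``arm`` names which EBE matched ('L' or 'R'); ``interval.strand`` is the
    strand on which the EBE reads 5'->3'; ``mismatches`` excludes position 0,
    whose T is required exact.
    """

    arm: str
    interval: GenomicInterval
    mismatches: int


@dataclass(frozen=True)
class OffTargetHit:
    """A paired match: plus-strand upstream arm + minus-strand downstream arm."""

    seq_id: str
    upstream_arm: ArmMatch
    downstream_arm: ArmMatch
    arrangement: str
    spacer_len: int
    total_mismatches: int
    activity: str
    rank_score: tuple = ()

    @property
    def span(self) -> GenomicInterval:
        """Outer footprint span (upstream arm start to downstream arm end)."""
        return GenomicInterval(
            self.seq_id, self.upstream_arm.interval.start,
            self.downstream_arm.interval.end, "+",
        )


def _encode(residues: str) -> np.ndarray:
    return np.frombuffer(residues.encode("ascii"), dtype="S1")


def scan_arm(
    genome: NucleotideSequence, ebe: str, max_mm: int, arm: str = "L"
) -> list[ArmMatch]:
    """Find all windows on both strands matching one EBE.

    A plus-strand match at ``i`` requires ``genome[i] == 'T'`` (EBE position
    0) and at most ``max_mm`` mismatches over EBE positions 1..L-1. A
    minus-strand window matches iff its reverse complement satisfies the same
    rule, i.e. the plus strand carries an A at the window's last position.
    Genomic ``N`` mismatches every EBE base (and never satisfies T0).
    Output is sorted by (start, strand), plus before minus.
    """
    ebe = ebe.upper()
    if ebe[0] != "T":
        raise ValueError("position-0 T is mandatory")
    if set(ebe) - set("ACGT"):
        raise ValueError("EBE must be over A/C/G/T")
    L = len(ebe)
    if L < 2:
        raise ValueError("EBE length must be >= 2")
    g = _encode(genome.residues)
    n = len(g)
    matches: list[ArmMatch] = []
    if n < L:
        return matches
    n_win = n - L + 1
    ebe_bytes = _encode(ebe)

    # plus strand: window i aligns EBE position j to genome position i+j
    mm_plus = np.zeros(n_win, dtype=np.int32)
    for j in range(1, L):
        mm_plus += g[j : j + n_win] != ebe_bytes[j]
    ok_plus = (g[:n_win] == b"T") & (mm_plus <= max_mm)

    # minus strand: EBE position j aligns to genome position i + (L-1-j),
    # compared against the complement of the EBE base
    comp = bytes(ebe, "ascii").translate(bytes.maketrans(b"ACGT", b"TGCA"))
    comp_bytes = np.frombuffer(comp, dtype="S1")
    mm_minus = np.zeros(n_win, dtype=np.int32)
    for j in range(1, L):
        mm_minus += g[L - 1 - j : L - 1 - j + n_win] != comp_bytes[j]
    ok_minus = (g[L - 1 : L - 1 + n_win] == b"A") & (mm_minus <= max_mm)

    for i in np.flatnonzero(ok_plus | ok_minus):
        i = int(i)
        if ok_plus[i]:
            matches.append(
                ArmMatch(arm, GenomicInterval(genome.id, i, i + L, "+"), int(mm_plus[i]))
            )
        if ok_minus[i]:
            matches.append(
                ArmMatch(arm, GenomicInterval(genome.id, i, i + L, "-"), int(mm_minus[i]))
            )
    matches.sort(key=lambda m: (m.interval.start, m.interval.strand))
    return matches


def classify_activity(spacer_len: int, criteria: OffTargetCriteria) -> str:
    """Label a spacer length by expected nuclease activity.

    ``likely_active`` iff the spacer lies in the closed activity-permissive
    interval; shorter or longer spacers give the scaffold lower disrupting
    activity.
    """
    if spacer_len < 1:
        raise ValueError("spacer_len must be >= 1")
    if criteria.active_spacer_low <= spacer_len <= criteria.active_spacer_high:
        return LIKELY_ACTIVE
    return LOW_ACTIVITY


def pair_arms(
    left: Sequence[ArmMatch],
    right: Sequence[ArmMatch],
    criteria: OffTargetCriteria = OffTargetCriteria(),
) -> list[OffTargetHit]:
    """Combine single-arm matches into paired hits under the criteria.

    For each enabled arrangement, every plus-strand arm is paired with every
    downstream minus-strand arm whose spacer (minus-arm start minus plus-arm
    end) and total mismatch count pass the filters. Arrangement labels which
    EBE served each position: ``LR`` = left EBE plus / right EBE minus,
    ``RL`` swapped, ``LL``/``RR`` homodimeric.
    """
    seq_ids = {m.interval.seq_id for m in list(left) + list(right)}
    if len(seq_ids) > 1:
        raise ValueError(f"arm matches span multiple sequences: {sorted(seq_ids)}")

    by_ebe_strand: dict[tuple[str, str], list[ArmMatch]] = {}
    for m in left:
        by_ebe_strand.setdefault(("L", m.interval.strand), []).append(m)
    for m in right:
        by_ebe_strand.setdefault(("R", m.interval.strand), []).append(m)

    hits: list[OffTargetHit] = []
    for arrangement in criteria.arrangements:
        up_ebe, down_ebe = arrangement[0], arrangement[1]
        ups = by_ebe_strand.get((up_ebe, "+"), [])
        downs = sorted(
            by_ebe_strand.get((down_ebe, "-"), []), key=lambda m: m.interval.start
        )
        for up in ups:
            for down in downs:
                spacer = down.interval.start - up.interval.end
                if spacer < criteria.min_spacer:
                    continue
                if spacer > criteria.max_spacer:
                    break  # downs sorted by start; spacer only grows
                total = up.mismatches + down.mismatches
                if not (
                    criteria.min_total_mismatch <= total <= criteria.max_total_mismatch
                ):
                    continue
                if criteria.max_arm_mismatch is not None and (
                    up.mismatches > criteria.max_arm_mismatch
                    or down.mismatches > criteria.max_arm_mismatch
                ):
                    continue
                hits.append(
                    OffTargetHit(
                        seq_id=up.interval.seq_id,
                        upstream_arm=up,
                        downstream_arm=down,
                        arrangement=arrangement,
                        spacer_len=spacer,
                        total_mismatches=total,
                        activity=classify_activity(spacer, criteria),
                    )
                )
    return hits


def scan_offtargets(
    genome: Iterable[NucleotideSequence],
    pair,
    criteria: OffTargetCriteria = OffTargetCriteria(),
    exclude: Sequence[GenomicInterval] = (),
) -> list[OffTargetHit]:
    """Scan a genome for paired off-target sites of a TALEN pair.

    Hits are ranked by credibility: fewer total mismatches first, then spacer
    closest to the designed spacer, then genomic position. ``exclude``
    optionally drops hits whose footprint overlaps a listed interval (e.g.
    an explicitly annotated on-target locus). Deterministic for fixed input.
    """
    all_hits: list[OffTargetHit] = []
    for seq in genome:
        left_matches = scan_arm(seq, pair.left_ebe, criteria.max_total_mismatch, "L")
        right_matches = scan_arm(seq, pair.right_ebe, criteria.max_total_mismatch, "R")
        all_hits.extend(pair_arms(left_matches, right_matches, criteria))
    if exclude:
        all_hits = [
            h for h in all_hits if not any(h.span.overlaps(iv) for iv in exclude)
        ]
    keyed = []
    for h in all_hits:
        key = (
            h.total_mismatches,
            abs(h.spacer_len - pair.designed_spacer),
            h.seq_id,
            h.upstream_arm.interval.start,
            h.downstream_arm.interval.start,
            h.arrangement,
        )
        keyed.append((key, h))
    keyed.sort(key=lambda item: item[0])
    return [replace(h, rank_score=key) for key, h in keyed]


# ---------------------------------------------------------------------------
# report serialization

def hits_to_dataframe(hits: Sequence[OffTargetHit]) -> pd.DataFrame:
    """Tabulate hits with 1-based inclusive coordinates for reporting."""
    rows = []
    for rank, h in enumerate(hits, start=1):
        span1, span2 = h.span.to_one_based()
        up1, up2 = h.upstream_arm.interval.to_one_based()
        dn1, dn2 = h.downstream_arm.interval.to_one_based()
        rows.append(
            {
                "seq_id": h.seq_id,
                "hit_start": span1,
                "hit_end": span2,
                "arrangement": h.arrangement,
                "up_arm": h.upstream_arm.arm,
                "up_start": up1,
                "up_end": up2,
                "up_strand": h.upstream_arm.interval.strand,
                "up_mm": h.upstream_arm.mismatches,
                "down_arm": h.downstream_arm.arm,
                "down_start": dn1,
                "down_end": dn2,
                "down_strand": h.downstream_arm.interval.strand,
                "down_mm": h.downstream_arm.mismatches,
                "spacer_len": h.spacer_len,
                "total_mm": h.total_mismatches,
                "activity": h.activity,
                "rank": rank,
            }
        )
    columns = [
        "seq_id", "hit_start", "hit_end", "arrangement",
        "up_arm", "up_start", "up_end", "up_strand", "up_mm",
        "down_arm", "down_start", "down_end", "down_strand", "down_mm",
        "spacer_len", "total_mm", "activity", "rank",
    ]
    return pd.DataFrame(rows, columns=columns)


def write_hits_tsv(hits: Sequence[OffTargetHit], path, metadata: dict | None = None) -> None:
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"#{key}={value}\n")
        hits_to_dataframe(hits).to_csv(fh, sep="\t", index=False)


def write_hits_bed(hits: Sequence[OffTargetHit], path) -> None:
    """BED6 export of the outer footprint span of each hit.

    Name encodes arrangement:total-mismatches:spacer; score is
    1000 - 100 * total mismatches, clamped at 0.
    """
    with open(path, "w") as fh:
        for h in hits:
            score = max(0, 1000 - 100 * h.total_mismatches)
            name = f"{h.arrangement}:{h.total_mismatches}:{h.spacer_len}"
            fh.write(
                f"{h.seq_id}\t{h.span.start}\t{h.span.end}\t{name}\t{score}\t+\n"
            )
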