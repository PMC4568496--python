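"""Candidate TALEN-pair enumeration in a target region.

A TALEN pair consists of a left arm binding the plus strand and a right arm
binding the minus strand, each recognizing an effector binding element (EBE)
that must begin with a thymine (the "T0" requirement of natural TALE binding
sites). FokI halves fused to the two arms dimerize and cut in the spacer
between the footprints, so candidate pairs are geometric: a plus-strand
window starting with T, a downstream minus-strand window whose 5' base on
the minus strand is T (a plus-strand A at its 3' genomic edge), and a spacer
of permitted length between them.

Default windows (EBE 15-20 nt including T0, spacer 14-18 bp) sit inside the
activity-permissive spacer range of the obligate-heterodimer FokI scaffold
and reflect common Golden-Gate design practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .seqio import GenomicInterval, NucleotideSequence, reverse_complement

__all__ = ["DesignParams", "TalenPair", "enumerate_pairs"]


@dataclass(frozen=True)
class DesignParams:
    """Length windows for candidate enumeration (all lengths in bases)."""

    ebe_len_min: int = 15
    ebe_len_max: int = 20
    spacer_min: int = 14
    spacer_max: int = 18

    def __post_init__(self) -> None:
        if not (10 <= self.ebe_len_min <= self.ebe_len_max <= 30):
            raise ValueError("require 10 <= ebe_len_min <= ebe_len_max <= 30")
        if not (1 <= self.spacer_min <= self.spacer_max):
            raise ValueError("require 1 <= spacer_min <= spacer_max")


@dataclass(frozen=True)
class TalenPair:
    """A TALEN pair: two EBE sequences (5'->3' on their binding strands).

    ``left_ebe`` reads along the plus strand; ``right_ebe`` reads along the
    minus strand. Both must start with the obligatory T at position 0, which
    is required exact everywhere and never counted in mismatch budgets.
    """

    name: str
    left_ebe: str
    right_ebe: str
    designed_spacer: int
    origin: Optional[GenomicInterval] = None

    def __post_init__(self) -> None:
        for label, ebe in (("left", self.left_ebe), ("right", self.right_ebe)):
            if len(ebe) < 2:
                raise ValueError(f"{label} EBE too short")
            if set(ebe) - set("ACGT"):
                raise ValueError(f"{label} EBE must be over A/C/G/T")
            if ebe[0] != "T":
                raise ValueError(f"{label} EBE position-0 T is mandatory")
        if self.designed_spacer < 1:
            raise ValueError("designed_spacer must be >= 1")


def enumerate_pairs(
    region: NucleotideSequence, params: DesignParams = DesignParams()
) -> list[TalenPair]:
    """Enumerate every candidate TALEN pair in ``region``.

    Returns pairs sorted by ascending left-arm start, ties broken by shorter
    spacer, then shorter combined arm length. A region too short to host any
    geometry yields an empty list. Windows containing ``N`` are skipped
    (an EBE is a concrete A/C/G/T sequence).
    """
    seq = region.residues
    n = len(seq)
    out: list[tuple[tuple, TalenPair]] = []
    counter = 0
    for s in range(n):
        if seq[s] != "T":
            continue
        for len_l in range(params.ebe_len_min, params.ebe_len_max + 1):
            left_end = s + len_l
            if left_end > n:
                break
            left_ebe = seq[s:left_end]
            if "N" in left_ebe:
                continue
            for spacer in range(params.spacer_min, params.spacer_max + 1):
                t = left_end + spacer
                for len_r in range(params.ebe_len_min, params.ebe_len_max + 1):
                    right_end = t + len_r
                    if right_end > n:
                        break
                    # minus-strand EBE starts with T iff the plus strand has
                    # an A at the footprint's 3' genomic edge
                    if seq[right_end - 1] != "A":
                        continue
                    window = seq[t:right_end]
                    if "N" in window:
                        continue
                    counter += 1
                    pair = TalenPair(
                        name=f"pair{counter:05d}",
                        left_ebe=left_ebe,
                        right_ebe=reverse_complement(window),
                        designed_spacer=spacer,
                        origin=GenomicInterval(region.id, s, right_end, "+"),
                    )
                    key = (s, spacer, len_l + len_r, len_l, t)
                    out.append((key, pair))
    out.sort(key=lambda item: item[0])
    # renumber in final order so names are deterministic and ordered
    pairs = []
    for i, (_, pair) in enumerate(out, start=1):
        pairs.append(
            TalenPair(
                name=f"pair{i:05d}",
                left_ebe=pair.left_ebe,
                right_ebe=pair.right_ebe,
                designed_spacer=pair.designed_spacer,
                origin=pair.origin,
            )
        )
    return pairs
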