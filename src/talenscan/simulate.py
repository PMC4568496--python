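"""Deterministic synthetic-data generator with planted ground truth.

Produces the test bed for every analysis module: random genomes with planted
paired off-target sites (exact arrangement, spacer and per-arm mismatch
counts), clone sets with planted indels, and upstream sequences with planted
motif instances. All generators are pure functions of their arguments and
seed, and every planted truth record is verifiable by direct inspection of
the emitted sequence.

Planting performs post-write verification. The full fixture suite
additionally verifies that a permissive genome-wide scan recovers exactly
the planted sites and nothing else; if the random background happens to
contain an accidental sub-threshold match, the background is regenerated
from the next derived seed (bounded retries). This keeps truth manifests
exact without probabilistic caveats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .design import TalenPair
from .genotype import left_align_deletion, left_align_insertion
from .motifs import MotifSpec, scan_motif
from .offtarget import OffTargetCriteria, scan_offtargets
from .seqio import (
    GenomicInterval,
    NucleotideSequence,
    reverse_complement,
    write_fasta,
    IUPAC_SETS,
)

__all__ = [
    "PlantedTruth",
    "make_genome",
    "plant_offtarget",
    "plant_indel_clones",
    "plant_motifs",
    "make_fixture_suite",
    "FixtureSuite",
]

_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class PlantedTruth:
    """One planted feature: its kind, locus and kind-specific parameters."""

    kind: str  # offtarget_site | indel_clone | motif_site
    locus: GenomicInterval
    parameters: dict


def make_genome(
    length: int, gc: float, seed: int, seq_id: str = "sim"
) -> NucleotideSequence:
    """An i.i.d. random genome with the given GC fraction, fixed by seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not (0.0 <= gc <= 1.0):
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    residues = "".join(rng.choice(_BASES, size=length, p=probs))
    return NucleotideSequence(id=seq_id, residues=residues)


def _mutate_ebe(rng: np.random.Generator, ebe: str, n_mm: int) -> str:
    """Introduce exactly n_mm substitutions at positions 1..L-1 (never T0)."""
    L = len(ebe)
    if n_mm > L - 1:
        raise ValueError(f"cannot place {n_mm} mismatches in an EBE of length {L}")
    positions = rng.choice(np.arange(1, L), size=n_mm, replace=False)
    out = list(ebe)
    for p in sorted(int(p) for p in positions):
        alternatives = [b for b in "ACGT" if b != out[p]]
        out[p] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(out)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def plant_offtarget(
    genome: NucleotideSequence,
    pair: TalenPair,
    spacer_len: int,
    mm_left: int,
    mm_right: int,
    arrangement: str,
    position: int,
    seed: int,
    existing: Sequence[PlantedTruth] = (),
) -> tuple[NucleotideSequence, PlantedTruth]:
    """Overwrite a genomic region with a paired site of exact geometry.

    The upstream arm is written on the plus strand, the downstream arm as
    the reverse complement of its (mutated) EBE. ``mm_left``/``mm_right``
    are the mismatch counts of the left/right EBE wherever each serves in
    ``arrangement``. Mismatch positions are seed-chosen, never position 0.
    After writing, mismatches are recounted and overlap with ``existing``
    planted loci is rejected.
    """
    if arrangement not in ("LR", "RL", "LL", "RR"):
        raise ValueError(f"unknown arrangement {arrangement!r}")
    if spacer_len < 1:
        raise ValueError("spacer_len must be >= 1")
    ebes = {"L": pair.left_ebe, "R": pair.right_ebe}
    mms = {"L": mm_left, "R": mm_right}
    up_key, down_key = arrangement[0], arrangement[1]
    up_ebe, down_ebe = ebes[up_key], ebes[down_key]
    mm_up, mm_down = mms[up_key], mms[down_key]

    rng = np.random.default_rng(seed)
    up_seq = _mutate_ebe(rng, up_ebe, mm_up)
    down_seq_minus = _mutate_ebe(rng, down_ebe, mm_down)
    down_seq_plus = reverse_complement(down_seq_minus)

    footprint = len(up_seq) + spacer_len + len(down_seq_plus)
    if not (0 <= position and position + footprint <= len(genome)):
        raise ValueError("planted site does not fit within the genome")
    locus = GenomicInterval(genome.id, position, position + footprint, "+")
    for truth in existing:
        if truth.kind == "offtarget_site" and truth.locus.overlaps(locus):
            raise ValueError(
                f"planted site at {position} overlaps an existing plant at "
                f"[{truth.locus.start}, {truth.locus.end})"
            )

    residues = genome.residues
    down_start = position + len(up_seq) + spacer_len
    new_residues = (
        residues[:position]
        + up_seq
        + residues[position + len(up_seq) : down_start]
        + down_seq_plus
        + residues[down_start + len(down_seq_plus) :]
    )
    planted = NucleotideSequence(id=genome.id, residues=new_residues)

    # post-write verification: recount mismatches on the written windows
    got_up = _hamming(planted.residues[position : position + len(up_seq)], up_ebe)
    got_down = _hamming(
        reverse_complement(
            planted.residues[down_start : down_start + len(down_seq_plus)]
        ),
        down_ebe,
    )
    if got_up != mm_up or got_down != mm_down or up_seq[0] != "T" or down_seq_minus[0] != "T":
        raise RuntimeError(
            f"post-write verification failed at {position}: "
            f"got ({got_up}, {got_down}) mismatches, requested ({mm_up}, {mm_down})"
        )

    truth = PlantedTruth(
        kind="offtarget_site",
        locus=locus,
        parameters={
            "arrangement": arrangement,
            "spacer_len": spacer_len,
            "mm_left": mm_left,
            "mm_right": mm_right,
            "mm_up": mm_up,
            "mm_down": mm_down,
            "total_mm": mm_up + mm_down,
            "up_start": position,
            "up_end": position + len(up_seq),
            "down_start": down_start,
            "down_end": down_start + len(down_seq_plus),
        },
    )
    return planted, truth


def plant_indel_clones(
    reference: NucleotideSequence,
    specs: Sequence[tuple[str, int, int]],
    seed: int,
    avoid: Sequence[str] = (),
) -> tuple[list[NucleotideSequence], list[PlantedTruth]]:
    """One mutant clone per (kind, size, position) spec.

    Deletions remove reference[position:position+size]; insertions place
    seed-derived random bases before reference[position]. Truth records
    carry both the requested and the left-aligned canonical position (the
    one an aligner normalizing gaps 5'-ward will report). Insertion content
    containing any ``avoid`` pattern is resampled (<=100 retries).
    """
    rng = np.random.default_rng(seed)
    ref = reference.residues
    clones: list[NucleotideSequence] = []
    truths: list[PlantedTruth] = []
    for i, (kind, size, position) in enumerate(specs, start=1):
        if kind == "deletion":
            if not (0 <= position and position + size <= len(ref)):
                raise ValueError(f"deletion spec {i} out of reference bounds")
            clone_seq = ref[:position] + ref[position + size :]
            canonical = left_align_deletion(ref, position, size)
            params = {
                "kind": kind,
                "size": size,
                "position": position,
                "canonical_position": canonical,
                "allele_name": f"Δ{size}",
                "frameshift": size % 3 != 0,
            }
            locus = GenomicInterval(reference.id, canonical, canonical + size)
        elif kind == "insertion":
            if not (0 <= position <= len(ref)):
                raise ValueError(f"insertion spec {i} out of reference bounds")
            pad = max((len(p) for p in avoid), default=1) - 1
            for _ in range(100):
                inserted = "".join(rng.choice(_BASES, size=size))
                # only occurrences newly created by the insertion are rejected
                window = (
                    ref[max(0, position - pad) : position]
                    + inserted
                    + ref[position : position + pad]
                )
                if not any(pat in window for pat in avoid):
                    break
            else:
                raise RuntimeError(
                    f"could not sample insertion content avoiding {list(avoid)}"
                )
            clone_seq = ref[:position] + inserted + ref[position:]
            canonical, canonical_ins = left_align_insertion(ref, position, inserted)
            params = {
                "kind": kind,
                "size": size,
                "position": position,
                "canonical_position": canonical,
                "inserted": canonical_ins,
                "allele_name": f"+{size}",
                "frameshift": size % 3 != 0,
            }
            locus = GenomicInterval(reference.id, canonical, canonical + 1)
        else:
            raise ValueError(f"unknown indel kind {kind!r}")
        clones.append(NucleotideSequence(id=f"clone{i:03d}_{kind}{size}", residues=clone_seq))
        truths.append(PlantedTruth(kind="indel_clone", locus=locus, parameters=params))
    return clones, truths


def _concrete_instance(rng: np.random.Generator, pattern: str) -> str:
    out = []
    for code in pattern:
        options = sorted(IUPAC_SETS[code])
        out.append(options[int(rng.integers(len(options)))])
    return "".join(out)


def plant_motifs(
    length: int,
    positions: Sequence[int],
    motif: MotifSpec,
    seed: int,
    seq_id: str = "upstream",
    gc: float = 0.5,
    max_retries: int = 200,
) -> tuple[NucleotideSequence, list[PlantedTruth]]:
    """A sequence containing motif instances exactly at ``positions``.

    The random background is regenerated (derived seeds, bounded retries)
    until scanning recovers exactly the planted count, so the emitted truth
    is exact rather than probabilistic.
    """
    m = len(motif.pattern)
    positions = sorted(positions)
    for a, b in zip(positions, positions[1:]):
        if b < a + m:
            raise ValueError("planted motif positions overlap")
    if positions and positions[-1] + m > length:
        raise ValueError("planted motif does not fit")
    base_rng = np.random.default_rng(seed)
    for attempt in range(max_retries):
        sub_seed = int(base_rng.integers(2**31))
        background = make_genome(length, gc, sub_seed, seq_id=seq_id)
        rng = np.random.default_rng(sub_seed + 1)
        residues = list(background.residues)
        for p in positions:
            inst = _concrete_instance(rng, motif.pattern)
            residues[p : p + m] = inst
        candidate = NucleotideSequence(id=seq_id, residues="".join(residues))
        report = scan_motif(candidate, motif)
        plus_hits = [pos for pos, strand in report.hits if strand == "+"]
        if report.count == len(positions) and plus_hits == positions:
            truths = [
                PlantedTruth(
                    kind="motif_site",
                    locus=GenomicInterval(seq_id, p, p + m, "+"),
                    parameters={"pattern": motif.pattern, "position": p},
                )
                for p in positions
            ]
            return candidate, truths
    raise RuntimeError(
        f"could not build a motif-clean background in {max_retries} attempts"
    )


# ---------------------------------------------------------------------------
# fixture suite


@dataclass
class FixtureSuite:
    """In-memory handle on a generated fixture bundle."""

    genome: NucleotideSequence
    pair: TalenPair
    offtarget_truths: list[PlantedTruth]
    reference: NucleotideSequence
    spacer_interval: GenomicInterval
    clones: list[NucleotideSequence]
    indel_truths: list[PlantedTruth]
    upstreams: list[NucleotideSequence]
    motif: MotifSpec
    motif_truths: dict[str, list[PlantedTruth]]
    out_dir: Optional[Path] = None


# spacer/mismatch combinations spanning the filter boundaries: spacers at
# 9/10/24/25 (activity edges) and 99/100 (pairing limit), totals at 0/1/10/11
# (mismatch-band edges) and 7 (the credible-candidate profile)
BOUNDARY_SITES: tuple[tuple[int, int, int], ...] = (
    (9, 1, 1),    # total 2: accepted, low_activity
    (10, 1, 0),   # total 1: accepted, likely_active (both boundaries)
    (12, 3, 4),   # total 7: accepted, likely_active
    (24, 5, 5),   # total 10: accepted, likely_active (both boundaries)
    (25, 2, 1),   # total 3: accepted, low_activity
    (99, 2, 3),   # total 5: accepted, low_activity (spacer boundary)
    (100, 2, 2),  # total 4: rejected, spacer >= 100
    (12, 0, 0),   # total 0: rejected, perfect pair excluded
    (12, 5, 6),   # total 11: rejected, above mismatch band
)

INDEL_SPECS: tuple[tuple[str, int, int], ...] = (
    ("deletion", 11, 195),   # the canonical frameshift deletion allele
    ("insertion", 16, 198),  # the canonical frameshift insertion allele
    ("deletion", 3, 192),    # in-frame
    ("insertion", 2, 200),
    ("deletion", 1, 197),
)

MOTIF_PLANT_COUNTS: tuple[int, ...] = (0, 1, 2, 3, 4, 6)


def _random_ebe(rng: np.random.Generator, length: int) -> str:
    return "T" + "".join(rng.choice(_BASES, size=length - 1))


def _truth_key(t: PlantedTruth) -> tuple:
    p = t.parameters
    return (
        p["up_start"], p["up_end"], p["down_start"], p["down_end"],
        p["arrangement"], p["spacer_len"], p["mm_up"], p["mm_down"],
    )


def _hit_key(h) -> tuple:
    return (
        h.upstream_arm.interval.start, h.upstream_arm.interval.end,
        h.downstream_arm.interval.start, h.downstream_arm.interval.end,
        h.arrangement, h.spacer_len,
        h.upstream_arm.mismatches, h.downstream_arm.mismatches,
    )


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _scrub_background(
    genome: NucleotideSequence,
    pair: TalenPair,
    truths: Sequence[PlantedTruth],
    criteria: OffTargetCriteria,
    max_iterations: int = 40,
) -> Optional[NucleotideSequence]:
    """Remove accidental background matches until the scan under ``criteria``
    returns exactly the planted sites that satisfy those criteria.

    Any hit not matching a planted truth has at least one arm that is not a
    planted window. Its position-0 base is flipped to C (disqualifying the
    window outright) when that base is outside every planted window;
    otherwise every unprotected position of the window is set to a base that
    is guaranteed to mismatch the arm's EBE there, chosen from {C, G} so no
    new T0 can appear. Bases inside planted arm windows are never touched.
    Returns None if an accidental arm cannot be destroyed without touching a
    planted window (the caller then tries the next background).
    """
    ebes = {"L": pair.left_ebe, "R": pair.right_ebe}
    planted_arm_windows = set()
    for t in truths:
        p = t.parameters
        planted_arm_windows.add((p["up_start"], p["up_end"], "+"))
        planted_arm_windows.add((p["down_start"], p["down_end"], "-"))
    protected = sorted((start, end) for start, end, _ in planted_arm_windows)

    def is_protected(pos: int) -> bool:
        return any(s <= pos < e for s, e in protected)

    expected = {
        _truth_key(t)
        for t in truths
        if criteria.min_total_mismatch
        <= t.parameters["total_mm"]
        <= criteria.max_total_mismatch
        and criteria.min_spacer <= t.parameters["spacer_len"] <= criteria.max_spacer
        and t.parameters["arrangement"] in criteria.arrangements
    }

    current = genome
    exhausted: set[tuple[int, int, str]] = set()  # fully flipped, still matching
    for _ in range(max_iterations):
        hits = scan_offtargets([current], pair, criteria)
        found = {_hit_key(h) for h in hits}
        if found == expected:
            return current
        if not (expected <= found):
            return None  # a planted site was damaged: unusable background
        residues = list(current.residues)
        changed = False
        for h in hits:
            if _hit_key(h) in expected:
                continue
            hit_handled = False
            for arm in (h.upstream_arm, h.downstream_arm):
                iv = arm.interval
                win = (iv.start, iv.end, iv.strand)
                if win in planted_arm_windows or win in exhausted:
                    continue
                ebe = ebes[arm.arm]
                t0_pos = iv.start if iv.strand == "+" else iv.end - 1
                if not is_protected(t0_pos):
                    residues[t0_pos] = "C"
                    changed = hit_handled = True
                    break
                # T0 is inside a planted window: force a mismatch at every
                # unprotected position of this accidental window instead
                flipped_any = False
                for pos in range(iv.start, iv.end):
                    if is_protected(pos):
                        continue
                    if iv.strand == "+":
                        want_mismatch_of = ebe[pos - iv.start]
                    else:
                        want_mismatch_of = _COMP[ebe[iv.end - 1 - pos]]
                    new_base = "G" if want_mismatch_of in ("C", "A") else "C"
                    if residues[pos] != new_base:
                        residues[pos] = new_base
                        flipped_any = True
                if flipped_any:
                    changed = hit_handled = True
                else:
                    exhausted.add(win)
                break
            if not hit_handled and not any(
                (a.interval.start, a.interval.end, a.interval.strand)
                not in planted_arm_windows | exhausted
                for a in (h.upstream_arm, h.downstream_arm)
            ):
                return None  # neither arm can be destroyed
        if not changed:
            return None
        current = NucleotideSequence(id=current.id, residues="".join(residues))
    return None


def make_fixture_suite(seed: int, out_dir: str | Path | None = None) -> FixtureSuite:
    """Build the self-contained test bundle (optionally written to disk).

    Contents: an ~11.5 kb genome with nine planted paired sites spanning the
    criteria boundaries (spacers 9/10/12/24/25/99/100, totals 0/1/7/10/11), a
    400 bp reference plus five indel clones (including the Δ11 and +16
    allele classes), and six upstream sequences with 0-6 planted motif
    instances. Byte-identical output for a fixed seed. The genome background
    is verified clean: a permissive scan recovers exactly the planted sites.
    """
    master = np.random.default_rng(seed)
    ebe_seed = int(master.integers(2**31))
    genome_seed = int(master.integers(2**31))
    plant_seed = int(master.integers(2**31))
    ref_seed = int(master.integers(2**31))
    indel_seed = int(master.integers(2**31))
    motif_seed = int(master.integers(2**31))

    genome_len = 11500
    default_criteria = OffTargetCriteria()
    genome = None
    pair = None
    truths: list[PlantedTruth] = []
    # A fresh EBE pair is drawn alongside each background: whether a planted
    # arm casts "ghost" matches at shifted offsets is a property of the EBE's
    # autocorrelation, so retrying the background alone cannot escape it.
    for attempt in range(40):
        ebe_rng = np.random.default_rng(ebe_seed + attempt)
        candidate_pair = TalenPair(
            name="sim_pair",
            left_ebe=_random_ebe(ebe_rng, 18),
            right_ebe=_random_ebe(ebe_rng, 18),
            designed_spacer=16,
        )
        background = make_genome(
            genome_len, 0.40, genome_seed + attempt, seq_id="sim_genome"
        )
        plant_rng = np.random.default_rng(plant_seed)
        g = background
        truths = []
        for i, (spacer, mm_l, mm_r) in enumerate(BOUNDARY_SITES):
            g, truth = plant_offtarget(
                g, candidate_pair, spacer, mm_l, mm_r, "LR",
                position=500 + i * 1200,
                seed=int(plant_rng.integers(2**31)),
                existing=truths,
            )
            truths.append(truth)
        cleaned = _scrub_background(g, candidate_pair, truths, default_criteria)
        if cleaned is not None:
            genome = cleaned
            pair = candidate_pair
            break
    if genome is None:
        raise RuntimeError("could not build a clean fixture genome in 40 attempts")

    reference = make_genome(400, 0.45, ref_seed, seq_id="ref_amplicon")
    spacer_interval = GenomicInterval("ref_amplicon", 190, 206)
    clones, indel_truths = plant_indel_clones(reference, INDEL_SPECS, indel_seed)

    motif = MotifSpec(name="SRY", pattern="WAACAAW")
    motif_rng = np.random.default_rng(motif_seed)
    upstreams: list[NucleotideSequence] = []
    motif_truths: dict[str, list[PlantedTruth]] = {}
    for i, count in enumerate(MOTIF_PLANT_COUNTS, start=1):
        positions = [40 + j * 60 for j in range(count)]
        seq_id = f"upstream{i:02d}"
        seq, m_truths = plant_motifs(
            length=400,
            positions=positions,
            motif=motif,
            seed=int(motif_rng.integers(2**31)),
            seq_id=seq_id,
        )
        upstreams.append(seq)
        motif_truths[seq_id] = m_truths

    suite = FixtureSuite(
        genome=genome,
        pair=pair,
        offtarget_truths=truths,
        reference=reference,
        spacer_interval=spacer_interval,
        clones=clones,
        indel_truths=indel_truths,
        upstreams=upstreams,
        motif=motif,
        motif_truths=motif_truths,
    )
    if out_dir is not None:
        _write_suite(suite, Path(out_dir), seed)
        suite.out_dir = Path(out_dir)
    return suite


def _write_suite(suite: FixtureSuite, out_dir: Path, seed: int) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_fasta([suite.genome], out_dir / "genome.fa")
    write_fasta([suite.reference], out_dir / "reference.fa")
    write_fasta(suite.clones, out_dir / "clones.fa")
    write_fasta(suite.upstreams, out_dir / "upstreams.fa")

    with open(out_dir / "pair.tsv", "w") as fh:
        fh.write("name\tleft_ebe\tright_ebe\tdesigned_spacer\n")
        fh.write(
            f"{suite.pair.name}\t{suite.pair.left_ebe}\t{suite.pair.right_ebe}"
            f"\t{suite.pair.designed_spacer}\n"
        )

    with open(out_dir / "offtarget_truth.tsv", "w") as fh:
        fh.write(
            "seq_id\tup_start\tup_end\tdown_start\tdown_end\tarrangement"
            "\tspacer_len\tmm_up\tmm_down\ttotal_mm\n"
        )
        for t in suite.offtarget_truths:
            p = t.parameters
            fh.write(
                f"{t.locus.seq_id}\t{p['up_start']}\t{p['up_end']}"
                f"\t{p['down_start']}\t{p['down_end']}\t{p['arrangement']}"
                f"\t{p['spacer_len']}\t{p['mm_up']}\t{p['mm_down']}\t{p['total_mm']}\n"
            )

    with open(out_dir / "indel_truth.tsv", "w") as fh:
        fh.write("clone_id\tkind\tsize\tcanonical_position\tallele_name\tframeshift\n")
        for clone, t in zip(suite.clones, suite.indel_truths):
            p = t.parameters
            fh.write(
                f"{clone.id}\t{p['kind']}\t{p['size']}\t{p['canonical_position']}"
                f"\t{p['allele_name']}\t{p['frameshift']}\n"
            )

    with open(out_dir / "motif_truth.tsv", "w") as fh:
        fh.write("seq_id\tpattern\tpositions\tcount\n")
        for seq in suite.upstreams:
            truths = suite.motif_truths[seq.id]
            pos = ",".join(str(t.parameters["position"]) for t in truths)
            fh.write(f"{seq.id}\t{suite.motif.pattern}\t{pos}\t{len(truths)}\n")

    with open(out_dir / "manifest.tsv", "w") as fh:
        fh.write("key\tvalue\n")
        fh.write(f"seed\t{seed}\n")
        fh.write(f"genome\tgenome.fa\n")
        fh.write(f"pair\tpair.tsv\n")
        fh.write(f"offtarget_truth\tofftarget_truth.tsv\n")
        fh.write(f"reference\treference.fa\n")
        fh.write(f"clones\tclones.fa\n")
        fh.write(f"indel_truth\tindel_truth.tsv\n")
        fh.write(f"spacer_interval\t{suite.spacer_interval.start}-{suite.spacer_interval.end}\n")
        fh.write(f"upstreams\tupstreams.fa\n")
        fh.write(f"motif_truth\tmotif_truth.tsv\n")
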