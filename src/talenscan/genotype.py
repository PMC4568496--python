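"""Screening-side computations: diagnostic bridge PCR, indel calling,
frameshift/truncation prediction and mutation-rate statistics.

The diagnostic assay uses two amplicons from three primers: an outer forward
primer and a reverse primer bridge both effector binding elements, while an
inner forward primer anneals across the spacer (where nuclease-induced
indels land). An intact allele yields both products; a disrupted allele
yields the outer product but not the inner one, because the indel destroys
the inner primer's annealing site.

Alleles are named by the field convention Δn (n-base deletion) / +n (n-base
insertion); an indel whose size is not a multiple of 3 shifts the reading
frame and typically truncates the protein at the first stop codon reached
in the shifted frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from Bio import Align
from Bio.Seq import Seq
from statsmodels.stats.proportion import proportion_confint

from .seqio import GenomicInterval, NucleotideSequence, reverse_complement

__all__ = [
    "PrimerSet",
    "DiagnosticCall",
    "IndelCall",
    "TruncationPrediction",
    "RateEstimate",
    "AlignmentError",
    "in_silico_pcr",
    "diagnose_disruption",
    "call_indel",
    "predict_truncation",
    "mutation_rate",
    "write_vcf",
]

DISRUPTED = "disrupted"
INTACT = "intact"
INDETERMINATE = "indeterminate"


class AlignmentError(ValueError):
    """Raised when a clone cannot be aligned to its reference."""


@dataclass(frozen=True)
class PrimerSet:
    """The three diagnostic primers.

    ``outer_fwd`` anneals upstream of the first EBE, ``inner_fwd`` across the
    spacer, and ``rev`` downstream of the second EBE (given 5'->3' as
    ordered, i.e. its reverse complement appears on the template plus
    strand).
    """

    outer_fwd: str
    inner_fwd: str
    rev: str

    def __post_init__(self) -> None:
        for label, primer in (
            ("outer_fwd", self.outer_fwd),
            ("inner_fwd", self.inner_fwd),
            ("rev", self.rev),
        ):
            if len(primer) < 12:
                raise ValueError(f"primer {label} shorter than 12 bases")
            if set(primer.upper()) - set("ACGT"):
                raise ValueError(f"primer {label} must be over A/C/G/T")


@dataclass(frozen=True)
class DiagnosticCall:
    verdict: str
    outer_len: Optional[int]
    inner_len: Optional[int]


@dataclass(frozen=True)
class IndelCall:
    """A simple indel (or 'complex'/'none') called against a reference.

    ``position`` is the left-aligned 0-based reference offset of the event
    (deletion: first deleted base; insertion: the reference offset before
    which the bases are inserted). ``frameshift`` is size mod 3 != 0 for
    simple indels.
    """

    kind: str  # deletion | insertion | complex | none
    size: int
    position: int
    allele_name: str
    in_spacer: bool
    frameshift: bool
    inserted: Optional[str] = None  # inserted bases (left-aligned), insertions only


@dataclass(frozen=True)
class TruncationPrediction:
    wt_protein_len: int
    mutant_protein_len: int
    premature_stop: bool
    altered_from: int


@dataclass(frozen=True)
class RateEstimate:
    """A mutant proportion k/n with its 95% Wilson score interval."""

    k: int
    n: int
    proportion: float
    ci_low: float
    ci_high: float


def in_silico_pcr(
    template: NucleotideSequence, fwd: str, rev: str, max_len: int = 5000
) -> Optional[int]:
    """Length of the shortest exact-match PCR product, or None if absent.

    The forward primer must match the plus strand exactly; the reverse primer
    must match the minus strand exactly, strictly downstream of the forward
    site (no overlap). Products longer than ``max_len`` are not reported.
    Absence is a value, not an error.
    """
    fwd = fwd.upper()
    rev = rev.upper()
    seq = template.residues
    rev_site = reverse_complement(rev)

    fwd_starts = _find_all(seq, fwd)
    rev_starts = _find_all(seq, rev_site)
    if not fwd_starts or not rev_starts:
        return None
    best: Optional[int] = None
    for f in fwd_starts:
        for r in rev_starts:
            if r < f + len(fwd):
                continue
            product = r + len(rev) - f
            if product <= max_len and (best is None or product < best):
                best = product
    return best


def _find_all(haystack: str, needle: str) -> list[int]:
    starts = []
    i = haystack.find(needle)
    while i != -1:
        starts.append(i)
        i = haystack.find(needle, i + 1)
    return starts


def diagnose_disruption(
    template: NucleotideSequence, primers: PrimerSet, max_len: int = 5000
) -> DiagnosticCall:
    """Apply the two-amplicon truth table to a template.

    disrupted = outer product present, inner absent; intact = both present;
    anything else is indeterminate (e.g. a rearrangement removing the outer
    sites as well).
    """
    outer = in_silico_pcr(template, primers.outer_fwd, primers.rev, max_len)
    inner = in_silico_pcr(template, primers.inner_fwd, primers.rev, max_len)
    if outer is not None and inner is None:
        verdict = DISRUPTED
    elif outer is not None and inner is not None:
        verdict = INTACT
    else:
        verdict = INDETERMINATE
    return DiagnosticCall(verdict=verdict, outer_len=outer, inner_len=inner)


# alignment scoring chosen to prefer one contiguous gap, since nuclease
# repair outcomes are predominantly single indels
_ALIGNER = Align.PairwiseAligner()
_ALIGNER.mode = "global"
_ALIGNER.match_score = 2
_ALIGNER.mismatch_score = -3
_ALIGNER.open_gap_score = -8
_ALIGNER.extend_gap_score = -1


def left_align_deletion(reference: str, position: int, size: int) -> int:
    """Shift a deletion of reference[position:position+size] maximally 5'-ward."""
    p = position
    while p > 0 and reference[p - 1] == reference[p + size - 1]:
        p -= 1
    return p


def left_align_insertion(reference: str, position: int, inserted: str) -> tuple[int, str]:
    """Shift an insertion (before reference[position]) maximally 5'-ward."""
    p = position
    s = inserted
    while p > 0 and reference[p - 1] == s[-1]:
        s = reference[p - 1] + s[:-1]
        p -= 1
    return p, s


def call_indel(
    reference: NucleotideSequence,
    clone: NucleotideSequence,
    spacer_interval: GenomicInterval,
) -> IndelCall:
    """Call a deletion/insertion from a clone sequence aligned to a reference.

    Global alignment with single-gap-preferring scoring; one contiguous gap
    run yields a simple deletion (gap in clone) or insertion (gap in
    reference) whose position is left-aligned per variant-normalization
    convention. Multiple gap runs, or three or more substitutions clustered
    within 10 bases, yield kind ``complex`` (no allele name is guessed).
    ``in_spacer`` is True iff the event overlaps ``spacer_interval``
    (an insertion point on either boundary counts as overlapping).
    """
    ref = reference.residues
    alt = clone.residues
    if ref == alt:
        return IndelCall("none", 0, 0, "wt", False, False)

    alignment = _ALIGNER.align(ref, alt)[0]
    ref_blocks, alt_blocks = alignment.aligned

    # identity over aligned (non-gap) columns
    matched = 0
    aligned_cols = 0
    sub_positions: list[int] = []
    for (rs, re), (as_, ae) in zip(ref_blocks, alt_blocks):
        aligned_cols += re - rs
        for k in range(re - rs):
            if ref[rs + k] == alt[as_ + k]:
                matched += 1
            else:
                sub_positions.append(int(rs + k))
    # identity over all alignment columns, gap columns included
    total_cols = len(ref) + len(alt) - aligned_cols
    if aligned_cols == 0 or matched / total_cols < 0.5:
        raise AlignmentError(
            f"clone {clone.id!r} shares <50% identity with reference {reference.id!r}"
        )

    # gap runs between consecutive aligned blocks (plus unaligned ends)
    deletions: list[tuple[int, int]] = []   # (ref position, size)
    insertions: list[tuple[int, str]] = []  # (ref position, inserted bases)

    def note_gap(ref_lo, ref_hi, alt_lo, alt_hi):
        ref_lo, ref_hi, alt_lo, alt_hi = map(int, (ref_lo, ref_hi, alt_lo, alt_hi))
        if ref_hi > ref_lo:
            deletions.append((ref_lo, ref_hi - ref_lo))
        if alt_hi > alt_lo:
            insertions.append((ref_lo, alt[alt_lo:alt_hi]))

    note_gap(0, ref_blocks[0][0], 0, alt_blocks[0][0])
    for i in range(len(ref_blocks) - 1):
        note_gap(
            ref_blocks[i][1], ref_blocks[i + 1][0],
            alt_blocks[i][1], alt_blocks[i + 1][0],
        )
    note_gap(ref_blocks[-1][1], len(ref), alt_blocks[-1][1], len(alt))

    n_gap_runs = len(deletions) + len(insertions)
    clustered_subs = _has_cluster(sub_positions, window=10, k=3)

    if n_gap_runs == 0 or n_gap_runs > 1 or clustered_subs:
        # substitutions only, multiple gap runs, or a substitution cluster:
        # not a simple Δn/+n allele, so no allele name is guessed
        event_points = (
            [p for p, _ in deletions] + [p for p, _ in insertions] + sub_positions
        )
        first = min(event_points)
        in_spacer = _any_in_spacer(event_points, spacer_interval)
        return IndelCall("complex", 0, first, "complex", in_spacer, False)

    if deletions:
        pos, size = deletions[0]
        pos = left_align_deletion(ref, pos, size)
        in_spacer = _event_in_spacer(pos, pos + size, spacer_interval)
        return IndelCall(
            "deletion", size, pos, f"Δ{size}", in_spacer, size % 3 != 0
        )
    pos, inserted = insertions[0]
    pos, inserted = left_align_insertion(ref, pos, inserted)
    size = len(inserted)
    in_spacer = (
        spacer_interval is not None
        and spacer_interval.start <= pos <= spacer_interval.end
    )
    return IndelCall(
        "insertion", size, pos, f"+{size}", in_spacer, size % 3 != 0, inserted=inserted
    )


def _has_cluster(positions: list[int], window: int, k: int) -> bool:
    if len(positions) < k:
        return False
    positions = sorted(positions)
    for i in range(len(positions) - k + 1):
        if positions[i + k - 1] - positions[i] < window:
            return True
    return False


def _event_in_spacer(start: int, end: int, spacer: GenomicInterval) -> bool:
    if spacer is None:
        return False
    return start < spacer.end and spacer.start < end


def _any_in_spacer(positions: list[int], spacer: GenomicInterval) -> bool:
    return any(_event_in_spacer(p, p + 1, spacer) for p in positions)


def predict_truncation(cds: NucleotideSequence, call: IndelCall) -> TruncationPrediction:
    """Predict the protein outcome of an indel applied to a coding sequence.

    The coding sequence must be a whole number of codons starting with ATG;
    ``call.position`` is interpreted in coding-sequence coordinates. Both
    wild-type and mutant sequences are translated with the standard genetic
    code up to the first stop codon. ``altered_from`` is the first codon
    index at which the mutant peptide diverges from (or falls short of) the
    wild type.
    """
    seq = cds.residues
    if len(seq) % 3 != 0:
        raise ValueError("coding sequence length must be divisible by 3")
    if not seq.startswith("ATG"):
        raise ValueError("coding sequence must begin with a start codon (ATG)")
    if call.kind in ("deletion", "insertion") and not (0 <= call.position <= len(seq)):
        raise ValueError("indel position outside the coding sequence")

    wt_protein = str(Seq(seq).translate(to_stop=True))

    if call.kind == "deletion":
        mut_seq = seq[: call.position] + seq[call.position + call.size :]
    elif call.kind == "insertion":
        filler = call.inserted if call.inserted else "A" * call.size
        mut_seq = seq[: call.position] + filler + seq[call.position :]
    else:
        mut_seq = seq

    # translate mutant up to first stop, over whole codons only
    mut_codons = mut_seq[: len(mut_seq) - (len(mut_seq) % 3)]
    mut_protein = str(Seq(mut_codons).translate(to_stop=True))
    stop_found = len(mut_protein) * 3 < len(mut_codons)

    diverge = 0
    limit = min(len(wt_protein), len(mut_protein))
    while diverge < limit and wt_protein[diverge] == mut_protein[diverge]:
        diverge += 1

    # a stop is premature only if it is not the wild type's own stop codon
    # reached in frame: map the mutant stop offset back to cds coordinates
    premature = False
    if stop_found and len(mut_protein) < len(wt_protein):
        stop_offset = 3 * len(mut_protein)
        if call.kind == "deletion" and stop_offset >= call.position:
            cds_equiv = stop_offset + call.size
        elif call.kind == "insertion" and stop_offset >= call.position + call.size:
            cds_equiv = stop_offset - call.size
        else:
            cds_equiv = stop_offset
        premature = cds_equiv != 3 * len(wt_protein)
    return TruncationPrediction(
        wt_protein_len=len(wt_protein),
        mutant_protein_len=len(mut_protein),
        premature_stop=premature,
        altered_from=diverge,
    )


def mutation_rate(k: int, n: int) -> RateEstimate:
    """Mutant proportion k/n with a 95% Wilson score confidence interval.

    Wilson rather than Wald because founder screens have small n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= k <= n):
        raise ValueError("require 0 <= k <= n")
    low, high = proportion_confint(k, n, alpha=0.05, method="wilson")
    p = k / n
    # guard against float noise at the boundaries (e.g. k = 0)
    low = min(max(float(low), 0.0), p)
    high = max(min(float(high), 1.0), p)
    return RateEstimate(k=k, n=n, proportion=p, ci_low=low, ci_high=high)


def write_vcf(
    reference: NucleotideSequence,
    calls: Sequence[tuple[str, IndelCall]],
    path,
) -> None:
    """Write simple indel calls as a minimal VCF 4.2 file.

    Alleles are anchored on the base before the event per VCF convention
    (positions here are already left-aligned). Complex and wild-type calls
    are skipped.
    """
    ref = reference.residues
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={reference.id},length={len(ref)}>\n")
        fh.write('##INFO=<ID=ALLELE,Number=1,Type=String,Description="Allele name">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for sample_id, call in calls:
            if call.kind == "deletion":
                p = call.position
                if p == 0:
                    # no preceding base: anchor on the following base
                    ref_allele = ref[p : p + call.size + 1]
                    alt_allele = ref[p + call.size]
                    pos1 = 1
                else:
                    ref_allele = ref[p - 1 : p + call.size]
                    alt_allele = ref[p - 1]
                    pos1 = p  # 1-based position of the anchor base
            elif call.kind == "insertion":
                p = call.position
                if p == 0:
                    continue  # insertion before the first base: unrepresentable simply
                inserted = call.inserted if call.inserted else "N" * call.size
                ref_allele = ref[p - 1]
                alt_allele = ref[p - 1] + inserted
                pos1 = p
            else:
                continue
            fh.write(
                f"{reference.id}\t{pos1}\t{sample_id}\t{ref_allele}\t{alt_allele}"
                f"\t.\tPASS\tALLELE={call.allele_name}\n"
            )
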