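# Methods

## Off-target model

A paired off-target site is defined purely combinatorially. For a TALEN pair
with left and right effector binding elements (EBEs, each written 5'→3' on
its binding strand and beginning with the obligatory T at position 0), a
candidate locus consists of:

* an upstream arm — a plus-strand window whose first base is T and whose
  Hamming distance to one EBE over positions 1..L−1 is within budget;
* a downstream arm — a minus-strand window satisfying the same rule for the
  other EBE (equivalently, a plus-strand window ending in A whose reverse
  complement matches);
* a spacer, `downstream.start − upstream.end`, between `min_spacer`
  (default 1) and `max_spacer` (default 99, i.e. strictly under 100 bp,
  the FokI dimerization limit).

The mismatch band applies to the **total** across both arms, default 1–10
inclusive. The phrase "mismatches in the pair of EBEs" is interpreted as
pair-level because the credible-candidate description in the source screen
is likewise a single pair-level count; a per-arm cap
(`max_arm_mismatch`) exists but is off by default. The lower bound of 1
excludes the designed on-target; an explicit exclusion-interval option is
also available. Position-0 T is a hard requirement, never part of the
budget.

Activity classification is a closed interval on spacer length: spacers in
[10, 24] bp are `likely_active`, anything shorter or longer `low_activity`
("less than 10" makes 9 low and 10 active; "more than 24" makes 25 low and
24 active).

Arrangements: `LR` (left EBE plus / right EBE minus) and the swapped `RL`
are scanned by default. Homodimeric `LL`/`RR` pairings are behind a flag and
off by default because obligate-heterodimer FokI variants (ELD/KKR) cut only
as an L+R pair.

Ranking is not part of the filter definition and was an open design choice;
hits are ordered by (total mismatches, |spacer − designed spacer|, genomic
position), reflecting the two credibility axes practitioners quote: fewer
mismatches and a near-design spacer. Ranking is deterministic for fixed
input.

Mismatch counting treats a genomic `N` as a mismatch to every EBE base, and
`N` can never satisfy the position-0 T (conservative on both counts).
Soft-masked (lowercase) genome residues are uppercased on read and not used
to exclude hits. The scan is implemented as vectorized shifted-array
comparisons (one pass per EBE position); its output is checked against an
exhaustive per-window oracle in the test suite.

## Coordinates

Internally all intervals are 0-based half-open. Every user-facing report is
1-based inclusive, the locus convention of the genome-editing literature;
`seqio.to_one_based` is the single conversion point.

## Design enumeration

`design.enumerate_pairs` enumerates every (left window, spacer, right
window) geometry with T at the left window start and A at the right window
end. Default windows are EBE length 15–20 nt (including T0) and spacer
14–18 bp. These defaults were an open choice: they sit inside the 10–24 bp
activity-permissive spacer range and match common Golden-Gate scaffold
practice. No RVD-composition scoring or repeat-content heuristics are
applied. Output order is left start, then shorter spacer, then shorter
combined arm length.

## Diagnostic PCR and genotyping

`in_silico_pcr` uses exact primer matching (the assay is presence/absence;
mismatch-tolerant annealing would add ambiguity without changing verdicts)
and returns the shortest product below a length cap, or absence as a value.
The two-amplicon truth table is: outer product present + inner absent →
disrupted; both present → intact; anything else → indeterminate.

`call_indel` globally aligns clone to reference with match +2, mismatch −3,
gap-open −8, gap-extend −1 — gap-open heavy so a single contiguous event is
preferred, as nuclease repair outcomes are predominantly single indels. A
single gap run becomes a deletion (Δn) or insertion (+n); its position is
left-aligned (gaps shifted maximally 5'-ward), the variant-normalization
convention used for the optional VCF 4.2 export. More than one gap run, or
three or more substitutions within 10 bp, yields `complex` rather than a
guessed allele name. Clones whose gap-inclusive alignment identity falls
below 50% raise an error rather than producing a call. The frameshift flag
is `size mod 3 ≠ 0` for simple indels.

`predict_truncation` applies a call to a coding sequence (whole codons,
ATG start required) and translates both alleles to the first stop.
`premature_stop` is true only when the mutant's stop, mapped back to coding
coordinates through the indel, is not the wild type's own stop codon reached
in frame — so an in-frame deletion that simply shortens the protein is not
flagged. `altered_from` is the first codon index at which the peptides
diverge.

`mutation_rate` reports k/n with a 95% Wilson score interval (statsmodels);
Wilson rather than Wald because founder screens have small n. Interval
bounds are clamped against float noise so `0 ≤ low ≤ p ≤ high ≤ 1` holds
exactly.

## Motif scanning

`scan_motif` slides an IUPAC consensus over each sequence, reporting every
(offset, strand) match including overlaps; minus-strand matching uses the
code-wise reverse complement of the pattern. A genomic `N` fails every
pattern code except `N`. The shipped default pattern is the canonical SRY
core `WAACAAW`; the concrete binding-site definition used in any given
study is rarely machine-readable, so the pattern is fully user-supplied and
all correctness claims are property-based (oracle equality, planted counts),
not literature count-matching. Window extraction (e.g. 2 kb upstream) is
the caller's job; position-weight-matrix scoring is out of scope.

## Synthetic data

The generator is the package's test bed and ships as first-class code.

* `make_genome` draws i.i.d. residues with a specified GC fraction, fully
  determined by the seed.
* `plant_offtarget` overwrites a region with a site of exact arrangement,
  spacer and per-arm mismatch counts (mismatch positions seed-chosen, never
  position 0), re-counts the written windows afterwards, and refuses
  overlaps with previously planted loci.
* `plant_indel_clones` emits one clone per (kind, size, position) spec and
  records the left-aligned canonical position in the truth, so recovery
  comparisons are exact even inside homopolymers. Insertion content is
  seed-derived; an optional `avoid` list rejection-samples content that
  would create a listed pattern across the insertion junction (bounded
  retries).
* `plant_motifs` builds a background, plants concrete instantiations of the
  pattern, and regenerates from derived seeds until a scan recovers exactly
  the planted count — truth manifests are exact, not probabilistic.
* `make_fixture_suite` bundles an ~11.5 kb genome (GC 0.40, in the range of
  compact fish genomes) carrying nine planted sites that span the filter
  boundaries — spacers 9/10/12/24/25/99/100 and totals 0/1/7/10/11,
  including the 12 bp-spacer/7-mismatch profile of a credible candidate —
  plus a 400 bp amplicon with five indel clones (Δ11, +16, Δ3, +2, Δ1) and
  six upstream sequences with 0–6 planted motif instances. Site spacing
  (1.2 kb) exceeds the maximum pairing distance so planted sites cannot
  cross-pair.

Random backgrounds inevitably contain windows that pass the generous
default mismatch budget by chance, and a planted arm can cast "ghost"
matches at shifted offsets of itself. The suite generator therefore scrubs
the background after planting: any hit not matching a planted truth has its
non-planted arm destroyed (position-0 base flipped, or guaranteed-mismatch
bases written at every position outside planted windows, always drawn from
{C, G} so no new T0 arises), iterating until a default-criteria scan
returns exactly the planted accepted sites. If an accidental arm cannot be
destroyed without touching a planted window, the EBE pair and background
are redrawn from derived seeds — ghost proneness is a property of EBE
autocorrelation, so the EBEs must be part of the retry. The whole procedure
is a pure function of the seed, and bundles are byte-identical across runs.

What the generator does **not** emulate: real genome composition
(repeats, GC heterogeneity, soft-masking), empirical TALEN repair-outcome
spectra (microhomology-biased deletions), chromatogram noise, and
heteroduplex artifacts. Passing the planted-recovery and oracle suites
therefore demonstrates algorithmic correctness of the scanners and callers
under the stated rules, not calibration against wet-lab mutation data.

## Problem sizes and numerics

The test suite and acceptance script run the off-target oracle comparison
on 20 random genomes of 2–8 kb under randomized criteria, the motif and PCR
oracles on 20 seeds each, and indel recovery on 200 planted clones of sizes
1–30 — sizes chosen so the exhaustive pure-Python oracles stay comfortably
fast while still exercising every filter boundary and both strands.
Reported percentages are exact fractions of these runs. Genome-scan
validation against any specific published candidate list is deliberately
not attempted: such lists depend on the genome release scanned and on EBE
sequences that are not machine-readable from figure artwork.

## Known limitations

* Arm matching is Hamming-only: no RVD-aware per-base binding energies or
  position-weighted TALE scoring, and no bulges within an EBE footprint.
* Primer annealing in the diagnostic assay is exact-match by design.
* `call_indel` names only single contiguous events; compound repair
  outcomes are reported as `complex` without decomposition.
* The motif scanner counts consensus presence/absence; it does not score
  affinity.
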