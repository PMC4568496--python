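import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from talenscan.genotype import (
    AlignmentError,
    IndelCall,
    PrimerSet,
    call_indel,
    diagnose_disruption,
    in_silico_pcr,
    left_align_deletion,
    left_align_insertion,
    mutation_rate,
    predict_truncation,
    write_vcf,
)
from talenscan.seqio import GenomicInterval, NucleotideSequence, reverse_complement
from talenscan.simulate import make_genome, plant_indel_clones

FWD = "ACGGATTACCAGGCAT"
REV = "TTGACCGGTTACCAGT"  # anneals to the minus strand
INNER = "GATTACAGATTACAGG"


def _template(middle: str) -> NucleotideSequence:
    return NucleotideSequence("t", FWD + middle + reverse_complement(REV))


class TestInSilicoPcr:
    def test_simple_product_length(self):
        t = _template("C" * 50)
        assert in_silico_pcr(t, FWD, REV, 500) == len(FWD) + 50 + len(REV)

    def test_absent_reverse_site(self):
        t = NucleotideSequence("t", FWD + "C" * 50)
        assert in_silico_pcr(t, FWD, REV, 500) is None

    def test_two_reverse_sites_shortest_product(self):
        middle = "C" * 20 + reverse_complement(REV) + "G" * 30
        t = _template(middle)
        got = in_silico_pcr(t, FWD, REV, 500)
        assert got == oracles.pcr_product(t.residues, FWD, REV, 500)
        assert got == len(FWD) + 20 + len(REV)

    def test_max_len_enforced(self):
        t = _template("C" * 50)
        assert in_silico_pcr(t, FWD, REV, 40) is None

    @pytest.mark.parametrize("seed", range(8))
    def test_oracle_equivalence_random_templates(self, seed):
        rng = np.random.default_rng(seed)
        base = make_genome(300, 0.5, seed + 10, seq_id="t").residues
        # plant a variable number of primer sites
        pieces = [base[:40]]
        for _ in range(int(rng.integers(0, 3))):
            pieces += [FWD, base[40:60]]
        for _ in range(int(rng.integers(0, 3))):
            pieces += [reverse_complement(REV), base[60:80]]
        t = NucleotideSequence("t", "".join(pieces))
        assert in_silico_pcr(t, FWD, REV, 400) == oracles.pcr_product(
            t.residues, FWD, REV, 400
        )


class TestDiagnoseDisruption:
    PRIMERS = PrimerSet(outer_fwd=FWD, inner_fwd=INNER, rev=REV)

    def test_wild_type_is_intact(self):
        t = _template("AA" + INNER + "GG")
        call = diagnose_disruption(t, self.PRIMERS, 500)
        assert call.verdict == "intact"
        assert call.outer_len is not None and call.inner_len is not None

    def test_deletion_destroying_inner_site_is_disrupted(self):
        # an 11-base deletion inside the inner primer's annealing site
        middle = "AA" + INNER[:3] + INNER[14:] + "GG"
        call = diagnose_disruption(_template(middle), self.PRIMERS, 500)
        assert call.verdict == "disrupted"
        assert call.inner_len is None

    def test_missing_reverse_site_is_indeterminate(self):
        t = NucleotideSequence("t", FWD + "AA" + INNER + "GG")
        assert diagnose_disruption(t, self.PRIMERS, 500).verdict == "indeterminate"

    @pytest.mark.parametrize("seed", range(6))
    def test_compositional_consistency(self, seed):
        t = make_genome(400, 0.5, seed, seq_id="t")
        call = diagnose_disruption(t, self.PRIMERS, 500)
        outer = in_silico_pcr(t, FWD, REV, 500)
        inner = in_silico_pcr(t, INNER, REV, 500)
        if outer is not None and inner is None:
            assert call.verdict == "disrupted"
        elif outer is not None and inner is not None:
            assert call.verdict == "intact"
        else:
            assert call.verdict == "indeterminate"

    def test_primer_length_validated(self):
        with pytest.raises(ValueError, match="shorter than 12"):
            PrimerSet("ACGTACGT", INNER, REV)


REFERENCE = make_genome(400, 0.45, 2024, seq_id="ref")
SPACER = GenomicInterval("ref", 190, 206)


class TestCallIndel:
    def test_eleven_base_deletion(self):
        ref = REFERENCE.residues
        clone = NucleotideSequence("c", ref[:195] + ref[206:])
        call = call_indel(REFERENCE, clone, SPACER)
        assert call.kind == "deletion"
        assert call.size == 11
        assert call.allele_name == "Δ11"
        assert call.in_spacer is True
        assert call.frameshift is True

    def test_sixteen_base_insertion(self):
        ref = REFERENCE.residues
        clone = NucleotideSequence("c", ref[:198] + "GATTACAGATTACAGG" + ref[198:])
        call = call_indel(REFERENCE, clone, SPACER)
        assert call.kind == "insertion"
        assert call.size == 16
        assert call.allele_name == "+16"
        assert call.frameshift is True

    def test_in_frame_deletion_not_frameshift(self):
        ref = REFERENCE.residues
        clone = NucleotideSequence("c", ref[:195] + ref[198:])
        call = call_indel(REFERENCE, clone, SPACER)
        assert call.kind == "deletion" and call.size == 3
        assert call.frameshift is False

    def test_identical_sequences(self):
        call = call_indel(REFERENCE, NucleotideSequence("c", REFERENCE.residues), SPACER)
        assert call.kind == "none" and call.size == 0

    def test_left_alignment_in_homopolymer(self):
        ref = NucleotideSequence("r", "GGCCTT" + "A" * 8 + "TTGGCC" + "C" * 30)
        # delete two A's from the right end of the run: canonical position is
        # the run start (offset 6)
        clone = NucleotideSequence("c", "GGCCTT" + "A" * 6 + "TTGGCC" + "C" * 30)
        call = call_indel(ref, clone, GenomicInterval("r", 0, 20))
        assert (call.kind, call.size, call.position) == ("deletion", 2, 6)

    def test_two_gap_runs_are_complex(self):
        ref = REFERENCE.residues
        clone = NucleotideSequence("c", ref[:100] + ref[105:250] + ref[260:])
        call = call_indel(REFERENCE, clone, SPACER)
        assert call.kind == "complex"

    def test_clustered_substitutions_are_complex(self):
        ref = list(REFERENCE.residues)
        for pos in (200, 202, 204):
            ref[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[ref[pos]]
        call = call_indel(REFERENCE, NucleotideSequence("c", "".join(ref)), SPACER)
        assert call.kind == "complex"

    def test_unalignable_clone_errors(self):
        noise = make_genome(400, 0.5, 999, seq_id="junk")
        with pytest.raises(AlignmentError, match="identity"):
            call_indel(REFERENCE, noise, SPACER)

    @pytest.mark.parametrize("seed", range(4))
    def test_planted_recovery_random_specs(self, seed):
        rng = np.random.default_rng(seed)
        specs = []
        for _ in range(12):
            kind = "deletion" if rng.integers(2) else "insertion"
            size = int(rng.integers(1, 31))
            position = int(rng.integers(60, 320))
            specs.append((kind, size, position))
        clones, truths = plant_indel_clones(REFERENCE, specs, seed + 1)
        for clone, truth in zip(clones, truths):
            call = call_indel(REFERENCE, clone, SPACER)
            p = truth.parameters
            assert call.kind == p["kind"]
            assert call.size == p["size"]
            assert call.position == p["canonical_position"]
            assert call.frameshift == (p["size"] % 3 != 0)


def test_left_align_helpers():
    assert left_align_deletion("CCAAAAGG", 4, 2) == 2
    pos, ins = left_align_insertion("CCAAGG", 4, "AA")
    assert pos == 2 and ins == "AA"


class TestPredictTruncation:
    @staticmethod
    def _cds():
        # ATG + 98 body codons + TAA; bases 83-85 are TAA so the frame
        # shifted by an 11-base deletion at codon 20 hits a stop at codon 24
        body = ["GCT"] * 98
        seq = "ATG" + "".join(body) + "TAA"
        seq = seq[:83] + "TAA" + seq[86:]
        assert len(seq) == 300
        # wild-type frame must not gain a stop: codon 27 = seq[81:84],
        # codon 28 = seq[84:87]
        assert "*" not in oracles.translate_to_stop(seq)[:99]
        return NucleotideSequence("cds", seq)

    def test_frameshift_deletion_truncates(self):
        cds = self._cds()
        call = IndelCall("deletion", 11, 60, "Δ11", True, True)
        pred = predict_truncation(cds, call)
        # independent oracle: apply the edit, translate with the codon table
        mutant = cds.residues[:60] + cds.residues[71:]
        wt_protein = oracles.translate_to_stop(cds.residues)
        mut_protein = oracles.translate_to_stop(mutant[: len(mutant) - len(mutant) % 3])
        assert pred.wt_protein_len == len(wt_protein) == 99
        assert pred.mutant_protein_len == len(mut_protein)
        assert pred.premature_stop is True
        assert pred.mutant_protein_len < pred.wt_protein_len
        assert pred.altered_from == 20

    def test_in_frame_deletion_shortens_by_one(self):
        cds = self._cds()
        call = IndelCall("deletion", 3, 60, "Δ3", True, False)
        pred = predict_truncation(cds, call)
        assert pred.premature_stop is False
        assert pred.mutant_protein_len == pred.wt_protein_len - 1
        assert pred.altered_from >= 20  # never earlier than the indel's codon

    def test_no_indel_is_identity(self):
        cds = self._cds()
        pred = predict_truncation(cds, IndelCall("none", 0, 0, "wt", False, False))
        assert pred.mutant_protein_len == pred.wt_protein_len
        assert pred.premature_stop is False

    def test_length_must_be_codon_multiple(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            predict_truncation(
                NucleotideSequence("c", "ATGC"),
                IndelCall("none", 0, 0, "wt", False, False),
            )

    @pytest.mark.parametrize("seed", range(6))
    def test_oracle_equivalence_random_indels(self, seed):
        rng = np.random.default_rng(seed)
        # random cds without internal stops in the wild-type frame
        codons = ["ATG"]
        while len(codons) < 60:
            c = "".join(rng.choice(list("ACGT"), size=3))
            if oracles.CODON_TABLE[c] != "*":
                codons.append(c)
        seq = "".join(codons) + "TAA"
        cds = NucleotideSequence("cds", seq)
        kind = "deletion" if rng.integers(2) else "insertion"
        size = int(rng.integers(1, 20))
        position = int(rng.integers(3, 120))
        inserted = "".join(rng.choice(list("ACGT"), size=size))
        call = IndelCall(kind, size, position, "x", True, size % 3 != 0,
                         inserted=inserted if kind == "insertion" else None)
        pred = predict_truncation(cds, call)
        if kind == "deletion":
            mutant = seq[:position] + seq[position + size :]
        else:
            mutant = seq[:position] + inserted + seq[position:]
        mut_protein = oracles.translate_to_stop(mutant[: len(mutant) - len(mutant) % 3])
        assert pred.wt_protein_len == len(oracles.translate_to_stop(seq))
        assert pred.mutant_protein_len == len(mut_protein)


class TestMutationRate:
    def test_founder_screen_rate(self):
        est = mutation_rate(15, 32)
        assert est.proportion == pytest.approx(0.46875)
        assert abs(100 * est.proportion - 46.9) < 0.1

    def test_zero_successes(self):
        est = mutation_rate(0, 10)
        assert est.proportion == 0.0
        assert est.ci_low == 0.0

    def test_wilson_matches_closed_form(self):
        est = mutation_rate(7, 20)
        low, high = oracles.wilson_interval(7, 20)
        assert est.ci_low == pytest.approx(low, abs=1e-9)
        assert est.ci_high == pytest.approx(high, abs=1e-9)

    @given(st.integers(min_value=1, max_value=200), st.data())
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_interval_ordering_invariant(self, n, data):
        k = data.draw(st.integers(min_value=0, max_value=n))
        est = mutation_rate(k, n)
        assert 0.0 <= est.ci_low <= est.proportion <= est.ci_high <= 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            mutation_rate(5, 0)
        with pytest.raises(ValueError):
            mutation_rate(11, 10)


def test_vcf_export_alleles_match_reference(tmp_path):
    ref = REFERENCE.residues
    clones = [
        NucleotideSequence("d11", ref[:195] + ref[206:]),
        NucleotideSequence("i16", ref[:198] + "GATTACAGATTACAGG" + ref[198:]),
    ]
    calls = [(c.id, call_indel(REFERENCE, c, SPACER)) for c in clones]
    out = tmp_path / "calls.vcf"
    write_vcf(REFERENCE, calls, out)
    lines = [l for l in out.read_text().splitlines() if not l.startswith("#")]
    assert len(lines) == 2
    for line in lines:
        chrom, pos, _, ref_allele, alt_allele, *_ = line.split("\t")
        pos = int(pos)
        assert ref[pos - 1 : pos - 1 + len(ref_allele)] == ref_allele
        assert ref_allele[0] == alt_allele[0]  # anchored on the same base
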