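"""Amplicon indel calling: alignment, window rule, control subtraction."""

import pytest

from pamscan import (
    ReadEmissionProfile,
    align_to_reference,
    analyze_amplicon,
    call_indel_mutations,
    mutation_frequency,
    rank_mutations,
    simulate_amplicon_reads,
)
from pamscan.indel_caller import (
    AmpliconTarget,
    MutationRecord,
    ReadAlignment,
    in_window,
)
from pamscan.readproc import SeqRead, quality_string
from pamscan.variants import Edit


def as_read(seq, rid="r"):
    return SeqRead(rid, seq, quality_string([40] * len(seq)))


class TestTargetValidation:
    def test_pam_must_abut_protospacer(self, amplicon):
        reference, *_ , target, _, _ = amplicon
        with pytest.raises(ValueError, match="immediately 3'"):
            AmpliconTarget(reference=reference,
                           protospacer=target.protospacer,
                           pam=(target.pam[0] + 1, target.pam[1] + 1),
                           prefix=target.prefix,
                           min_len=target.min_len, max_len=target.max_len)

    def test_cut_is_three_nt_inside_protospacer(self, amplicon):
        *_, target, _, _ = amplicon
        assert target.expected_cut == target.pam[0] - 3

    def test_json_round_trip(self, tmp_path, amplicon):
        *_, target, _, _ = amplicon
        path = tmp_path / "target.json"
        target.to_json(path)
        assert AmpliconTarget.read_json(path) == target


class TestAlignment:
    def test_reference_read_has_no_edits(self, amplicon):
        reference, *_ , target, _, _ = amplicon
        aln = align_to_reference(as_read(reference), target)
        assert aln.edits == ()
        assert aln.score == 2 * len(reference)

    def test_planted_deletion_recovered_at_cut(self, amplicon):
        reference, cut, _, target, _, _ = amplicon
        edit = Edit("del", cut, 1)
        aln = align_to_reference(as_read(edit.apply(reference)), target)
        assert aln.edits == (edit.left_aligned(reference),)

    def test_planted_insertion_recovered(self, amplicon):
        reference, cut, _, target, _, _ = amplicon
        edit = Edit("ins", cut + 1, 2, "AG")
        aln = align_to_reference(as_read(edit.apply(reference)), target)
        assert aln.edits == (edit.left_aligned(reference),)

    def test_homopolymer_deletion_anchored_leftmost(self):
        # run of four A's: deleting any one yields the same sequence
        ref = "ACGTGGTCTCATGCAGGCCGGTCAAAAGTCCTGACGTACGTTAGCATCGA"
        run = ref.index("AAAA")
        target = AmpliconTarget(reference=ref, protospacer=(5, 25),
                                pam=(25, 33), prefix="ACGTG",
                                min_len=len(ref) - 5, max_len=len(ref) + 5)
        for offset in range(4):
            read = as_read(Edit("del", run + offset, 1).apply(ref))
            aln = align_to_reference(read, target)
            assert aln.edits == (Edit("del", run, 1),)

    def test_substitutions_produce_no_edits(self, amplicon):
        reference, cut, _, target, _, _ = amplicon
        mutated = reference[:cut] + ("A" if reference[cut] != "A" else "C") \
            + reference[cut + 1:]
        aln = align_to_reference(as_read(mutated), target)
        assert aln.edits == ()

    def test_garbage_read_rejected(self, amplicon):
        reference, *_ , target, _, _ = amplicon
        aln = align_to_reference(as_read("GC" * (len(reference) // 2)), target)
        assert aln is None


class TestWindowRule:
    def brute_force_in_window(self, edit, cut, window=10):
        return cut - window // 2 <= edit.pos < cut + window // 2

    def test_window_rule_matches_scan_oracle(self, amplicon):
        reference, cut, _, target, _, _ = amplicon
        for pos in range(cut - 8, cut + 8):
            for edit in (Edit("del", pos, 1), Edit("ins", pos, 1, "T")):
                assert in_window(edit, target) == self.brute_force_in_window(
                    edit, cut
                ), str(edit)

    def test_wild_type_read_not_mutant(self, amplicon):
        reference, *_ , target, _, _ = amplicon
        aln = align_to_reference(as_read(reference), target)
        assert call_indel_mutations([aln], target) == []

    def test_insertion_at_cut_is_mutant(self, amplicon):
        reference, cut, _, target, _, _ = amplicon
        edit = Edit("ins", cut, 1, "T").left_aligned(reference)
        aln = align_to_reference(as_read(edit.apply(reference)), target)
        records = call_indel_mutations([aln], target)
        assert len(records) == 1 and records[0].edits == (edit,)

    def test_distant_deletion_not_mutant(self, amplicon):
        reference, cut, _, target, _, _ = amplicon
        edit = Edit("del", cut + 20, 2)
        aln = ReadAlignment("r", 0.0, (edit,))
        assert call_indel_mutations([aln], target) == []

    def test_odd_window_rejected(self, amplicon):
        *_, target, _, _ = amplicon
        with pytest.raises(ValueError):
            in_window(Edit("del", 0, 1), target, window=9)


class TestControlSubtraction:
    def test_shared_edit_excluded(self, amplicon):
        reference, cut, _, target, _, artifact = amplicon
        aln = align_to_reference(as_read(artifact.apply(reference)), target)
        assert call_indel_mutations([aln], target, controls=[artifact]) == []
        # without the control set the same read is a mutant
        assert len(call_indel_mutations([aln], target)) == 1

    def test_positional_slack(self, amplicon):
        *_, target, _, _ = amplicon
        cut = target.expected_cut
        edit = Edit("del", cut + 1, 1)
        control = Edit("del", cut, 1)
        aln = ReadAlignment("r", 0.0, (edit,))
        assert call_indel_mutations([aln], target, controls=[control]) != []
        assert call_indel_mutations([aln], target, controls=[control],
                                    control_slack=1) == []


class TestRanking:
    def rec(self, edit, n=1):
        return MutationRecord(edits=(edit,), read_count=n)

    def test_identical_edits_collapse(self):
        e = Edit("ins", 50, 1, "A")
        top, full = rank_mutations([self.rec(e), self.rec(e)])
        assert len(full) == 1 and full[0].read_count == 2

    def test_top_ten_of_eleven(self):
        records = [self.rec(Edit("del", 40 + i, 1), n=20 - i) for i in range(11)]
        top, full = rank_mutations(records, n=10)
        assert len(top) == 10 and len(full) == 11

    def test_count_ties_break_by_position(self):
        a = self.rec(Edit("del", 44, 1), n=5)
        b = self.rec(Edit("del", 41, 1), n=5)
        top, _ = rank_mutations([a, b])
        assert [r.edit.pos for r in top] == [41, 44]


class TestMutationFrequency:
    def test_zero_mutants(self):
        assert mutation_frequency(0, 1000) == 0.0

    def test_thirty_percent(self):
        assert mutation_frequency(300, 1000) == pytest.approx(30.0)

    def test_no_valid_reads_is_missing(self):
        assert mutation_frequency(0, 0) is None

    def test_more_mutants_than_valid_rejected(self):
        with pytest.raises(ValueError):
            mutation_frequency(5, 4)


class TestEndToEnd:
    def test_recovers_planted_spectrum(self, amplicon):
        reference, cut, prefix, target, spectrum, artifact = amplicon
        profile = ReadEmissionProfile(read_len=len(reference) + 5,
                                      substitution_error_rate=0.0,
                                      mean_quality=40, quality_sd=0)
        reads, truth = simulate_amplicon_reads(reference, cut, spectrum, 0.25,
                                               profile, 4000, seed=21)
        report = analyze_amplicon(reads, target)
        truth_counts = truth.loc[truth.is_mutant, "edit"].value_counts()
        assert report.valid_reads == 4000
        assert report.mutant_reads == int(truth_counts.sum())
        recovered = {";".join(str(e) for e in r.edits): r.read_count
                     for r in report.all_mutations}
        assert recovered == dict(truth_counts.items())

    def test_control_artifact_absent_from_calls(self, amplicon):
        reference, cut, prefix, target, spectrum, artifact = amplicon
        profile = ReadEmissionProfile(read_len=len(reference) + 5,
                                      substitution_error_rate=0.0,
                                      mean_quality=40, quality_sd=0)
        mix = [(e, w * 0.9) for e, w in spectrum] + [(artifact, 0.1)]
        reads, _ = simulate_amplicon_reads(reference, cut, mix, 0.25,
                                           profile, 2000, seed=22)
        controls, _ = simulate_amplicon_reads(reference, cut,
                                              [(artifact, 1.0)], 0.1,
                                              profile, 500, seed=23)
        report = analyze_amplicon(reads, target, control_reads=controls)
        called = {str(e) for r in report.all_mutations for e in r.edits}
        assert str(artifact) not in called
        assert artifact in report.control_variants
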