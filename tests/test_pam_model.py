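"""PFM construction, normalization, information content, consensus calls."""

import numpy as np
import pytest

from pamscan import (
    PamCountTable,
    PFMatrix,
    call_consensus,
    compare_doses,
    compute_pfm,
    extend_pfm_with_shift,
    information_content,
    logo_heights,
    normalize_counts,
)


def pfm_from_columns(*columns):
    """Build a PFM from per-position {base: prob} dicts."""
    probs = np.array([[col.get(b, 0.0) for b in "ACGT"] for col in columns])
    return PFMatrix(probs=probs)


class TestNormalizeCounts:
    def test_uniform_library_preserves_cleaved_frequencies(self):
        cleaved = PamCountTable({"AA": 30, "CC": 10})
        library = PamCountTable({p: 1 for p in ("AA", "CC", "GG", "TT")})
        norm = normalize_counts(cleaved, library, pseudocount=0.0)
        assert norm.freq("AA") == pytest.approx(0.75)
        assert norm.freq("CC") == pytest.approx(0.25)

    def test_biased_library_reweights(self):
        cleaved = PamCountTable.from_frequencies({"AA": 0.5, "CC": 0.5})
        library = PamCountTable.from_frequencies({"AA": 0.25, "CC": 0.75})
        norm = normalize_counts(cleaved, library, pseudocount=0.0)
        # weights 2 and 2/3 rescale to 0.75 / 0.25
        assert norm.freq("AA") == pytest.approx(0.75)
        assert norm.freq("CC") == pytest.approx(0.25)

    def test_missing_library_pam_needs_pseudocount(self):
        cleaved = PamCountTable({"AA": 1, "CC": 1})
        library = PamCountTable({"AA": 4})
        with pytest.raises(ValueError, match="pseudocount"):
            normalize_counts(cleaved, library, pseudocount=0.0)
        norm = normalize_counts(cleaved, library, pseudocount=0.1)
        assert 0 < norm.freq("CC") < 1

    def test_invariant_to_count_rescaling(self):
        cleaved = PamCountTable({"AA": 3, "CC": 9, "GT": 6})
        library = PamCountTable({"AA": 5, "CC": 5, "GT": 10})
        base = normalize_counts(cleaved, library, pseudocount=0.0)
        scaled = normalize_counts(
            PamCountTable({p: 7 * c for p, c in cleaved.counts().items()}),
            PamCountTable({p: 13 * c for p, c in library.counts().items()}),
            pseudocount=0.0,
        )
        for pam in cleaved:
            assert scaled.freq(pam) == pytest.approx(base.freq(pam))

    def test_pam_len_mismatch_rejected(self):
        with pytest.raises(ValueError):
            normalize_counts(PamCountTable({"AA": 1}),
                             PamCountTable({"AAA": 1}))


class TestComputePfm:
    def test_single_pam_is_deterministic_matrix(self):
        pfm = compute_pfm(PamCountTable({"GTCCC": 7}))
        assert pfm.column(1) == {"A": 0.0, "C": 0.0, "G": 1.0, "T": 0.0}
        assert pfm.column(3)["C"] == 1.0

    def test_two_pam_mixture(self):
        pfm = compute_pfm(
            PamCountTable.from_frequencies({"AAGGG": 0.5, "ACGGG": 0.5})
        )
        assert pfm.column(1)["A"] == pytest.approx(1.0)
        assert pfm.column(2) == pytest.approx({"A": 0.5, "C": 0.5,
                                               "G": 0.0, "T": 0.0})

    def test_uniform_table_gives_flat_matrix(self, scheme5):
        table = PamCountTable({p: 1 for p in scheme5.all_pams()})
        pfm = compute_pfm(table)
        assert np.allclose(pfm.probs, 0.25)

    def test_matches_per_read_tally_oracle(self):
        rng = np.random.default_rng(5)
        bases = np.array(list("ACGT"))
        pams = {"".join(rng.choice(bases, size=4)): int(rng.integers(1, 50))
                for _ in range(300)}
        pfm = compute_pfm(PamCountTable(pams))
        # oracle: expand table into individual reads and tally per position
        reads = [p for p, c in pams.items() for _ in range(c)]
        for j in range(4):
            for bi, b in enumerate("ACGT"):
                expected = sum(1 for r in reads if r[j] == b) / len(reads)
                assert pfm.probs[j, bi] == pytest.approx(expected)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            compute_pfm(PamCountTable({}, pam_len=5))

    def test_tsv_round_trip(self, tmp_path):
        pfm = compute_pfm(PamCountTable({"GT": 3, "GA": 1}))
        path = tmp_path / "pfm.tsv"
        pfm.to_tsv(path)
        again = PFMatrix.read_tsv(path)
        assert np.allclose(again.probs, pfm.probs)


class TestInformationContent:
    def test_uniform_column_is_zero_bits(self):
        pfm = pfm_from_columns({"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25})
        assert information_content(pfm)[0] == pytest.approx(0.0)

    def test_deterministic_column_is_two_bits(self):
        pfm = pfm_from_columns({"G": 1.0})
        assert information_content(pfm)[0] == pytest.approx(2.0)

    def test_half_half_column_is_one_bit(self):
        pfm = pfm_from_columns({"A": 0.5, "T": 0.5})
        assert information_content(pfm)[0] == pytest.approx(1.0)


class TestCallConsensus:
    def test_dominant_base_called(self):
        pfm = pfm_from_columns({"C": 0.97, "A": 0.01, "G": 0.01, "T": 0.01})
        assert str(call_consensus(pfm)) == "C"

    def test_near_uniform_column_is_n(self):
        pfm = pfm_from_columns({"A": 0.26, "C": 0.25, "G": 0.25, "T": 0.24})
        assert str(call_consensus(pfm)) == "N"

    def test_three_base_set_is_d(self):
        pfm = pfm_from_columns({"A": 0.4, "G": 0.3, "T": 0.25, "C": 0.05})
        call = call_consensus(pfm, support_threshold=0.9)
        assert str(call) == "D"
        assert call.per_position_support[0] == pytest.approx(0.95)

    def test_tied_bases_are_both_retained(self):
        pfm = pfm_from_columns({"A": 0.45, "G": 0.45, "T": 0.05, "C": 0.05})
        assert str(call_consensus(pfm, support_threshold=0.9)) == "R"

    def test_no_base_above_floor_is_n(self):
        pfm = pfm_from_columns({"A": 0.30, "C": 0.30, "G": 0.30, "T": 0.10})
        assert str(call_consensus(pfm, n_floor=0.30)) == "N"

    def test_multi_position_consensus(self):
        pfm = pfm_from_columns(
            {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25},
            {"G": 0.95, "A": 0.05},
            {"G": 0.92, "C": 0.08},
        )
        assert str(call_consensus(pfm)) == "NGG"


class TestCompareDoses:
    def test_identical_pfms_have_zero_delta(self):
        pfm = pfm_from_columns({"G": 0.9, "A": 0.1}, {"C": 1.0})
        cmp = compare_doses(pfm, pfm)
        assert np.allclose(cmp.delta_bits, 0.0)
        assert cmp.total_delta_bits == 0.0
        assert cmp.flagged_positions == ()

    def test_specific_to_relaxed_is_two_bits(self):
        low = pfm_from_columns({"G": 1.0})
        high = pfm_from_columns({"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25})
        cmp = compare_doses(low, high)
        assert cmp.delta_bits[0] == pytest.approx(2.0)
        assert cmp.flagged_positions == (1,)

    def test_position_mismatch_rejected(self):
        low = pfm_from_columns({"G": 1.0})
        high = PFMatrix(probs=np.array([[1.0, 0, 0, 0]]), positions=(2,))
        with pytest.raises(ValueError):
            compare_doses(low, high)


class TestShiftExtension:
    def _flat(self, n):
        return pfm_from_columns(*({"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
                                  for _ in range(n)))

    def test_zero_shift_is_identity(self):
        base = self._flat(7)
        ext, diag = extend_pfm_with_shift(base, self._flat(7), shift=0)
        assert ext is base and diag.overlap_tv == {}

    def test_shift_extends_positions_to_ten(self):
        ext, _ = extend_pfm_with_shift(self._flat(7), self._flat(7), shift=3)
        assert ext.positions == tuple(range(1, 11))

    def test_signal_beyond_window_comes_from_shifted_arm(self):
        # planted preference at PAM position 8 = shifted-experiment position 5
        cols = [{"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}] * 7
        shifted_cols = list(cols)
        shifted_cols[4] = {"A": 0.9, "C": 0.05, "G": 0.03, "T": 0.02}
        shifted = pfm_from_columns(*shifted_cols)
        ext, diag = extend_pfm_with_shift(self._flat(7), shifted, shift=3)
        assert ext.column(8)["A"] == pytest.approx(0.9)
        assert str(call_consensus(ext))[7] == "A"
        assert diag.discordant_positions == ()

    def test_overlap_discordance_flagged(self):
        shifted_cols = [{"G": 1.0}] + [
            {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}] * 6
        # shifted position 1 reports on PAM position 4, which disagrees
        ext, diag = extend_pfm_with_shift(
            self._flat(7), pfm_from_columns(*shifted_cols), shift=3)
        assert 4 in diag.discordant_positions
        assert diag.overlap_tv[4] == pytest.approx(0.75)
        # overlap is reported from the unshifted experiment
        assert ext.column(4)["G"] == pytest.approx(0.25)


class TestLogoHeights:
    def test_probability_mode_equals_probs(self):
        pfm = pfm_from_columns({"G": 0.7, "A": 0.3}, {"C": 1.0})
        heights = logo_heights(pfm, mode="probability")
        assert heights.loc["G", 1] == pytest.approx(0.7)
        assert heights[1].sum() == pytest.approx(1.0)

    def test_bits_mode_equals_p_times_ic(self):
        pfm = pfm_from_columns({"A": 0.5, "T": 0.5})
        heights = logo_heights(pfm, mode="bits")
        assert heights.loc["A", 1] == pytest.approx(0.5)  # p=0.5 x IC=1 bit
        assert heights[1].sum() == pytest.approx(1.0)

    def test_unknown_mode_rejected(self):
        pfm = pfm_from_columns({"A": 1.0})
        with pytest.raises(ValueError):
            logo_heights(pfm, mode="weblogo")
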