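import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nlrdiv import (
    Alignment,
    AlignedSeq,
    HvCriteria,
    classify_hv,
    column_entropy,
    count_hv_by_domain,
    hydrophobic_fraction,
    mask_gappy_columns,
    profile_alignment,
)
from nlrdiv.diversity import MAX_ENTROPY_BITS
from nlrdiv.errors import InputError
from nlrdiv.io import AA20


def aln_from_columns(columns):
    """Build an alignment whose i-th column is columns[i]."""
    n = len(columns[0])
    seqs = ["".join(col[i] for col in columns) for i in range(n)]
    return Alignment(records=[AlignedSeq(f"s{i}", "", s) for i, s in enumerate(seqs)])


class TestColumnEntropy:
    @pytest.mark.parametrize(
        "column,expected",
        [
            ("AAAA", 0.0),
            ("AC", 1.0),                       # balanced pair: exactly 1 bit
            (AA20, math.log2(20)),             # all twenty equal: log2 20
            ("AAAC", 0.8112781244591328),      # -(3/4 log 3/4 + 1/4 log 1/4)
            ("A-A--", 0.0),                    # gaps not counted
            ("AX*C", 1.0),                     # ambiguity codes excluded too
        ],
    )
    def test_known_values(self, column, expected):
        assert column_entropy(column) == pytest.approx(expected, abs=1e-12)

    def test_empty_column_rejected(self):
        with pytest.raises(InputError):
            column_entropy("")

    @settings(max_examples=200, derandomize=True)
    @given(st.text(alphabet=AA20 + "-X", min_size=1, max_size=60))
    def test_bounds_and_zero_condition(self, column):
        h = column_entropy(column)
        assert 0.0 <= h <= MAX_ENTROPY_BITS + 1e-12
        counted = [c for c in column if c in AA20]
        assert (h == 0.0) == (len(set(counted)) <= 1)

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.sampled_from(AA20 + "-"), min_size=2, max_size=40))
    def test_invariant_to_order_and_duplication(self, residues):
        col = "".join(residues)
        shuffled = "".join(sorted(residues))
        assert column_entropy(col) == pytest.approx(column_entropy(shuffled))
        assert column_entropy(col * 3) == pytest.approx(column_entropy(col))


class TestHydrophobicFraction:
    @pytest.mark.parametrize(
        "column,expected",
        [("VVLL", 100.0), ("VVSS", 50.0), ("V-SS", 100.0 / 3), ("----", 0.0)],
    )
    def test_values(self, column, expected):
        assert hydrophobic_fraction(column) == pytest.approx(expected)


class TestProfileAlignment:
    def test_columnwise_entropies(self):
        aln = Alignment(records=[AlignedSeq("a", "", "AAA"), AlignedSeq("b", "", "AAC")])
        profile = profile_alignment(aln)
        assert profile.entropy == pytest.approx([0.0, 0.0, 1.0])
        assert list(profile.n_obs) == [2, 2, 2]

    def test_profile_matches_per_column_function(self, small_sim):
        _, _, alignments, _ = (None, *small_sim[1:])
        aln = next(iter(small_sim[2].values()))
        profile = profile_alignment(aln)
        cols = ["".join(r.seq[j] for r in aln.records) for j in range(aln.length)]
        sample = np.linspace(0, aln.length - 1, 25, dtype=int)
        for j in sample:
            assert profile.entropy[j] == pytest.approx(column_entropy(cols[j]))
            assert profile.hydrophobic_fraction[j] == pytest.approx(
                hydrophobic_fraction(cols[j])
            )

    def test_invariant_to_sequence_shuffle_and_duplication(self):
        aln = aln_from_columns(["AACC", "GGGT", "W-Y-"])
        base = profile_alignment(aln)
        shuffled = Alignment(records=list(reversed(aln.records)))
        doubled = Alignment(records=[
            AlignedSeq(f"{r.id}{tag}", "", r.seq)
            for tag in ("", "_dup") for r in aln.records
        ])
        for other in (shuffled, doubled):
            assert profile_alignment(other).entropy == pytest.approx(base.entropy)

    def test_gap_only_sequence_changes_nothing(self):
        aln = aln_from_columns(["AACC", "GGGT"])
        plus_gaps = Alignment(
            records=aln.records + [AlignedSeq("gapper", "", "-" * aln.length)]
        )
        assert profile_alignment(plus_gaps).entropy == pytest.approx(
            profile_alignment(aln).entropy
        )


class TestMaskGappyColumns:
    def test_boundary_is_inclusive(self):
        # column 1: 9/10 gaps (masked at 0.90); column 2: 8/10 gaps (kept)
        cols = ["-" * 9 + "A", "-" * 8 + "AC", "A" * 10]
        aln = aln_from_columns(cols)
        masked, cmap = mask_gappy_columns(aln, 0.90)
        assert masked.length == 2
        assert cmap == {1: 2, 2: 3}

    def test_fraction_above_one_is_identity(self):
        aln = aln_from_columns(["----", "AAAA"])
        masked, cmap = mask_gappy_columns(aln, 1.01)
        assert masked.length == aln.length
        assert cmap == {1: 1, 2: 2}

    def test_all_masked_errors(self):
        aln = aln_from_columns(["----"])
        with pytest.raises(InputError):
            mask_gappy_columns(aln, 0.5)


class TestClassifyHv:
    def make_profile(self, n_high, high_bits=1.585, n_total=50):
        # columns of 3 equiprobable residues give ~1.585 bits >= 1.5
        high = ["ACD" * 4] * n_high
        low = ["AAAA" * 3] * (n_total - n_high)
        return profile_alignment(aln_from_columns(high + low))

    def test_boundary_ten_positions(self):
        assert classify_hv(self.make_profile(10))[0] is True
        assert classify_hv(self.make_profile(9))[0] is False

    def test_all_zero_profile(self):
        profile = profile_alignment(aln_from_columns(["AAAA"] * 5))
        is_hv, positions = classify_hv(profile)
        assert is_hv is False and positions == []

    def test_positions_ascending(self):
        profile = self.make_profile(12)
        _, positions = classify_hv(profile)
        assert positions == sorted(positions)

    def test_monotone_in_criteria(self):
        profile = self.make_profile(10)
        assert classify_hv(profile, HvCriteria())[0]
        assert not classify_hv(profile, HvCriteria(min_positions=11))[0]
        assert not classify_hv(profile, HvCriteria(entropy_cutoff=2.0))[0]


class TestCountHvByDomain:
    def _alignment(self):
        # 60-residue reference: preNB 1-10, LRR 21-60; hv columns at 30, 40
        ref = "A" * 60
        variant = "A" * 29 + "C" + "A" * 9 + "D" + "A" * 20
        variant2 = "A" * 29 + "G" + "A" * 9 + "W" + "A" * 20
        variant3 = "A" * 29 + "W" + "A" * 9 + "C" + "A" * 20
        return Alignment(
            records=[
                AlignedSeq("ref", "", ref),
                AlignedSeq("v1", "", variant),
                AlignedSeq("v2", "", variant2),
                AlignedSeq("v3", "", variant3),
            ],
            reference_id="ref",
            domains=[("preNB", 1, 10), ("LRR", 21, 60)],
        )

    def test_hand_count_in_lrr(self):
        aln = self._alignment()
        profile = profile_alignment(aln)
        table = count_hv_by_domain(profile, aln).set_index("domain")
        assert table.loc["LRR", "n_hv"] == 2
        assert table.loc["LRR", "pct_of_domain"] == pytest.approx(5.0)

    def test_no_hv_columns(self):
        aln = Alignment(
            records=[AlignedSeq("ref", "", "A" * 30), AlignedSeq("s", "", "A" * 30)],
            reference_id="ref",
            domains=[("preNB", 1, 10), ("LRR", 11, 30)],
        )
        table = count_hv_by_domain(profile_alignment(aln), aln)
        assert (table["n_hv"] == 0).all()

    def test_column_before_all_domains_goes_to_preNB(self):
        # hv column at reference residue 2; only an LRR interval annotated
        cols = ["AAAA", "ACDW", "AAAA", "AAAA", "AAAA", "AAAA"]
        aln = aln_from_columns(cols)
        aln = Alignment(
            records=aln.records, reference_id="s0", domains=[("LRR", 4, 6)]
        )
        profile = profile_alignment(aln)
        table = count_hv_by_domain(profile, aln).set_index("domain")
        assert table.loc["preNB", "n_hv"] == 1

    def test_missing_domains_rejected(self):
        aln = aln_from_columns(["AAAA"])
        with pytest.raises(InputError):
            count_hv_by_domain(profile_alignment(aln), aln)
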