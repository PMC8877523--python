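"""Charge-sequence parsing, descriptors, enumeration and sampling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polytrans.sequences import (
    ChargeMapping,
    ChargeSequence,
    SequenceError,
    enumerate_charge_matrix,
    enumerate_sequences,
    enumerate_with_charge,
    format_sequence,
    parse_sequence,
    read_sequence_file,
    reduce_protein,
    sample_sequences,
    write_sequence_file,
)


class TestParsing:
    def test_token_mapping(self):
        assert parse_sequence("11-111").charges == (1, 1, -1, 1, 1)

    def test_whitespace_ignored(self):
        assert parse_sequence(" 1 1-1\t11 ").charges == (1, 1, -1, 1, 1)

    @pytest.mark.parametrize(
        "text, n, q",
        [
            ("11-111-111-111-111-111-111", 20, 8),  # regular benchmark sequence
            ("11-1111-1-11 -111-1-111", 16, 4),  # IN reduction, stray space
        ],
    )
    def test_benchmark_strings(self, text, n, q):
        seq = parse_sequence(text)
        assert seq.N == n
        assert seq.Q == q

    def test_regular_sequence_antagonistic_count(self):
        seq = parse_sequence("11-111-111-111-111-111-111")
        assert sum(1 for c in seq if c == -1) == 6

    @pytest.mark.parametrize("bad", ["11-11-", "11-1x1", "11--111", "2111-1"])
    def test_malformed_inputs_rejected(self, bad):
        with pytest.raises(SequenceError):
            parse_sequence(bad)

    def test_error_names_position(self):
        with pytest.raises(SequenceError, match="position 4"):
            parse_sequence("1111x1")

    def test_too_short_rejected(self):
        with pytest.raises(SequenceError):
            parse_sequence("11-1")

    @given(st.lists(st.sampled_from([-1, 1]), min_size=5, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_format_parse_round_trip(self, charges):
        seq = ChargeSequence(tuple(charges))
        assert parse_sequence(format_sequence(seq)).charges == seq.charges


class TestDescriptors:
    def test_net_charge_all_favorable(self):
        assert ChargeSequence((1,) * 20).Q == 20

    def test_head_charge_of_benchmark_rows(self, bench):
        for record in bench.values():
            assert record.sequence.head_charge() == record.Qh

    def test_min_window_charge_of_benchmark_rows(self, bench):
        for record in bench.values():
            assert record.sequence.min_window_charge() == record.Qmin

    def test_head_charge_all_negative(self):
        assert ChargeSequence((-1,) * 20).head_charge() == -5

    def test_min_window_all_favorable_is_window(self):
        assert ChargeSequence((1,) * 9).min_window_charge(window=5) == 5

    def test_window_larger_than_sequence_errors(self):
        with pytest.raises(SequenceError):
            ChargeSequence((1,) * 6).head_charge(window=7)

    def test_qmin_bounded_by_qh(self, random_sequences):
        for seq in random_sequences:
            assert seq.min_window_charge() <= seq.head_charge()

    def test_reverse_is_involution_and_flips_head(self, random_sequences):
        for seq in random_sequences:
            rev = seq.reverse()
            assert rev.reverse().charges == seq.charges
            assert rev.head_charge() == sum(seq.charges[-5:])

    def test_reverse_of_benchmark_pairs(self, bench):
        assert bench["c"].sequence.charges == bench["b"].sequence.reverse().charges
        assert bench["i"].sequence.charges == bench["h"].sequence.reverse().charges


class TestEnumeration:
    def test_small_enumeration_complete_and_distinct(self):
        seqs = list(enumerate_sequences(5))
        assert len(seqs) == 32
        assert len({s.charges for s in seqs}) == 32

    def test_refuses_oversized_enumeration(self):
        with pytest.raises(SequenceError):
            list(enumerate_sequences(25))

    def test_neutral_charge_count_matches_binomial(self):
        # brute-force count of Q = 0 sequences over the full N = 16 space
        mat = enumerate_charge_matrix(16)
        assert mat.shape == (65536, 16)
        q = mat.sum(axis=1, dtype=np.int64)
        assert int((q == 0).sum()) == math.comb(16, 8)

    def test_full_space_size_n20(self):
        assert enumerate_charge_matrix(20).shape[0] == 2**20

    def test_fixed_charge_subensemble_size(self):
        subs = enumerate_with_charge(20, 16)
        assert len(subs) == math.comb(20, 2) == 190
        assert all(s.Q == 16 for s in subs)

    def test_infeasible_charge_rejected(self):
        with pytest.raises(SequenceError):
            enumerate_with_charge(20, 15)  # parity violation


class TestSampling:
    def test_same_seed_reproduces(self):
        a = sample_sequences(20, 50, seed=5)
        b = sample_sequences(20, 50, seed=5)
        assert [s.charges for s in a] == [s.charges for s in b]

    def test_unconstrained_mean_charge_near_zero(self):
        seqs = sample_sequences(20, 1000, seed=7)
        mean_q = np.mean([s.Q for s in seqs])
        assert abs(mean_q) < 3 * math.sqrt(20 / 1000)

    def test_constrained_composition_exact(self):
        seqs = sample_sequences(20, 200, seed=8, Q=10)
        assert all(sum(1 for c in s if c == 1) == 15 for s in seqs)

    def test_infeasible_constraint_errors(self):
        with pytest.raises(SequenceError):
            sample_sequences(20, 5, seed=0, Q=11)


class TestProteinReduction:
    def test_basic_mapping(self):
        seq = reduce_protein("MKDAEKR", favorable_sign=1)
        assert seq.charges == (1, -1, -1, 1, 1)

    def test_favorable_sign_flip(self):
        # acidic-majority protein driven as an anion: 10 acidic + 6 basic
        aa = "DDDDDDDDDD" + "KKKKKK"
        seq = reduce_protein(aa, favorable_sign=-1)
        assert seq.N == 16
        assert seq.Q == 4  # net physical charge -4 becomes +4 in favorable units

    def test_histidine_dropped_by_default_but_configurable(self):
        with pytest.raises(SequenceError):
            reduce_protein("HAHAHAH")  # everything dropped -> too short
        mapping = ChargeMapping().with_histidine(1)
        assert reduce_protein("HDHDHDHDH", mapping=mapping).Q == 1

    def test_unknown_residue_listed(self):
        with pytest.raises(SequenceError, match="B"):
            reduce_protein("KDBEK")

    def test_empty_charged_set_errors(self):
        with pytest.raises(SequenceError):
            reduce_protein("GGGGGG")


class TestSequenceFiles:
    def test_round_trip_with_ids_and_comments(self, tmp_path, bench):
        path = tmp_path / "seqs.txt"
        seqs = [r.sequence for r in bench.values()]
        write_sequence_file(path, seqs, header="benchmark set")
        back = read_sequence_file(path)
        assert [s.charges for s in back] == [s.charges for s in seqs]
        assert [s.id for s in back] == [s.id for s in seqs]

    def test_error_reports_file_line(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("ok\t11-111\nbad\t11-1x\n")
        with pytest.raises(SequenceError, match="bad.txt:2"):
            read_sequence_file(path)
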