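"""Unit and property tests for the 2-bit encoding layer."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqops import (
    AmbiguousBaseError,
    DnaSequence,
    KmerValue,
    build_tables,
    decode_kmer,
    encode_kmer,
    reverse_kmer,
    revcomp_kmer,
    revcomp_seq,
)
from conftest import random_dna
from oracles import arithmetic_encode, string_revcomp

dna = st.text(alphabet="ACGT", min_size=1, max_size=64)


class TestTables:
    def test_bit2base_is_a_bijection_on_two_bits(self):
        t = build_tables()
        assert sorted(t.bit2base) == ["A", "C", "G", "T"]

    def test_rc4_is_an_involution(self):
        t = build_tables()
        assert all(t.rc4[t.rc4[i]] == i for i in range(256))

    def test_base2bit_inverts_bit2base(self):
        t = build_tables()
        for code in range(4):
            assert t.base2bit[ord(t.bit2base[code])] == code

    def test_non_nucleotide_bytes_are_invalid(self):
        t = build_tables()
        for ch in "XNU*>@ \n0":
            assert t.base2bit[ord(ch)] == 0xFF

    def test_complement_constraint_on_base_map(self):
        # f(A) = ~f(T) and f(C) = ~f(G) over two bits
        t = build_tables()
        f = {b: int(t.base2bit[ord(b)]) for b in "ACGT"}
        assert f["A"] == ~f["T"] & 0b11
        assert f["C"] == ~f["G"] & 0b11


class TestEncodeDecode:
    @pytest.mark.parametrize(
        "s,code", [("A", 0), ("ACGT", 27), ("T", 3), ("GATTACA", 9156)]
    )
    def test_encode_matches_positional_arithmetic(self, s, code):
        assert arithmetic_encode(s) == code  # frozen from the oracle
        assert encode_kmer(s).code == code

    @pytest.mark.parametrize("bad", ["ACGN", "ACGX", "acgn"])
    def test_ambiguous_base_rejected(self, bad):
        with pytest.raises(AmbiguousBaseError):
            encode_kmer(bad, 4)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            encode_kmer("ACG", 4)

    def test_lowercase_normalized(self):
        assert encode_kmer("acgt") == encode_kmer("ACGT")

    @pytest.mark.parametrize("s", ["GATTACA", "A", "ACGT"])
    def test_round_trip(self, s):
        assert decode_kmer(encode_kmer(s)) == s

    def test_decode_examples(self):
        assert decode_kmer(KmerValue(k=1, code=0)) == "A"
        assert decode_kmer(KmerValue(k=4, code=27)) == "ACGT"

    def test_kmer_value_invariants(self):
        with pytest.raises(ValueError):
            KmerValue(k=0, code=0)
        with pytest.raises(ValueError):
            KmerValue(k=1025, code=0)
        with pytest.raises(ValueError):
            KmerValue(k=2, code=16)

    @given(dna)
    @settings(derandomize=True, max_examples=200)
    def test_round_trip_property(self, s):
        assert decode_kmer(encode_kmer(s)) == s

    @given(dna, dna)
    @settings(derandomize=True, max_examples=200)
    def test_code_order_is_lexicographic(self, u, v):
        # pad to equal length so integer comparison is meaningful
        n = max(len(u), len(v))
        u, v = u.ljust(n, "A"), v.ljust(n, "A")
        assert (encode_kmer(u).code < encode_kmer(v).code) == (u < v)

    def test_wide_kmers_round_trip(self, rng):
        for k in (7, 33, 100, 511, 1024):
            s = random_dna(rng, k)
            assert decode_kmer(encode_kmer(s)) == s


class TestRevcompReverse:
    @pytest.mark.parametrize(
        "s,expected",
        [("ACGT", "ACGT"), ("AACC", "GGTT"), ("ACGTA", "TACGT"), ("GATTACA", "TGTAATC")],
    )
    def test_revcomp_against_string_oracle(self, s, expected):
        assert string_revcomp(s) == expected
        assert decode_kmer(revcomp_kmer(encode_kmer(s))) == expected

    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5, 6, 7, 8, 9, 63, 64, 65])
    def test_padding_paths_all_k_mod_4(self, k, rng):
        s = random_dna(rng, k)
        assert decode_kmer(revcomp_kmer(encode_kmer(s))) == string_revcomp(s)

    @given(dna)
    @settings(derandomize=True, max_examples=300)
    def test_revcomp_involution(self, s):
        km = encode_kmer(s)
        assert revcomp_kmer(revcomp_kmer(km)) == km

    @pytest.mark.parametrize(
        "s,expected", [("ACGT", "TGCA"), ("AA", "AA"), ("ACGTA", "ATGCA")]
    )
    def test_reverse_decodes_to_reversed_string(self, s, expected):
        assert s[::-1] == expected
        assert decode_kmer(reverse_kmer(encode_kmer(s))) == expected

    @given(dna)
    @settings(derandomize=True, max_examples=300)
    def test_reverse_is_bit_inverted_revcomp(self, s):
        km = encode_kmer(s)
        mask = (1 << (2 * km.k)) - 1
        assert reverse_kmer(km).code == ~revcomp_kmer(km).code & mask


class TestSequenceLevel:
    @pytest.mark.parametrize(
        "s,expected", [("A", "T"), ("ACGT", "ACGT"), ("ANT", "ANT"), ("", "")]
    )
    def test_revcomp_seq(self, s, expected):
        assert revcomp_seq(s) == expected

    def test_dna_sequence_validates_and_normalizes(self):
        assert DnaSequence("acgTn") == "ACGTN"
        with pytest.raises(ValueError):
            DnaSequence("ACGU")
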