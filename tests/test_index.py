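"""Unit and property tests for the k-mer seeding index."""

import io
from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqops import (
    FastqRecord,
    DnaSequence,
    KmerValue,
    build_index,
    decode_kmer,
    encode_kmer,
    generate_reference,
    revcomp_seq,
    seed_reads,
)
from seqops.index import KmerIndex
from conftest import random_dna
from oracles import BruteIndex

reference = st.text(alphabet="ACGTN", min_size=8, max_size=200)


class TestBuildAndLookup:
    def test_positions_by_hand(self):
        ix = build_index("ACGTACGTAC", k=4)
        assert ix.lookup(encode_kmer("ACGT")) == [0, 4]
        assert ix.lookup(encode_kmer("CGTA")) == [1, 5]

    def test_single_window(self):
        ix = build_index("AAAA", k=4)
        assert ix.lookup(encode_kmer("AAAA")) == [0]

    def test_absent_kmer(self):
        ix = build_index("AAAA", k=4)
        assert ix.lookup(encode_kmer("TTTT")) == []

    def test_n_windows_are_absent(self):
        ix = build_index("ACGNACG", k=3)
        assert ix.lookup(encode_kmer("ACG")) == [0, 4]
        assert sum(len(v) for v in ix.entries.values()) == 2

    def test_reference_too_short(self):
        with pytest.raises(ValueError):
            build_index("ACG", k=4)

    def test_k_mismatch(self):
        ix = build_index("ACGTACGT", k=4)
        with pytest.raises(ValueError):
            ix.lookup(encode_kmer("ACG"))
        with pytest.raises(ValueError):
            ix.prefetch(encode_kmer("ACG"))

    def test_multi_contig_offsets(self):
        ix = build_index([("c1", "ACGTA"), ("c2", "TTTT")], k=4)
        assert ix.contig_offsets == {"c1": 0, "c2": 5}
        assert ix.lookup(encode_kmer("TTTT")) == [5]

    @given(reference)
    @settings(derandomize=True, max_examples=100)
    def test_matches_naive_string_scan(self, ref):
        k = 4
        if len(ref) < k:
            return
        ix = build_index(ref, k=k)
        brute = BruteIndex(ref, k)
        for code, positions in ix.entries.items():
            w = str(decode_kmer(KmerValue(k=k, code=code)))
            assert brute.table.get(w, []) == positions

    @given(reference)
    @settings(derandomize=True, max_examples=100)
    def test_self_consistency(self, ref):
        k = 5
        if len(ref) < k:
            return
        ix = build_index(ref, k=k)
        for code, positions in ix.entries.items():
            for p in positions:
                assert 0 <= p <= ix.reference_length - k
                assert encode_kmer(ref[p : p + k].upper()).code == code


class TestPrefetchProtocol:
    def test_prefetch_is_semantically_inert(self):
        ix = build_index("ACGTACGTAC", k=4)
        km = encode_kmer("ACGT")
        ix.prefetch(km)
        assert ix.lookup(km) == [0, 4]
        assert ix.prefetch_counter == 1 and ix.access_counter == 1

    def test_counters_per_task(self):
        ix = build_index(generate_reference(500, seed=7), k=6)
        reads = [("r%d" % i, generate_reference(30, seed=100 + i)) for i in range(40)]
        before = ix.prefetch_counter
        list(seed_reads(ix, reads, step=1, prefetch=True, M=8))
        assert ix.prefetch_counter - before == len(reads)  # one hint per task


class TestSeeding:
    def test_hand_counted_example(self):
        ix = build_index("ACGTACGTAC", k=4)
        (rep,) = seed_reads(ix, [("r1", "ACGTACGT")], step=1)
        # windows ACGT,CGTA,GTAC,TACG,ACGT -> 2+2+2+1+2
        assert rep.hits_forward == 9

    def test_all_n_read(self):
        ix = build_index("ACGTACGTAC", k=4)
        (rep,) = seed_reads(ix, [("r1", "NNNNNNNN")], step=1)
        assert rep.hits_forward == rep.hits_reverse == 0

    def test_default_step_is_k(self):
        ix = build_index("ACGTACGTAC", k=4)
        (rep,) = seed_reads(ix, [("r1", "ACGTACGT")], step=None)
        # non-overlapping windows ACGT, ACGT -> 2 + 2
        assert rep.hits_forward == 4

    def test_accepts_fastq_records(self):
        ix = build_index("ACGTACGTAC", k=4)
        rec = FastqRecord(name="q", seq=DnaSequence("ACGT"), qual="IIII")
        (rep,) = seed_reads(ix, [rec], step=1)
        assert rep.name == "q" and rep.hits_forward == 2

    def test_prefetch_multiset_equivalence(self, rng):
        ref = generate_reference(2000, seed=11)
        ix = build_index(ref, k=6)
        reads = [("r%d" % i, random_dna(rng, 40)) for i in range(300)]
        serial = [(r.name, r.hits_forward, r.hits_reverse) for r in seed_reads(ix, reads, step=1)]
        sched = [
            (r.name, r.hits_forward, r.hits_reverse)
            for r in seed_reads(ix, reads, step=1, prefetch=True, M=16)
        ]
        assert Counter(serial) == Counter(sched)

    def test_reverse_symmetry(self, rng):
        ref = generate_reference(3000, seed=5)
        ix = build_index(ref, k=5)
        for _ in range(30):
            read = random_dna(rng, 25)
            (fwd,) = seed_reads(ix, [("a", read)], step=1)
            (rev,) = seed_reads(ix, [("b", str(revcomp_seq(read)))], step=1)
            assert fwd.hits_reverse == rev.hits_forward
            assert fwd.hits_forward == rev.hits_reverse


class TestPersistence:
    def test_round_trip(self):
        ix = build_index(generate_reference(300, seed=3), k=6)
        buf = io.StringIO()
        ix.save(buf)
        buf.seek(0)
        loaded = KmerIndex.load(buf)
        assert loaded.k == ix.k
        assert loaded.reference_length == ix.reference_length
        assert loaded.entries == ix.entries

    def test_bad_header_rejected(self):
        with pytest.raises(ValueError):
            KmerIndex.load(io.StringIO("garbage\n"))
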