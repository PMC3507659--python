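"""Counting phase, partial sums, partitioned insertion, bucket sorting."""

import numpy as np
import pytest

from spmgraph.kmercodes import KmerConfig, phi_code
from spmgraph.readset import EncodedReadSet, encode, prefilter
from spmgraph.spmindex import (
    BufferConfig,
    CountTable,
    IndexConsistencyError,
    build_sorted_buckets,
    collect_initial_kmers,
    compute_partial_sums,
    counting_phase,
    dedup_and_count,
    enumerate_candidate_suffixes,
    insertion_phase,
    plan_partitions,
    sort_bucket,
)
from conftest import simulated_read_set

TRIO = ["TGGACGT", "GGACGTAA", "ACGTAACC"]
CFG4 = KmerConfig(k=4, k_prime=4, k_dbl_prime=3)


@pytest.fixture
def trio_E():
    return EncodedReadSet(TRIO)


def brute_force_relevant_suffixes(seqs, l_min, k, both_strands=True):
    """Oracle: whole reads plus proper suffixes of length >= l_min whose
    initial k-mer equals some strand's initial k-mer."""
    from spmgraph.readset import revcomp

    strands = list(seqs) + ([revcomp(s) for s in seqs] if both_strands else [])
    initial = {s[:k] for s in strands}
    out = set()
    for i, s in enumerate(strands, start=1):
        out.add((i, 0))
        for q in range(1, len(s) - l_min + 1):
            if s[q : q + k] in initial:
                out.add((i, q))
    return out


class TestKeyTables:
    def test_trio_initial_kmers(self, trio_E):
        codes = collect_initial_kmers(trio_E, CFG4, both_strands=False)
        assert codes.tolist() == sorted(phi_code(s[:4], 4) for s in TRIO)

    def test_one_read_two_strands(self):
        E = EncodedReadSet(["AACGT"])
        codes = collect_initial_kmers(E, KmerConfig(k=3, k_prime=3, k_dbl_prime=2))
        assert codes.size == 2
        assert sorted(codes.tolist()) == sorted([phi_code("AAC", 3), phi_code("ACG", 3)])

    def test_dedup_and_count(self):
        K, C, P, Q = dedup_and_count(np.array([5, 5, 9], dtype=np.uint64), CFG4)
        assert K.K.tolist() == [5, 9]
        assert C.C.tolist() == [2, 1]

    def test_trio_dedup(self, trio_E):
        codes = collect_initial_kmers(trio_E, CFG4, both_strands=False)
        K, C, _, _ = dedup_and_count(codes, CFG4)
        assert K.d == 3
        assert C.C.tolist() == [1, 1, 1]


class TestCandidates:
    def test_offset_range(self):
        # |r| - l_min candidate offsets, starting at 1
        E = EncodedReadSet(["AACGT"])
        cfg = KmerConfig(k=3, k_prime=3, k_dbl_prime=2)
        codes = collect_initial_kmers(E, cfg)
        _, _, P, Q = dedup_and_count(codes, cfg)
        got = {(s, q) for s, q, _ in enumerate_candidate_suffixes(E, P, Q, 3, cfg)}
        assert all(1 <= q <= E.length(s) - 3 for s, q in got)

    def test_read_at_minimum_length_has_no_candidates(self):
        E = EncodedReadSet(["ACGT"])
        cfg = KmerConfig(k=4, k_prime=2, k_dbl_prime=2)
        codes = collect_initial_kmers(E, cfg)
        _, _, P, Q = dedup_and_count(codes, cfg)
        assert list(enumerate_candidate_suffixes(E, P, Q, 4, cfg)) == []


class TestCountingPhase:
    def test_trio_counts(self, trio_E):
        codes = collect_initial_kmers(trio_E, CFG4, both_strands=False)
        K, C0, P, Q = dedup_and_count(codes, CFG4)
        C = counting_phase(trio_E, K, C0, P, Q, 4, CFG4, both_strands=False)
        by_mer = dict(zip(K.K.tolist(), C.C.tolist()))
        # matching candidates: r@1, r@3 and s@2 (initial 4-mers GGAC, ACGT, ACGT)
        assert by_mer[phi_code("ACGT", 4)] == 3
        assert by_mer[phi_code("GGAC", 4)] == 2
        assert by_mer[phi_code("TGGA", 4)] == 1

    def test_no_candidates_leaves_counts(self):
        E = EncodedReadSet(["ACGT", "TTTT"])
        cfg = KmerConfig(k=4, k_prime=2, k_dbl_prime=2)
        codes = collect_initial_kmers(E, cfg)
        K, C0, P, Q = dedup_and_count(codes, cfg)
        C = counting_phase(E, K, C0, P, Q, 4, cfg)
        assert C.C.tolist() == C0.C.tolist()

    @pytest.mark.parametrize("floor", [1, 7, 10**6])
    def test_batching_invariance(self, floor):
        _, reads = simulated_read_set(3, l_min=15)
        E, _ = prefilter(encode(reads, 15))
        cfg = KmerConfig(k=8, k_prime=6, k_dbl_prime=5)
        codes = collect_initial_kmers(E, cfg)
        K, C0, P, Q = dedup_and_count(codes, cfg)
        ref = counting_phase(E, K, C0, P, Q, 15, cfg)
        got = counting_phase(E, K, C0, P, Q, 15, cfg, buf=BufferConfig(floor=floor))
        assert got.C.tolist() == ref.C.tolist()


class TestPartialSums:
    def test_printed_recurrence(self):
        ps = compute_partial_sums(CountTable(np.array([3, 1, 1])))
        assert ps.pi.tolist() == [3, 4, 5, 5]
        assert ps.g == 5

    def test_single_bucket(self):
        ps = compute_partial_sums(CountTable(np.array([1])))
        assert ps.pi.tolist() == [1, 1]

    def test_total_consistency(self):
        C = np.array([2, 5, 1, 3])
        ps = compute_partial_sums(CountTable(C))
        assert ps.g == C.sum()
        assert [ps.bucket_bounds(i) for i in range(4)] == [(0, 2), (2, 7), (7, 8), (8, 11)]


class TestInsertion:
    def _index(self, E, cfg, l_min, both=False):
        codes = collect_initial_kmers(E, cfg, both)
        K, C0, P, Q = dedup_and_count(codes, cfg)
        C = counting_phase(E, K, C0, P, Q, l_min, cfg, both_strands=both)
        return K, P, Q, compute_partial_sums(C)

    def test_trio_buckets(self, trio_E):
        K, P, Q, ps = self._index(trio_E, CFG4, 4)
        seg_s, seg_q, base = insertion_phase(trio_E, K, ps, P, Q, 4, CFG4, both_strands=False)
        assert base == 0
        buckets = {}
        for i in range(K.d):
            s0, s1 = ps.bucket_bounds(i)
            buckets[int(K.K[i])] = {(int(a), int(b)) for a, b in zip(seg_s[s0:s1], seg_q[s0:s1])}
        assert buckets[phi_code("ACGT", 4)] == {(3, 0), (1, 3), (2, 2)}
        assert buckets[phi_code("GGAC", 4)] == {(2, 0), (1, 1)}
        assert buckets[phi_code("TGGA", 4)] == {(1, 0)}

    def test_underfill_detected(self, trio_E):
        K, P, Q, ps = self._index(trio_E, CFG4, 4)
        ps.pi += 1  # corrupt the cumulative sums
        with pytest.raises(IndexConsistencyError):
            insertion_phase(trio_E, K, ps, P, Q, 4, CFG4, both_strands=False)

    def test_content_matches_brute_force(self):
        for seed in (0, 1, 2):
            _, reads = simulated_read_set(seed, l_min=15)
            E, _ = prefilter(encode(reads, 15))
            cfg = KmerConfig(k=8, k_prime=6, k_dbl_prime=5)
            buckets = build_sorted_buckets(E, 15, cfg)
            got = {
                (int(s), int(q))
                for b in buckets
                for s, q in zip(b.strands, b.offsets)
            }
            want = brute_force_relevant_suffixes(E.forward_sequences(), 15, 8)
            assert got == want

    @pytest.mark.parametrize("q", [2, 3, 7])
    def test_partition_invariance(self, q):
        _, reads = simulated_read_set(5, l_min=15)
        E, _ = prefilter(encode(reads, 15))
        cfg = KmerConfig(k=8, k_prime=6, k_dbl_prime=5)
        ref = build_sorted_buckets(E, 15, cfg, q_parts=1)
        got = build_sorted_buckets(E, 15, cfg, q_parts=q)
        assert len(got) == len(ref)
        for a, b in zip(got, ref):
            assert a.key_code == b.key_code
            assert a.strands.tolist() == b.strands.tolist()
            assert a.offsets.tolist() == b.offsets.tolist()
            assert a.L.tolist() == b.L.tolist()

    def test_memory_limit_partitioning(self):
        _, reads = simulated_read_set(6, l_min=15)
        E, _ = prefilter(encode(reads, 15))
        cfg = KmerConfig(k=8, k_prime=6, k_dbl_prime=5)
        ref = build_sorted_buckets(E, 15, cfg, q_parts=1)
        got = build_sorted_buckets(E, 15, cfg, memory_limit=4096)
        assert [b.key_code for b in got] == [b.key_code for b in ref]
        assert all(a.strands.tolist() == b.strands.tolist() for a, b in zip(got, ref))

    def test_memory_limit_below_bucket_size_rejected(self, trio_E):
        K, P, Q, ps = self._index(trio_E, CFG4, 4)
        with pytest.raises(ValueError, match="memory limit"):
            plan_partitions(K, ps, memory_limit=1)


class TestPlanPartitions:
    def _tables(self, sizes):
        K = np.arange(len(sizes), dtype=np.uint64)
        from spmgraph.spmindex import KmerTable

        ps = compute_partial_sums(CountTable(np.asarray(sizes)))
        return KmerTable(K), ps

    def test_single_part_covers_everything(self):
        K, ps = self._tables([3, 1, 4])
        part = plan_partitions(K, ps, q_parts=1)
        assert part.q == 1
        assert (part.parts[0].lo_idx, part.parts[0].hi_idx) == (0, 3)

    def test_balance(self):
        K, ps = self._tables([10] * 10)
        part = plan_partitions(K, ps, q_parts=2)
        assert part.q == 2
        loads = [sum(10 for _ in range(p.lo_idx, p.hi_idx)) for p in part.parts]
        assert max(loads) <= 50 + 10

    def test_one_part_per_bucket(self):
        K, ps = self._tables([2, 3, 4])
        part = plan_partitions(K, ps, q_parts=3)
        assert [(p.lo_idx, p.hi_idx) for p in part.parts] == [(0, 1), (1, 2), (2, 3)]


class TestSortBucket:
    def test_trio_acgt_bucket(self, trio_E):
        strands = np.array([3, 1, 2])
        offsets = np.array([0, 3, 2])
        b = sort_bucket(trio_E, strands, offsets, 4, phi_code("ACGT", 4))
        # C < sentinel makes the longer suffix smaller
        assert list(zip(b.strands.tolist(), b.offsets.tolist())) == [(3, 0), (2, 2), (1, 3)]
        assert b.L.tolist() == [6, 4]
        assert b.suffix_lengths.tolist() == [8, 6, 4]

    def test_singleton(self, trio_E):
        b = sort_bucket(trio_E, np.array([1]), np.array([0]), 4, phi_code("TGGA", 4))
        assert b.beta == 1 and b.L.size == 0

    def test_equal_remainders_tie_by_strand(self):
        E = EncodedReadSet(["ACGTT", "ACGTT"])  # identical suffixes from 2 reads
        b = sort_bucket(E, np.array([2, 1]), np.array([0, 0]), 4, phi_code("ACGT", 4))
        assert b.strands.tolist() == [1, 2]
        assert b.L.tolist() == [5]  # full suffix length
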