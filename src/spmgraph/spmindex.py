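"""Identification, bucketing and sorting of SPM-relevant suffixes.

An *(l_min, k)-SPM-relevant suffix* is either a whole read (offset 0) or a
proper suffix of length >= l_min whose initial k-mer equals the initial
k-mer of some read.  The module follows a counting-sort strategy:

1. *counting phase* -- the distinct initial k-mers of all strands form the
   sorted key table K; a buffered scan over all candidate suffixes counts,
   per key, how many SPM-relevant suffixes start with it (table C);
2. *partial sums* -- C is turned into the cumulative table pi, which both
   addresses the buckets and provides the decrementing insertion cursors;
3. *insertion phase* -- a second buffered scan places every SPM-relevant
   suffix (read number, read offset) into its bucket of the suffix store S;
4. per bucket, the remaining suffixes (beyond the shared initial k-mer) are
   sorted under the virtual-sentinel order and the lcp table L is computed
   as a byproduct.

The key/bucket tables can be tiled into q contiguous code-range parts that
are processed independently (each part re-scans the read set); the final
bucket contents are invariant under the choice of q.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .kmercodes import BitFilter, KmerConfig, build_filters, window_code_matrix
from .readset import SENTINEL, EncodedReadSet, _lcp

logger = logging.getLogger(__name__)


class IndexConsistencyError(RuntimeError):
    """Counting and insertion phases disagree about bucket occupancy."""


# ---------------------------------------------------------------------------
# Table types
# ---------------------------------------------------------------------------

@dataclass
class KmerTable:
    """Sorted distinct initial k-mer codes of all strands."""

    K: np.ndarray  # uint64, strictly increasing

    @property
    def d(self) -> int:
        return int(self.K.size)


@dataclass
class CountTable:
    """Per-key counts; after the counting phase C[i] is the number of
    SPM-relevant suffixes whose initial k-mer is K[i]."""

    C: np.ndarray  # int64, size d


@dataclass
class PartialSums:
    """Inclusive cumulative sums of C: pi[0] = C[0], pi[i] = pi[i-1] + C[i]
    for 1 <= i <= d-1, and pi[d] = pi[d-1].  Bucket i occupies the slice
    [pi[i-1], pi[i]) of the suffix store, with pi[-1] taken as 0; pi[d] is
    g, the total number of SPM-relevant suffixes."""

    pi: np.ndarray  # int64, size d+1

    @property
    def g(self) -> int:
        return int(self.pi[-1])

    @property
    def d(self) -> int:
        return int(self.pi.size - 1)

    def bucket_bounds(self, i: int) -> tuple[int, int]:
        start = 0 if i == 0 else int(self.pi[i - 1])
        return start, int(self.pi[i])

    def bucket_sizes(self) -> np.ndarray:
        ends = self.pi[: self.d]
        starts = np.concatenate([[0], ends[:-1]])
        return ends - starts


@dataclass(frozen=True)
class BufferConfig:
    """Capacity policy for the counting/insertion buffers (b = max(floor,
    d/gamma)); results are invariant under the capacity, only the batching
    changes."""

    gamma: float = 4.0
    floor: int = 1024

    def __post_init__(self):
        if self.gamma <= 1.0:
            raise ValueError("gamma must be > 1")
        if self.floor < 1:
            raise ValueError("floor must be >= 1")

    def capacity(self, d: int) -> int:
        return max(self.floor, int(d / self.gamma))


@dataclass(frozen=True)
class PartRange:
    """One contiguous key range of a partition: K indices [lo_idx, hi_idx)."""

    lo_idx: int
    hi_idx: int
    lo_code: int
    hi_code: int  # inclusive


@dataclass
class Partition:
    parts: list[PartRange] = field(default_factory=list)

    @property
    def q(self) -> int:
        return len(self.parts)


@dataclass
class SortedBucket:
    """One fully sorted bucket of SPM-relevant suffixes.

    ``strands[j]``/``offsets[j]`` identify the j-th suffix in lexicographic
    order (sentinel rule: end-of-string sorts after T, per-strand sentinels
    ordered by strand index); ``suffix_lengths[j]`` is its length;
    ``L[j-1] >= k`` is the lcp of suffixes j-1 and j.
    """

    key_code: int
    k: int
    strands: np.ndarray  # int64, 1-based strand indices
    offsets: np.ndarray  # int64, 0-based read offsets (0 = whole read)
    suffix_lengths: np.ndarray  # int64
    L: np.ndarray  # int64, size beta-1

    @property
    def beta(self) -> int:
        return int(self.strands.size)


# ---------------------------------------------------------------------------
# Key collection
# ---------------------------------------------------------------------------

def initial_codes(E: EncodedReadSet, cfg: KmerConfig, both_strands: bool = True) -> np.ndarray:
    """Unsorted initial k-mer codes, one per strand (index order)."""
    codes, nwin = window_code_matrix(E, cfg.k, both_strands)
    if (nwin < 1).any():
        raise ValueError("all reads must be at least k long")
    return codes[:, 0].copy()


def collect_initial_kmers(
    E: EncodedReadSet, cfg: KmerConfig, both_strands: bool = True
) -> np.ndarray:
    """Sorted multiset of the initial k-mer codes of all strands."""
    return np.sort(initial_codes(E, cfg, both_strands))


def dedup_and_count(
    sorted_codes: np.ndarray, cfg: KmerConfig
) -> tuple[KmerTable, CountTable, BitFilter, BitFilter]:
    """One linear scan: distinct keys K, their multiplicities, and the P/Q
    filters derived from the initial codes."""
    uniq, counts = np.unique(np.asarray(sorted_codes, dtype=np.uint64), return_counts=True)
    P, Q = build_filters(uniq, cfg)
    return KmerTable(uniq), CountTable(counts.astype(np.int64)), P, Q


# ---------------------------------------------------------------------------
# Candidate enumeration
# ---------------------------------------------------------------------------

def _candidate_arrays(
    E: EncodedReadSet, l_min: int, cfg: KmerConfig, both_strands: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All proper candidate suffixes as flat arrays (strand, offset, code).

    Offsets run over 1 .. len - l_min (0-based), i.e. proper suffixes of
    length >= l_min; position 0 is excluded (a whole read matching at
    position 0 would contradict prefix-freeness).  No filters are applied
    here.
    """
    codes, _ = window_code_matrix(E, cfg.k, both_strands)
    lengths = E.strand_lengths(both_strands)
    counts = np.maximum(lengths - l_min, 0)
    total = int(counts.sum())
    if total == 0:
        e = np.empty(0, dtype=np.int64)
        return e, e.copy(), np.empty(0, dtype=np.uint64)
    strands0 = np.repeat(np.arange(counts.size, dtype=np.int64), counts)
    starts = np.cumsum(counts) - counts
    qs = np.arange(total, dtype=np.int64) - np.repeat(starts, counts) + 1
    return strands0 + 1, qs, codes[strands0, qs]


def _filter_mask(
    codes: np.ndarray,
    P: BitFilter,
    Q: BitFilter,
    cfg: KmerConfig,
    code_range: tuple[int, int] | None,
) -> np.ndarray:
    shift = np.uint64(2 * (cfg.k - cfg.k_prime))
    mask = np.uint64((1 << (2 * cfg.k_dbl_prime)) - 1)
    keep = P.contains(codes >> shift) & Q.contains(codes & mask)
    if code_range is not None:
        lo, hi = code_range
        keep &= (codes >= np.uint64(lo)) & (codes <= np.uint64(hi))
    return keep


def enumerate_candidate_suffixes(
    E: EncodedReadSet,
    P: BitFilter,
    Q: BitFilter,
    l_min: int,
    cfg: KmerConfig,
    code_range: tuple[int, int] | None = None,
    both_strands: bool = True,
) -> Iterator[tuple[int, int, int]]:
    """Yield (strand, offset, code) for every proper candidate suffix that
    survives the P/Q filters (and the partition code range, if given)."""
    strands, qs, codes = _candidate_arrays(E, l_min, cfg, both_strands)
    keep = _filter_mask(codes, P, Q, cfg, code_range)
    for s, q, c in zip(strands[keep], qs[keep], codes[keep]):
        yield int(s), int(q), int(c)


# ---------------------------------------------------------------------------
# Counting phase
# ---------------------------------------------------------------------------

def counting_phase(
    E: EncodedReadSet,
    K: KmerTable,
    C_init: CountTable,
    P: BitFilter,
    Q: BitFilter,
    l_min: int,
    cfg: KmerConfig,
    buf: BufferConfig | None = None,
    both_strands: bool = True,
) -> CountTable:
    """Count, per key, the proper candidate suffixes whose initial k-mer
    occurs in K; candidates passing P/Q but absent from K are dropped.
    Buffered batches are sorted and merged against K; the result is
    independent of the buffer capacity."""
    buf = buf or BufferConfig()
    b = buf.capacity(K.d)
    C = C_init.C.copy()
    strands, qs, codes = _candidate_arrays(E, l_min, cfg, both_strands)
    keep = _filter_mask(codes, P, Q, cfg, None)
    codes = codes[keep]
    for lo in range(0, codes.size, b):
        batch = np.sort(codes[lo : lo + b])
        uq, cnt = np.unique(batch, return_counts=True)
        idx = np.searchsorted(K.K, uq)
        inside = idx < K.d
        hit = inside.copy()
        hit[inside] = K.K[idx[inside]] == uq[inside]
        np.add.at(C, idx[hit], cnt[hit])
    return CountTable(C)


def compute_partial_sums(C: CountTable) -> PartialSums:
    d = C.C.size
    if d == 0:
        return PartialSums(np.zeros(1, dtype=np.int64))
    pi = np.empty(d + 1, dtype=np.int64)
    np.cumsum(C.C, out=pi[:d])
    pi[d] = pi[d - 1]
    return PartialSums(pi)


# ---------------------------------------------------------------------------
# Partitioning
# ---------------------------------------------------------------------------

#: Simplified size model for the memory-driven partition planner: each
#: suffix-store entry is costed as two machine words (strand + offset).
BYTES_PER_ENTRY = 16


def plan_partitions(
    K: KmerTable,
    pi: PartialSums,
    q_parts: int | None = None,
    memory_limit: int | None = None,
) -> Partition:
    """Tile the key range into contiguous parts of roughly equal total
    bucket size.  With ``memory_limit`` (bytes), the minimal number of parts
    whose largest part fits the documented per-entry size model is chosen."""
    if (q_parts is None) == (memory_limit is None):
        raise ValueError("specify exactly one of q_parts or memory_limit")
    d = K.d
    if d == 0:
        return Partition([])
    sizes = pi.bucket_sizes()
    cum = np.cumsum(sizes)
    g = int(cum[-1])

    def _part(lo: int, hi: int) -> PartRange:
        return PartRange(lo, hi, int(K.K[lo]), int(K.K[hi - 1]))

    if memory_limit is not None:
        cap = memory_limit // BYTES_PER_ENTRY
        if cap < int(sizes.max()):
            raise ValueError(
                f"memory limit {memory_limit} below the largest single bucket "
                f"({int(sizes.max())} entries x {BYTES_PER_ENTRY} bytes)"
            )
        parts = []
        lo = 0
        acc = 0
        for i in range(d):
            if acc + int(sizes[i]) > cap:
                parts.append(_part(lo, i))
                lo, acc = i, 0
            acc += int(sizes[i])
        parts.append(_part(lo, d))
        return Partition(parts)

    q = max(1, min(int(q_parts), d))
    # greedy accumulation towards g/q per part; a part is closed early when
    # exactly one bucket must be left for each remaining part
    parts = []
    lo, acc, rem_g, rem_parts = 0, 0, g, q
    for i in range(d):
        acc += int(sizes[i])
        buckets_left = d - (i + 1)
        if rem_parts > 1 and (acc * rem_parts >= rem_g or buckets_left == rem_parts - 1):
            parts.append(_part(lo, i + 1))
            lo, rem_g, rem_parts, acc = i + 1, rem_g - acc, rem_parts - 1, 0
    parts.append(_part(lo, d))
    return Partition(parts)


# ---------------------------------------------------------------------------
# Insertion phase
# ---------------------------------------------------------------------------

def insertion_phase(
    E: EncodedReadSet,
    K: KmerTable,
    pi: PartialSums,
    P: BitFilter,
    Q: BitFilter,
    l_min: int,
    cfg: KmerConfig,
    part: PartRange | None = None,
    buf: BufferConfig | None = None,
    both_strands: bool = True,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Fill the suffix-store segment of one partition part.

    Whole reads (offset 0) are inserted unconditionally; proper candidates
    are validated against K during the buffered merge.  Entries are placed
    with decrementing per-bucket cursors starting at each bucket's end
    boundary, so after the scan the segment is exactly bucket-partitioned
    (within-bucket order is unspecified at this stage).

    Returns ``(strands, offsets, base)`` where ``base`` is the global store
    index of the segment's first slot.
    """
    buf = buf or BufferConfig()
    d = K.d
    if part is None:
        part = PartRange(0, d, int(K.K[0]), int(K.K[-1])) if d else PartRange(0, 0, 0, 0)
    lo_i, hi_i = part.lo_idx, part.hi_idx
    if lo_i >= hi_i:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64), 0

    starts = np.array([pi.bucket_bounds(i)[0] for i in range(lo_i, hi_i)], dtype=np.int64)
    ends = np.array([pi.bucket_bounds(i)[1] for i in range(lo_i, hi_i)], dtype=np.int64)
    base = int(starts[0])
    seg_len = int(ends[-1]) - base
    seg_strands = np.full(seg_len, -1, dtype=np.int64)
    seg_offsets = np.full(seg_len, -1, dtype=np.int64)
    cursors = ends.copy()  # consumed: decremented towards bucket starts

    def place(key_idx: np.ndarray, strands: np.ndarray, qs: np.ndarray) -> None:
        order = np.argsort(key_idx, kind="stable")
        ii = key_idx[order] - lo_i
        uq, first, cnt = np.unique(ii, return_index=True, return_counts=True)
        within = np.arange(ii.size, dtype=np.int64) - np.repeat(first, cnt)
        slots = np.repeat(cursors[uq], cnt) - 1 - within
        if (slots < np.repeat(starts[uq], cnt)).any():
            raise IndexConsistencyError("bucket overflow during insertion")
        cursors[uq] -= cnt
        seg_strands[slots - base] = strands[order]
        seg_offsets[slots - base] = qs[order]

    code_range = (part.lo_code, part.hi_code)

    # whole reads: always SPM-relevant, their keys are in K by construction
    init = initial_codes(E, cfg, both_strands)
    idx0 = np.searchsorted(K.K, init)
    in_part = (idx0 >= lo_i) & (idx0 < hi_i)
    whole_strands = np.nonzero(in_part)[0].astype(np.int64) + 1
    b = buf.capacity(d) // 2 or 1  # insertion buffer holds wider records
    for lo in range(0, whole_strands.size, b):
        sl = slice(lo, lo + b)
        place(idx0[in_part][sl], whole_strands[sl], np.zeros(min(b, whole_strands.size - lo), dtype=np.int64))

    # proper candidates, filtered by P/Q, the part's code range, and K
    strands, qs, codes = _candidate_arrays(E, l_min, cfg, both_strands)
    keep = _filter_mask(codes, P, Q, cfg, code_range)
    strands, qs, codes = strands[keep], qs[keep], codes[keep]
    for lo in range(0, codes.size, b):
        sl = slice(lo, lo + b)
        bc, bs, bq = codes[sl], strands[sl], qs[sl]
        order = np.argsort(bc, kind="stable")  # buffer sorted by key
        bc, bs, bq = bc[order], bs[order], bq[order]
        idx = np.searchsorted(K.K, bc)
        inside = idx < d
        hit = inside.copy()
        hit[inside] = K.K[idx[inside]] == bc[inside]
        hit &= (idx >= lo_i) & (idx < hi_i)
        if hit.any():
            place(idx[hit], bs[hit], bq[hit])

    if (cursors != starts).any():
        raise IndexConsistencyError("bucket underfill: counting/insertion mismatch")
    return seg_strands, seg_offsets, base


# ---------------------------------------------------------------------------
# Bucket sorting
# ---------------------------------------------------------------------------

def sort_bucket(
    E: EncodedReadSet,
    strands: np.ndarray,
    offsets: np.ndarray,
    k: int,
    key_code: int,
) -> SortedBucket:
    """Sort one bucket's suffixes under the full sentinel order.

    All entries share the initial k-mer ``key_code``; only the remaining
    suffixes (from offset + k on) are compared.  The lcp table is obtained
    as a byproduct: L[j] = k + lcp(remaining_{j-1}, remaining_j) >= k.
    """
    items = []
    for s, q in zip(strands.tolist(), offsets.tolist()):
        rem = E.strand_seq(s)[q + k :]
        items.append((rem + SENTINEL, s, q, len(rem) + k))
    items.sort(key=lambda it: (it[0], it[1]))
    beta = len(items)
    L = np.empty(max(beta - 1, 0), dtype=np.int64)
    for j in range(1, beta):
        L[j - 1] = k + _lcp(items[j - 1][0][:-1], items[j][0][:-1])
    return SortedBucket(
        key_code=key_code,
        k=k,
        strands=np.array([it[1] for it in items], dtype=np.int64),
        offsets=np.array([it[2] for it in items], dtype=np.int64),
        suffix_lengths=np.array([it[3] for it in items], dtype=np.int64),
        L=L,
    )


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def build_sorted_buckets(
    E: EncodedReadSet,
    l_min: int,
    cfg: KmerConfig | None = None,
    q_parts: int = 1,
    memory_limit: int | None = None,
    buf: BufferConfig | None = None,
    both_strands: bool = True,
) -> list[SortedBucket]:
    """Full index construction: keys, counts, partial sums, partitioned
    insertion, per-bucket sorting.  Buckets are returned in ascending order
    of their initial k-mer, independent of the partitioning."""
    if E.is_empty:
        return []
    cfg = cfg or KmerConfig.defaults(l_min, max(E.n, 2))
    cfg.validate_against(l_min)
    sorted_init = collect_initial_kmers(E, cfg, both_strands)
    K, C_init, P, Q = dedup_and_count(sorted_init, cfg)
    C = counting_phase(E, K, C_init, P, Q, l_min, cfg, buf, both_strands)
    pi = compute_partial_sums(C)
    if memory_limit is not None:
        partition = plan_partitions(K, pi, memory_limit=memory_limit)
    else:
        partition = plan_partitions(K, pi, q_parts=q_parts)
    logger.info(
        "spmindex: d=%d g=%d parts=%d (k=%d k'=%d k''=%d)",
        K.d, pi.g, partition.q, cfg.k, cfg.k_prime, cfg.k_dbl_prime,
    )
    buckets: list[SortedBucket] = []
    for part in partition.parts:
        seg_s, seg_q, base = insertion_phase(
            E, K, pi, P, Q, l_min, cfg, part, buf, both_strands
        )
        for i in range(part.lo_idx, part.hi_idx):
            s0, s1 = pi.bucket_bounds(i)
            buckets.append(
                sort_bucket(E, seg_s[s0 - base : s1 - base], seg_q[s0 - base : s1 - base], cfg.k, int(K.K[i]))
            )
    return buckets
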