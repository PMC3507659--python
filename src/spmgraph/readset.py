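"""Read ingestion, strand-aware encoding and the suffix-/prefix-free prefilter.

A read set ``R = (r_1, ..., r_m)`` is handled together with its reverse
complements as the extended multiset ``R+RC = (r_1, ..., r_m, rc(r_1), ...,
rc(r_m))``; *strand index* ``i <= m`` denotes the forward read ``r_i`` and
``m + i`` its reverse complement.  Every strand is conceptually padded on the
right by a per-strand sentinel ``$_i`` with ``A < C < G < T < $_1 < $_2 <
...``; sentinels are virtual: they are never stored, only realised in the
comparison rules.  Under this order a proper prefix sorts *after* all its
extensions, which is what makes containment detection a single scan over
lexicographically consecutive strands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Virtual-sentinel stand-in used in sort keys only: any single character
#: strictly greater than 'T'.  Ties between identical sequences are broken by
#: strand index, realising the $_i < $_j (i < j) rule.
SENTINEL = "\x7f"

VALID_BASES = frozenset("ACGT")


def revcomp(s: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T}."""
    return s.translate(_COMPLEMENT)[::-1]


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass(frozen=True)
class Read:
    """A single input read: 1-based id in input order plus its sequence."""

    read_id: int
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("read sequence must be non-empty")


@dataclass
class PrefilterReport:
    """Aggregated outcome of the suffix-/prefix-free prefilter."""

    input_count: int = 0
    kept_count: int = 0
    removed_duplicates: int = 0
    removed_prefix_contained: int = 0
    removed_suffix_contained: int = 0
    kept_ids: list[int] = field(default_factory=list)

    @property
    def removed_total(self) -> int:
        return (
            self.removed_duplicates
            + self.removed_prefix_contained
            + self.removed_suffix_contained
        )

    def to_dict(self) -> dict:
        return {
            "input_count": self.input_count,
            "kept_count": self.kept_count,
            "removed_duplicates": self.removed_duplicates,
            "removed_prefix_contained": self.removed_prefix_contained,
            "removed_suffix_contained": self.removed_suffix_contained,
        }


class EncodedReadSet:
    """An ordered read multiset with virtual reverse-complement strands.

    Strand indices are 1-based: ``1..m`` are the forward reads in input
    order, ``m+1..2m`` their reverse complements (strand ``m+i`` pairs with
    forward read ``i``).  Base access on strand ``m+i`` at position ``p``
    (1-based) yields the Watson-Crick complement of read ``i`` at position
    ``|r_i| - p + 1``, i.e. the reverse complement is never stored twice.
    """

    def __init__(self, sequences: Sequence[str], read_ids: Sequence[int] | None = None):
        self._fwd: list[str] = list(sequences)
        self.m = len(self._fwd)
        if read_ids is None:
            read_ids = list(range(1, self.m + 1))
        if len(read_ids) != self.m:
            raise ValueError("read_ids length must match sequence count")
        self.read_ids = np.asarray(read_ids, dtype=np.int64)
        self.lengths = np.array([len(s) for s in self._fwd], dtype=np.int64)
        self.n = int(self.lengths.sum())
        self._rc: list[str | None] = [None] * self.m
        self._base_matrix: np.ndarray | None = None  # built on demand

    # -- basic accessors ---------------------------------------------------
    @property
    def is_empty(self) -> bool:
        return self.m == 0

    def num_strands(self, both_strands: bool = True) -> int:
        return 2 * self.m if both_strands else self.m

    def length(self, strand_idx: int) -> int:
        i = strand_idx - 1 if strand_idx <= self.m else strand_idx - self.m - 1
        return int(self.lengths[i])

    def strand_seq(self, strand_idx: int) -> str:
        """Full sequence of a strand (1..2m), RC strands computed lazily."""
        if not 1 <= strand_idx <= 2 * self.m:
            raise IndexError(f"strand index {strand_idx} out of range 1..{2 * self.m}")
        if strand_idx <= self.m:
            return self._fwd[strand_idx - 1]
        i = strand_idx - self.m - 1
        if self._rc[i] is None:
            self._rc[i] = revcomp(self._fwd[i])
        return self._rc[i]

    def base(self, strand_idx: int, pos1: int) -> str:
        s = self.strand_seq(strand_idx)
        if not 1 <= pos1 <= len(s):
            raise IndexError(f"position {pos1} out of range for strand {strand_idx}")
        return s[pos1 - 1]

    def forward_sequences(self) -> list[str]:
        return list(self._fwd)

    def strand_lengths(self, both_strands: bool = True) -> np.ndarray:
        """Lengths indexed by strand (0-based array of size m or 2m)."""
        if both_strands:
            return np.concatenate([self.lengths, self.lengths])
        return self.lengths

    # -- packed base store --------------------------------------------------
    def base_matrix(self, both_strands: bool = True) -> np.ndarray:
        """(num_strands, max_len) uint8 matrix of base codes 0..3, pad 255."""
        if self._base_matrix is None:
            lut = np.full(256, 255, dtype=np.uint8)
            for b, c in zip(b"ACGT", range(4)):
                lut[b] = c
            nmax = int(self.lengths.max()) if self.m else 0
            mat = np.full((2 * self.m, nmax), 255, dtype=np.uint8)
            for i in range(self.m):
                row = lut[np.frombuffer(self._fwd[i].encode(), dtype=np.uint8)]
                mat[i, : len(row)] = row
                mat[self.m + i, : len(row)] = 3 - row[::-1]  # complement, reversed
            self._base_matrix = mat
        if both_strands:
            return self._base_matrix
        return self._base_matrix[: self.m]


# ---------------------------------------------------------------------------
# FASTA ingestion
# ---------------------------------------------------------------------------

def _check_fasta_syntax(path: Path) -> None:
    """Reject sequence data appearing before any header, naming the line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(";"):
                continue
            if not stripped.startswith(">"):
                raise FastaParseError("sequence data before first FASTA header", lineno)
            return


def read_fasta(path: str | Path, start_id: int = 1) -> list[Read]:
    """Read DNA reads from a FASTA file, dropping ambiguous sequences.

    Sequences are case-folded to upper case; any record containing a symbol
    outside {A,C,G,T} (ambiguity codes such as N) is dropped and the dropped
    count is logged.  Returned reads are numbered consecutively from
    ``start_id`` in file order (numbering skips dropped records).
    """
    from Bio import SeqIO

    path = Path(path)
    _check_fasta_syntax(path)
    reads: list[Read] = []
    dropped = 0
    next_id = start_id
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if not seq or not VALID_BASES.issuperset(seq):
            dropped += 1
            continue
        reads.append(Read(next_id, seq))
        next_id += 1
    if dropped:
        logger.info("read_fasta(%s): dropped %d read(s) with ambiguity codes", path, dropped)
    return reads


def read_fasta_files(paths: Iterable[str | Path]) -> list[Read]:
    """Read several FASTA files with consecutive read numbering."""
    reads: list[Read] = []
    for p in paths:
        reads.extend(read_fasta(p, start_id=len(reads) + 1))
    return reads


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

def encode(reads: Sequence[Read], l_min: int) -> EncodedReadSet:
    """Build an EncodedReadSet, excluding reads shorter than ``l_min``.

    Reads shorter than the minimum match length cannot take part in any
    suffix-prefix match and are removed at ingestion.
    """
    if l_min < 1:
        raise ValueError("l_min must be >= 1")
    kept = [r for r in reads if len(r.sequence) >= l_min]
    short = len(reads) - len(kept)
    if short:
        logger.info("encode: excluded %d read(s) shorter than l_min=%d", short, l_min)
    return EncodedReadSet([r.sequence for r in kept], [r.read_id for r in kept])


# ---------------------------------------------------------------------------
# Lexicographic sort with lcp byproduct
# ---------------------------------------------------------------------------

def _lcp(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def lex_sort_with_lcp(E: EncodedReadSet) -> tuple[list[int], list[int]]:
    """Sort all 2m strands under the virtual-sentinel order; lcps as byproduct.

    Returns ``(order, lcps)`` where ``order`` lists strand indices (1..2m) in
    lexicographic order of the sentinel-padded sequences and ``lcps[t]`` is
    the longest-common-prefix length of the sequences at ``order[t]`` and
    ``order[t+1]``.
    """
    if E.is_empty:
        raise ValueError("cannot sort an empty read set")
    two_m = 2 * E.m
    # SENTINEL sorts after every base; equal full sequences fall back to the
    # strand index, realising $_i < $_j for i < j.
    order = sorted(range(1, two_m + 1), key=lambda i: (E.strand_seq(i) + SENTINEL, i))
    lcps = [
        _lcp(E.strand_seq(order[t]), E.strand_seq(order[t + 1]))
        for t in range(two_m - 1)
    ]
    return order, lcps


# ---------------------------------------------------------------------------
# Prefilter
# ---------------------------------------------------------------------------

_DUP, _PREFIX, _SUFFIX = 0, 1, 2  # mark reasons, in priority order


def prefilter(E: EncodedReadSet) -> tuple[EncodedReadSet, PrefilterReport]:
    """Remove reads that are duplicates, prefixes or suffixes of other reads.

    One scan over the lexicographically sorted strands suffices:

    * consecutive pair ``(u, v)`` with ``lcp == |v| < |u|``: ``v`` is a proper
      prefix of ``u`` -- mark ``v`` (a mark on an RC strand means the forward
      read is a *suffix* of something);
    * a maximal run of identical strand strings: keep the read with the
      smallest forward index present in the run, mark every other read.
      A run consisting of the two strands of a single read (a
      reverse-complement palindrome) places no mark.

    The kept set is suffix- and prefix-free over reads plus reverse
    complements, and the operation is idempotent.
    """
    if E.is_empty:
        return E, PrefilterReport(input_count=0, kept_count=0, kept_ids=[])

    m = E.m
    order, lcps = lex_sort_with_lcp(E)
    reasons: dict[int, int] = {}  # 0-based forward read position -> reason

    def mark(read0: int, reason: int) -> None:
        prev = reasons.get(read0)
        if prev is None or reason < prev:
            reasons[read0] = reason

    def read0_of(strand: int) -> int:
        return strand - 1 if strand <= m else strand - m - 1

    two_m = 2 * m
    # Group the sorted strands into maximal runs of identical strings: within
    # a run apply the duplicate rule, across adjacent runs the prefix rule.
    runs: list[tuple[int, int]] = []  # (start, end) positions in `order`, inclusive
    start = 0
    for t in range(two_m - 1):
        identical = lcps[t] == E.length(order[t]) == E.length(order[t + 1])
        if not identical:
            runs.append((start, t))
            start = t + 1
    runs.append((start, two_m - 1))

    for start, end in runs:
        if end > start:
            members = {read0_of(order[j]) for j in range(start, end + 1)}
            keeper = min(members)
            for r0 in members:
                if r0 != keeper:
                    mark(r0, _DUP)

    for (ps, pe), (cs, ce) in zip(runs, runs[1:]):
        l = lcps[pe]  # lcp between last strand of prev run and first of cur run
        if l == E.length(order[cs]) < E.length(order[pe]):
            # the current run's string is a proper prefix of the previous,
            # longer string (prefixes sort after their extensions)
            for j in range(cs, ce + 1):
                v = order[j]
                mark(read0_of(v), _PREFIX if v <= m else _SUFFIX)

    kept_pos = [i for i in range(m) if i not in reasons]
    kept_seqs = [E.strand_seq(i + 1) for i in kept_pos]
    kept_ids = [int(E.read_ids[i]) for i in kept_pos]
    report = PrefilterReport(
        input_count=m,
        kept_count=len(kept_pos),
        removed_duplicates=sum(1 for r in reasons.values() if r == _DUP),
        removed_prefix_contained=sum(1 for r in reasons.values() if r == _PREFIX),
        removed_suffix_contained=sum(1 for r in reasons.values() if r == _SUFFIX),
        kept_ids=kept_ids,
    )
    logger.info("prefilter: %s", report.to_dict())
    return EncodedReadSet(kept_seqs, kept_ids), report


# ---------------------------------------------------------------------------
# Versioned text sidecar for the encoded read set
# ---------------------------------------------------------------------------

_SIDECAR_MAGIC = "#spmgraph-readset\tv1"


def save_readset(E: EncodedReadSet, path: str | Path) -> None:
    """Serialise the read set to a versioned TSV sidecar."""
    with open(path, "w") as fh:
        fh.write(f"{_SIDECAR_MAGIC}\tm={E.m}\tn={E.n}\n")
        for i in range(E.m):
            fh.write(f"{int(E.read_ids[i])}\t{E.strand_seq(i + 1)}\n")


def load_readset(path: str | Path) -> EncodedReadSet:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith(_SIDECAR_MAGIC):
            raise ValueError(f"{path}: not a spmgraph read-set sidecar")
        ids: list[int] = []
        seqs: list[str] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                rid, seq = line.split("\t")
                ids.append(int(rid))
            except ValueError as exc:
                raise ValueError(f"{path}: malformed sidecar line {lineno}") from exc
            seqs.append(seq)
    return EncodedReadSet(seqs, ids)
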