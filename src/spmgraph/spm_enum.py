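"""Suffix-prefix match enumeration over sorted buckets.

Within one bucket, every suffix-prefix match <r_p, r_j, l> (the length-l
suffix of r_p equals the length-l prefix of r_j, l >= l_min) appears as an
lcp-interval of lcp-value l that lies on the *whole-read path* of r_j (the
root-to-leaf path of r_j's offset-0 entry) and has a *terminal edge* for
r_p (a leaf whose suffix ends exactly at depth l, so its remaining label is
just the virtual sentinel).  The bottom-up traversal therefore collects

* ``W`` -- whole-read leaves seen so far (emptied when an interval of
  lcp < l_min completes: below that depth no further match can reach them);
* ``T`` -- terminal edges of the current interval (emptied after each
  cartesian product; sentinels sort last, so terminal edges always follow
  all branch edges of their interval),

and emits ``T x W[itv.firstinW..]`` at every completed interval of lcp >=
l_min, which enumerates matches per destination in order of decreasing
overlap length.

That ordering makes early transitivity classification possible: a match
<r, t, l''> is transitive iff it is derived from an irreducible <s, t, l'>
with l' > l'' whose left context LC(s, l') = s[1..|s|-l'] is a suffix of
LC(r, l'').  The first match on a whole-read path is always irreducible;
each later one is checked against the stored left contexts of its
destination's dictionary.

Reverse complements are handled by running over all 2m strands; exactly one
of a mirror pair <r, s, l> / <rc(s), rc(r), l> is kept (non-redundancy
conditions), applied *after* classification so every whole-read path stays
complete.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .lcptree import LcpInterval, TraversalCallbacks, traverse_bucket
from .readset import EncodedReadSet, revcomp
from .spmindex import SortedBucket

logger = logging.getLogger(__name__)

IRREDUCIBLE = "irreducible"
TRANSITIVE = "transitive"


@dataclass(frozen=True)
class Spm:
    """An oriented suffix-prefix match between two strands (1..2m)."""

    src: int
    dst: int
    length: int
    status: str | None = None

    @property
    def key(self) -> tuple[int, int, int]:
        return (self.src, self.dst, self.length)


class LeftContextDict:
    """Dictionary of left contexts of the irreducible matches of one
    destination read.

    ``lcsearch(s)`` returns True iff some previously added string is a
    suffix of ``s``; otherwise ``s`` is added and False is returned.  A
    plain reversed-string set with a linear suffix scan is sufficient at
    the scales handled here (a blind trie would give the same contract).
    """

    __slots__ = ("_items",)

    def __init__(self):
        self._items: list[str] = []

    def lcsearch(self, s: str) -> bool:
        if not s:
            raise ValueError("left contexts are non-empty by construction")
        for t in self._items:
            if s.endswith(t):
                return True
        self._items.append(s)
        return False

    def __len__(self) -> int:
        return len(self._items)


def lcsearch(D: LeftContextDict, s: str) -> bool:
    """Module-level convenience wrapper around :meth:`LeftContextDict.lcsearch`."""
    return D.lcsearch(s)


def is_nonredundant(src: int, dst: int, m: int) -> bool:
    """Non-redundancy of a strand-level match: keep it iff both strands are
    forward, or exactly one is a reverse complement and the forward read of
    the forward strand precedes (input order) the forward read of the RC
    strand."""
    if src <= m and dst <= m:
        return True
    if src <= m < dst:
        return src < dst - m
    if dst <= m < src:
        return dst < src - m
    return False


def _forward_read(strand: int, m: int) -> int:
    return strand if strand <= m else strand - m


# ---------------------------------------------------------------------------
# Pass 1: internally contained reads
# ---------------------------------------------------------------------------

class _ContainmentScan(TraversalCallbacks):
    """Flags reads whose whole-read leaf hangs below an interval as deep as
    the read itself: some other SPM-relevant suffix then has the read as a
    proper prefix, i.e. the read occurs internally in another read."""

    def __init__(self, E: EncodedReadSet):
        self.E = E
        self.flags = np.zeros(E.m + 1, dtype=bool)  # 1-based forward reads

    def process_leafedge(self, firstedge: bool, itv: LcpInterval, leaf: tuple[int, int]) -> None:
        strand, q = leaf
        if q == 0 and itv.lcp == self.E.length(strand):
            self.flags[_forward_read(strand, self.E.m)] = True


def detect_internally_contained(
    buckets: Iterable[SortedBucket], E: EncodedReadSet
) -> np.ndarray:
    """Boolean flags (1-based, size m+1) of internally contained reads.

    Requires a suffix- and prefix-free read set: a whole read equal to the
    prefix of another SPM-relevant suffix can then only be an internal
    occurrence.  Flags raised on either strand map to the forward read.
    """
    scan = _ContainmentScan(E)
    for bucket in buckets:
        traverse_bucket(bucket, scan)
    return scan.flags


# ---------------------------------------------------------------------------
# Pass 2: SPM enumeration with early transitivity classification
# ---------------------------------------------------------------------------

class _SpmScan(TraversalCallbacks):
    def __init__(
        self,
        E: EncodedReadSet,
        l_min: int,
        contained: np.ndarray | None,
        out: list[Spm],
        keep_transitive: bool,
    ):
        self.E = E
        self.m = E.m
        self.l_min = l_min
        self.contained = contained
        self.out = out
        self.keep_transitive = keep_transitive
        # W holds (strand, dictionary) per whole-read leaf; T holds (strand)
        # per pending terminal edge of the interval being completed.
        self.W: list[tuple[int, LeftContextDict]] = []
        self.T: list[int] = []

    def _excluded(self, strand: int) -> bool:
        return self.contained is not None and bool(
            self.contained[_forward_read(strand, self.m)]
        )

    def process_leafedge(self, firstedge: bool, itv: LcpInterval, leaf: tuple[int, int]) -> None:
        if firstedge:
            itv.firstinW = len(self.W)
        strand, q = leaf
        if self._excluded(strand):
            return
        if q == 0:
            self.W.append((strand, LeftContextDict()))
        elif self.E.length(strand) - q == itv.lcp:
            # label beyond the interval prefix is only the sentinel
            self.T.append(strand)

    def process_branchedge(self, firstedge: bool, itv: LcpInterval, child: LcpInterval) -> None:
        if firstedge:
            itv.firstinW = child.firstinW

    def process_lcpinterval(self, itv: LcpInterval) -> None:
        l = itv.lcp
        if l >= self.l_min and self.T:
            first = itv.firstinW if itv.firstinW is not None else len(self.W)
            for p in self.T:
                seq_p = self.E.strand_seq(p)
                lc = seq_p[: len(seq_p) - l]
                for j, D in self.W[first:]:
                    if p == j:
                        continue  # self-overlap: no use in the layout
                    if D.lcsearch(lc):
                        if self.keep_transitive:
                            self.out.append(Spm(p, j, l, TRANSITIVE))
                    else:
                        self.out.append(Spm(p, j, l, IRREDUCIBLE))
        self.T.clear()
        if l < self.l_min:
            self.W.clear()


def enumerate_spms(
    buckets: Iterable[SortedBucket],
    l_min: int,
    E: EncodedReadSet,
    contained: np.ndarray | None = None,
    keep_transitive: bool = True,
) -> list[Spm]:
    """Enumerate and classify all suffix-prefix matches of length >= l_min.

    ``contained`` (from :func:`detect_internally_contained`) removes both
    strands of internally contained reads from the traversal state, so no
    match touches them.  With ``keep_transitive`` False, only irreducible
    matches are returned (transitive ones are classified and discarded on
    the fly); the classification itself always sees the full stream.
    """
    out: list[Spm] = []
    scan = _SpmScan(E, l_min, contained, out, keep_transitive)
    for bucket in buckets:
        traverse_bucket(bucket, scan)
        scan.W.clear()
        scan.T.clear()
    return out


def filter_nonredundant(spms: Iterable[Spm], m: int) -> list[Spm]:
    """Keep exactly one of each mirror pair (strand-level conditions)."""
    return [s for s in spms if is_nonredundant(s.src, s.dst, m)]


# ---------------------------------------------------------------------------
# SPM file format
# ---------------------------------------------------------------------------

def _spm_sort_key(E: EncodedReadSet):
    m = E.m

    def key(s: Spm):
        src_r, dst_r = _forward_read(s.src, m), _forward_read(s.dst, m)
        return (
            int(E.read_ids[src_r - 1]),
            s.src > m,
            int(E.read_ids[dst_r - 1]),
            s.dst > m,
            -s.length,
        )

    return key


def write_spm_file(spms: Sequence[Spm], E: EncodedReadSet, path: str | Path) -> None:
    """Write matches as TSV: srcId, srcStrand(+/-), dstId, dstStrand, length.

    Lines are sorted by (srcId, srcStrand, dstId, dstStrand, -length) so the
    output is byte-identical across runs and partitionings.
    """
    m = E.m
    rows = sorted(spms, key=_spm_sort_key(E))
    with open(path, "w") as fh:
        for s in rows:
            src_r, dst_r = _forward_read(s.src, m), _forward_read(s.dst, m)
            fh.write(
                f"{int(E.read_ids[src_r - 1])}\t{'-' if s.src > m else '+'}\t"
                f"{int(E.read_ids[dst_r - 1])}\t{'-' if s.dst > m else '+'}\t{s.length}\n"
            )


def read_spm_file(path: str | Path) -> list[tuple[int, str, int, str, int]]:
    """Parse an SPM TSV file; raises ValueError naming the offending line."""
    rows: list[tuple[int, str, int, str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            try:
                src, ss, dst, ds, l = parts
                if ss not in "+-" or ds not in "+-":
                    raise ValueError
                rows.append((int(src), ss, int(dst), ds, int(l)))
            except ValueError as exc:
                raise ValueError(f"{path}: malformed SPM line {lineno}: {line!r}") from exc
    return rows


# ---------------------------------------------------------------------------
# Brute-force oracles (test plumbing; independent of the bucket machinery)
# ---------------------------------------------------------------------------

def _strand_seqs(reads: Sequence[str], both_strands: bool) -> list[str]:
    seqs = list(reads)
    if both_strands:
        seqs += [revcomp(s) for s in reads]
    return seqs


def brute_force_spms(
    reads: Sequence[str],
    l_min: int,
    both_strands: bool = True,
    exclude: set[int] | None = None,
) -> set[tuple[int, int, int]]:
    """All-pairs suffix-prefix matches by direct string comparison.

    Returns strand-level triples (src, dst, length) with 1-based strand
    indices (i <= m forward, m+i reverse complement).  ``exclude`` removes
    forward read indices (e.g. contained reads) from both strands.  A
    prefix dictionary keyed on the length-l_min read prefixes prunes the
    quadratic pair scan; every reported triple is verified by a direct
    slice comparison.
    """
    m = len(reads)
    seqs = _strand_seqs(reads, both_strands)
    nstr = len(seqs)
    active = [
        i
        for i in range(1, nstr + 1)
        if not (exclude and ((i if i <= m else i - m) in exclude))
    ]
    by_prefix: dict[str, list[int]] = {}
    for j in active:
        by_prefix.setdefault(seqs[j - 1][:l_min], []).append(j)
    out: set[tuple[int, int, int]] = set()
    for i in active:
        s = seqs[i - 1]
        for q in range(1, len(s) - l_min + 1):
            suffix = s[q:]
            for j in by_prefix.get(suffix[:l_min], ()):
                if j == i:
                    continue
                t = seqs[j - 1]
                if len(t) >= len(suffix) and t.startswith(suffix):
                    out.add((i, j, len(suffix)))
    return out


def brute_force_classify(
    spms: set[tuple[int, int, int]], reads: Sequence[str], both_strands: bool = True
) -> dict[tuple[int, int, int], str]:
    """Definitional transitivity: <r, t, l''> is transitive iff matches
    <r, s, l> and <s, t, l'> exist with l + l' == |s| + l''."""
    seqs = _strand_seqs(reads, both_strands)
    by_src: dict[int, list[tuple[int, int]]] = {}
    for (r, s, l) in spms:
        by_src.setdefault(r, []).append((s, l))
    statuses: dict[tuple[int, int, int], str] = {}
    for (r, t, l2) in spms:
        transitive = False
        for (s, l) in by_src.get(r, ()):
            if s == t and l == l2:
                continue
            l_prime = len(seqs[s - 1]) + l2 - l
            if l_prime > 0 and (s, t, l_prime) in spms:
                transitive = True
                break
        statuses[(r, t, l2)] = TRANSITIVE if transitive else IRREDUCIBLE
    return statuses


def brute_force_contained(reads: Sequence[str]) -> set[int]:
    """Forward read indices (1-based) occurring internally (non-empty flanks
    on both sides) in another read, on either strand."""
    out: set[int] = set()
    for i, r in enumerate(reads, start=1):
        for j, other in enumerate(reads, start=1):
            if i == j:
                continue
            for t in (other, revcomp(other)):
                pos = t.find(r, 1)
                while pos != -1:
                    if pos + len(r) < len(t):
                        out.add(i)
                        break
                    pos = t.find(r, pos + 1)
                if i in out:
                    break
            if i in out:
                break
    return out
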