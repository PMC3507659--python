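"""Assembly string graph construction and contig extraction.

Each read r contributes two vertices, r.B (begin) and r.E (end); each
non-redundant irreducible suffix-prefix match contributes two complementary
directed edges, one per strand of the implied double-stranded join:

1. <r, s, l>, both forward:          r.E -> s.E   and   s.B -> r.B
2. <r, rc(s), l>:                    r.E -> s.B   and   s.E -> r.B
3. <rc(s), r, l>:                    r.B -> s.E   and   s.B -> r.E

An edge into x.E extends the walk with the forward tail x[l+1..|x|]; an
edge into x.B extends it with the reverse-complement tail rc(x)[l+1..|x|].
Walks therefore always spell valid assemblies (read coherence).  Contigs
are maximal unbranched walks; an edge and its complement are visited
together, so each double-stranded contig is reported once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .readset import EncodedReadSet, revcomp
from .spm_enum import Spm

logger = logging.getLogger(__name__)


class GraphConsistencyError(RuntimeError):
    """An SPM references a read outside the encoded set, or a removed read."""


def _vertex(read_pos: int, end: bool) -> int:
    """Vertex id of read ``read_pos`` (1-based): 2i-2 is r_i.B, 2i-1 is r_i.E."""
    return 2 * (read_pos - 1) + (1 if end else 0)


def _vertex_read(v: int) -> int:
    return v // 2 + 1


def _vertex_is_end(v: int) -> bool:
    return v % 2 == 1


@dataclass
class Contig:
    """An assembled contig: spelled sequence, the ordered oriented reads it
    is built from, and each read's start offset within the contig."""

    sequence: str
    read_path: list[tuple[int, str]]  # (original read id, '+'/'-')
    coordinates: list[int]

    def __len__(self) -> int:
        return len(self.sequence)


class StringGraph:
    """Flat-array string graph: 2m vertices, 2*rho edges.

    Edges are stored grouped by source vertex (counting sort over the SPM
    list); ``out_start[v] .. out_start[v+1]`` indexes the out-edges of
    vertex ``v``.  ``complement[e]`` is the other edge of e's match, an
    involution.
    """

    def __init__(self, E: EncodedReadSet, spms: Sequence[Spm]):
        self.E = E
        self.m = E.m
        self.vertex_count = 2 * self.m
        self.rho = len(spms)
        self.spms = list(spms)

        srcs = np.empty(2 * self.rho, dtype=np.int64)
        dsts = np.empty(2 * self.rho, dtype=np.int64)
        lablens = np.empty(2 * self.rho, dtype=np.int64)
        spm_ref = np.empty(2 * self.rho, dtype=np.int64)
        m = self.m
        for x, spm in enumerate(self.spms):
            a, b, l = spm.src, spm.dst, spm.length
            if not (1 <= a <= 2 * m and 1 <= b <= 2 * m):
                raise GraphConsistencyError(f"SPM strand out of range: {spm}")
            if a <= m and b <= m:  # rule 1
                r, s = a, b
                e1 = (_vertex(r, True), _vertex(s, True), E.length(s) - l)
                e2 = (_vertex(s, False), _vertex(r, False), E.length(r) - l)
            elif a <= m < b:  # rule 2: <r, rc(s)>
                r, s = a, b - m
                e1 = (_vertex(r, True), _vertex(s, False), E.length(s) - l)
                e2 = (_vertex(s, True), _vertex(r, False), E.length(r) - l)
            elif b <= m < a:  # rule 3: <rc(s), r>
                s, r = a - m, b
                e1 = (_vertex(r, False), _vertex(s, True), E.length(s) - l)
                e2 = (_vertex(s, False), _vertex(r, True), E.length(r) - l)
            else:
                raise GraphConsistencyError(
                    f"redundant match between two RC strands reached the graph: {spm}"
                )
            for j, (u, v, ll) in enumerate((e1, e2)):
                if ll < 1:
                    raise GraphConsistencyError(f"non-positive edge label for {spm}")
                srcs[2 * x + j], dsts[2 * x + j], lablens[2 * x + j] = u, v, ll
                spm_ref[2 * x + j] = x

        # two-scan construction: outdegree counts, partial sums, fill
        outdeg = np.bincount(srcs, minlength=self.vertex_count) if self.rho else np.zeros(
            self.vertex_count, dtype=np.int64
        )
        self.out_start = np.zeros(self.vertex_count + 1, dtype=np.int64)
        np.cumsum(outdeg, out=self.out_start[1:])
        cursor = self.out_start[:-1].copy()
        ne = 2 * self.rho
        self.edge_dst = np.empty(ne, dtype=np.int64)
        self.edge_lablen = np.empty(ne, dtype=np.int64)
        self.edge_spm = np.empty(ne, dtype=np.int64)
        self.complement = np.empty(ne, dtype=np.int64)
        slot_of = np.empty(ne, dtype=np.int64)
        for i in range(ne):
            slot = cursor[srcs[i]]
            cursor[srcs[i]] += 1
            self.edge_dst[slot] = dsts[i]
            self.edge_lablen[slot] = lablens[i]
            self.edge_spm[slot] = spm_ref[i]
            slot_of[i] = slot
        for x in range(self.rho):
            e1, e2 = slot_of[2 * x], slot_of[2 * x + 1]
            self.complement[e1] = e2
            self.complement[e2] = e1
        self.indeg = np.bincount(self.edge_dst, minlength=self.vertex_count) if ne else np.zeros(
            self.vertex_count, dtype=np.int64
        )
        self.outdeg = outdeg

    # -- edge accessors ----------------------------------------------------
    @property
    def edge_count(self) -> int:
        return 2 * self.rho

    def out_edges(self, v: int) -> range:
        return range(int(self.out_start[v]), int(self.out_start[v + 1]))

    def edge_src(self, e: int) -> int:
        return int(np.searchsorted(self.out_start, e, side="right") - 1)

    def edge_overlap(self, e: int) -> int:
        """Overlap length of the match behind edge e."""
        dst_read = _vertex_read(int(self.edge_dst[e]))
        return self.E.length(dst_read) - int(self.edge_lablen[e])

    def oriented_seq(self, v: int) -> str:
        """Sequence of the read ending (walk-wise) at vertex v: forward for
        x.E, reverse complement for x.B."""
        r = _vertex_read(v)
        seq = self.E.strand_seq(r)
        return seq if _vertex_is_end(v) else revcomp(seq)

    def edge_label(self, e: int) -> str:
        """Spelled label: the tail of the destination's oriented sequence."""
        return self.oriented_seq(int(self.edge_dst[e]))[-int(self.edge_lablen[e]):]


def complement_edge(G: StringGraph, edge_idx: int) -> int:
    """The other edge of the same match; an involution."""
    return int(G.complement[edge_idx])


def build_graph(
    spms: Iterable[Spm],
    E: EncodedReadSet,
    contained: np.ndarray | None = None,
) -> StringGraph:
    """Build the string graph from non-redundant irreducible matches.

    ``contained`` flags (1-based) are checked: a match touching a contained
    read is a pipeline error upstream and raises GraphConsistencyError.
    """
    spms = list(spms)
    if contained is not None:
        m = E.m
        for s in spms:
            for strand in (s.src, s.dst):
                r = strand if strand <= m else strand - m
                if contained[r]:
                    raise GraphConsistencyError(
                        f"match {s} references internally contained read {r}"
                    )
    return StringGraph(E, spms)


# ---------------------------------------------------------------------------
# Contig extraction
# ---------------------------------------------------------------------------

def _simple_edges(G: StringGraph) -> np.ndarray:
    """An edge u -> v is *simple* (merge-able into a unitig) iff u has
    outdegree 1 and v indegree 1: joining it can then never place a read in
    two contigs."""
    if G.edge_count == 0:
        return np.zeros(0, dtype=bool)
    srcs = np.searchsorted(G.out_start, np.arange(G.edge_count), side="right") - 1
    return (G.outdeg[srcs] == 1) & (G.indeg[G.edge_dst] == 1)


def _walk(G: StringGraph, first_edge: int, simple: np.ndarray, visited: np.ndarray) -> list[int]:
    """Follow the chain of simple edges from ``first_edge``; marks each
    traversed edge and its complement visited."""
    path = []
    e = first_edge
    while True:
        path.append(e)
        visited[e] = True
        visited[G.complement[e]] = True
        v = int(G.edge_dst[e])
        if G.outdeg[v] != 1:
            break
        nxt = G.out_edges(v).start
        if not simple[nxt] or visited[nxt]:
            break  # branch ahead, or cycle closed
        e = nxt
    return path


def _spell(G: StringGraph, edges: list[int]) -> Contig:
    E = G.E
    v0 = G.edge_src(edges[0])
    r0 = _vertex_read(v0)
    strand0 = "+" if _vertex_is_end(v0) else "-"
    seq_parts = [G.oriented_seq(v0)]
    read_path = [(int(E.read_ids[r0 - 1]), strand0)]
    coords = [0]
    length = len(seq_parts[0])
    for e in edges:
        v = int(G.edge_dst[e])
        r = _vertex_read(v)
        lab = G.edge_label(e)
        overlap = E.length(r) - len(lab)
        coords.append(length - overlap)
        length += len(lab)
        seq_parts.append(lab)
        read_path.append((int(E.read_ids[r - 1]), "+" if _vertex_is_end(v) else "-"))
    return Contig("".join(seq_parts), read_path, coords)


def extract_contigs(
    G: StringGraph,
    min_len: int | None = None,
    contained: np.ndarray | None = None,
) -> list[Contig]:
    """Maximal unbranched walks over the simple edges of the graph, one per
    double-stranded path.

    Only simple edges (source outdegree 1, destination indegree 1) are
    merged, so every read belongs to exactly one contig; a branching read
    therefore starts a contig of its own instead of being absorbed into the
    walks that reach it.  Chains are traversed from their first simple edge
    (no simple edge enters its source vertex); leftover simple-edge cycles
    seed further walks in ascending edge order.  Reads covered by no chain
    (isolated or adjacent only to branch points), unless internally
    contained, become single-read contigs.  Contigs shorter than
    ``min_len`` are dropped.  Traversal order is deterministic (ascending
    vertex ids).
    """
    simple = _simple_edges(G)
    visited = np.zeros(G.edge_count, dtype=bool)
    simple_in = np.zeros(G.vertex_count, dtype=np.int64)
    if G.edge_count:
        np.add.at(simple_in, G.edge_dst[simple], 1)
    contigs: list[Contig] = []
    in_contig = np.zeros(G.m + 1, dtype=bool)

    def emit(chain: list[int]) -> None:
        c = _spell(G, chain)
        contigs.append(c)
        for v in [G.edge_src(chain[0])] + [int(G.edge_dst[e]) for e in chain]:
            in_contig[_vertex_read(v)] = True

    for v in range(G.vertex_count):
        if G.outdeg[v] != 1 or simple_in[v]:
            continue
        e = G.out_edges(v).start
        if simple[e] and not visited[e]:
            emit(_walk(G, e, simple, visited))
    for e in range(G.edge_count):  # simple-edge cycles
        if simple[e] and not visited[e]:
            emit(_walk(G, e, simple, visited))
    # remaining reads: isolated, or incident only to non-simple edges
    for r in range(1, G.m + 1):
        if in_contig[r] or (contained is not None and contained[r]):
            continue
        contigs.append(Contig(G.E.strand_seq(r), [(int(G.E.read_ids[r - 1]), "+")], [0]))
    if min_len is not None:
        contigs = [c for c in contigs if len(c) >= min_len]
    logger.info("extract_contigs: %d contig(s)", len(contigs))
    return contigs


def write_contigs_fasta(contigs: Sequence[Contig], path: str | Path, width: int = 70) -> None:
    """FASTA output, headers ``contig_<n> length=<L> reads=<count>``."""
    with open(path, "w") as fh:
        for n, c in enumerate(contigs, start=1):
            fh.write(f">contig_{n} length={len(c)} reads={len(c.read_path)}\n")
            for i in range(0, len(c.sequence), width):
                fh.write(c.sequence[i : i + width] + "\n")


def write_dot(G: StringGraph, path: str | Path) -> None:
    """GraphViz dump for small graphs (debugging convenience)."""
    with open(path, "w") as fh:
        fh.write("digraph stringgraph {\n")
        for v in range(G.vertex_count):
            r = _vertex_read(v)
            name = f"r{int(G.E.read_ids[r - 1])}.{'E' if _vertex_is_end(v) else 'B'}"
            fh.write(f'  v{v} [label="{name}"];\n')
        for v in range(G.vertex_count):
            for e in G.out_edges(v):
                fh.write(
                    f'  v{v} -> v{int(G.edge_dst[e])} [label="{int(G.edge_lablen[e])}"];\n'
                )
        fh.write("}\n")
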