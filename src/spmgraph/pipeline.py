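"""End-to-end assembly pipeline: prefilter -> overlap -> string graph -> contigs."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .kmercodes import KmerConfig, MAX_K
from .readset import EncodedReadSet, PrefilterReport, Read, encode, prefilter
from .spm_enum import (
    Spm,
    detect_internally_contained,
    enumerate_spms,
    filter_nonredundant,
)
from .spmindex import BufferConfig, build_sorted_buckets
from .stringgraph import Contig, StringGraph, build_graph, extract_contigs

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Tunable parameters of the assembly pipeline.

    l_min: minimum suffix-prefix match length (bases).
    k / k_prime / k_dbl_prime: mer sizes of the SPM index; derived from
        l_min and the input size when left unset (constraint chain
        k'' <= k' <= k <= min(l_min, 32)).
    parts: number of partition parts for the insertion phase (output is
        invariant under this choice); alternatively memory_limit (bytes).
    min_contig_length: contigs shorter than this are dropped
        (default l_min + 1).
    both_strands: include reverse complements (forward-only mode exists for
        testing against hand-computed examples).
    """

    l_min: int = 45
    k: int | None = None
    k_prime: int | None = None
    k_dbl_prime: int | None = None
    parts: int = 1
    memory_limit: int | None = None
    min_contig_length: int | None = None
    both_strands: bool = True
    buffer: BufferConfig = field(default_factory=BufferConfig)

    def kmer_config(self, total_length: int) -> KmerConfig:
        base = KmerConfig.defaults(self.l_min, max(total_length, 2))
        k = self.k if self.k is not None else base.k
        kp = self.k_prime if self.k_prime is not None else min(base.k_prime, k)
        kd = self.k_dbl_prime if self.k_dbl_prime is not None else min(base.k_dbl_prime, kp)
        cfg = KmerConfig(k=k, k_prime=kp, k_dbl_prime=kd)
        if cfg.k > min(self.l_min, MAX_K):
            raise ValueError(f"k={cfg.k} must be <= min(l_min, {MAX_K}) = {min(self.l_min, MAX_K)}")
        return cfg

    @property
    def contig_cutoff(self) -> int:
        return self.min_contig_length if self.min_contig_length is not None else self.l_min + 1


@dataclass
class AssemblyResult:
    readset: EncodedReadSet
    report: PrefilterReport
    contained: np.ndarray
    spms_all: list[Spm]          # classified, pre-redundancy-filter
    spms_irreducible: list[Spm]  # non-redundant irreducible (graph input)
    graph: StringGraph
    contigs: list[Contig]

    @property
    def stats(self) -> dict:
        return {
            "reads_kept": self.readset.m,
            "total_length": self.readset.n,
            "contained_reads": int(self.contained.sum()),
            "spms_total": len(self.spms_all),
            "spms_transitive": sum(1 for s in self.spms_all if s.status == "transitive"),
            "spms_irreducible_nonredundant": len(self.spms_irreducible),
            "contigs": len(self.contigs),
            "longest_contig": max((len(c) for c in self.contigs), default=0),
        }


def compute_spms(
    E: EncodedReadSet, cfg: PipelineConfig
) -> tuple[list[Spm], list[Spm], np.ndarray]:
    """Overlap phase on a suffix-/prefix-free read set.

    Two bottom-up passes over the sorted buckets: the first flags internally
    contained reads, the second enumerates and classifies matches with the
    contained reads' entries treated as absent.  Returns (all classified
    matches, non-redundant irreducible matches, contained flags).
    """
    if E.is_empty:
        return [], [], np.zeros(1, dtype=bool)
    kcfg = cfg.kmer_config(E.n)
    buckets = build_sorted_buckets(
        E,
        cfg.l_min,
        kcfg,
        q_parts=cfg.parts,
        memory_limit=cfg.memory_limit,
        buf=cfg.buffer,
        both_strands=cfg.both_strands,
    )
    contained = detect_internally_contained(buckets, E)
    spms_all = enumerate_spms(buckets, cfg.l_min, E, contained=contained)
    irreducible = [s for s in spms_all if s.status == "irreducible"]
    nonredundant = (
        filter_nonredundant(irreducible, E.m) if cfg.both_strands else irreducible
    )
    logger.info(
        "overlap: %d matches, %d irreducible, %d non-redundant irreducible, "
        "%d contained read(s)",
        len(spms_all), len(irreducible), len(nonredundant), int(contained.sum()),
    )
    return spms_all, nonredundant, contained


def assemble_reads(reads: Sequence[Read], cfg: PipelineConfig | None = None) -> AssemblyResult:
    """Run the full pipeline on already-validated reads."""
    cfg = cfg or PipelineConfig()
    E0 = encode(reads, cfg.l_min)
    if E0.is_empty:
        raise ValueError("no reads of length >= l_min in the input")
    E, report = prefilter(E0)
    if E.is_empty:
        raise ValueError("prefilter removed all reads")
    spms_all, nonredundant, contained = compute_spms(E, cfg)
    graph = build_graph(nonredundant, E, contained)
    contigs = extract_contigs(graph, min_len=cfg.contig_cutoff, contained=contained)
    return AssemblyResult(
        readset=E,
        report=report,
        contained=contained,
        spms_all=spms_all,
        spms_irreducible=nonredundant,
        graph=graph,
        contigs=contigs,
    )
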