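"""Synthetic templates and read sets for testing and benchmarking.

Reads are drawn error-free from a random template genome and its reverse
complement by uniform position/strand sampling (the standard protocol for
benchmarking exact-overlap assemblers: 20x coverage, constant 100 bp reads,
both strands), or deterministically tiled across the template when a
coverage guarantee is needed.  An optional substitution-noise rate is
available to demonstrate how exact-match overlap enumeration degrades with
sequencing errors; it is off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .readset import Read, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Read-simulation parameters.

    coverage: mean fold coverage of the template.
    read_length: constant length, or an inclusive (min, max) range for
        variable-length sets.
    error_rate: per-base substitution probability (0 = error-free).
    mode: 'random-sample' (uniform positions and strands) or 'tiled'
        (deterministic offsets, forward strand).
    """

    template_length: int
    coverage: float = 20.0
    read_length: int | tuple[int, int] = 100
    seed: int = 1
    mode: str = "random-sample"
    error_rate: float = 0.0
    tile_step: int | None = None

    def __post_init__(self):
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        lo, hi = self.length_range
        if not 1 <= lo <= hi <= self.template_length:
            raise ValueError("read length must be within [1, template_length]")
        if self.mode not in ("random-sample", "tiled"):
            raise ValueError(f"unknown simulation mode {self.mode!r}")

    @property
    def length_range(self) -> tuple[int, int]:
        if isinstance(self.read_length, tuple):
            return self.read_length
        return (self.read_length, self.read_length)

    @property
    def mean_read_length(self) -> float:
        lo, hi = self.length_range
        return (lo + hi) / 2.0


def random_genome(length: int, seed: int | np.random.Generator) -> str:
    """Uniform i.i.d. random DNA template, deterministic per seed."""
    if length < 1:
        raise ValueError("template length must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.choice(_BASES, size=length).tobytes().decode()


def simulate_reads(template: str, cfg: SimConfig) -> list[Read]:
    """Sample reads from the template and its reverse complement.

    The read count is ceil(coverage * |template| / mean_read_length); each
    read is an exact substring of the template or of its reverse complement
    (position and strand uniform), optionally perturbed by substitution
    noise.  Deterministic per cfg.seed.
    """
    if cfg.mode == "tiled":
        lo, hi = cfg.length_range
        step = cfg.tile_step or lo // 2
        return tile_reads(template, lo, step)
    rng = np.random.default_rng(cfg.seed)
    n_reads = math.ceil(cfg.coverage * len(template) / cfg.mean_read_length)
    lo, hi = cfg.length_range
    rc = revcomp(template)
    reads: list[Read] = []
    for i in range(n_reads):
        L = int(rng.integers(lo, hi + 1))
        pos = int(rng.integers(0, len(template) - L + 1))
        strand = int(rng.integers(0, 2))
        seq = (template if strand == 0 else rc)[pos : pos + L]
        if cfg.error_rate > 0.0:
            seq = _substitute(seq, cfg.error_rate, rng)
        reads.append(Read(i + 1, seq))
    return reads


def _substitute(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def tile_reads(
    template: str, L: int, step: int, l_min: int | None = None
) -> list[Read]:
    """Deterministic tiling: reads at offsets 0, step, 2*step, ... plus one
    flush-right read, guaranteeing consecutive overlaps of >= L - step.

    With ``l_min`` given, ``step > L - l_min`` is rejected (the tiling could
    otherwise not guarantee overlaps of the minimum match length).
    """
    if l_min is not None and step > L - l_min:
        raise ValueError(
            f"step {step} too large: must be <= L - l_min = {L - l_min} to "
            f"guarantee overlaps of at least l_min={l_min}"
        )
    if not 1 <= L <= len(template):
        raise ValueError("read length must be within the template")
    if step < 1:
        raise ValueError("step must be >= 1")
    offsets = list(range(0, len(template) - L + 1, step))
    last = len(template) - L
    if offsets[-1] != last:
        offsets.append(last)
    return [Read(i + 1, template[o : o + L]) for i, o in enumerate(offsets)]
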