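"""Integer k-mer codes and the prefix/suffix membership filters.

A string ``s`` of length >= k is encoded by the order-preserving integer code
``phi_k(s) = sum_{i=1..k} 4^(k-i) * phi(s[i])`` with ``phi = [A->0, C->1,
G->2, T->3]``, so ``s <= s'`` lexicographically implies ``phi_k(s) <=
phi_k(s')``.  Two derived codes are obtained in constant time from
``phi_k(s)``:

* the code of the length-k' prefix: ``phi_k(s) >> 2*(k - k')``;
* the code of ``s[k-k''+1 .. k]`` (the tail of the initial k-mer):
  ``phi_k(s) & (4^k'' - 1)``.

The sets P (all initial k'-mer codes of the reads) and Q (all derived-suffix
codes of the reads' initial k-mers) act as cheap filters: a proper suffix
whose derived codes miss P or Q cannot share a length-k prefix with any read
and is discarded before the exact initial-k-mer check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .readset import EncodedReadSet

#: Largest supported k: one code per 64-bit machine word, 2 bits per base.
MAX_K = 32

BASE_TO_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class KmerConfig:
    """Mer sizes for the SPM index: k (bucket key), k' (P), k'' (Q)."""

    k: int
    k_prime: int
    k_dbl_prime: int

    def __post_init__(self):
        if not 1 <= self.k <= MAX_K:
            raise ValueError(f"k must be in 1..{MAX_K}, got {self.k}")
        if not 1 <= self.k_dbl_prime <= self.k_prime <= self.k:
            raise ValueError(
                f"mer sizes must satisfy 1 <= k'' <= k' <= k, got "
                f"k={self.k}, k'={self.k_prime}, k''={self.k_dbl_prime}"
            )

    def validate_against(self, l_min: int) -> None:
        if self.k > l_min:
            raise ValueError(f"k={self.k} must not exceed l_min={l_min}")

    @classmethod
    def defaults(cls, l_min: int, total_length: int) -> "KmerConfig":
        """Default mer sizes: k = min(l_min, 32); k' scales with log2 of the
        total input length (clamped to [8, k]); k'' = k' - 1 (floor 1)."""
        k = min(l_min, MAX_K)
        k_prime = math.ceil(math.log2(total_length)) - 8 if total_length > 1 else 8
        k_prime = max(8, k_prime)
        k_prime = min(k_prime, k)
        k_dbl = max(1, k_prime - 1)
        return cls(k=k, k_prime=k_prime, k_dbl_prime=k_dbl)


# ---------------------------------------------------------------------------
# Scalar codes
# ---------------------------------------------------------------------------

def phi_code(s: str, k: int | None = None) -> int:
    """Integer code of the length-k prefix of ``s`` (k defaults to len(s))."""
    if k is None:
        k = len(s)
    if k > len(s):
        raise ValueError(f"string of length {len(s)} too short for k={k}")
    code = 0
    for ch in s[:k]:
        code = (code << 2) | BASE_TO_CODE[ch]
    return code


def phi_k(E: "EncodedReadSet", strand_idx: int, pos1: int, k: int) -> int:
    """Code of the k-mer of a strand starting at 1-based position ``pos1``."""
    seq = E.strand_seq(strand_idx)
    if pos1 + k - 1 > len(seq):
        raise ValueError(
            f"k-mer window [{pos1}..{pos1 + k - 1}] exceeds strand length {len(seq)}"
        )
    return phi_code(seq[pos1 - 1 :], k)


def derive_prefix_code(code: int, k: int, k_prime: int) -> int:
    """Code of the k'-prefix of a k-mer: a right shift by 2(k - k') bits."""
    return code >> (2 * (k - k_prime))


def derive_suffix_code(code: int, k: int, k_dbl_prime: int) -> int:
    """Code of positions k-k''+1..k of a k-mer: a mask with 4^k'' - 1."""
    return code & ((1 << (2 * k_dbl_prime)) - 1)


def sliding_codes(E: "EncodedReadSet", strand_idx: int, k: int) -> Iterator[tuple[int, int]]:
    """Yield (pos1, code) for every k-window of a strand, rolling in O(1).

    Each step drops the highest base digit, shifts, and adds the new base.
    """
    seq = E.strand_seq(strand_idx)
    if len(seq) < k:
        return
    mask = (1 << (2 * k)) - 1
    code = phi_code(seq, k)
    yield 1, code
    for pos0 in range(k, len(seq)):
        code = ((code << 2) | BASE_TO_CODE[seq[pos0]]) & mask
        yield pos0 - k + 2, code


# ---------------------------------------------------------------------------
# Vectorised window codes (shared by the counting and insertion phases)
# ---------------------------------------------------------------------------

def window_code_matrix(
    E: "EncodedReadSet", k: int, both_strands: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """All k-window codes of all strands at once.

    Returns ``(codes, nwin)``: ``codes[i, c]`` is the uint64 code of the
    window starting at 0-based offset ``c`` on strand ``i+1`` (valid for
    ``c < nwin[i]`` where ``nwin[i] = len_i - k + 1``); entries beyond a
    strand's last window are meaningless and must be masked by the caller.
    """
    mat = E.base_matrix(both_strands)
    lengths = E.strand_lengths(both_strands)
    if mat.shape[1] < k:
        raise ValueError(f"k={k} exceeds the longest read")
    width = mat.shape[1] - k + 1
    codes = np.zeros((mat.shape[0], width), dtype=np.uint64)
    for j in range(k):
        codes <<= np.uint64(2)
        codes |= mat[:, j : j + width].astype(np.uint64)
    nwin = lengths - k + 1
    return codes, nwin


# ---------------------------------------------------------------------------
# Membership filters
# ---------------------------------------------------------------------------

class BitFilter:
    """Exact membership structure over integer codes in [0 .. 4^merSize - 1].

    Backed by a sorted unique code array with binary-search membership, which
    stays compact for large mer sizes while keeping queries exact.
    """

    def __init__(self, mer_size: int, codes: np.ndarray | None = None):
        self.mer_size = mer_size
        if codes is None:
            codes = np.empty(0, dtype=np.uint64)
        self._codes = np.unique(np.asarray(codes, dtype=np.uint64))
        limit = 1 << (2 * mer_size)
        if self._codes.size and int(self._codes[-1]) >= limit:
            raise ValueError(f"code {int(self._codes[-1])} out of range for mer size {mer_size}")

    def __len__(self) -> int:
        return int(self._codes.size)

    def __contains__(self, code: int) -> bool:
        return bool(self.contains(np.asarray([code], dtype=np.uint64))[0])

    def contains(self, codes: np.ndarray) -> np.ndarray:
        """Vectorised membership test."""
        codes = np.asarray(codes, dtype=np.uint64)
        out = np.zeros(codes.shape, dtype=bool)
        if self._codes.size == 0:
            return out
        idx = np.searchsorted(self._codes, codes)
        inside = idx < self._codes.size
        out[inside] = self._codes[idx[inside]] == codes[inside]
        return out


def build_filters(
    initial_codes: np.ndarray, cfg: KmerConfig
) -> tuple[BitFilter, BitFilter]:
    """Build the P and Q filters from the (sorted) initial k-mer codes."""
    codes = np.asarray(initial_codes, dtype=np.uint64)
    shift = np.uint64(2 * (cfg.k - cfg.k_prime))
    p_codes = codes >> shift
    mask = np.uint64((1 << (2 * cfg.k_dbl_prime)) - 1)
    q_codes = codes & mask
    return BitFilter(cfg.k_prime, p_codes), BitFilter(cfg.k_dbl_prime, q_codes)
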