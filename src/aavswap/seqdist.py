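"""Levenshtein utilities shared across the package.

edlib provides the pairwise distances; this module adds the radius queries the
dictionary filters need and a pigeonhole-partition index so that barcode sets
in the tens of thousands can be rejection-sampled with a minimum pairwise
distance without an all-pairs scan.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import edlib


def levenshtein(a: str, b: str, k: int = -1) -> int:
    """Levenshtein distance; returns -1 if a cap ``k`` >= 0 is exceeded."""
    return edlib.align(a, b, mode="NW", task="distance", k=k)["editDistance"]


def within(a: str, b: str, radius: int) -> bool:
    """True when Levenshtein(a, b) <= radius."""
    d = levenshtein(a, b, k=radius)
    return 0 <= d <= radius


def neighbors_within(query: str, pool: Iterable[str], radius: int) -> List[str]:
    """All sequences from ``pool`` within Levenshtein ``radius`` of ``query``."""
    return [s for s in pool if within(query, s, radius)]


class NeighborIndex:
    """Exact Levenshtein radius queries over same-length sequences.

    Uses the pigeonhole principle: if d(q, s) <= r then at least one of the
    r+1 contiguous parts of q occurs *exactly* as a substring of s.  Stored
    sequences are indexed by all substrings of the part lengths, candidate
    hits are verified with edlib.  Exact (no false negatives) for any radius.
    """

    def __init__(self, radius: int, seq_len: int):
        if radius < 0:
            raise ValueError("radius must be >= 0")
        self.radius = radius
        self.seq_len = seq_len
        self.seqs: List[str] = []
        n_parts = radius + 1
        base, extra = divmod(seq_len, n_parts)
        self._part_bounds: List[Tuple[int, int]] = []
        pos = 0
        for i in range(n_parts):
            ln = base + (1 if i < extra else 0)
            self._part_bounds.append((pos, pos + ln))
            pos += ln
        self._part_lengths: Set[int] = {e - s for s, e in self._part_bounds if e > s}
        self._index: Dict[str, Set[int]] = defaultdict(set)

    def _parts(self, seq: str) -> List[str]:
        return [seq[s:e] for s, e in self._part_bounds if e > s]

    def has_neighbor(self, seq: str) -> bool:
        """True if any stored sequence is within ``radius`` of ``seq``."""
        if len(seq) != self.seq_len:
            raise ValueError("sequence length mismatch")
        if self.radius == 0:
            return bool(self._index.get(seq))
        cands: Set[int] = set()
        for part in self._parts(seq):
            cands |= self._index.get(part, set())
        return any(within(seq, self.seqs[i], self.radius) for i in cands)

    def add(self, seq: str) -> None:
        idx = len(self.seqs)
        self.seqs.append(seq)
        if self.radius == 0:
            self._index[seq].add(idx)
            return
        for ln in self._part_lengths:
            for i in range(self.seq_len - ln + 1):
                self._index[seq[i:i + ln]].add(idx)


def pairs_within_radius(
    seqs: Sequence[str], radius: int
) -> List[Tuple[int, int]]:
    """All index pairs (i < j) with Levenshtein distance <= radius.

    Brute force; intended for the modest high-count barcode sets fed to the
    connected-component error correction.
    """
    out = []
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            if within(seqs[i], seqs[j], radius):
                out.append((i, j))
    return out
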