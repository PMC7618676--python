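"""Low-level sequence helpers shared by the simulator and the toy mapper.

Bases are encoded A=0, C=1, G=2, T=3; anything else (N) gets code 4 and is
excluded from k-mer indexing. All coordinates are 0-based half-open.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_CODE[ord("U")] = 3  # RNA uracil maps onto thymine for genomic work
_CODE[ord("u")] = 3

_COMP = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as uint8 codes (A0 C1 G2 T3, other 4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Packed integer codes for every k-mer; -1 where the window contains non-ACGT."""
    if codes.size < k:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k).astype(np.int64)
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    vals = win @ weights
    bad = np.lib.stride_tricks.sliding_window_view(codes == 4, k).any(axis=1)
    vals[bad] = -1
    return vals


class KmerIndex:
    """Sorted exact k-mer index over a multi-chromosome genome.

    Chromosomes are concatenated with k-1 N spacers so no k-mer spans a
    boundary; lookups return (chrom index, position-on-chrom) pairs.
    """

    def __init__(self, genome: Mapping[str, str], k: int):
        self.k = k
        self.chroms = list(genome)
        self.chrom_len = np.array([len(genome[c]) for c in self.chroms], dtype=np.int64)
        spacer = "N" * (k - 1)
        concat = spacer.join(genome[c] for c in self.chroms)
        self.offsets = np.zeros(len(self.chroms), dtype=np.int64)
        off = 0
        for i, c in enumerate(self.chroms):
            self.offsets[i] = off
            off += len(genome[c]) + k - 1
        self.codes = encode(concat)
        kmers = kmer_codes(self.codes, k)
        order = np.argsort(kmers, kind="stable")
        self._sorted = kmers[order]
        self._pos = order.astype(np.int64)
        # trim the invalid (-1) block from the front
        first = np.searchsorted(self._sorted, 0, side="left")
        self._sorted = self._sorted[first:]
        self._pos = self._pos[first:]

    def lookup_many(self, queries: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """For an array of packed k-mer codes, return (query index, global position)
        for every genomic occurrence of every query."""
        lo = np.searchsorted(self._sorted, queries, side="left")
        hi = np.searchsorted(self._sorted, queries, side="right")
        counts = hi - lo
        qidx = np.repeat(np.arange(queries.size), counts)
        if qidx.size == 0:
            return qidx, np.empty(0, dtype=np.int64)
        # expand [lo, hi) ranges into flat indices
        starts = np.repeat(lo, counts)
        within = np.arange(counts.sum()) - np.repeat(np.cumsum(counts) - counts, counts)
        return qidx, self._pos[starts + within]

    def to_chrom(self, gpos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map global concatenated positions to (chrom index, local position)."""
        ci = np.searchsorted(self.offsets, gpos, side="right") - 1
        return ci, gpos - self.offsets[ci]
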