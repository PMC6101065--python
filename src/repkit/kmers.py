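"""K-mer counting and frequency-tier classification.

Repeat families leave a footprint in the k-mer frequency spectrum of a
read set: a k-mer conserved across c copies of a repeat is seen roughly
c times more often than a k-mer from single-copy sequence. This module
counts (optionally canonical) k-mers, estimates the single-copy base
frequency from the count histogram, and splits the table into a highly
frequent tier (confident repeat k-mers) and an intermediate tier
(candidate repeat k-mers recovered later by recruitment).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from ._seq import BASE_CODE, CODE_BASE, canonical, encode, reverse_complement

__all__ = [
    "KmerTable",
    "SelectionParams",
    "EmptyTableError",
    "BaseFreqError",
    "count_kmers",
    "frequency_histogram",
    "estimate_base_freq",
    "classify_kmers",
]


class EmptyTableError(ValueError):
    """No k-mer could be extracted (k exceeds every read length)."""


class BaseFreqError(ValueError):
    """The count histogram has no usable bin; supply base_freq manually."""


@dataclass
class KmerTable:
    """Mapping from fixed-length DNA words to positive counts.

    When ``canonical`` is true every key is lexicographically <= its
    reverse complement and pools the counts of both orientations.
    """

    k: int
    counts: dict[str, int] = field(default_factory=dict)
    canonical: bool = True

    def __len__(self) -> int:
        return len(self.counts)

    def __getitem__(self, key: str) -> int:
        return self.counts[key]

    def __contains__(self, key: str) -> bool:
        return key in self.counts

    def __iter__(self) -> Iterator[str]:
        return iter(self.counts)

    def items(self):
        return self.counts.items()

    def validate(self) -> None:
        for w, c in self.counts.items():
            if len(w) != self.k:
                raise ValueError(f"key {w!r} does not have length k={self.k}")
            if set(w) - set("ACGT"):
                raise ValueError(f"key {w!r} has non-ACGT characters")
            if c < 1:
                raise ValueError(f"count for {w!r} is {c} < 1")
            if self.canonical and reverse_complement(w) < w:
                raise ValueError(f"key {w!r} is not canonical")


@dataclass
class SelectionParams:
    """Frequency cutoffs, as multiples of the single-copy base frequency.

    ``high_multiplier`` (default 10) sets the highly-frequent tier and
    can be read as the minimum copy number targeted; ``mid_multiplier``
    (default 3) sets the floor of the intermediate tier. Both lower
    bounds are inclusive.
    """

    base_freq: float
    high_multiplier: float = 10.0
    mid_multiplier: float = 3.0

    def __post_init__(self) -> None:
        if self.base_freq <= 0:
            raise ValueError("base_freq must be positive")
        if not 0 < self.mid_multiplier < self.high_multiplier:
            raise ValueError("need 0 < mid_multiplier < high_multiplier")


def _count_batch(codes: np.ndarray, k: int, canonical_mode: bool) -> np.ndarray:
    """Return int64 k-mer codes for every valid window of a code matrix."""
    n, length = codes.shape
    if length < k:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k, axis=1)
    valid = (win != 255).all(axis=2)
    pw = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    fwd = win.astype(np.int64) @ pw
    if canonical_mode:
        # reverse complement: complement codes, read positions in reverse
        rc = (3 - win.astype(np.int64)) @ pw[::-1]
        fwd = np.minimum(fwd, rc)
    return fwd[valid]


def _decode_batch(codes: np.ndarray, k: int) -> list[str]:
    """Vectorised decoding of int64 k-mer codes back to strings."""
    if codes.size == 0:
        return []
    digits = np.empty((codes.size, k), dtype=np.uint8)
    rem = codes.copy()
    for j in range(k - 1, -1, -1):
        digits[:, j] = rem & 3
        rem >>= 2
    ascii_mat = CODE_BASE[digits]
    flat = np.ascontiguousarray(ascii_mat).view(f"S{k}").ravel()
    return [s.decode("ascii") for s in flat]


def count_kmers(reads: Iterable[str], k: int, canonical: bool = True) -> KmerTable:
    """Count all length-k windows over a collection of reads.

    Windows containing ambiguous bases (anything outside ACGT) are
    skipped. With ``canonical=True`` a window and its reverse complement
    pool under the lexicographically smaller word. Raises
    :class:`EmptyTableError` if no read is long enough.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k <= 31:  # 2k bits fit an int64: vectorised path
        by_len: dict[int, list[np.ndarray]] = {}
        n_reads = 0
        for read in reads:
            n_reads += 1
            if len(read) < k:
                continue
            by_len.setdefault(len(read), []).append(encode(read))
        if n_reads == 0:
            raise ValueError("reads collection is empty")
        chunks = []
        for length, rows in by_len.items():
            mat = np.vstack(rows) if len(rows) > 1 else rows[0][None, :]
            chunks.append(_count_batch(mat, k, canonical))
        if not chunks or all(c.size == 0 for c in chunks):
            raise EmptyTableError(f"no read has length >= k={k}")
        codes = np.concatenate(chunks)
        uniq, cnt = np.unique(codes, return_counts=True)
        keys = _decode_batch(uniq, k)
        return KmerTable(k=k, counts=dict(zip(keys, cnt.tolist())), canonical=canonical)
    # fallback for very long words
    counter: Counter[str] = Counter()
    n_reads = 0
    for read in reads:
        n_reads += 1
        read = read.upper()
        for i in range(len(read) - k + 1):
            w = read[i : i + k]
            if set(w) - set("ACGT"):
                continue
            counter[canonical_word(w) if canonical else w] += 1
    if n_reads == 0:
        raise ValueError("reads collection is empty")
    if not counter:
        raise EmptyTableError(f"no read has length >= k={k}")
    return KmerTable(k=k, counts=dict(counter), canonical=canonical)


def canonical_word(w: str) -> str:
    return canonical(w)


def frequency_histogram(table: KmerTable) -> dict[int, int]:
    """Map count -> number of distinct k-mers with that count."""
    if len(table) == 0:
        raise ValueError("empty k-mer table")
    hist: Counter[int] = Counter(table.counts.values())
    return dict(hist)


def estimate_base_freq(hist: dict[int, int], min_count: int = 2) -> int:
    """Single-copy k-mer frequency: the histogram mode above the error peak.

    Sequencing errors produce a large spike of k-mers seen once (or very
    few times); bins below ``min_count`` are excluded before taking the
    mode. Ties resolve to the smaller count for determinism. Users with
    known read depth may bypass this and set ``base_freq`` directly.
    """
    eligible = {c: n for c, n in hist.items() if c >= min_count}
    if not eligible:
        raise BaseFreqError(
            "no histogram bin with count >= "
            f"{min_count}; supply base_freq manually"
        )
    best = max(sorted(eligible), key=lambda c: eligible[c])
    return best


def classify_kmers(
    table: KmerTable, params: SelectionParams
) -> tuple[KmerTable, KmerTable]:
    """Split a table into (highly frequent, intermediate) tiers.

    high: count >= high_multiplier * base_freq;
    intermediate: mid_multiplier * base_freq <= count < the high cutoff.
    Everything below the intermediate floor is discarded.
    """
    hi_cut = params.high_multiplier * params.base_freq
    mid_cut = params.mid_multiplier * params.base_freq
    high: dict[str, int] = {}
    mid: dict[str, int] = {}
    for w, c in table.items():
        if c >= hi_cut:
            high[w] = c
        elif c >= mid_cut:
            mid[w] = c
    return (
        KmerTable(k=table.k, counts=high, canonical=table.canonical),
        KmerTable(k=table.k, counts=mid, canonical=table.canonical),
    )
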