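"""Recruitment of intermediate-frequency repeat k-mers.

K-mers from diverged repeat regions often fall below the highly
frequent cutoff but remain near-identical in sequence to some highly
frequent k-mer. Recruitment recovers them with a seed-and-check rule:
a candidate must share an exact ``seed_len``-mer with a high-tier
k-mer, and its best match-only alignment score against a seed-sharing
high k-mer (the longest common subsequence, since mismatches and gaps
carry no penalty) must reach ``min_score`` (default k-5). The step can
be iterated, letting newly recruited k-mers recruit their neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._seq import lcs_length, reverse_complement
from .kmers import KmerTable

__all__ = [
    "RecruitmentParams",
    "SeedIndex",
    "match_score",
    "shares_seed",
    "recruit_kmers",
    "iterative_recruit",
]


@dataclass
class RecruitmentParams:
    """min_score defaults to k-5 when left as None."""

    min_score: int | None = None
    seed_len: int = 12
    max_rounds: int = 1

    def resolved_min_score(self, k: int) -> int:
        ms = self.min_score if self.min_score is not None else k - 5
        if not 1 <= self.seed_len <= ms <= k:
            raise ValueError(
                f"need 1 <= seed_len ({self.seed_len}) <= min_score ({ms}) <= k ({k})"
            )
        return ms

    def __post_init__(self) -> None:
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")


def match_score(a: str, b: str) -> int:
    """Optimal alignment score with match reward 1 and zero penalties.

    Equals the longest-common-subsequence length of the two words.
    """
    return lcs_length(a, b)


class SeedIndex:
    """Exact-seed index over the high-tier k-mers.

    Maps every length-``seed_len`` window of every indexed k-mer (both
    strands when the table is canonical) to the set of source words.
    """

    def __init__(self, high: KmerTable, seed_len: int):
        self.seed_len = seed_len
        self._index: dict[str, set[str]] = {}
        for w in high:
            orients = (w, reverse_complement(w)) if high.canonical else (w,)
            for o in orients:
                for i in range(len(o) - seed_len + 1):
                    self._index.setdefault(o[i : i + seed_len], set()).add(w)

    def candidates(self, query: str) -> set[str]:
        """High k-mers sharing at least one seed with the query."""
        out: set[str] = set()
        for i in range(len(query) - self.seed_len + 1):
            hit = self._index.get(query[i : i + self.seed_len])
            if hit:
                out |= hit
        return out


def shares_seed(a: str, high_index: SeedIndex, seed_len: int | None = None) -> bool:
    """True iff some window of ``a`` occurs in an indexed high k-mer."""
    if seed_len is not None and seed_len != high_index.seed_len:
        raise ValueError("seed_len does not match the index")
    return bool(high_index.candidates(a))


def recruit_kmers(
    intermediate: KmerTable, high: KmerTable, params: RecruitmentParams
) -> KmerTable:
    """One recruitment round: filter intermediate k-mers by similarity to high.

    A k-mer is recruited when some orientation of it shares a seed with a
    high k-mer and scores >= min_score against one of the seed-sharing
    candidates. Counts are preserved from the intermediate table;
    alignments are per-k-mer, never across k-mer boundaries.
    """
    if intermediate.k != high.k:
        raise ValueError(f"k mismatch: {intermediate.k} vs {high.k}")
    k = intermediate.k
    ms = params.resolved_min_score(k)
    index = SeedIndex(high, params.seed_len)
    recruited: dict[str, int] = {}
    for w, c in intermediate.items():
        orients = (w, reverse_complement(w)) if intermediate.canonical else (w,)
        hit = False
        for o in orients:
            for cand in index.candidates(o):
                if match_score(o, cand) >= ms:
                    hit = True
                    break
            if hit:
                break
        if hit:
            recruited[w] = c
    return KmerTable(k=k, counts=recruited, canonical=intermediate.canonical)


def iterative_recruit(
    intermediate: KmerTable, high: KmerTable, params: RecruitmentParams
) -> KmerTable:
    """Run recruitment for up to ``max_rounds`` and merge with the high tier.

    Round r recruits the remaining intermediate k-mers against the union
    of the high tier and everything recruited in rounds < r, so the
    result grows monotonically with max_rounds. Returns high plus all
    recruited k-mers (counts from their source tables).
    """
    merged = dict(high.counts)
    remaining = dict(intermediate.counts)
    reference = high
    for _ in range(params.max_rounds):
        got = recruit_kmers(
            KmerTable(intermediate.k, remaining, intermediate.canonical),
            reference,
            params,
        )
        if len(got) == 0:
            break
        merged.update(got.counts)
        for w in got:
            del remaining[w]
        reference = KmerTable(high.k, merged, high.canonical)
    return KmerTable(k=high.k, counts=merged, canonical=high.canonical)
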