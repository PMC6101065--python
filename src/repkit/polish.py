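"""Randomized consensus polishing of repeat k-mers.

Copies of a repeat differ from their consensus by scattered mutations,
so k-mers drawn from the same repeat position are near-identical
("end-to-end matched"). Polishing groups such k-mers and replaces each
group by a frequency-weighted positional consensus:

* For each of ``n_trials`` trials, the same random subset of h of the k
  positions is extracted from every k-mer; k-mers with identical h-mers
  in at least one trial are linked, and groups are the connected
  components of the link graph.
* Two k-mers at edit distance e are linked in one trial with probability
  C(k-e, h) / C(k, h), hence grouped overall with probability
  p = 1 - (1 - C(k-e,h)/C(k,h))^n  (exact for substitutions).
* Each group votes per position, every member weighting its base by its
  count; the winning base forms the consensus and the maximum winning
  vote across positions becomes the consensus frequency.

Execution can be partitioned map-reduce style over bucket keys; the
result is bit-identical for any partition count.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np

from .kmers import KmerTable

__all__ = [
    "PolishParams",
    "grouping_probability",
    "default_n_trials",
    "draw_position_sets",
    "find_groups",
    "consensus_vote",
    "polish",
]


def grouping_probability(k: int, h: int, e: int, n: int) -> float:
    """Probability that two k-mers at edit distance e are grouped.

    Exact closed form 1 - (1 - C(k-e,h)/C(k,h))^n with integer binomial
    coefficients; C(k-e,h) is 0 when h > k-e.
    """
    if not (1 <= h <= k):
        raise ValueError("need 1 <= h <= k")
    if e < 0 or e >= k:
        raise ValueError("need 0 <= e < k")
    if n < 1:
        raise ValueError("need n >= 1")
    miss = 1 - comb(k - e, h) / comb(k, h)
    return 1.0 - miss**n


def default_n_trials(k: int, h: int, e: int, target: float = 0.99) -> int:
    """Smallest trial count with grouping_probability >= target."""
    n = 1
    while grouping_probability(k, h, e, n) < target:
        n += 1
        if n > 10_000:
            raise ValueError("target probability unreachable for these k, h, e")
    return n


@dataclass
class PolishParams:
    """Parameters of the randomized grouping.

    h defaults to min(15, k); n_trials, when None, is the smallest count
    giving grouping probability >= 0.99 at the configured (k, h, e).
    e=1 tolerates one mismatch/indel per k-mer, reasonable for k < 100.
    """

    k: int
    h: int | None = None
    n_trials: int | None = None
    e: int = 1
    seed: int = 0
    n_partitions: int = 1

    def __post_init__(self) -> None:
        if self.h is None:
            self.h = min(15, self.k)
        if not 1 <= self.h <= self.k:
            raise ValueError("need 1 <= h <= k")
        if not 0 <= self.e < self.k:
            raise ValueError("need 0 <= e < k")
        if self.n_trials is None:
            self.n_trials = default_n_trials(self.k, self.h, self.e)
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.n_partitions < 1:
            raise ValueError("n_partitions must be >= 1")


def draw_position_sets(params: PolishParams) -> list[tuple[int, ...]]:
    """n_trials sorted position subsets of {0..k-1}, each of size h.

    Sampling is without replacement within a trial and independent
    across trials; deterministic given the seed. The same subsets are
    applied to every k-mer of a trial, which preserves the pairwise
    grouping probability while allowing linear-time bucketing.
    """
    rng = np.random.default_rng(params.seed)
    return [
        tuple(sorted(rng.choice(params.k, size=params.h, replace=False).tolist()))
        for _ in range(params.n_trials)
    ]


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        p = self.parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def find_groups(
    kmers: KmerTable | Sequence[str], params: PolishParams
) -> list[list[str]]:
    """Partition k-mers into end-to-end-match groups.

    Per trial, k-mers are bucketed by the h-mer extracted at that
    trial's positions; k-mers sharing a bucket in any trial are linked
    and groups are the connected components. Partitioned execution
    splits the (trial, bucket) work units by a deterministic key; links
    are pooled globally so output does not depend on n_partitions.
    """
    keys = list(kmers) if not isinstance(kmers, KmerTable) else list(kmers.counts)
    for w in keys:
        if len(w) != params.k:
            raise ValueError(f"k-mer {w!r} does not have length k={params.k}")
    if not keys:
        return []
    mat = (
        np.frombuffer("".join(keys).encode("ascii"), dtype=np.uint8)
        .reshape(len(keys), params.k)
    )
    trials = draw_position_sets(params)
    uf = _UnionFind(len(keys))
    # map-reduce shape: each partition handles the buckets whose key
    # hashes to it; links from all partitions are unioned identically.
    all_links: list[list[tuple[int, int]]] = [[] for _ in range(params.n_partitions)]
    for t, positions in enumerate(trials):
        sub = np.ascontiguousarray(mat[:, list(positions)])
        bucket_keys = sub.view(f"S{params.h}").ravel()
        order = np.argsort(bucket_keys, kind="stable")
        sorted_keys = bucket_keys[order]
        boundaries = np.nonzero(sorted_keys[1:] != sorted_keys[:-1])[0] + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [len(keys)]))
        for s, e_ in zip(starts.tolist(), ends.tolist()):
            if e_ - s < 2:
                continue
            part = (int.from_bytes(sorted_keys[s], "big") + t) % params.n_partitions
            members = order[s:e_].tolist()
            first = members[0]
            for m in members[1:]:
                all_links[part].append((first, m))
    for part_links in all_links:
        for a, b in part_links:
            uf.union(a, b)
    groups: dict[int, list[str]] = {}
    for i, w in enumerate(keys):
        groups.setdefault(uf.find(i), []).append(w)
    return list(groups.values())


_BASES = "ACGT"


def consensus_vote(group: Sequence[tuple[str, int]]) -> tuple[str, int]:
    """Frequency-weighted positional consensus of a k-mer group.

    Each member votes for its base at every position with weight equal
    to its count; the maximum-vote base wins (ties to the
    lexicographically smallest base) and the maximum winning vote over
    all positions becomes the consensus frequency.
    """
    if not group:
        raise ValueError("empty group")
    k = len(group[0][0])
    word = []
    best_votes = []
    for pos in range(k):
        tally = dict.fromkeys(_BASES, 0)
        for w, c in group:
            tally[w[pos]] += c
        top = max(tally.values())
        win = min(b for b in _BASES if tally[b] == top)  # tie -> lexicographic
        word.append(win)
        best_votes.append(tally[win])
    return "".join(word), max(best_votes)


def polish(kmers: KmerTable, params: PolishParams) -> KmerTable:
    """Replace each end-to-end-match group by its consensus k-mer.

    Colliding consensus words pool by summing counts. Never increases
    the number of distinct k-mers; deterministic given the seed and
    invariant to n_partitions.
    """
    if kmers.k != params.k:
        raise ValueError(f"table k={kmers.k} does not match params k={params.k}")
    out: dict[str, int] = {}
    for group in find_groups(kmers, params):
        word, count = consensus_vote([(w, kmers[w]) for w in group])
        out[word] = out.get(word, 0) + count
    return KmerTable(k=kmers.k, counts=out, canonical=kmers.canonical)
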