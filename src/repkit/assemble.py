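"""Native de Bruijn unitig assembly and prefix-suffix contig merging.

Polished repeat k-mers are treated as "reads" over the repeat
consensus: nodes are (assembly_k-1)-mers, edges the assembly_k-mers
contained in the input k-mers, and contigs are maximal non-branching
paths (unitigs). Because repeat copies diverge, direct assembly yields
short contigs; a second stage greedily merges contigs with reliable
suffix-prefix overlaps into longer consensus repeats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import canonical, reverse_complement

from .kmers import KmerTable

__all__ = [
    "Contig",
    "MergeParams",
    "Overlap",
    "assemble_contigs",
    "best_overlap",
    "merge_contigs",
]


@dataclass
class Contig:
    """Assembled sequence with the mean count of its supporting k-mers."""

    id: str
    sequence: str
    mean_support: float

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class MergeParams:
    """Reliable-overlap criteria for second-stage contig merging.

    min_output_len of None means "no length filter here"; the pipeline
    sets it to 2*k by default.
    """

    min_overlap: int = 10
    max_overlap_mismatch: int = 1
    allow_revcomp: bool = True
    min_output_len: int | None = None

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if self.max_overlap_mismatch < 0:
            raise ValueError("max_overlap_mismatch must be >= 0")


def _build_graph(
    kmers: KmerTable, assembly_k: int, min_edge_support: int
) -> tuple[dict[str, float], dict[str, list[str]], dict[str, int], dict[str, int]]:
    """Edge support plus adjacency/in-degree/out-degree over (ak-1)-mer nodes."""
    support: dict[str, float] = {}
    for w, c in kmers.items():
        orients = (w, reverse_complement(w)) if kmers.canonical else (w,)
        for o in orients:
            for i in range(len(o) - assembly_k + 1):
                e = o[i : i + assembly_k]
                support[e] = support.get(e, 0) + c
    if min_edge_support > 1:
        support = {e: s for e, s in support.items() if s >= min_edge_support}
    out_edges: dict[str, list[str]] = {}
    indeg: dict[str, int] = {}
    outdeg: dict[str, int] = {}
    for e in support:
        u, v = e[:-1], e[1:]
        out_edges.setdefault(u, []).append(e)
        outdeg[u] = outdeg.get(u, 0) + 1
        indeg[v] = indeg.get(v, 0) + 1
    return support, out_edges, indeg, outdeg


def _extract_unitigs(
    support: dict[str, float],
    out_edges: dict[str, list[str]],
    indeg: dict[str, int],
    outdeg: dict[str, int],
) -> list[tuple[str, float]]:
    """Maximal non-branching paths; returns (sequence, mean edge support)."""
    visited: set[str] = set()
    unitigs: list[tuple[str, float]] = []

    def walk(start_edge: str) -> None:
        path = [start_edge]
        visited.add(start_edge)
        v = start_edge[1:]
        while outdeg.get(v, 0) == 1 and indeg.get(v, 0) == 1:
            nxt = out_edges[v][0]
            if nxt in visited:
                break
            path.append(nxt)
            visited.add(nxt)
            v = nxt[1:]
        seq = path[0] + "".join(e[-1] for e in path[1:])
        unitigs.append((seq, sum(support[e] for e in path) / len(path)))

    # start edges: those leaving a branch/terminal node (deterministic order)
    for e in sorted(support):
        u = e[:-1]
        if e not in visited and (indeg.get(u, 0) != 1 or outdeg.get(u, 0) != 1):
            walk(e)
    for e in sorted(support):  # leftover cycles
        if e not in visited:
            walk(e)
    return unitigs


def _prune_tips(
    support: dict[str, float],
    out_edges: dict[str, list[str]],
    indeg: dict[str, int],
    outdeg: dict[str, int],
    assembly_k: int,
    tip_max_support: float,
) -> dict[str, float]:
    """Drop short dead-end branches whose every edge has support <= threshold."""
    drop: set[str] = set()
    for seq, _sup in _extract_unitigs(support, out_edges, indeg, outdeg):
        if len(seq) >= 2 * assembly_k:
            continue
        edges = [seq[i : i + assembly_k] for i in range(len(seq) - assembly_k + 1)]
        if any(support[e] > tip_max_support for e in edges):
            continue
        u, v = seq[: assembly_k - 1], seq[-(assembly_k - 1):]
        dead_end = indeg.get(u, 0) == 0 or outdeg.get(v, 0) == 0
        attached = indeg.get(u, 0) > 0 or outdeg.get(v, 0) > 0
        if dead_end and attached:
            drop.update(edges)
    return {e: s for e, s in support.items() if e not in drop}


def assemble_contigs(
    kmers: KmerTable,
    assembly_k: int,
    min_edge_support: int = 1,
    prune_tips: bool = True,
    tip_max_support: float = 1.0,
) -> list[Contig]:
    """Assemble k-mers into unitig contigs.

    Builds the de Bruijn graph of assembly_k-mers (both orientations
    when the table is canonical), optionally prunes weak short tips,
    and reports maximal non-branching paths. Reverse-complement
    duplicate unitigs collapse onto the canonical orientation.
    """
    if len(kmers) == 0:
        raise ValueError("empty k-mer table")
    if assembly_k >= kmers.k:
        raise ValueError(f"assembly_k ({assembly_k}) must be < k ({kmers.k})")
    if assembly_k < 2:
        raise ValueError("assembly_k must be >= 2")
    support, out_edges, indeg, outdeg = _build_graph(kmers, assembly_k, min_edge_support)
    if prune_tips:
        pruned = _prune_tips(
            support, out_edges, indeg, outdeg, assembly_k, tip_max_support
        )
        if len(pruned) < len(support) and pruned:
            support = pruned
            out_edges, indeg, outdeg = {}, {}, {}
            for e in support:
                u, v = e[:-1], e[1:]
                out_edges.setdefault(u, []).append(e)
                outdeg[u] = outdeg.get(u, 0) + 1
                indeg[v] = indeg.get(v, 0) + 1
    raw = _extract_unitigs(support, out_edges, indeg, outdeg)
    seen: dict[str, float] = {}
    for seq, sup in raw:
        key = canonical(seq) if kmers.canonical else seq
        if key not in seen or sup > seen[key]:
            seen[key] = sup
    contigs = [
        Contig(id=f"ctg{i}", sequence=seq, mean_support=seen[seq])
        for i, seq in enumerate(sorted(seen))
    ]
    return contigs


@dataclass
class Overlap:
    orientation: str  # "forward" or "revcomp" (of the second contig)
    length: int
    mismatches: int


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def best_overlap(a: Contig, b: Contig, params: MergeParams) -> Overlap | None:
    """Longest qualifying suffix(a)/prefix(b) overlap, or None.

    Considers b forward and (if allowed) reverse-complemented; an
    overlap qualifies when length >= min_overlap and the Hamming
    mismatch count <= max_overlap_mismatch. Ties between orientations
    at equal length break toward fewer mismatches, then forward.
    """
    if a.id == b.id:
        raise ValueError("cannot overlap a contig with itself")
    orients = [("forward", b.sequence)]
    if params.allow_revcomp:
        orients.append(("revcomp", reverse_complement(b.sequence)))
    best: tuple[int, int, int] | None = None  # (length, -mm, orient_rank)
    best_ov: Overlap | None = None
    for rank, (name, bseq) in enumerate(orients):
        max_l = min(len(a.sequence), len(bseq))
        for length in range(max_l, params.min_overlap - 1, -1):
            mm = _hamming(a.sequence[-length:], bseq[:length])
            if mm <= params.max_overlap_mismatch:
                cand = (length, -mm, -rank)
                if best is None or cand > best:
                    best = cand
                    best_ov = Overlap(name, length, mm)
                break  # longest qualifying for this orientation found
    return best_ov


@dataclass
class _Mergeable:
    contig: Contig
    alive: bool = True


def _merge_pair(a: Contig, b: Contig, ov: Overlap, new_id: str) -> Contig:
    bseq = b.sequence if ov.orientation == "forward" else reverse_complement(b.sequence)
    left, right = a.sequence, bseq
    junction = list(left[-ov.length:])
    if ov.mismatches and b.mean_support > a.mean_support:
        junction = list(right[: ov.length])  # higher-support contig wins the junction
    seq = left[: -ov.length] + "".join(junction) + right[ov.length:]
    total = len(a.sequence) + len(bseq)
    sup = (a.mean_support * len(a.sequence) + b.mean_support * len(bseq)) / total
    return Contig(id=new_id, sequence=seq, mean_support=sup)


def _contained_in(short: str, long: str, max_mismatch: int) -> bool:
    """True if ``short`` matches some window of ``long`` with <= max_mismatch
    substitutions (gap-free containment)."""
    n, m = len(short), len(long)
    if n > m:
        return False
    if max_mismatch == 0:
        return short in long
    s = np.frombuffer(short.encode("ascii"), dtype=np.uint8)
    l = np.frombuffer(long.encode("ascii"), dtype=np.uint8)
    win = np.lib.stride_tricks.sliding_window_view(l, n)
    return bool((win != s).sum(axis=1).min() <= max_mismatch)


def _remove_contained(contigs: list[Contig], params: MergeParams) -> list[Contig]:
    """Absorb contigs contained in a longer contig.

    Containment is tolerant of up to ``max_overlap_mismatch`` substitutions,
    so short variant branches of a repeat collapse onto the dominant
    contig instead of derailing the greedy overlap merging.
    """
    ordered = sorted(contigs, key=lambda c: (-len(c.sequence), c.sequence))
    kept: list[Contig] = []
    mm = params.max_overlap_mismatch
    for c in ordered:
        rc = reverse_complement(c.sequence)
        contained = any(
            _contained_in(c.sequence, k.sequence, mm)
            or (params.allow_revcomp and _contained_in(rc, k.sequence, mm))
            for k in kept
        )
        if not contained:
            kept.append(c)
    return kept


def merge_contigs(contigs: list[Contig], params: MergeParams) -> list[Contig]:
    """Greedy second-stage merging of contigs by reliable overlaps.

    Repeatedly merges the pair with the longest qualifying overlap
    (ties: fewer mismatches, then forward orientation, then contig ids)
    until no qualifying pair remains; contained contigs are absorbed
    first. Junction disagreements take the base of the higher-support
    contig. Output is filtered to min_output_len when set.
    """
    if not contigs:
        raise ValueError("no contigs to merge")
    pool = {c.id: c for c in _remove_contained(contigs, params)}
    counter = 0
    while True:
        best_key: tuple | None = None
        best_item: tuple[Contig, Contig, Overlap] | None = None
        ids = sorted(pool)
        for ia in ids:
            # both orientations of the first contig: a junction between the
            # two contig *prefixes* is only visible with the first one flipped
            a_variants = [(0, pool[ia])]
            if params.allow_revcomp:
                a_variants.append(
                    (1, Contig(ia, reverse_complement(pool[ia].sequence),
                               pool[ia].mean_support))
                )
            for ib in ids:
                if ia == ib:
                    continue
                for a_rank, a_cand in a_variants:
                    ov = best_overlap(a_cand, pool[ib], params)
                    if ov is None:
                        continue
                    key = (
                        ov.length,
                        -ov.mismatches,
                        0 if ov.orientation == "forward" else -1,
                        -a_rank,
                        ia,
                        ib,
                    )
                    if best_key is None or key > best_key:
                        best_key = key
                        best_item = (a_cand, pool[ib], ov)
        if best_item is None:
            break
        a, b, ov = best_item
        merged = _merge_pair(a, b, ov, new_id=f"merge{counter}")
        counter += 1
        del pool[a.id], pool[b.id]
        pool[merged.id] = merged
        pool = {c.id: c for c in _remove_contained(list(pool.values()), params)}
    out = sorted(pool.values(), key=lambda c: (-len(c.sequence), c.sequence))
    if params.min_output_len is not None:
        out = [c for c in out if len(c.sequence) >= params.min_output_len]
    for i, c in enumerate(out):
        c.id = f"rep{i}"
    return out
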