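"""Copy clustering of assembled repeats.

Diverged assemblies often include several near-copies of the same
repeat consensus. Copies are collapsed by single-linkage clustering:
pairs whose similarity exceeds a threshold (default 0.85) are linked
with a union-find structure and each connected component keeps its
longest member as representative.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._seq import lcs_length, reverse_complement

__all__ = ["ClusterParams", "ClusterResult", "pairwise_similarity", "cluster_repeats"]


@dataclass
class ClusterParams:
    sim_threshold: float = 0.85

    def __post_init__(self) -> None:
        if not 0 < self.sim_threshold <= 1:
            raise ValueError("sim_threshold must be in (0, 1]")


def pairwise_similarity(a: str, b: str) -> float:
    """Fraction of the shorter sequence matched in the best gapped alignment.

    Matched bases are counted as the LCS of the better orientation pair
    (forward/forward vs forward/revcomp) and normalised by min(|a|,|b|)
    so a fragment scores 1.0 against its full-length parent. Symmetric;
    similarity(x, x) == 1.
    """
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    m = max(lcs_length(a, b), lcs_length(a, reverse_complement(b)))
    return m / min(len(a), len(b))


@dataclass
class ClusterResult:
    """cluster_of maps record id -> cluster id; a cluster id is the id of
    its representative (longest member, ties to smaller id)."""

    cluster_of: dict[str, str]
    representatives: dict[str, str]  # cluster id -> representative record id

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)

    def members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for rid, cid in self.cluster_of.items():
            out.setdefault(cid, []).append(rid)
        return {cid: sorted(ms) for cid, ms in out.items()}


def cluster_repeats(
    records: list[tuple[str, str]], params: ClusterParams | None = None
) -> ClusterResult:
    """Single-linkage clustering of repeat records at a similarity threshold.

    ``records`` is a list of (id, sequence). Pairs with similarity
    strictly above ``sim_threshold`` are joined; clusters are the
    connected components. The assignment is independent of record order:
    clusters are labelled by their representative's id.
    """
    if not records:
        raise ValueError("no records to cluster")
    params = params or ClusterParams()
    ids = [rid for rid, _ in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids")
    seqs = dict(records)
    parent = {rid: rid for rid in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    ordered = sorted(ids)
    for i, ra in enumerate(ordered):
        for rb in ordered[i + 1 :]:
            if find(ra) == find(rb):
                continue
            if pairwise_similarity(seqs[ra], seqs[rb]) > params.sim_threshold:
                parent[find(rb)] = find(ra)

    comps: dict[str, list[str]] = {}
    for rid in ids:
        comps.setdefault(find(rid), []).append(rid)
    cluster_of: dict[str, str] = {}
    representatives: dict[str, str] = {}
    for members in comps.values():
        rep = min(members, key=lambda r: (-len(seqs[r]), r))
        for rid in members:
            cluster_of[rid] = rep
        representatives[rep] = rep
    return ClusterResult(cluster_of=cluster_of, representatives=representatives)
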