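"""Evaluation of an assembled repeat set against a reference library.

Three summary metrics, computed from local alignments of assembled
repeats onto each library consensus:

* ``n_full`` (N_h): library entries reconstructed by a single assembled
  repeat at identity above a threshold (default 0.85) measured across
  the entire library sequence, uncovered positions counting as
  mismatches.
* ``n_hit`` (N_0): library entries with at least one qualifying local hit.
* ``c_avg``: mean covered fraction over hit entries, using the
  non-overlapping set of hit intervals of maximum total length
  (weighted interval scheduling).
* ``c_m``: mean covered fraction over hit entries using only the single
  longest assembled repeat that hits the entry.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass

from Bio import Align

from ._seq import reverse_complement

__all__ = [
    "AlignmentInterval",
    "LibraryMetrics",
    "align_to_library",
    "max_nonoverlapping_coverage",
    "best_full_length_identity",
    "compute_metrics",
]


@dataclass
class AlignmentInterval:
    """A local hit of an assembled repeat on a library sequence.

    Coordinates are 0-based half-open on the library sequence; identity
    is matches / alignment columns of the local alignment.
    """

    library_id: str
    start: int
    end: int
    identity: float
    query_id: str
    query_len: int


@dataclass
class LibraryMetrics:
    n_assembled: int  # N: assembled repeats scored
    n_full: int  # N_h: entries reconstructed at > threshold full-length identity
    n_hit: int  # N_0: entries with any qualifying hit
    c_avg: float
    c_m: float


def _make_aligner(mode: str = "local") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner


def _alignment_stats(alignment, target: str, query: str) -> tuple[int, int, int, int]:
    """(matches, columns, target_start, target_end) of one alignment."""
    t_blocks, q_blocks = alignment.aligned
    matches = 0
    aligned_cols = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        aligned_cols += te - ts
        matches += sum(
            1 for x, y in zip(target[ts:te], query[qs:qe]) if x == y
        )
    gap_cols = 0
    for i in range(1, len(t_blocks)):
        gap_cols += max(
            t_blocks[i][0] - t_blocks[i - 1][1], q_blocks[i][0] - q_blocks[i - 1][1]
        )
    columns = aligned_cols + gap_cols
    t_start = int(t_blocks[0][0])
    t_end = int(t_blocks[-1][1])
    return matches, columns, t_start, t_end


def align_to_library(
    repeats: list[tuple[str, str]],
    library: list[tuple[str, str]],
    min_local_identity: float = 0.85,
    min_hit_len: int = 30,
) -> list[AlignmentInterval]:
    """Local-align every assembled repeat to every library entry.

    Both orientations of each repeat are tried; the best local alignment
    per (repeat, entry, orientation) is reported when its identity
    (matches / columns) reaches ``min_local_identity`` and it spans at
    least ``min_hit_len`` columns. The length floor keeps the short
    perfect matches expected between unrelated sequences from counting
    as hits. Scores: match 1, mismatch -1, gap open -2, extend -1.
    """
    if not repeats or not library:
        raise ValueError("repeats and library must be nonempty")
    aligner = _make_aligner()
    out: list[AlignmentInterval] = []
    for lib_id, lib_seq in library:
        for rep_id, rep_seq in repeats:
            for oriented in (rep_seq, reverse_complement(rep_seq)):
                alns = aligner.align(lib_seq, oriented)
                if len(alns) == 0 or alns.score <= 0:
                    continue
                matches, columns, ts, te = _alignment_stats(alns[0], lib_seq, oriented)
                if columns < min_hit_len or columns == 0:
                    continue
                identity = matches / columns
                if identity >= min_local_identity:
                    out.append(
                        AlignmentInterval(
                            library_id=lib_id,
                            start=ts,
                            end=te,
                            identity=identity,
                            query_id=rep_id,
                            query_len=len(rep_seq),
                        )
                    )
    return out


def max_nonoverlapping_coverage(intervals: list[AlignmentInterval]) -> int:
    """Maximum total length of a pairwise non-overlapping interval subset.

    Weighted interval scheduling with weight = interval length, over
    half-open intervals (abutting intervals do not overlap).
    """
    if not intervals:
        return 0
    if len({iv.library_id for iv in intervals}) != 1:
        raise ValueError("intervals must all lie on one library sequence")
    ivs = sorted(intervals, key=lambda iv: (iv.end, iv.start))
    ends = [iv.end for iv in ivs]
    best = [0] * (len(ivs) + 1)
    for i, iv in enumerate(ivs, start=1):
        j = bisect_right(ends, iv.start, 0, i - 1)
        best[i] = max(best[i - 1], best[j] + (iv.end - iv.start))
    return best[-1]


def _full_length_identity(
    rep_seq: str, lib_seq: str, aligner: Align.PairwiseAligner
) -> float:
    """Best matches / |library entry| over both orientations.

    Positions of the entry not covered by the local alignment count as
    mismatches, so a fragment cannot "fully reconstruct" an entry.
    """
    best = 0
    for oriented in (rep_seq, reverse_complement(rep_seq)):
        alns = aligner.align(lib_seq, oriented)
        if len(alns) == 0 or alns.score <= 0:
            continue
        matches, _, _, _ = _alignment_stats(alns[0], lib_seq, oriented)
        best = max(best, matches)
    return best / len(lib_seq)


def best_full_length_identity(
    repeats: list[tuple[str, str]], library_entry: str
) -> float:
    """Best single-repeat identity across the full length of one entry."""
    if not repeats:
        return 0.0
    aligner = _make_aligner()
    return max(
        _full_length_identity(seq, library_entry, aligner) for _, seq in repeats
    )


def compute_metrics(
    repeats: list[tuple[str, str]],
    library: list[tuple[str, str]],
    identity_threshold: float = 0.85,
    min_hit_len: int = 30,
) -> LibraryMetrics:
    """Score an assembled repeat set against a reference repeat library."""
    if not library:
        raise ValueError("empty reference library")
    if not repeats:
        return LibraryMetrics(0, 0, 0, 0.0, 0.0)
    intervals = align_to_library(
        repeats, library, min_local_identity=identity_threshold, min_hit_len=min_hit_len
    )
    by_entry: dict[str, list[AlignmentInterval]] = {}
    for iv in intervals:
        by_entry.setdefault(iv.library_id, []).append(iv)

    aligner = _make_aligner()
    lib_len = dict(library)
    n_full = 0
    cov_fracs: list[float] = []
    cov_longest: list[float] = []
    for lib_id, ivs in by_entry.items():
        entry_len = len(lib_len[lib_id])
        cov_fracs.append(max_nonoverlapping_coverage(ivs) / entry_len)
        longest_query = max(ivs, key=lambda iv: (iv.query_len, iv.query_id)).query_id
        own = [iv for iv in ivs if iv.query_id == longest_query]
        cov_longest.append(max_nonoverlapping_coverage(own) / entry_len)
    rep_seqs = dict(repeats)
    for lib_id, lib_seq in library:
        if lib_id not in by_entry:
            continue
        hitters = {iv.query_id for iv in by_entry[lib_id]}
        full = max(
            _full_length_identity(rep_seqs[q], lib_seq, aligner) for q in hitters
        )
        if full > identity_threshold:
            n_full += 1
    n_hit = len(by_entry)
    return LibraryMetrics(
        n_assembled=len(repeats),
        n_full=n_full,
        n_hit=n_hit,
        c_avg=sum(cov_fracs) / n_hit if n_hit else 0.0,
        c_m=sum(cov_longest) / n_hit if n_hit else 0.0,
    )
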