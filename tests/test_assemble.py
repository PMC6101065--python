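"""De Bruijn unitig assembly and greedy prefix-suffix contig merging."""

import pytest

from repkit import (
    Contig,
    KmerTable,
    MergeParams,
    assemble_contigs,
    best_overlap,
    merge_contigs,
    reverse_complement,
)
from repkit.simulate import random_dna

from conftest import random_dna as _rd  # noqa: F401  (fixture helper import side)


def kmers_of(seq, k):
    return [seq[i : i + k] for i in range(len(seq) - k + 1)]


def table_from(seq, k, canonical=False):
    counts = {}
    for w in kmers_of(seq, k):
        counts[w] = counts.get(w, 0) + 1
    return KmerTable(k, counts, canonical=canonical)


def unique_internal(seq, k):
    words = kmers_of(seq, k)
    return len(set(words)) == len(words)


class TestAssembleContigs:
    def test_linear_path_single_contig(self):
        t = table_from("ACGGTCAT", 5)
        contigs = assemble_contigs(t, assembly_k=4)
        assert [c.sequence for c in contigs] == ["ACGGTCAT"]

    def test_disconnected_components(self):
        a, b = "AAAAAAAAAA", "CCCCCCCCCC"
        counts = {**table_from(a, 5).counts, **table_from(b, 5).counts}
        t = KmerTable(5, counts, canonical=False)
        contigs = assemble_contigs(t, assembly_k=4)
        assert len(contigs) == 2

    def test_unique_path_recovers_string(self, rng):
        recovered = 0
        for trial in range(20):
            s = random_dna(length=300, rng=rng)
            if not unique_internal(s, 24):
                continue
            t = table_from(s, 26, canonical=True)
            contigs = assemble_contigs(t, assembly_k=25)
            assert any(c.sequence in (s, reverse_complement(s)) for c in contigs)
            recovered += 1
        assert recovered >= 15

    def test_order_independence(self, rng):
        s = random_dna(length=200, rng=rng)
        t = table_from(s, 21, canonical=True)
        base = sorted(c.sequence for c in assemble_contigs(t, assembly_k=16))
        shuffled = dict(sorted(t.counts.items(), reverse=True))
        t2 = KmerTable(21, shuffled, canonical=True)
        assert sorted(c.sequence for c in assemble_contigs(t2, assembly_k=16)) == base

    def test_adjacent_overlaps_are_input_edges(self, rng):
        s = random_dna(length=150, rng=rng)
        ak = 10
        t = table_from(s, 15, canonical=False)
        edges = set()
        for w in t:
            edges.update(kmers_of(w, ak))
        for c in assemble_contigs(t, assembly_k=ak, prune_tips=False):
            for e in kmers_of(c.sequence, ak):
                assert e in edges or reverse_complement(e) in edges

    def test_mean_support_positive(self, rng):
        s = random_dna(length=100, rng=rng)
        t = table_from(s, 15)
        for c in assemble_contigs(t, assembly_k=10):
            assert c.mean_support > 0
            assert len(c.sequence) >= 10

    def test_assembly_k_validation(self, rng):
        t = table_from(random_dna(length=60, rng=rng), 15)
        with pytest.raises(ValueError):
            assemble_contigs(t, assembly_k=15)
        with pytest.raises(ValueError):
            assemble_contigs(KmerTable(15, {}, canonical=False), assembly_k=10)


class TestBestOverlap:
    def test_exact_junction(self):
        a = Contig("a", "AAAACCCC", 1.0)
        b = Contig("b", "CCCCGGGG", 1.0)
        ov = best_overlap(a, b, MergeParams(min_overlap=4))
        assert (ov.orientation, ov.length, ov.mismatches) == ("forward", 4, 0)

    def test_no_overlap(self):
        a = Contig("a", "AAAA", 1.0)
        b = Contig("b", "GGGG", 1.0)
        assert best_overlap(a, b, MergeParams(min_overlap=2)) is None

    def test_revcomp_overlap_found(self):
        a = Contig("a", "AAAATTCGA", 1.0)
        b = Contig("b", "CCCCTCGAA", 1.0)  # revcomp = TTCGAGGGG
        ov = best_overlap(a, b, MergeParams(min_overlap=5, max_overlap_mismatch=0))
        assert ov.orientation == "revcomp" and ov.length == 5

    def test_agrees_with_exhaustive_scan(self, rng):
        params = MergeParams(min_overlap=4, max_overlap_mismatch=1)
        for _ in range(200):
            a = Contig("a", random_dna(length=int(rng.integers(8, 30)), rng=rng), 1.0)
            b = Contig("b", random_dna(length=int(rng.integers(8, 30)), rng=rng), 1.0)
            ov = best_overlap(a, b, params)
            best = None
            for rank, bseq in enumerate([b.sequence, reverse_complement(b.sequence)]):
                for length in range(min(len(a.sequence), len(bseq)), 3, -1):
                    mm = sum(x != y for x, y in zip(a.sequence[-length:], bseq[:length]))
                    if mm <= 1:
                        cand = (length, -mm, -rank)
                        if best is None or cand > best:
                            best = cand
                        break
            if best is None:
                assert ov is None
            else:
                assert (ov.length, -ov.mismatches,
                        -(0 if ov.orientation == "forward" else 1)) == best


class TestMergeContigs:
    def _fragments(self, seq, n, rng, lo=15, hi=30):
        """Cut a string into n fragments with [lo, hi] bp overlaps."""
        while True:
            cuts = sorted(
                int(c)
                for c in rng.choice(range(60, len(seq) - 60), size=n - 1, replace=False)
            )
            if all(b - a >= 80 for a, b in zip(cuts, cuts[1:])):
                break
        frags = []
        prev = 0
        for i, cut in enumerate(list(cuts) + [len(seq)]):
            start = max(0, prev - (int(rng.integers(lo, hi + 1)) if i else 0))
            frags.append(seq[start:cut])
            prev = cut
        return frags

    def test_chain_merge_reconstructs(self, rng):
        s = random_dna(length=400, rng=rng)
        frags = self._fragments(s, 4, rng)
        contigs = [Contig(f"c{i}", f, 1.0) for i, f in enumerate(frags)]
        out = merge_contigs(contigs, MergeParams(min_overlap=10))
        assert [c.sequence for c in out] == [s]

    def test_non_overlapping_is_fixed_point(self):
        contigs = [
            Contig("a", "AAAAAAAAAACCAAAAAAAAAA", 1.0),
            Contig("b", "GGGGGGGGGGTTGGGGGGGGGG", 1.0),
        ]
        out = merge_contigs(contigs, MergeParams(min_overlap=10))
        assert sorted(c.sequence for c in out) == sorted(c.sequence for c in contigs)

    def test_reconstruction_600bp_five_fragments(self, rng):
        for trial in range(10):
            s = random_dna(length=600, rng=rng)
            frags = self._fragments(s, 5, rng)
            contigs = [Contig(f"c{i}", f, 1.0) for i, f in enumerate(frags)]
            out = merge_contigs(contigs, MergeParams(min_overlap=10))
            assert [c.sequence for c in out] == [s]

    def test_junction_takes_higher_support_base(self):
        left = "ACGTACGTAC" + "GGGGGGGGGG"
        right_good = "GGGGGGGGGG" + "TTTTACGTTT"
        right_bad = "GGGGGGGGGG"[:-1] + "C" + "TTTTACGTTT"  # one junction mismatch
        a = Contig("a", left, 5.0)
        b = Contig("b", right_bad, 50.0)
        out = merge_contigs([a, b], MergeParams(min_overlap=8, max_overlap_mismatch=1))
        assert len(out) == 1
        # b has higher support, so the junction keeps b's C
        assert "GGGGGGGGGC" in out[0].sequence
        a2 = Contig("a", left, 50.0)
        b2 = Contig("b", right_bad, 5.0)
        out2 = merge_contigs([a2, b2], MergeParams(min_overlap=8, max_overlap_mismatch=1))
        assert "GGGGGGGGGG" + "TTTTACGTTT" in out2[0].sequence
        del right_good

    def test_idempotent_on_own_output(self, rng):
        frags = [random_dna(length=80, rng=rng) for _ in range(6)]
        contigs = [Contig(f"c{i}", f, 1.0) for i, f in enumerate(frags)]
        params = MergeParams(min_overlap=10)
        once = merge_contigs(contigs, params)
        twice = merge_contigs(once, params)
        assert sorted(c.sequence for c in once) == sorted(c.sequence for c in twice)

    def test_min_output_len_filter(self, rng):
        contigs = [
            Contig("a", random_dna(length=30, rng=rng), 1.0),
            Contig("b", random_dna(length=80, rng=rng), 1.0),
        ]
        out = merge_contigs(contigs, MergeParams(min_overlap=25, min_output_len=60))
        assert all(len(c.sequence) >= 60 for c in out)
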