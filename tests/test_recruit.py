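"""Seed-and-check recruitment of intermediate-frequency k-mers."""

import pytest

from repkit import (
    KmerTable,
    RecruitmentParams,
    SeedIndex,
    iterative_recruit,
    match_score,
    recruit_kmers,
    reverse_complement,
    shares_seed,
)
from repkit.simulate import random_dna

from conftest import lcs_dp

import numpy as np


def _mutate_at(word, positions, rng):
    out = list(word)
    for p in positions:
        out[p] = rng.choice([b for b in "ACGT" if b != word[p]])
    return "".join(out)


class TestMatchScore:
    def test_identity(self, rng):
        for _ in range(5):
            w = random_dna(length=int(rng.integers(1, 60)), rng=rng)
            assert match_score(w, w) == len(w)

    def test_disjoint_alphabets(self):
        assert match_score("AAAA", "CCCC") == 0

    def test_equals_dp_oracle(self, rng):
        for _ in range(300):
            a = random_dna(length=30, rng=rng)
            b = random_dna(length=30, rng=rng)
            assert match_score(a, b) == lcs_dp(a, b)

    def test_equals_dp_oracle_unequal_lengths(self, rng):
        for _ in range(100):
            a = random_dna(length=int(rng.integers(1, 80)), rng=rng)
            b = random_dna(length=int(rng.integers(1, 80)), rng=rng)
            assert match_score(a, b) == lcs_dp(a, b)


class TestSharesSeed:
    def test_indexed_kmer_shares(self, rng):
        words = [random_dna(length=20, rng=rng) for _ in range(10)]
        idx = SeedIndex(KmerTable(20, dict.fromkeys(words, 5), canonical=False), 8)
        for w in words:
            assert shares_seed(w, idx)

    def test_disjoint_alphabet_never_shares(self):
        idx = SeedIndex(KmerTable(8, {"CGCGCGCG": 5, "GGGGCCCC": 5}, canonical=False), 4)
        assert not shares_seed("AAAAAAAA", idx)

    def test_agrees_with_window_scan(self, rng):
        highs = [random_dna(length=15, rng=rng) for _ in range(30)]
        seed_len = 6
        idx = SeedIndex(KmerTable(15, dict.fromkeys(highs, 9), canonical=False), seed_len)
        for _ in range(200):
            q = random_dna(length=15, rng=rng)
            brute = any(
                q[i : i + seed_len] in h
                for i in range(15 - seed_len + 1)
                for h in highs
            )
            assert shares_seed(q, idx) == brute


class TestRecruit:
    def _tables(self, inter, high, k=30):
        return (
            KmerTable(k, dict(inter), canonical=False),
            KmerTable(k, dict(high), canonical=False),
        )

    def test_identical_kmer_recruited(self, rng):
        w = random_dna(length=30, rng=rng)
        inter, high = self._tables({w: 40}, {w: 200})
        got = recruit_kmers(inter, high, RecruitmentParams())
        assert got.counts == {w: 40}

    def test_one_substitution_recruited(self, rng):
        h = random_dna(length=30, rng=rng)
        w = _mutate_at(h, [14], rng)
        inter, high = self._tables({w: 40}, {h: 200})
        got = recruit_kmers(inter, high, RecruitmentParams())
        assert w in got  # score >= 29 >= 25

    def test_distant_kmer_rejected(self, rng):
        # find a 6-substitution variant whose LCS provably drops below k-5
        h = random_dna(length=30, rng=rng)
        for _ in range(200):
            w = _mutate_at(h, rng.choice(30, size=6, replace=False), rng)
            if lcs_dp(w, h) < 25 and lcs_dp(reverse_complement(w), h) < 25:
                break
        else:
            pytest.fail("could not construct a distant variant")
        inter, high = self._tables({w: 40}, {h: 200})
        got = recruit_kmers(inter, high, RecruitmentParams())
        assert w not in got

    def test_matches_all_pairs_brute_force(self, rng):
        k, seed_len, min_score = 20, 6, 15
        highs = {random_dna(length=k, rng=rng): 100 for _ in range(25)}
        inters = {}
        for _ in range(60):
            if rng.random() < 0.5:  # half near-duplicates, half random
                base = list(highs)[int(rng.integers(len(highs)))]
                w = _mutate_at(base, rng.choice(k, size=int(rng.integers(1, 6)), replace=False), rng)
            else:
                w = random_dna(length=k, rng=rng)
            if w not in highs:
                inters[w] = 30
        inter, high = self._tables(inters, highs, k=k)
        params = RecruitmentParams(min_score=min_score, seed_len=seed_len)
        got = recruit_kmers(inter, high, params)
        for w in inters:
            seeded = {
                h for h in highs
                if any(w[i:i + seed_len] in h for i in range(k - seed_len + 1))
            }
            expect = any(lcs_dp(w, h) >= min_score for h in seeded)
            assert (w in got) == expect, w

    def test_counts_preserved_and_subset(self, rng):
        h = random_dna(length=30, rng=rng)
        inters = {_mutate_at(h, [i], rng): 30 + i for i in range(5)}
        inter, high = self._tables(inters, {h: 300})
        got = recruit_kmers(inter, high, RecruitmentParams())
        assert set(got) <= set(inters)
        for w in got:
            assert got[w] == inters[w]

    def test_min_score_monotonicity(self, rng):
        h = {random_dna(length=30, rng=rng): 200 for _ in range(5)}
        inters = {random_dna(length=30, rng=rng): 40 for _ in range(50)}
        inter, high = self._tables(inters, h)
        prev = None
        for ms in (28, 24, 20, 16):
            got = set(recruit_kmers(inter, high, RecruitmentParams(min_score=ms)))
            if prev is not None:
                assert prev <= got
            prev = got

    def test_k_mismatch_errors(self, rng):
        inter = KmerTable(20, {random_dna(length=20, rng=rng): 5}, canonical=False)
        high = KmerTable(30, {random_dna(length=30, rng=rng): 50}, canonical=False)
        with pytest.raises(ValueError):
            recruit_kmers(inter, high, RecruitmentParams())


class TestIterativeRecruit:
    def test_single_round_equals_recruit_plus_high(self, rng):
        h = {random_dna(length=30, rng=rng): 200 for _ in range(5)}
        inters = {}
        for base in h:
            inters[_mutate_at(base, [3, 9], rng)] = 40
        for _ in range(10):
            inters[random_dna(length=30, rng=rng)] = 40
        inter = KmerTable(30, inters, canonical=False)
        high = KmerTable(30, h, canonical=False)
        params = RecruitmentParams(max_rounds=1)
        merged = iterative_recruit(inter, high, params)
        direct = recruit_kmers(inter, high, params)
        assert merged.counts == {**h, **direct.counts}

    def test_chain_needs_two_rounds(self, rng):
        # w1 is close to the high k-mer; w2 is close only to w1
        for _ in range(500):
            h = random_dna(length=30, rng=rng)
            w1 = _mutate_at(h, rng.choice(30, size=3, replace=False), rng)
            w2 = _mutate_at(w1, rng.choice(30, size=4, replace=False), rng)
            ok = (
                lcs_dp(w1, h) >= 25
                and lcs_dp(w2, w1) >= 25
                and lcs_dp(w2, h) < 25
                and lcs_dp(reverse_complement(w1), h) < 25
                and lcs_dp(reverse_complement(w2), h) < 25
                and lcs_dp(reverse_complement(w2), w1) < 25
            )
            if ok:
                break
        else:
            pytest.fail("could not construct the chain")
        inter = KmerTable(30, {w1: 40, w2: 41}, canonical=False)
        high = KmerTable(30, {h: 300}, canonical=False)
        one = iterative_recruit(inter, high, RecruitmentParams(max_rounds=1))
        two = iterative_recruit(inter, high, RecruitmentParams(max_rounds=2))
        assert set(one) == {h, w1}
        assert set(two) == {h, w1, w2}

    def test_monotone_in_rounds(self, rng):
        h = {random_dna(length=30, rng=rng): 200 for _ in range(4)}
        inters = {random_dna(length=30, rng=rng): 40 for _ in range(40)}
        for base in list(h):
            w1 = _mutate_at(base, rng.choice(30, size=3, replace=False), rng)
            inters[w1] = 40
            inters[_mutate_at(w1, rng.choice(30, size=3, replace=False), rng)] = 40
        inter = KmerTable(30, inters, canonical=False)
        high = KmerTable(30, h, canonical=False)
        prev = None
        for rounds in (1, 2, 3):
            got = set(iterative_recruit(inter, high, RecruitmentParams(max_rounds=rounds)))
            if prev is not None:
                assert prev <= got
            prev = got
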