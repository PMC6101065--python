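import numpy as np
import pytest

BASES = "ACGT"


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260101)


def naive_count(reads, k, canonical_mode):
    """Sliding-window k-mer counting oracle (independent of the package
    internals except for the reverse-complement definition)."""
    comp = str.maketrans("ACGT", "TGCA")
    counts = {}
    for read in reads:
        for i in range(len(read) - k + 1):
            w = read[i : i + k]
            if any(ch not in BASES for ch in w):
                continue
            if canonical_mode:
                rc = w.translate(comp)[::-1]
                w = min(w, rc)
            counts[w] = counts.get(w, 0) + 1
    return counts


def lcs_dp(a: str, b: str) -> int:
    """Textbook quadratic LCS dynamic program (oracle)."""
    prev = [0] * (len(b) + 1)
    for x in a:
        cur = [0]
        for j, y in enumerate(b, 1):
            cur.append(prev[j - 1] + 1 if x == y else max(prev[j], cur[-1]))
        prev = cur
    return prev[-1]
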