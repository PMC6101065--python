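"""Low-level sequence primitives shared across the package.

DNA words are plain Python strings over {A,C,G,T}. Numeric encodings
(2 bits per base) are used internally for vectorised k-mer counting.
"""

from __future__ import annotations

import numpy as np

COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# byte -> 2-bit code; 255 marks anything that is not an unambiguous base
BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    BASE_CODE[_b] = _i
    BASE_CODE[_b + 32] = _i  # lowercase

CODE_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


class InvalidAlphabetError(ValueError):
    """A sequence contains characters outside {A,C,G,T}."""


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of a DNA word.

    Raises :class:`InvalidAlphabetError` on characters outside ACGT
    (case-insensitive).
    """
    out = seq.translate(COMPLEMENT)[::-1]
    if len(out.lstrip("ACGTacgt")) != len(seq.lstrip("ACGTacgt")):
        # translate() passes unknown characters through unchanged
        bad = set(seq.upper()) - set("ACGT")
        raise InvalidAlphabetError(f"non-ACGT characters in sequence: {sorted(bad)}")
    return out


def canonical(seq: str) -> str:
    """Lexicographically smaller of a word and its reverse complement."""
    rc = reverse_complement(seq)
    return seq if seq <= rc else rc


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as uint8 2-bit codes (255 for ambiguous bases)."""
    return BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_codes(codes: np.ndarray) -> str:
    """Inverse of :func:`encode` for a fully valid code vector."""
    return CODE_BASE[codes].tobytes().decode("ascii")


def lcs_length(a: str, b: str) -> int:
    """Length of the longest common subsequence of two strings.

    This equals the optimal gapped-alignment score when matches score 1
    and mismatches/gaps cost nothing, which is the scoring regime used
    for k-mer recruitment and repeat similarity. Bit-parallel algorithm
    (Hyyro), O(|a| * |b|/w) with arbitrary-precision words.
    """
    if not a or not b:
        return 0
    if len(b) > len(a):  # fewer outer iterations over the longer string
        a, b = b, a
    m = len(b)
    mask = (1 << m) - 1
    pm: dict[str, int] = {}
    for i, c in enumerate(b):
        pm[c] = pm.get(c, 0) | (1 << i)
    v = mask
    for c in a:
        u = v & pm.get(c, 0)
        v = ((v + u) | (v - u)) & mask
    return m - v.bit_count()
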