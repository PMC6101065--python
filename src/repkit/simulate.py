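"""Synthetic planted-repeat genomes and uniform-coverage read sets.

The generator emulates the signal the pipeline exploits: a random
background genome carries planted repeat families, each copy an
independently mutated (substitutions + short indels) instance of a
family consensus, and reads sample the genome uniformly on both strands
with i.i.d. per-base substitution errors. All randomness flows from a
single seed and outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import reverse_complement

__all__ = [
    "RepeatSimSpec",
    "ReadSimSpec",
    "PlantedCopy",
    "GenomeTruth",
    "random_dna",
    "mutate_sequence",
    "simulate_genome",
    "simulate_reads",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class RepeatSimSpec:
    """One planted repeat family.

    Divergence is applied per copy: each base substitutes with
    ``sub_rate`` and starts an indel with ``indel_rate`` (insertions and
    deletions equally likely, lengths uniform on [1, indel_max_len]).
    """

    consensus_len: int
    copy_number: int
    sub_rate: float = 0.0
    indel_rate: float = 0.0
    indel_max_len: int = 3
    name: str | None = None

    def __post_init__(self) -> None:
        if self.consensus_len < 50:
            raise ValueError("consensus_len must be >= 50")
        if self.copy_number < 1:
            raise ValueError("copy_number must be >= 1")
        if not 0 <= self.sub_rate + self.indel_rate < 0.5:
            raise ValueError("sub_rate + indel_rate must be in [0, 0.5)")


@dataclass
class ReadSimSpec:
    """Uniform-coverage single-end read simulation parameters."""

    read_len: int
    depth: float
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_len < 2:
            raise ValueError("read_len must be >= 2")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0 <= self.error_rate < 0.1:
            raise ValueError("error_rate must be in [0, 0.1)")


@dataclass
class PlantedCopy:
    family: str
    start: int  # 0-based half-open on the genome
    end: int
    strand: str  # "+" or "-"


@dataclass
class GenomeTruth:
    genome: str
    consensus: dict[str, str]  # family name -> consensus sequence
    copies: list[PlantedCopy] = field(default_factory=list)


def random_dna(length: int, rng: np.random.Generator) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def mutate_sequence(
    seq: str,
    sub_rate: float,
    indel_rate: float,
    indel_max_len: int,
    rng: np.random.Generator,
) -> str:
    """Independent per-base substitutions and short indels."""
    out: list[str] = []
    bases = "ACGT"
    i = 0
    n = len(seq)
    while i < n:
        ch = seq[i]
        if indel_rate and rng.random() < indel_rate:
            ln = int(rng.integers(1, indel_max_len + 1))
            if rng.random() < 0.5:  # insertion before this base
                out.append(random_dna(ln, rng))
            else:  # deletion of ln bases starting here
                i += ln
                continue
        if sub_rate and rng.random() < sub_rate:
            out.append(str(rng.choice([b for b in bases if b != ch])))
        else:
            out.append(ch)
        i += 1
    return "".join(out)


def simulate_genome(
    bg_len: int, specs: list[RepeatSimSpec], seed: int = 0
) -> GenomeTruth:
    """Random background genome with planted, mutated repeat copies.

    Copies replace background segments at non-overlapping, non-nested
    uniform positions; each copy lands on a random strand. The truth
    object records every family consensus and the 0-based half-open
    interval of every planted copy.
    """
    rng = np.random.default_rng(seed)
    genome = list(random_dna(bg_len, rng))
    truth = GenomeTruth(genome="", consensus={})
    placements: list[tuple[int, int]] = []

    jobs: list[tuple[str, str]] = []  # (family, copy sequence)
    for fi, spec in enumerate(specs):
        name = spec.name or f"family{fi}"
        consensus = random_dna(spec.consensus_len, rng)
        truth.consensus[name] = consensus
        for _ in range(spec.copy_number):
            copy = mutate_sequence(
                consensus, spec.sub_rate, spec.indel_rate, spec.indel_max_len, rng
            )
            jobs.append((name, copy))
    if sum(len(c) for _, c in jobs) > bg_len:
        raise ValueError("background too short for the requested repeat copies")

    for name, copy in jobs:
        strand = "+" if rng.random() < 0.5 else "-"
        placed_seq = copy if strand == "+" else reverse_complement(copy)
        ln = len(placed_seq)
        for _ in range(10_000):
            start = int(rng.integers(0, bg_len - ln + 1))
            if all(start + ln <= s or start >= e for s, e in placements):
                break
        else:
            raise ValueError("could not place repeat copies without overlap")
        genome[start : start + ln] = placed_seq
        placements.append((start, start + ln))
        truth.copies.append(PlantedCopy(name, start, start + ln, strand))
    truth.genome = "".join(genome)
    return truth


def simulate_reads(genome: str, spec: ReadSimSpec) -> list[tuple[str, str]]:
    """Uniform single-end reads with i.i.d. substitution errors.

    Read count is round(depth * |genome| / read_len); start positions
    are uniform and each read comes off a random strand. Returns
    (read id, sequence) pairs, deterministic given the seed.
    """
    if len(genome) < spec.read_len:
        raise ValueError("genome shorter than read length")
    rng = np.random.default_rng(spec.seed)
    n_reads = int(round(spec.depth * len(genome) / spec.read_len))
    g = np.frombuffer(genome.encode("ascii"), dtype=np.uint8)
    code = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        code[b] = i
    gcodes = code[g]
    starts = rng.integers(0, len(genome) - spec.read_len + 1, size=n_reads)
    idx = starts[:, None] + np.arange(spec.read_len)[None, :]
    mat = gcodes[idx]
    rev = rng.random(n_reads) < 0.5
    mat[rev] = 3 - mat[rev][:, ::-1]
    if spec.error_rate > 0:
        errs = rng.random(mat.shape) < spec.error_rate
        shift = rng.integers(1, 4, size=int(errs.sum()))
        mat[errs] = (mat[errs] + shift) % 4
    ascii_mat = _BASES[mat]
    flat = np.ascontiguousarray(ascii_mat).view(f"S{spec.read_len}").ravel()
    return [(f"read{i}", s.decode("ascii")) for i, s in enumerate(flat)]
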