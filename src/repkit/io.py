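"""File formats: FASTA/FASTQ reads, TSV k-mer tables, cluster/metric tables."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .assemble import Contig
from .kmers import KmerTable

__all__ = [
    "read_sequences",
    "write_fasta",
    "write_fastq",
    "read_kmer_table",
    "write_kmer_table",
    "read_contigs_fasta",
    "write_contigs_fasta",
]


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _sniff_format(path: Path) -> str:
    name = path.name.removesuffix(".gz")
    if name.endswith((".fq", ".fastq")):
        return "fastq"
    if name.endswith((".fa", ".fasta", ".fna")):
        return "fasta"
    raise ValueError(f"cannot infer sequence format from file name: {path.name}")


def read_sequences(path: str | Path) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs from FASTA or FASTQ (optionally gzipped)."""
    path = Path(path)
    fmt = _sniff_format(path)
    with _open_text(path) as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, fmt)]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


def write_fastq(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_kmer_table(table: KmerTable, path: str | Path) -> None:
    """Headerless two-column TSV, lexicographically sorted for stable diffs."""
    with open(path, "w") as fh:
        for w in sorted(table.counts):
            fh.write(f"{w}\t{table.counts[w]}\n")


def read_kmer_table(path: str | Path, canonical: bool = True) -> KmerTable:
    counts: dict[str, int] = {}
    k = None
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            w, c = line.split("\t")
            if k is None:
                k = len(w)
            elif len(w) != k:
                raise ValueError(f"mixed k-mer lengths in {path}")
            counts[w] = int(c)
    if k is None:
        raise ValueError(f"empty k-mer table: {path}")
    return KmerTable(k=k, counts=counts, canonical=canonical)


def read_contigs_fasta(path: str | Path) -> list[Contig]:
    """Read contigs written by :func:`write_contigs_fasta`, keeping support."""
    out: list[Contig] = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            support = 1.0
            for token in rec.description.split():
                if token.startswith("support="):
                    support = float(token.removeprefix("support="))
            out.append(Contig(id=rec.id, sequence=str(rec.seq).upper(), mean_support=support))
    return out


def write_contigs_fasta(contigs: Iterable[Contig], path: str | Path) -> None:
    """Headers carry length and mean k-mer support: ``rep0 len=.. support=..``."""
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(
                f">{c.id} len={len(c.sequence)} support={c.mean_support:.2f}\n"
                f"{c.sequence}\n"
            )
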