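"""End-to-end orchestration of the repeat-construction stages.

Stage order: count -> classify -> recruit -> polish -> assemble ->
merge -> cluster (-> evaluate when a reference library is supplied).
Every stage writes its artifact to the working directory under a
stage-stamped name, so later stages (and the CLI) can resume from
files. All randomness flows from the single config seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as rio
from .assemble import Contig, MergeParams, assemble_contigs, merge_contigs
from .cluster import ClusterParams, ClusterResult, cluster_repeats
from .evaluate import LibraryMetrics, compute_metrics
from .kmers import (
    KmerTable,
    SelectionParams,
    classify_kmers,
    count_kmers,
    estimate_base_freq,
    frequency_histogram,
)
from .polish import PolishParams, polish
from .recruit import RecruitmentParams, iterative_recruit

logger = logging.getLogger("repkit")

__all__ = ["PipelineConfig", "PipelineResult", "StageError", "run_pipeline", "run_stage"]

STAGES = (
    "count",
    "classify",
    "recruit",
    "polish",
    "assemble",
    "merge",
    "cluster",
    "evaluate",
)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Flat configuration aggregating every stage's parameters.

    Defaults target the standard study conditions (k=30, high tier at
    10x the base frequency, intermediate floor at 3x). ``base_freq``
    of None means "estimate from the count histogram".
    """

    k: int = 30
    canonical: bool = True
    # selection
    base_freq: float | None = None
    high_multiplier: float = 10.0
    mid_multiplier: float = 3.0
    # recruitment
    enable_recruit: bool = True
    min_score: int | None = None  # default k - 5
    seed_len: int = 12
    max_rounds: int = 1
    # polishing
    enable_polish: bool = True
    h: int | None = None  # default min(15, k)
    n_trials: int | None = None  # default: smallest n reaching p >= 0.99
    e: int = 1
    n_partitions: int = 1
    # assembly & merging
    assembly_k: int | None = None  # default k - 5
    min_edge_support: int = 1
    min_overlap: int = 10
    max_overlap_mismatch: int = 1
    allow_revcomp: bool = True
    min_output_len: int | None = None  # default 2 * k
    # clustering
    sim_threshold: float = 0.85
    # evaluation
    identity_threshold: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if self.assembly_k is not None and self.assembly_k >= self.k:
            raise ValueError("assembly_k must be < k")

    @property
    def resolved_assembly_k(self) -> int:
        return self.assembly_k if self.assembly_k is not None else self.k - 5

    @property
    def resolved_min_output_len(self) -> int:
        return self.min_output_len if self.min_output_len is not None else 2 * self.k

    def selection_params(self, base_freq: float) -> SelectionParams:
        return SelectionParams(
            base_freq=base_freq,
            high_multiplier=self.high_multiplier,
            mid_multiplier=self.mid_multiplier,
        )

    def recruitment_params(self) -> RecruitmentParams:
        return RecruitmentParams(
            min_score=self.min_score, seed_len=self.seed_len, max_rounds=self.max_rounds
        )

    def polish_params(self) -> PolishParams:
        return PolishParams(
            k=self.k,
            h=self.h,
            n_trials=self.n_trials,
            e=self.e,
            seed=self.seed,
            n_partitions=self.n_partitions,
        )

    def merge_params(self) -> MergeParams:
        return MergeParams(
            min_overlap=self.min_overlap,
            max_overlap_mismatch=self.max_overlap_mismatch,
            allow_revcomp=self.allow_revcomp,
            min_output_len=self.resolved_min_output_len,
        )

    def cluster_params(self) -> ClusterParams:
        return ClusterParams(sim_threshold=self.sim_threshold)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class PipelineResult:
    repeats: list[Contig]
    contigs: list[Contig]
    clusters: ClusterResult
    metrics: LibraryMetrics | None
    manifest: dict = field(default_factory=dict)


def _load_reads(reads) -> list[tuple[str, str]]:
    """Accept (id, seq) pairs, a path, or a list of paths."""
    if isinstance(reads, (str, Path)):
        reads = [reads]
    if reads and isinstance(reads[0], (str, Path)) and not isinstance(reads[0], tuple):
        out: list[tuple[str, str]] = []
        for p in reads:
            out.extend(rio.read_sequences(p))
        return out
    return list(reads)


def _write_clusters_tsv(clusters: ClusterResult, path: Path) -> None:
    with open(path, "w") as fh:
        for rid in sorted(clusters.cluster_of):
            cid = clusters.cluster_of[rid]
            rep = "1" if clusters.representatives.get(cid) == rid else "0"
            fh.write(f"{rid}\t{cid}\t{rep}\n")


def _write_metrics_tsv(metrics: LibraryMetrics, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("N\tN_h\tN_0\tC_avg\tC_m\n")
        fh.write(
            f"{metrics.n_assembled}\t{metrics.n_full}\t{metrics.n_hit}\t"
            f"{metrics.c_avg:.6f}\t{metrics.c_m:.6f}\n"
        )


def run_pipeline(
    reads,
    config: PipelineConfig | None = None,
    workdir: str | Path | None = None,
    library: list[tuple[str, str]] | None = None,
) -> PipelineResult:
    """Run every stage on a read set and return the assembled repeats.

    ``reads`` may be (id, sequence) pairs or FASTA/FASTQ path(s);
    ``library``, when given, is a reference repeat library used for the
    final evaluation. Artifacts and a run manifest land in ``workdir``.
    """
    config = config or PipelineConfig()
    wd = Path(workdir) if workdir is not None else None
    if wd is not None:
        wd.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}}

    def run(stage: str, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:  # noqa: BLE001 - annotate with stage name
            raise StageError(stage, exc) from exc
        dt = time.perf_counter() - t0
        return out, dt

    def note(stage: str, dt: float, **counts: int | float):
        manifest["stages"][stage] = dict(counts)
        pretty = " ".join(f"{k}={v}" for k, v in counts.items())
        logger.info("stage=%s elapsed=%.2fs %s", stage, dt, pretty)

    seqs = _load_reads(reads)
    table, dt = run("count", lambda: count_kmers(
        (s for _, s in seqs), config.k, canonical=config.canonical
    ))
    note("count", dt, reads=len(seqs), distinct_kmers=len(table))
    if wd:
        rio.write_kmer_table(table, wd / "01_kmers.tsv")

    def _classify():
        bf = config.base_freq
        if bf is None:
            bf = estimate_base_freq(frequency_histogram(table))
        return bf, classify_kmers(table, config.selection_params(bf))

    (base_freq, (high, mid)), dt = run("classify", _classify)
    note("classify", dt, base_freq=base_freq, high=len(high), intermediate=len(mid))
    if wd:
        rio.write_kmer_table(high, wd / "02_high.tsv")
        rio.write_kmer_table(mid, wd / "02_intermediate.tsv")

    if config.enable_recruit:
        merged_kmers, dt = run(
            "recruit",
            lambda: iterative_recruit(mid, high, config.recruitment_params()),
        )
        note("recruit", dt, merged=len(merged_kmers), recruited=len(merged_kmers) - len(high))
    else:
        merged_kmers, dt = high, 0.0
        note("recruit", dt, merged=len(high), recruited=0, skipped=1)
    if wd:
        rio.write_kmer_table(merged_kmers, wd / "03_merged_kmers.tsv")

    if config.enable_polish:
        polished, dt = run("polish", lambda: polish(merged_kmers, config.polish_params()))
        note("polish", dt, polished=len(polished))
    else:
        polished, dt = merged_kmers, 0.0
        note("polish", dt, polished=len(polished), skipped=1)
    if wd:
        rio.write_kmer_table(polished, wd / "04_polished.tsv")

    contigs, dt = run(
        "assemble",
        lambda: assemble_contigs(
            polished,
            config.resolved_assembly_k,
            min_edge_support=config.min_edge_support,
        ),
    )
    note("assemble", dt, contigs=len(contigs))
    if wd:
        rio.write_contigs_fasta(contigs, wd / "05_contigs.fasta")

    repeats, dt = run("merge", lambda: merge_contigs(contigs, config.merge_params()))
    note("merge", dt, repeats=len(repeats))
    if wd:
        rio.write_contigs_fasta(repeats, wd / "06_repeats.fasta")

    if repeats:
        clusters, dt = run(
            "cluster",
            lambda: cluster_repeats(
                [(c.id, c.sequence) for c in repeats], config.cluster_params()
            ),
        )
    else:
        clusters, dt = ClusterResult(cluster_of={}, representatives={}), 0.0
    note("cluster", dt, clusters=clusters.n_clusters)
    if wd:
        _write_clusters_tsv(clusters, wd / "07_clusters.tsv")

    metrics = None
    if library is not None:
        metrics, dt = run(
            "evaluate",
            lambda: compute_metrics(
                [(c.id, c.sequence) for c in repeats],
                library,
                identity_threshold=config.identity_threshold,
            ),
        )
        note(
            "evaluate",
            dt,
            n_hit=metrics.n_hit,
            n_full=metrics.n_full,
            c_avg=round(metrics.c_avg, 6),
            c_m=round(metrics.c_m, 6),
        )
        if wd:
            _write_metrics_tsv(metrics, wd / "08_metrics.tsv")

    if wd:
        with open(wd / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return PipelineResult(
        repeats=repeats,
        contigs=contigs,
        clusters=clusters,
        metrics=metrics,
        manifest=manifest,
    )


def run_stage(
    stage: str,
    config: PipelineConfig,
    workdir: str | Path,
    reads=None,
    library: list[tuple[str, str]] | None = None,
):
    """Run a single stage, consuming earlier stage files from ``workdir``.

    Enables resumable, file-to-file execution with the same semantics as
    :func:`run_pipeline`.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    wd = Path(workdir)
    wd.mkdir(parents=True, exist_ok=True)

    def need(name: str) -> Path:
        p = wd / name
        if not p.exists():
            raise StageError(stage, FileNotFoundError(f"missing prerequisite {p}"))
        return p

    try:
        if stage == "count":
            if reads is None:
                raise ValueError("count stage requires reads")
            seqs = _load_reads(reads)
            table = count_kmers((s for _, s in seqs), config.k, config.canonical)
            rio.write_kmer_table(table, wd / "01_kmers.tsv")
            return table
        if stage == "classify":
            table = rio.read_kmer_table(need("01_kmers.tsv"), config.canonical)
            bf = config.base_freq
            if bf is None:
                bf = estimate_base_freq(frequency_histogram(table))
            high, mid = classify_kmers(table, config.selection_params(bf))
            rio.write_kmer_table(high, wd / "02_high.tsv")
            rio.write_kmer_table(mid, wd / "02_intermediate.tsv")
            return high, mid
        if stage == "recruit":
            high = rio.read_kmer_table(need("02_high.tsv"), config.canonical)
            mid = rio.read_kmer_table(need("02_intermediate.tsv"), config.canonical)
            merged = (
                iterative_recruit(mid, high, config.recruitment_params())
                if config.enable_recruit
                else high
            )
            rio.write_kmer_table(merged, wd / "03_merged_kmers.tsv")
            return merged
        if stage == "polish":
            merged = rio.read_kmer_table(need("03_merged_kmers.tsv"), config.canonical)
            out = (
                polish(merged, config.polish_params())
                if config.enable_polish
                else merged
            )
            rio.write_kmer_table(out, wd / "04_polished.tsv")
            return out
        if stage == "assemble":
            polished = rio.read_kmer_table(need("04_polished.tsv"), config.canonical)
            contigs = assemble_contigs(
                polished,
                config.resolved_assembly_k,
                min_edge_support=config.min_edge_support,
            )
            rio.write_contigs_fasta(contigs, wd / "05_contigs.fasta")
            return contigs
        if stage == "merge":
            contigs = rio.read_contigs_fasta(need("05_contigs.fasta"))
            repeats = merge_contigs(contigs, config.merge_params())
            rio.write_contigs_fasta(repeats, wd / "06_repeats.fasta")
            return repeats
        if stage == "cluster":
            recs = rio.read_sequences(need("06_repeats.fasta"))
            clusters = cluster_repeats(recs, config.cluster_params())
            _write_clusters_tsv(clusters, wd / "07_clusters.tsv")
            return clusters
        # evaluate
        recs = rio.read_sequences(need("06_repeats.fasta"))
        if library is None:
            raise ValueError("evaluate stage requires a reference library")
        metrics = compute_metrics(
            recs, library, identity_threshold=config.identity_threshold
        )
        _write_metrics_tsv(metrics, wd / "08_metrics.tsv")
        return metrics
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc
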