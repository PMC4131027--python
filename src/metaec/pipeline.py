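"""Pipeline orchestration: hits -> elimination -> correction -> report."""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import io_formats
from .assignment import alpha_count_vector, top_score_matrix
from .correction import AbundanceEstimate, correct_abundance
from .elimination import BootstrapDecision, bootstrap_eliminate
from .io_formats import GenomeRecord, HitTable
from .similarity import SimilarityMatrix, restrict_matrix
from .synth import (
    SyntheticCommunity,
    generate_genome,
    mutate_genome,
    naive_align,
    simulate_reads,
)

__all__ = ["PipelineConfig", "CommunitySpec", "run_estimate", "run_simulate", "estimate_from_hits"]

log = logging.getLogger("metaec")


@dataclass
class PipelineConfig:
    """Tunable parameters of the estimator, with the recommended defaults.

    alpha: score-ratio threshold for multi-assignment (a genome must reach
        alpha * the read's max score to share the read).
    k0: simulated reads per genome when building a similarity matrix.
    similarity_threshold: entries of W below this are treated as 0.
    cutoff_frac: bootstrap abundance cutoff as a fraction of the top
        genome's claimed count (0.0005 = 0.05%).
    occurrence_frac: a genome below the cutoff in more than this fraction
        of bootstrap replicates is eliminated.
    n_bootstraps: bootstrap replicates in the elimination stage.
    min_reads: minimum claimed reads c for the non-bootstrap greedy pass.
    """

    alpha: float = 0.96
    k0: int = 30_000
    similarity_threshold: float = 0.001
    cutoff_frac: float = 0.0005
    occurrence_frac: float = 0.05
    n_bootstraps: int = 100
    min_reads: int = 1
    seed: int = 17
    read_length: int = 100

    def __post_init__(self) -> None:
        for name in ("alpha",):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("similarity_threshold", "cutoff_frac", "occurrence_frac"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1)")
        for name in ("k0", "n_bootstraps", "min_reads", "read_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load from a YAML mapping; keyword overrides win over the file."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def describe(self) -> list[str]:
        return [f"{f.name} = {getattr(self, f.name)}" for f in fields(self)]


@dataclass
class CommunitySpec:
    """Recipe for a synthetic community.

    ``relatedness[i]`` is None for an independent random genome or a
    substitution rate, in which case genome i is a mutant of genome 0 at
    that rate (controlled pairwise similarity).
    """

    n_genomes: int
    genome_length: int
    proportions: Sequence[float]
    total_reads: int
    read_length: int = 100
    error_rate: float = 0.0
    relatedness: Sequence[float | None] | None = None

    def __post_init__(self) -> None:
        if len(self.proportions) != self.n_genomes:
            raise ValueError("one proportion per genome required")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError(
                f"proportions sum to {sum(self.proportions)}, expected 1"
            )
        if self.relatedness is not None and len(self.relatedness) != self.n_genomes:
            raise ValueError("relatedness must have one entry per genome")
        if self.genome_length < self.read_length:
            raise ValueError("genomes must be at least one read long")


def build_community(spec: CommunitySpec, seed: int) -> SyntheticCommunity:
    """Materialize the genomes of a :class:`CommunitySpec` deterministically."""
    child = np.random.SeedSequence(seed).generate_state(spec.n_genomes + 1) % (2**31)
    genomes: list[GenomeRecord] = []
    rel = spec.relatedness or [None] * spec.n_genomes
    for i in range(spec.n_genomes):
        gid = f"g{i + 1}"
        if rel[i] is None or i == 0:
            genomes.append(generate_genome(spec.genome_length, int(child[i]), gid))
        else:
            genomes.append(
                mutate_genome(genomes[0], float(rel[i]), int(child[i]), gid)
            )
    return SyntheticCommunity(
        genomes=genomes,
        proportions=np.asarray(spec.proportions, dtype=np.float64),
        read_length=spec.read_length,
        error_rate=spec.error_rate,
        seed=int(child[-1]),
    )


def estimate_from_hits(
    hits: HitTable, matrix: SimilarityMatrix, config: PipelineConfig
) -> tuple[list[AbundanceEstimate], list[BootstrapDecision]]:
    """Run elimination + correction on an in-memory hit table.

    Returns the per-genome estimates (over genomes surviving elimination;
    correction-dropped ones flagged) and the bootstrap report.
    """
    if hits.n_hits == 0:
        raise ValueError("no assignable reads in the hit table")
    A = top_score_matrix(hits)
    log.info("assignment: %d reads x %d genomes", len(A.read_ids), len(A.genome_ids))
    retained, decisions = bootstrap_eliminate(
        A,
        n_bootstraps=config.n_bootstraps,
        cutoff_frac=config.cutoff_frac,
        occurrence_frac=config.occurrence_frac,
        seed=config.seed,
    )
    log.info(
        "elimination: retained %d, eliminated %d",
        len(retained),
        len(A.genome_ids) - len(retained),
    )
    missing = [g for g in retained if g not in matrix.genome_ids]
    if missing:
        raise KeyError(
            f"genomes surviving elimination are absent from the similarity "
            f"matrix: {missing}"
        )
    W_sub = restrict_matrix(matrix, retained)
    b = alpha_count_vector(hits, retained, config.alpha)
    estimates = correct_abundance(b, W_sub)
    dropped = [e.genome_id for e in estimates if e.dropped_in_correction]
    if dropped:
        log.info("correction dropped %d genome(s): %s", len(dropped), dropped)
    return estimates, decisions


def run_estimate(
    hits_path: str | Path,
    matrix_path: str | Path,
    out_path: str | Path,
    config: PipelineConfig,
    score_column: int = 12,
    bootstrap_report_path: str | Path | None = None,
) -> list[AbundanceEstimate]:
    """File-level pipeline: parse hits, estimate, write the abundance report."""
    hits = io_formats.parse_blast_tabular(hits_path, score_column=score_column)
    matrix = io_formats.read_similarity_matrix(matrix_path)
    if matrix.alpha != config.alpha:
        log.warning(
            "alpha mismatch: similarity matrix built at %.4g, pipeline uses "
            "%.4g; the correction stage should reuse the matrix alpha",
            matrix.alpha,
            config.alpha,
        )
    estimates, decisions = estimate_from_hits(hits, matrix, config)
    io_formats.write_abundance_table(
        estimates, out_path, header_comments=config.describe()
    )
    if bootstrap_report_path is not None:
        with Path(bootstrap_report_path).open("w") as fh:
            fh.write("genome_id\tn_below_cutoff\tn_bootstraps\teliminated\n")
            for d in decisions:
                fh.write(
                    f"{d.genome_id}\t{d.n_below_cutoff}\t{d.n_bootstraps}\t"
                    f"{int(d.eliminated)}\n"
                )
    return estimates


def hit_table_to_blast_lines(hits: HitTable, read_length: int) -> list[str]:
    """Render a hit table as minimal outfmt-6 lines (score in column 12)."""
    lines = []
    for h in hits:
        lines.append(
            f"{h.read_id}\t{h.genome_id}\t100.00\t{read_length}\t0\t0\t1\t"
            f"{read_length}\t1\t{read_length}\t0.0\t{h.score:g}"
        )
    return lines


def run_simulate(
    spec: CommunitySpec, outdir: str | Path, seed: int
) -> dict[str, Path]:
    """Generate a community and emit genomes/reads FASTA, truth and hits TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    community = build_community(spec, seed)
    reads = simulate_reads(community, spec.total_reads)
    paths = {
        "genomes": outdir / "genomes.fasta",
        "reads": outdir / "reads.fasta",
        "truth": outdir / "truth.tsv",
        "hits": outdir / "hits.tsv",
    }
    io_formats.write_fasta(
        ((g.genome_id, g.sequence) for g in community.genomes), paths["genomes"]
    )
    io_formats.write_fasta(((r.read_id, r.sequence) for r in reads), paths["reads"])
    io_formats.write_truth_table(
        {
            g.genome_id: int(c)
            for g, c in zip(community.genomes, community.true_counts)
        },
        paths["truth"],
    )
    hits = naive_align(reads, community.genomes)
    with paths["hits"].open("w") as fh:
        for line in hit_table_to_blast_lines(hits, spec.read_length):
            fh.write(line + "\n")
    return paths
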