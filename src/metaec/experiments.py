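"""End-to-end benchmark experiments on synthetic communities.

These are the package's reference experiments: fully self-contained runs of
the whole pipeline (simulate -> align -> similarity -> eliminate -> correct
-> evaluate) on communities whose composition is known, used both by the
test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assignment import top_score_matrix
from .elimination import EliminationResult, eliminate_iterative
from .io_formats import HitTable, parse_blast_tabular
from .metrics import ErrorReport, error_measures
from .pipeline import CommunitySpec, PipelineConfig, build_community, estimate_from_hits
from .similarity import estimate_similarity
from .synth import naive_align, simulate_reads

__all__ = [
    "worked_example_hit_lines",
    "run_worked_example",
    "dissimilar_community_maxre",
    "similar_pair_recovery",
]

# Synthetic stand-in for the classic six-read, four-genome alignment output
# used to illustrate the elimination stage: G1 and G2 only ever share their
# top-scoring reads with G3/G4, so no read is uniquely attributable to them
# and the greedy pass retains exactly {G3, G4}.
_WORKED_EXAMPLE_TOP_HITS: list[tuple[str, str, float]] = [
    ("r1", "G3", 100.0),
    ("r1", "G1", 100.0),
    ("r1", "G2", 80.0),
    ("r2", "G3", 100.0),
    ("r3", "G3", 100.0),
    ("r3", "G2", 100.0),
    ("r4", "G4", 90.0),
    ("r4", "G2", 90.0),
    ("r5", "G4", 95.0),
    ("r6", "G3", 88.0),
    ("r6", "G4", 88.0),
]


def worked_example_hit_lines() -> list[str]:
    """The six-read example as BLAST outfmt-6 lines (bit score in col 12)."""
    lines = []
    for rid, gid, score in _WORKED_EXAMPLE_TOP_HITS:
        lines.append(
            f"{rid}\t{gid}\t98.00\t100\t2\t0\t1\t100\t501\t600\t1e-45\t{score:g}"
        )
    return lines


def run_worked_example(path=None, c: int = 1) -> EliminationResult:
    """Parse the six-read example and run greedy elimination with minimum c.

    ``path`` may point to an existing outfmt-6 file; by default the built-in
    synthetic example is used in memory.
    """
    if path is not None:
        hits = parse_blast_tabular(path)
    else:
        from .io_formats import AlignmentHit

        hits = HitTable(AlignmentHit(*h) for h in _WORKED_EXAMPLE_TOP_HITS)
    return eliminate_iterative(top_score_matrix(hits), c=c)


@dataclass
class BenchmarkResult:
    report: ErrorReport
    true_counts: dict[str, int]
    estimated_counts: dict[str, float]
    n_reads: int


def _run_community(
    spec: CommunitySpec, config: PipelineConfig, seed: int, k0: int
) -> BenchmarkResult:
    community = build_community(spec, seed)
    reads = simulate_reads(community, spec.total_reads)
    hits = naive_align(reads, community.genomes)
    matrix = estimate_similarity(
        community.genomes,
        K0=k0,
        read_length=spec.read_length,
        alpha=config.alpha,
        threshold=config.similarity_threshold,
        seed=seed + 1,
    )
    estimates, _ = estimate_from_hits(hits, matrix, config)
    est = {
        e.genome_id: e.corrected_count
        for e in estimates
        if not e.dropped_in_correction
    }
    truth = {
        g.genome_id: int(c)
        for g, c in zip(community.genomes, community.true_counts)
    }
    return BenchmarkResult(
        report=error_measures(est, truth),
        true_counts=truth,
        estimated_counts=est,
        n_reads=spec.total_reads,
    )


def dissimilar_community_maxre(
    seed: int,
    n_genomes: int = 5,
    genome_length: int = 50_000,
    total_reads: int = 150_000,
    read_length: int = 100,
    k0: int = 5_000,
) -> BenchmarkResult:
    """Full-pipeline error on a community of mutually dissimilar genomes.

    Five independent random genomes share essentially no exact k-mers, so
    the estimated similarity matrix is the identity and the corrected counts
    should track the true counts closely.  Abundance ratios span 1:20
    (1 : 2 : 5 : 10 : 20), the widest spread studied.
    """
    ratios = np.array([20.0, 10.0, 5.0, 2.0, 1.0][:n_genomes])
    spec = CommunitySpec(
        n_genomes=n_genomes,
        genome_length=genome_length,
        proportions=(ratios / ratios.sum()).tolist(),
        total_reads=total_reads,
        read_length=read_length,
        error_rate=0.0,
    )
    config = PipelineConfig(seed=seed % (2**31), read_length=read_length, k0=k0)
    return _run_community(spec, config, seed % (2**31), k0)


def similar_pair_recovery(
    seed: int,
    genome_length: int = 50_000,
    substitution_rate: float = 0.05,
    total_reads: int = 30_000,
    read_length: int = 100,
    k0: int = 3_000,
) -> tuple[dict[str, float], dict[str, float]]:
    """Recover proportions (2/3, 1/3) of a base genome and a 5% mutant.

    Returns (estimated relative abundances, true proportions) by genome id.
    The genomes share substantial similarity, so this exercises the
    correction solve with a genuinely non-identity W.
    """
    spec = CommunitySpec(
        n_genomes=2,
        genome_length=genome_length,
        proportions=[2.0 / 3.0, 1.0 / 3.0],
        total_reads=total_reads,
        read_length=read_length,
        error_rate=0.0,
        relatedness=[None, substitution_rate],
    )
    config = PipelineConfig(seed=seed % (2**31), read_length=read_length, k0=k0)
    result = _run_community(spec, config, seed % (2**31), k0)
    total = sum(result.estimated_counts.values())
    est = {g: c / total for g, c in result.estimated_counts.items()}
    truth = {"g1": 2.0 / 3.0, "g2": 1.0 / 3.0}
    return est, truth
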