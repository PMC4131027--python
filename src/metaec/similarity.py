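"""Genome-to-genome similarity matrix estimation.

The similarity w[j, j'] is the estimated probability that a read originating
from genome j is assigned (under the alpha * max-score rule) to genome j'.
It is measured empirically: K0 error-free reads are simulated from each
genome, aligned against the whole reference set, multi-assigned by the alpha
rule, and the assignment counts are normalized by the self-assigned count
n[j -> j], which pins the diagonal at exactly 1.  Entries below a small
threshold are zeroed — they are indistinguishable from alignment noise and
keeping them would only perturb the correction solve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import AlignmentHit, GenomeRecord, HitTable
from .synth import SimulatedRead, SyntheticCommunity, naive_align, simulate_reads

__all__ = [
    "SimilarityMatrix",
    "alpha_assign",
    "estimate_similarity",
    "select_matrix_by_read_length",
    "restrict_matrix",
    "DegenerateReferenceError",
]

_TIE_TOL = 1e-9


class DegenerateReferenceError(RuntimeError):
    """No simulated read mapped back to its own genome."""


@dataclass
class SimilarityMatrix:
    """Square matrix W of read mis-assignment probabilities, with metadata.

    Rows are indexed by source genome: W[j, j'] = P(read from genome j is
    assigned to genome j').  Diagonal is exactly 1; off-diagonal entries are
    0 or in [threshold, 1].  W need not be symmetric.
    """

    genome_ids: list[str]
    W: np.ndarray
    read_length: int
    K0: int
    alpha: float
    threshold: float

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=np.float64)
        m = len(self.genome_ids)
        if self.W.shape != (m, m):
            raise ValueError(f"W shape {self.W.shape} does not match {m} ids")
        if np.any(self.W < 0) or np.any(self.W > 1):
            raise ValueError("similarity entries must lie in [0, 1]")
        if not np.all(np.diag(self.W) == 1.0):
            raise ValueError("similarity diagonal must be exactly 1")

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SimilarityMatrix)
            and self.genome_ids == other.genome_ids
            and self.W.shape == other.W.shape
            and bool(np.all(self.W == other.W))
            and self.read_length == other.read_length
            and self.K0 == other.K0
            and self.alpha == other.alpha
            and self.threshold == other.threshold
        )


def alpha_assign(hits_for_read: Sequence[AlignmentHit], alpha: float) -> set[str]:
    """Genomes whose score reaches ``alpha * max score`` for this read.

    Always contains an arg-max genome; an empty hit list leaves the read
    unassigned (empty set).
    """
    if not (0 <= alpha <= 1):
        raise ValueError("alpha must be in [0, 1]")
    if not hits_for_read:
        return set()
    smax = max(h.score for h in hits_for_read)
    return {h.genome_id for h in hits_for_read if h.score >= alpha * smax - _TIE_TOL}


def _alpha_counts(ht: HitTable, alpha: float) -> np.ndarray:
    """Per-genome counts of alpha-qualified assignments (HitTable-local order)."""
    rmax = np.full(ht.n_reads, -np.inf)
    np.maximum.at(rmax, ht.read_idx, ht.scores)
    q = ht.scores >= alpha * rmax[ht.read_idx] - _TIE_TOL
    return np.bincount(ht.genome_idx[q], minlength=ht.n_genomes)


def estimate_similarity(
    genomes: Sequence[GenomeRecord],
    K0: int = 30_000,
    read_length: int = 100,
    alpha: float = 0.96,
    aligner=None,
    threshold: float = 0.001,
    seed: int = 0,
    normalize_by_k0: bool = False,
) -> SimilarityMatrix:
    """Estimate W by simulating K0 error-free reads per genome.

    For each source genome j the reads are aligned against the whole set,
    alpha-assigned, and w[j, j'] = n[j->j'] / n[j->j] (clamped to <= 1).
    ``normalize_by_k0`` divides by K0 instead of the self-assigned count
    (an alternative reading of the ratio; the default keeps the diagonal at
    exactly 1, which the correction solve relies on).  Entries below
    ``threshold`` are zeroed; the diagonal is set to 1.  Deterministic under
    ``seed``.
    """
    if K0 < 1:
        raise ValueError("K0 must be >= 1")
    if aligner is None:
        aligner = naive_align
    ids = [g.genome_id for g in genomes]
    m = len(ids)
    gpos = {gid: i for i, gid in enumerate(ids)}
    W = np.zeros((m, m))
    child_seeds = np.random.SeedSequence(seed).generate_state(m) % (2**31)
    for j, g in enumerate(genomes):
        if g.length < read_length:
            raise ValueError(
                f"genome {g.genome_id!r} shorter than read length {read_length}"
            )
        comm = SyntheticCommunity(
            genomes=[g],
            proportions=np.array([1.0]),
            read_length=read_length,
            error_rate=0.0,
            seed=int(child_seeds[j]),
        )
        reads = simulate_reads(comm, K0)
        ht = aligner(reads, list(genomes))
        counts_local = _alpha_counts(ht, alpha)
        counts = np.zeros(m)
        for gi, gid in enumerate(ht.genome_ids):
            counts[gpos[gid]] = counts_local[gi]
        if counts[j] == 0:
            raise DegenerateReferenceError(
                f"no simulated read from {g.genome_id!r} was assigned back to "
                "it; the reference is degenerate"
            )
        denom = float(K0) if normalize_by_k0 else counts[j]
        W[j] = np.minimum(counts / denom, 1.0)
    W[W < threshold] = 0.0
    np.fill_diagonal(W, 1.0)
    return SimilarityMatrix(
        genome_ids=ids,
        W=W,
        read_length=read_length,
        K0=K0,
        alpha=alpha,
        threshold=threshold,
    )


def select_matrix_by_read_length(
    available: Sequence[SimilarityMatrix], mean_read_length: float
) -> SimilarityMatrix:
    """Pick the matrix whose read length is nearest the sample's mean.

    A matrix built at a very different read length misestimates the
    mis-assignment probabilities, so the closest one is used; ties go to the
    shorter read length.
    """
    if not available:
        raise ValueError("no similarity matrices available")
    return min(
        available,
        key=lambda mat: (abs(mat.read_length - mean_read_length), mat.read_length),
    )


def restrict_matrix(
    matrix: SimilarityMatrix, genome_ids: Sequence[str]
) -> SimilarityMatrix:
    """Principal submatrix over ``genome_ids`` in the requested order."""
    ids = list(genome_ids)
    if not ids:
        raise ValueError("empty genome selection")
    pos = {gid: i for i, gid in enumerate(matrix.genome_ids)}
    missing = [g for g in ids if g not in pos]
    if missing:
        raise KeyError(f"genomes not in similarity matrix: {missing}")
    idx = np.array([pos[g] for g in ids])
    return SimilarityMatrix(
        genome_ids=ids,
        W=matrix.W[np.ix_(idx, idx)],
        read_length=matrix.read_length,
        K0=matrix.K0,
        alpha=matrix.alpha,
        threshold=matrix.threshold,
    )
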