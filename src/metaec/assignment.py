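"""Turn alignment hits into the two evidence structures the method uses.

The elimination stage consumes a binary top-score assignment matrix A (each
read marks the genome(s) holding its best score).  The correction stage
consumes the alpha-threshold count vector b, recomputed over the genomes
that survive elimination.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import HitTable

__all__ = ["AssignmentMatrix", "CountVector", "top_score_matrix", "alpha_count_vector"]

# Bit scores are computed floats; exact equality would make tie detection
# brittle, so scores within this absolute tolerance of the max are ties.
SCORE_TIE_TOL = 1e-9


@dataclass
class AssignmentMatrix:
    """Binary K x N matrix: A[i, j] = 1 iff read i is top-score-assigned to
    genome j.  Every row has at least one 1."""

    A: np.ndarray
    read_ids: list[str]
    genome_ids: list[str]


@dataclass
class CountVector:
    """Per-genome read counts b under the alpha multi-assignment rule."""

    genome_ids: list[str]
    b: np.ndarray


def top_score_matrix(hits: HitTable) -> AssignmentMatrix:
    """Assign each read to the genome(s) with its highest alignment score.

    Rows follow first-appearance read order, columns first-appearance genome
    order, so the matrix is deterministic for a given hit table.
    """
    if hits.n_hits == 0:
        raise ValueError("empty hit table")
    rmax = np.full(hits.n_reads, -np.inf)
    np.maximum.at(rmax, hits.read_idx, hits.scores)
    top = hits.scores >= rmax[hits.read_idx] - SCORE_TIE_TOL
    A = np.zeros((hits.n_reads, hits.n_genomes), dtype=np.uint8)
    A[hits.read_idx[top], hits.genome_idx[top]] = 1
    return AssignmentMatrix(A=A, read_ids=list(hits.read_ids), genome_ids=list(hits.genome_ids))


def alpha_count_vector(
    hits: HitTable, genome_ids: Sequence[str], alpha: float
) -> CountVector:
    """Count reads per retained genome under the alpha * max-score rule.

    Hits are first restricted to the retained genomes; the max is recomputed
    over that restriction (the read is *re*assigned among survivors), and
    every genome reaching ``alpha * max`` receives the read.  Reads with no
    hit to a retained genome contribute nothing.
    """
    if not genome_ids:
        raise ValueError("retained genome set must be non-empty")
    if not (0 <= alpha <= 1):
        raise ValueError("alpha must be in [0, 1]")
    ids = list(genome_ids)
    pos = {g: i for i, g in enumerate(ids)}
    keep_col = np.array([pos.get(g, -1) for g in hits.genome_ids], dtype=np.int64)
    sel = keep_col[hits.genome_idx] >= 0
    r = hits.read_idx[sel]
    g = keep_col[hits.genome_idx[sel]]
    s = hits.scores[sel]
    rmax = np.full(hits.n_reads, -np.inf)
    np.maximum.at(rmax, r, s)
    q = s >= alpha * rmax[r] - SCORE_TIE_TOL
    b = np.bincount(g[q], minlength=len(ids))
    return CountVector(genome_ids=ids, b=b.astype(np.int64))
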