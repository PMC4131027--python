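"""Elimination stage: remove genomes with no uniquely attributable reads.

Every true genome has unique regions, so with sufficient coverage some reads
must be attributable to it alone.  The greedy procedure repeatedly selects
the genome column with the most currently unclaimed reads, lets it claim
them, and removes those reads from every other column; genomes whose
remaining support falls below a minimum count c are eliminated.  Two
implementations are provided — a direct while-loop and a literal
matrix-algebra form using permutation/subtraction matrices with an entrywise
clamp at zero — and are required to agree exactly; their equivalence is the
module's primary internal oracle.

A non-parametric bootstrap over reads turns the hard threshold into a
stability criterion: a genome is declared false only if it falls below the
abundance cutoff in more than a given fraction of resampled replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .assignment import AssignmentMatrix

__all__ = [
    "EliminationResult",
    "BootstrapDecision",
    "eliminate_iterative",
    "eliminate_matrix_form",
    "bootstrap_eliminate",
    "AllGenomesEliminatedError",
]


class AllGenomesEliminatedError(RuntimeError):
    """Bootstrap filtering removed every genome."""


@dataclass
class EliminationResult:
    retained_ids: list[str]
    eliminated_ids: list[str]
    claimed_counts: dict[str, int]
    order_selected: list[str]


@dataclass
class BootstrapDecision:
    genome_id: str
    n_bootstraps: int
    n_below_cutoff: int
    eliminated: bool


def _argmax_column(norms: np.ndarray, ids: list[str], active: np.ndarray) -> int:
    """Index of the max-norm active column; ties -> smallest genome_id."""
    mx = norms[active].max()
    cand = np.nonzero(active & (norms == mx))[0]
    return min(cand, key=lambda i: ids[i])


def eliminate_iterative(A: AssignmentMatrix, c: int = 1) -> EliminationResult:
    """Greedy unique-read elimination (while-loop form).

    Repeatedly select the column with maximal L1-norm; stop when that norm
    drops below ``c`` (a genome needs at least c unclaimed reads to count as
    present).  The selected genome claims its reads, which are zeroed out of
    every other column, so each read is claimed at most once.
    """
    if c < 1:
        raise ValueError("c must be >= 1")
    M = A.A.astype(np.int64).copy()
    ids = A.genome_ids
    n = len(ids)
    active = np.ones(n, dtype=bool)
    retained: list[str] = []
    claimed: dict[str, int] = {}
    while active.any():
        norms = M.sum(axis=0)
        j = _argmax_column(norms, ids, active)
        if norms[j] < c:
            break
        rows = M[:, j] > 0
        retained.append(ids[j])
        claimed[ids[j]] = int(norms[j])
        M[rows, :] = 0
        active[j] = False
    eliminated = [g for g in ids if g not in claimed]
    return EliminationResult(
        retained_ids=retained,
        eliminated_ids=eliminated,
        claimed_counts=claimed,
        order_selected=list(retained),
    )


def eliminate_matrix_form(A: AssignmentMatrix, c: int = 1) -> EliminationResult:
    """Greedy elimination via explicit permutation/subtraction matrices.

    Step j right-multiplies by a permutation matrix P_j (swapping the
    max-norm column into position j) and a subtraction matrix S_j
    (subtracting column j from every later column), then clamps entrywise at
    zero.  Columns left of the stopping position are the retained genomes.
    Contractually identical to :func:`eliminate_iterative`.
    """
    if c < 1:
        raise ValueError("c must be >= 1")
    M = A.A.astype(np.float64).copy()
    ids = list(A.genome_ids)
    n = len(ids)
    j0 = n
    claimed: dict[str, int] = {}
    for j in range(n):
        norms = M.sum(axis=0)
        tail = np.zeros(n, dtype=bool)
        tail[j:] = True
        jbest = _argmax_column(norms, ids, tail)
        if norms[jbest] < c:
            j0 = j
            break
        P = np.eye(n)
        if jbest != j:
            P[:, [j, jbest]] = P[:, [jbest, j]]
            ids[j], ids[jbest] = ids[jbest], ids[j]
        S = np.eye(n)
        S[j, j + 1 :] = -1.0
        M = np.maximum(M @ P @ S, 0.0)
        claimed[ids[j]] = int(round(norms[jbest]))
    retained = ids[:j0]
    eliminated = sorted(ids[j0:], key=A.genome_ids.index)
    return EliminationResult(
        retained_ids=retained,
        eliminated_ids=eliminated,
        claimed_counts=claimed,
        order_selected=list(retained),
    )


def bootstrap_eliminate(
    A: AssignmentMatrix,
    n_bootstraps: int = 100,
    cutoff_frac: float = 0.0005,
    occurrence_frac: float = 0.05,
    seed: int = 0,
) -> tuple[list[str], list[BootstrapDecision]]:
    """Bootstrap-stabilized elimination.

    Each replicate resamples the K reads (rows of A) with replacement and
    reruns the greedy pass with a per-replicate minimum count
    ``c = max(1, ceil(cutoff_frac * max column norm))`` — the max column norm
    is what the most abundant genome claims, since the greedy pass always
    selects it first.  A genome is "below cutoff" in a replicate if it is
    eliminated there or claims fewer than ``cutoff_frac`` times the top
    genome's claim.  Genomes below cutoff in more than ``occurrence_frac`` of
    replicates are declared false and removed.
    """
    if n_bootstraps < 1:
        raise ValueError("n_bootstraps must be >= 1")
    if not (0 < cutoff_frac < 1):
        raise ValueError("cutoff_frac must be in (0, 1)")
    if not (0 <= occurrence_frac < 1):
        raise ValueError("occurrence_frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    K = A.A.shape[0]
    ids = A.genome_ids
    below = np.zeros(len(ids), dtype=np.int64)
    for _ in range(n_bootstraps):
        idx = rng.integers(0, K, size=K)
        Ab = AssignmentMatrix(A=A.A[idx], read_ids=[], genome_ids=ids)
        top = int(Ab.A.sum(axis=0).max())
        c_rep = max(1, math.ceil(cutoff_frac * top))
        res = eliminate_iterative(Ab, c=c_rep)
        cut = cutoff_frac * max(res.claimed_counts.values(), default=0)
        for i, g in enumerate(ids):
            if g not in res.claimed_counts or res.claimed_counts[g] < cut:
                below[i] += 1
    decisions = [
        BootstrapDecision(
            genome_id=g,
            n_bootstraps=n_bootstraps,
            n_below_cutoff=int(below[i]),
            eliminated=below[i] / n_bootstraps > occurrence_frac,
        )
        for i, g in enumerate(ids)
    ]
    retained = [d.genome_id for d in decisions if not d.eliminated]
    if not retained:
        raise AllGenomesEliminatedError(
            "bootstrap filtering eliminated every genome; lower cutoff_frac "
            "or occurrence_frac"
        )
    return retained, decisions
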