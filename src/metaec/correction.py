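"""Correction stage: invert the similarity system to de-bias read counts.

A genome's observed count b_j mixes reads it truly generated with reads
bled over from similar genomes.  Writing t_j for the reads genome j receives
only due to its own presence, the observed counts satisfy b = W^T t, where
W[j, j'] is the probability a read from genome j is assigned to genome j'.
With off-diagonal similarities strictly below 1 the system is invertible and
t is recovered by a direct solve.  Negative (or zero) solutions are
impossible read counts: those genomes are dropped and the reduced system is
re-solved until all counts are positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assignment import CountVector
from .similarity import SimilarityMatrix

__all__ = [
    "AbundanceEstimate",
    "correct_abundance",
    "forward_counts",
    "SingularSimilarityError",
    "AllGenomesDroppedError",
]


class SingularSimilarityError(RuntimeError):
    """The similarity system is numerically singular."""


class AllGenomesDroppedError(RuntimeError):
    """The drop loop removed every genome."""


@dataclass
class AbundanceEstimate:
    genome_id: str
    corrected_count: float
    relative_abundance: float
    dropped_in_correction: bool = False


def forward_counts(t: np.ndarray, W_sub: SimilarityMatrix) -> np.ndarray:
    """Expected observed counts b = W^T t (the generative direction)."""
    t = np.asarray(t, dtype=np.float64)
    if t.shape != (len(W_sub.genome_ids),):
        raise ValueError("t length does not match matrix dimension")
    return W_sub.W.T @ t


def correct_abundance(
    b: CountVector,
    W_sub: SimilarityMatrix,
    cond_bound: float = 1e12,
    drop_one_at_a_time: bool = False,
) -> list[AbundanceEstimate]:
    """Solve W^T t = b, iteratively dropping genomes with t <= 0.

    ``b`` and ``W_sub`` must list the same genomes in the same order.  By
    default every non-positive component is dropped in one pass (the loop
    still terminates in at most m passes); ``drop_one_at_a_time`` removes
    only the most negative one per pass, for sensitivity analysis.  Returns
    one estimate per input genome, dropped ones flagged with zero abundance;
    relative abundances are normalized over survivors.
    """
    if b.genome_ids != W_sub.genome_ids:
        raise ValueError("count vector and similarity matrix genomes differ")
    ids = list(b.genome_ids)
    survivors = list(range(len(ids)))
    bvec = np.asarray(b.b, dtype=np.float64)
    t_final: dict[int, float] = {}
    while True:
        if not survivors:
            raise AllGenomesDroppedError(
                "every genome was dropped during correction"
            )
        idx = np.array(survivors)
        WT = W_sub.W[np.ix_(idx, idx)].T
        if np.linalg.cond(WT) > cond_bound:
            raise SingularSimilarityError(
                "similarity system is numerically singular (condition number "
                f"> {cond_bound:g}); consider a larger alpha or merging "
                "indistinguishable genomes"
            )
        t = np.linalg.solve(WT, bvec[idx])
        neg = np.nonzero(t <= 0)[0]
        if neg.size == 0:
            for i, ti in zip(survivors, t):
                t_final[i] = float(ti)
            break
        if drop_one_at_a_time:
            neg = neg[np.argsort(t[neg])][:1]
        drop = {survivors[i] for i in neg}
        survivors = [i for i in survivors if i not in drop]
    total = sum(t_final.values())
    return [
        AbundanceEstimate(
            genome_id=g,
            corrected_count=t_final.get(i, 0.0),
            relative_abundance=t_final[i] / total if i in t_final else 0.0,
            dropped_in_correction=i not in t_final,
        )
        for i, g in enumerate(ids)
    ]
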