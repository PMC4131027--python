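"""Error measures for evaluating abundance estimates against known truth.

With per-genome relative errors e_i = (t_i - tau_i) / tau_i over the N true
genomes (t_i the estimated and tau_i the true read count):

    RRMSE = 100 * sqrt(mean(e_i^2))      relative root mean squared error
    AVGRE = 100 * mean(|e_i|)            average relative error
    MAXRE = 100 * max(|e_i|)             maximum relative error

All three are scale-invariant, so they agree whether computed on read counts
or on relative abundances when the totals match.  A true genome missing from
the estimate contributes e_i = -1 (100% error).  Genomes estimated present
but absent from the truth are excluded from the measures and reported
separately as false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = ["ErrorReport", "error_measures"]


@dataclass
class ErrorReport:
    rrmse: float
    avgre: float
    maxre: float
    n_genomes: int
    false_positives: list[str] = field(default_factory=list)


def error_measures(
    estimated: Mapping[str, float], truth: Mapping[str, float]
) -> ErrorReport:
    """Compute RRMSE / AVGRE / MAXRE (in percent) of ``estimated`` vs ``truth``."""
    if not truth:
        raise ValueError("truth must contain at least one genome")
    bad = [g for g, tau in truth.items() if tau <= 0]
    if bad:
        raise ValueError(f"true counts must be positive; offending: {bad}")
    e = np.array(
        [(estimated.get(g, 0.0) - tau) / tau for g, tau in truth.items()],
        dtype=np.float64,
    )
    return ErrorReport(
        rrmse=100.0 * float(np.sqrt(np.mean(e**2))),
        avgre=100.0 * float(np.mean(np.abs(e))),
        maxre=100.0 * float(np.max(np.abs(e))),
        n_genomes=len(truth),
        false_positives=sorted(set(estimated) - set(truth)),
    )
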