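import numpy as np
import pytest

from metaec.experiments import worked_example_hit_lines
from metaec.io_formats import AlignmentHit, HitTable


@pytest.fixture
def six_read_blast(tmp_path):
    """Six-read, four-genome outfmt-6 file (synthetic worked example)."""
    p = tmp_path / "six_reads.tsv"
    p.write_text("\n".join(worked_example_hit_lines()) + "\n")
    return p


@pytest.fixture
def simple_hits():
    """Four reads over three genomes for hand-checkable assignment tests."""
    return HitTable(
        [
            AlignmentHit("r1", "G1", 100.0),
            AlignmentHit("r1", "G2", 100.0),
            AlignmentHit("r2", "G2", 100.0),
            AlignmentHit("r3", "G2", 100.0),
            AlignmentHit("r3", "G3", 100.0),
            AlignmentHit("r4", "G3", 100.0),
        ]
    )


def random_assignment_matrix(rng, max_reads=50, max_genomes=10, density=0.3):
    """Random binary matrix with every row non-empty (a valid A)."""
    from metaec.assignment import AssignmentMatrix

    K = int(rng.integers(1, max_reads + 1))
    N = int(rng.integers(1, max_genomes + 1))
    A = (rng.random((K, N)) < density).astype(np.uint8)
    empty = A.sum(axis=1) == 0
    A[empty, rng.integers(0, N, size=int(empty.sum()))] = 1
    return AssignmentMatrix(
        A=A,
        read_ids=[f"r{i}" for i in range(K)],
        genome_ids=[f"g{j}" for j in range(N)],
    )
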