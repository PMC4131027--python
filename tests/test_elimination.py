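import numpy as np
import pytest

from conftest import random_assignment_matrix
from metaec.assignment import AssignmentMatrix, top_score_matrix
from metaec.elimination import (
    AllGenomesEliminatedError,
    bootstrap_eliminate,
    eliminate_iterative,
    eliminate_matrix_form,
)
from metaec.io_formats import AlignmentHit, HitTable


def _A(rows, genome_ids=None):
    arr = np.array(rows, dtype=np.uint8)
    gids = genome_ids or [f"G{j + 1}" for j in range(arr.shape[1])]
    return AssignmentMatrix(
        A=arr, read_ids=[f"r{i + 1}" for i in range(arr.shape[0])], genome_ids=gids
    )


class TestEliminateIterative:
    def test_identity_like_all_retained(self):
        res = eliminate_iterative(_A(np.eye(3, dtype=int)), c=1)
        assert sorted(res.retained_ids) == ["G1", "G2", "G3"]
        assert res.eliminated_ids == []
        assert all(v == 1 for v in res.claimed_counts.values())

    def test_hand_executed_greedy(self):
        # r1->{G1,G2}, r2->{G2}, r3->{G2,G3}, r4->{G3}
        res = eliminate_iterative(
            _A([[1, 1, 0], [0, 1, 0], [0, 1, 1], [0, 0, 1]]), c=1
        )
        assert res.order_selected == ["G2", "G3"]
        assert res.claimed_counts == {"G2": 3, "G3": 1}
        assert res.eliminated_ids == ["G1"]

    def test_six_read_worked_example(self, six_read_blast):
        from metaec.io_formats import parse_blast_tabular

        A = top_score_matrix(parse_blast_tabular(six_read_blast))
        res = eliminate_iterative(A, c=1)
        assert sorted(res.retained_ids) == ["G3", "G4"]
        assert sorted(res.eliminated_ids) == ["G1", "G2"]

    def test_tie_broken_by_smallest_genome_id(self):
        res = eliminate_iterative(_A([[0, 1], [1, 0]], ["Gz", "Ga"]), c=1)
        assert res.order_selected[0] == "Ga"

    def test_reads_claimed_at_most_once(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            A = random_assignment_matrix(rng)
            res = eliminate_iterative(A, c=1)
            assert sum(res.claimed_counts.values()) <= A.A.shape[0]

    def test_uniquely_held_reads_guarantee_retention(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            A = random_assignment_matrix(rng)
            unique_rows = A.A.sum(axis=1) == 1
            unique_counts = A.A[unique_rows].sum(axis=0)
            res = eliminate_iterative(A, c=1)
            for j, g in enumerate(A.genome_ids):
                if unique_counts[j] >= 1:
                    assert g in res.retained_ids

    def test_monotone_in_c(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            A = random_assignment_matrix(rng)
            r1 = set(eliminate_iterative(A, c=1).retained_ids)
            r3 = set(eliminate_iterative(A, c=3).retained_ids)
            assert r3 <= r1

    def test_partition_of_genomes(self):
        rng = np.random.default_rng(3)
        A = random_assignment_matrix(rng)
        res = eliminate_iterative(A, c=2)
        assert sorted(res.retained_ids + res.eliminated_ids) == sorted(A.genome_ids)
        assert not set(res.retained_ids) & set(res.eliminated_ids)


class TestMatrixFormEquivalence:
    def test_single_column(self):
        res = eliminate_matrix_form(_A([[1], [1], [1]]), c=1)
        assert res.retained_ids == ["G1"] and res.claimed_counts == {"G1": 3}

    def test_matches_iterative_on_random_matrices(self):
        """The literal permutation/subtraction/clamp recursion and the
        while-loop produce identical results on 1,000 random matrices."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            A = random_assignment_matrix(rng)
            c = int(rng.integers(1, 4))
            it = eliminate_iterative(A, c=c)
            mf = eliminate_matrix_form(A, c=c)
            assert it.retained_ids == mf.retained_ids
            assert it.eliminated_ids == mf.eliminated_ids
            assert it.claimed_counts == mf.claimed_counts
            assert it.order_selected == mf.order_selected


class TestBootstrapEliminate:
    def test_single_genome_always_retained(self):
        A = _A([[1]] * 20, ["G1"])
        retained, decisions = bootstrap_eliminate(A, n_bootstraps=10, seed=0)
        assert retained == ["G1"]
        assert decisions[0].n_below_cutoff == 0

    def test_two_strong_genomes_both_retained(self):
        arr = np.zeros((1500, 2), dtype=np.uint8)
        arr[:1000, 0] = 1
        arr[1000:, 1] = 1
        retained, _ = bootstrap_eliminate(
            _A(arr), n_bootstraps=50, cutoff_frac=0.0005, seed=1
        )
        assert sorted(retained) == ["G1", "G2"]

    def test_vanishingly_rare_genome_eliminated(self):
        # 1 read among 10,000: always below 0.05% of the top genome's claim
        arr = np.zeros((10_000, 2), dtype=np.uint8)
        arr[:-1, 0] = 1
        arr[-1, 1] = 1
        retained, decisions = bootstrap_eliminate(
            _A(arr), n_bootstraps=100, cutoff_frac=0.0005, occurrence_frac=0.05, seed=2
        )
        assert retained == ["G1"]
        d = {d.genome_id: d for d in decisions}
        assert d["G2"].eliminated
        assert d["G2"].n_below_cutoff > 95

    def test_decision_invariant(self):
        arr = np.zeros((200, 2), dtype=np.uint8)
        arr[:190, 0] = 1
        arr[190:, 1] = 1
        _, decisions = bootstrap_eliminate(
            _A(arr), n_bootstraps=40, cutoff_frac=0.2, occurrence_frac=0.1, seed=3
        )
        for d in decisions:
            assert 0 <= d.n_below_cutoff <= d.n_bootstraps
            assert d.eliminated == (d.n_below_cutoff / d.n_bootstraps > 0.1)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        A = random_assignment_matrix(rng, max_reads=200)
        r1 = bootstrap_eliminate(A, n_bootstraps=20, seed=7)
        r2 = bootstrap_eliminate(A, n_bootstraps=20, seed=7)
        assert r1[0] == r2[0]
        assert [d.n_below_cutoff for d in r1[1]] == [d.n_below_cutoff for d in r2[1]]

    def test_all_eliminated_raises(self):
        # two genomes with one unique read each: resampling 2 reads with
        # replacement drops each genome in ~25% of replicates, so with
        # occurrence_frac=0 (any below-cutoff occurrence eliminates) both
        # genomes are removed and the advisory error fires
        arr = np.eye(2, dtype=np.uint8)
        with pytest.raises(AllGenomesEliminatedError):
            bootstrap_eliminate(
                _A(arr), n_bootstraps=50, cutoff_frac=0.5, occurrence_frac=0.0, seed=0
            )
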