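import numpy as np
import pytest

from metaec.io_formats import GenomeRecord
from metaec.synth import (
    SyntheticCommunity,
    generate_genome,
    largest_remainder,
    mutate_genome,
    naive_align,
    simulate_reads,
)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


class TestGenerateGenome:
    def test_deterministic_under_seed(self):
        assert generate_genome(8, 3).sequence == generate_genome(8, 3).sequence

    def test_different_seeds_differ(self):
        a = generate_genome(200, 3).sequence
        b = generate_genome(200, 4).sequence
        assert a != b

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            generate_genome(0, 1)

    def test_alphabet(self):
        assert set(generate_genome(500, 0).sequence) <= set("ACGT")


class TestMutateGenome:
    def test_rate_zero_identical(self):
        g = generate_genome(100, 0)
        assert mutate_genome(g, 0.0, 1).sequence == g.sequence

    def test_rate_one_every_base_changed(self):
        g = generate_genome(100, 0)
        m = mutate_genome(g, 1.0, 1)
        assert _hamming(g.sequence, m.sequence) == 100

    def test_rate_concentrates_around_expectation(self):
        g = generate_genome(10_000, 0)
        m = mutate_genome(g, 0.05, 7)
        frac = _hamming(g.sequence, m.sequence) / 10_000
        assert 0.03 <= frac <= 0.07


class TestLargestRemainder:
    @pytest.mark.parametrize(
        "props,total,expected",
        [
            ([1.0], 5, [5]),
            ([0.5, 0.5], 4, [2, 2]),
            ([1 / 3, 2 / 3], 100, [33, 67]),
            ([0.2, 0.3, 0.5], 7, [1, 2, 4]),
        ],
    )
    def test_examples(self, props, total, expected):
        assert largest_remainder(np.array(props), total).tolist() == expected

    def test_conserves_total(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.dirichlet(np.ones(rng.integers(1, 8)))
            total = int(rng.integers(1, 10_000))
            assert largest_remainder(p, total).sum() == total


class TestSimulateReads:
    def _community(self, genomes, props, L=10, err=0.0, seed=0):
        return SyntheticCommunity(
            genomes=genomes,
            proportions=np.array(props),
            read_length=L,
            error_rate=err,
            seed=seed,
        )

    def test_single_genome(self):
        g = generate_genome(50, 0)
        comm = self._community([g], [1.0])
        reads = simulate_reads(comm, 5)
        assert len(reads) == 5
        assert all(r.origin_genome_id == g.genome_id for r in reads)
        assert comm.true_counts.tolist() == [5]

    def test_error_free_reads_are_substrings(self):
        gs = [generate_genome(60, i, f"g{i}") for i in range(2)]
        comm = self._community(gs, [0.5, 0.5])
        reads = simulate_reads(comm, 4)
        assert comm.true_counts.tolist() == [2, 2]
        by_id = {g.genome_id: g.sequence for g in gs}
        for r in reads:
            assert by_id[r.origin_genome_id][r.start : r.start + 10] == r.sequence

    def test_read_conservation(self):
        gs = [generate_genome(100, i, f"g{i}") for i in range(3)]
        comm = self._community(gs, [0.2, 0.3, 0.5], err=0.1, seed=5)
        reads = simulate_reads(comm, 997)
        assert len(reads) == 997
        assert comm.true_counts.sum() == 997

    def test_short_genome_rejected(self):
        g = GenomeRecord("tiny", "ACGT")
        with pytest.raises(ValueError, match="tiny"):
            simulate_reads(self._community([g], [1.0], L=10), 3)

    def test_deterministic_under_seed(self):
        gs = [generate_genome(100, i, f"g{i}") for i in range(2)]
        r1 = simulate_reads(self._community(gs, [0.5, 0.5], err=0.05, seed=9), 20)
        r2 = simulate_reads(self._community(gs, [0.5, 0.5], err=0.05, seed=9), 20)
        assert [(x.sequence, x.start) for x in r1] == [
            (x.sequence, x.start) for x in r2
        ]


class TestNaiveAlign:
    def test_perfect_match_scores_full_length(self):
        g1 = generate_genome(2000, 1, "g1")
        g2 = generate_genome(2000, 2, "g2")
        comm = SyntheticCommunity([g1], np.array([1.0]), read_length=100, seed=0)
        reads = simulate_reads(comm, 1)
        ht = naive_align(reads, [g1, g2], k=16, match=1, mismatch=-2)
        hits = list(ht)
        assert len(hits) == 1
        assert hits[0].genome_id == "g1" and hits[0].score == 100.0

    def test_identical_genomes_tie(self):
        g1 = generate_genome(2000, 1, "g1")
        g2 = GenomeRecord("g2", g1.sequence)
        comm = SyntheticCommunity([g1], np.array([1.0]), read_length=100, seed=0)
        reads = simulate_reads(comm, 10)
        ht = naive_align(reads, [g1, g2])
        per_read = {}
        for h in ht:
            per_read.setdefault(h.read_id, {})[h.genome_id] = h.score
        for scores in per_read.values():
            assert scores["g1"] == scores["g2"]

    def test_substitutions_scored_by_hand(self):
        g1 = generate_genome(5000, 1, "g1")
        seq = list(g1.sequence[200:300])
        # flip 5 spread-out positions so a 16-mer seed survives between them
        for pos in (0, 20, 40, 60, 99):
            seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
        from metaec.synth import SimulatedRead

        read = SimulatedRead("r0", "g1", "".join(seq), 200)
        ht = naive_align([read], [g1], k=16, match=1, mismatch=-2)
        scores = {h.genome_id: h.score for h in ht}
        assert scores["g1"] == 95 * 1 + 5 * (-2)

    def test_unrelated_genomes_no_cross_hits(self):
        gs = [generate_genome(20_000, i, f"g{i}") for i in range(2)]
        comm = SyntheticCommunity(
            [gs[0]], np.array([1.0]), read_length=100, seed=0
        )
        reads = simulate_reads(comm, 200)
        ht = naive_align(reads, gs)
        assert set(ht.genome_ids) == {"g0"}

    def test_fasta_input_path(self, tmp_path):
        from metaec.io_formats import write_fasta

        g1 = generate_genome(2000, 1, "g1")
        comm = SyntheticCommunity([g1], np.array([1.0]), read_length=50, seed=0)
        reads = simulate_reads(comm, 3)
        p = tmp_path / "reads.fa"
        write_fasta(((r.read_id, r.sequence) for r in reads), p)
        ht = naive_align(p, [g1])
        assert ht.n_reads == 3
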