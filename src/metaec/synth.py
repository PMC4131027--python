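"""Synthetic communities, reads, and a built-in k-mer seed aligner.

This module makes the whole pipeline testable without external aligners or
genome downloads.  Genomes are i.i.d. uniform random sequences; "closely
related" genomes are produced by per-site substitution of a base genome at a
controlled rate, which maps directly onto the similarity the downstream
matrix estimates.  Reads are fixed-length, forward-strand, with an optional
substitution error model.  The aligner seeds on exact shared k-mers and
scores the implied full-length ungapped alignment — deliberately simple, but
it produces exactly the kind of scored hit table a BLAST run would, so score
ratios (all the method ever uses) behave realistically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .io_formats import GenomeRecord, HitTable

__all__ = [
    "SyntheticCommunity",
    "SimulatedRead",
    "generate_genome",
    "mutate_genome",
    "largest_remainder",
    "simulate_reads",
    "naive_align",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# byte -> 2-bit code; N (and anything else) -> 4, never matching a real base
_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _LUT[_b] = _i


def _encode(seq: str) -> np.ndarray:
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode("ascii")


@dataclass
class SimulatedRead:
    """A read drawn from a known genome at a known forward-strand offset."""

    read_id: str
    origin_genome_id: str
    sequence: str
    start: int


@dataclass
class SyntheticCommunity:
    """A community with known composition, for end-to-end evaluation.

    ``true_counts`` (the per-genome read tallies tau) is populated by
    :func:`simulate_reads`.
    """

    genomes: list[GenomeRecord]
    proportions: np.ndarray
    read_length: int
    error_rate: float = 0.0
    seed: int = 0
    true_counts: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=np.float64)
        if len(self.proportions) != len(self.genomes):
            raise ValueError("one proportion per genome required")
        if np.any(self.proportions < 0):
            raise ValueError("proportions must be non-negative")
        if abs(self.proportions.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"proportions sum to {self.proportions.sum()}, expected 1"
            )
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate must be in [0, 1)")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")


def generate_genome(length: int, seed: int, genome_id: str = "g1") -> GenomeRecord:
    """An i.i.d. uniform random genome; deterministic under ``seed``."""
    if length <= 0:
        raise ValueError("genome length must be positive")
    rng = np.random.default_rng(seed)
    return GenomeRecord(genome_id, _decode(rng.integers(0, 4, size=length, dtype=np.uint8)))


def mutate_genome(
    base: GenomeRecord,
    substitution_rate: float,
    seed: int,
    genome_id: str | None = None,
) -> GenomeRecord:
    """Substitute each position, independently with probability
    ``substitution_rate``, by a uniformly chosen *different* base.

    This gives a mutant whose expected per-site identity to ``base`` is
    1 - substitution_rate, the knob controlling downstream similarity.
    """
    if not (0 <= substitution_rate <= 1):
        raise ValueError("substitution_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    arr = _encode(base.sequence).copy()
    hit = rng.random(arr.size) < substitution_rate
    shift = rng.integers(1, 4, size=int(hit.sum()), dtype=np.uint8)
    arr[hit] = (arr[hit] + shift) % 4
    gid = genome_id if genome_id is not None else base.genome_id + "_mut"
    return GenomeRecord(gid, _decode(arr))


def largest_remainder(proportions: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` integer counts to ``proportions`` deterministically.

    Floors are assigned first; leftover units go to the largest fractional
    remainders (ties: larger proportion, then lower index).
    """
    p = np.asarray(proportions, dtype=np.float64)
    raw = p * total
    counts = np.floor(raw).astype(np.int64)
    short = total - int(counts.sum())
    if short > 0:
        rem = raw - counts
        order = sorted(range(len(p)), key=lambda i: (-rem[i], -p[i], i))
        for i in order[:short]:
            counts[i] += 1
    return counts


def simulate_reads(
    community: SyntheticCommunity, total_reads: int, multinomial: bool = False
) -> list[SimulatedRead]:
    """Draw ``total_reads`` fixed-length reads from the community genomes.

    Per-genome counts follow largest-remainder allocation of the proportions
    (exact tau, so evaluation carries no allocation noise); ``multinomial=True``
    samples them instead.  Start positions are uniform on the forward strand;
    substitution errors are applied at ``community.error_rate``.  The counts
    are recorded on ``community.true_counts``.
    """
    L = community.read_length
    for g in community.genomes:
        if g.length < L:
            raise ValueError(
                f"genome {g.genome_id!r} (length {g.length}) shorter than "
                f"read length {L}"
            )
    rng = np.random.default_rng(community.seed)
    if multinomial:
        counts = rng.multinomial(total_reads, community.proportions).astype(np.int64)
    else:
        counts = largest_remainder(community.proportions, total_reads)
    community.true_counts = counts
    reads: list[SimulatedRead] = []
    n = 0
    for g, cnt in zip(community.genomes, counts):
        if cnt == 0:
            continue
        arr = _encode(g.sequence)
        starts = rng.integers(0, g.length - L + 1, size=cnt)
        block = arr[starts[:, None] + np.arange(L)]
        if community.error_rate > 0:
            hit = rng.random(block.shape) < community.error_rate
            shift = rng.integers(1, 4, size=int(hit.sum()), dtype=np.uint8)
            block[hit] = (block[hit] + shift) % 4
        for s, row in zip(starts, block):
            rid = f"read{n}|origin={g.genome_id}|pos={int(s)}"
            reads.append(SimulatedRead(rid, g.genome_id, _decode(row), int(s)))
            n += 1
    return reads


def _kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Pack each length-k window into an int64; windows containing N -> -1."""
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    for i in range(k):
        codes = (codes << 2) | (arr[i : i + n] & 3)
    isn = np.cumsum(np.concatenate([[0], (arr == 4).astype(np.int64)]))
    codes[(isn[k:] - isn[:-k]) > 0] = -1
    return codes


def _expand_ranges(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    lengths = hi - lo
    total = int(lengths.sum())
    out = np.repeat(lo, lengths)
    offsets = np.arange(total) - np.repeat(
        np.concatenate([[0], np.cumsum(lengths)[:-1]]), lengths
    )
    return out + offsets


def naive_align(
    reads: Sequence[SimulatedRead] | str | Path,
    genomes: Sequence[GenomeRecord],
    k: int = 16,
    match: int = 1,
    mismatch: int = -2,
    chunk: int = 16384,
) -> HitTable:
    """Seed-and-score ungapped alignment of fixed-length reads vs genomes.

    For each read and genome, every shared exact k-mer implies a diagonal
    (offset); the full read is scored ungapped at each implied offset as
    ``match * matches + mismatch * mismatches`` and the genome's best score
    is kept.  A hit is emitted only when the best score is positive.  N never
    matches.  Deterministic; vectorized over reads.
    """
    if isinstance(reads, (str, Path)):
        from Bio import SeqIO

        reads = [
            SimulatedRead(rec.id, "", str(rec.seq).upper(), 0)
            for rec in SeqIO.parse(str(reads), "fasta")
        ]
    if not reads:
        return HitTable()
    if match <= 0 or mismatch > 0:
        raise ValueError("require match > 0 and mismatch <= 0")
    L = len(reads[0].sequence)
    if any(len(r.sequence) != L for r in reads):
        raise ValueError("all reads must have equal length")
    if k > L:
        raise ValueError("seed length k exceeds read length")

    R = len(reads)
    read_arr = _LUT[
        np.frombuffer("".join(r.sequence for r in reads).encode("ascii"), dtype=np.uint8)
    ].reshape(R, L)
    read_codes = np.empty((R, L - k + 1), dtype=np.int64)
    for i, row in enumerate(read_arr):
        read_codes[i] = _kmer_codes(row, k)

    best = np.full((R, len(genomes)), -np.inf)
    for gi, g in enumerate(genomes):
        garr = _encode(g.sequence)
        gcodes = _kmer_codes(garr, k)
        valid = np.nonzero(gcodes >= 0)[0]
        order = valid[np.argsort(gcodes[valid], kind="stable")]
        gsorted = gcodes[order]
        max_off = g.length - L
        if max_off < 0:
            continue
        for c0 in range(0, R, chunk):
            c1 = min(c0 + chunk, R)
            flat = read_codes[c0:c1].ravel()
            lo = np.searchsorted(gsorted, flat, side="left")
            hi = np.searchsorted(gsorted, flat, side="right")
            cnt = hi - lo
            m = cnt > 0
            if not m.any():
                continue
            P = L - k + 1
            rlocal = np.repeat(np.nonzero(m)[0] // P, cnt[m])
            rpos = np.repeat(np.nonzero(m)[0] % P, cnt[m])
            gpos = order[_expand_ranges(lo[m], hi[m])]
            offs = gpos - rpos
            ok = (offs >= 0) & (offs <= max_off)
            rlocal, offs = rlocal[ok], offs[ok]
            if rlocal.size == 0:
                continue
            key = rlocal * np.int64(max_off + 1) + offs
            key = np.unique(key)
            rlocal = key // (max_off + 1)
            offs = key % (max_off + 1)
            win = garr[offs[:, None] + np.arange(L)]
            rseq = read_arr[c0 + rlocal]
            nmatch = ((win == rseq) & (win < 4)).sum(axis=1)
            score = match * nmatch + mismatch * (L - nmatch)
            np.maximum.at(best[:, gi], c0 + rlocal, score.astype(np.float64))

    rows, cols = np.nonzero(best > 0)
    # compress to reads/genomes that actually appear, preserving order
    used_r = np.unique(rows)
    used_g = []
    gmap = np.full(len(genomes), -1, dtype=np.int64)
    for r, c in zip(rows, cols):
        if gmap[c] < 0:
            gmap[c] = len(used_g)
            used_g.append(genomes[c].genome_id)
    rmap = np.full(R, -1, dtype=np.int64)
    rmap[used_r] = np.arange(used_r.size)
    return HitTable.from_arrays(
        [reads[i].read_id for i in used_r],
        used_g,
        rmap[rows],
        gmap[cols],
        best[rows, cols],
    )


Aligner = Callable[[Sequence[SimulatedRead], Sequence[GenomeRecord]], HitTable]
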