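"""Readers and writers for the formats the pipeline touches.

Alignment evidence arrives as BLAST tabular output (``-outfmt 6``; the
commented ``-outfmt 7`` variant is tolerated), reference genomes as FASTA,
and two artifacts are persisted as plain TSV: the genome similarity matrix
(with ``#``-prefixed metadata lines) and the final abundance report.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "AlignmentHit",
    "HitTable",
    "GenomeRecord",
    "BlastParseError",
    "FastaFormatError",
    "MatrixFormatError",
    "parse_blast_tabular",
    "read_fasta",
    "write_abundance_table",
    "read_abundance_table",
    "write_similarity_matrix",
    "read_similarity_matrix",
    "write_truth_table",
    "read_truth_table",
]

_ALLOWED_BASES = frozenset("ACGTN")


class BlastParseError(ValueError):
    """Raised when a BLAST tabular file cannot be parsed."""


class FastaFormatError(ValueError):
    """Raised for duplicate ids or illegal characters in a FASTA file."""


class MatrixFormatError(ValueError):
    """Raised when a similarity-matrix file is malformed."""


class AlignmentHit(NamedTuple):
    """One (read, genome) alignment with its score (bit score by default)."""

    read_id: str
    genome_id: str
    score: float


@dataclass(frozen=True)
class GenomeRecord:
    """A reference genome: id and uppercase sequence over {A,C,G,T,N}."""

    genome_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


class HitTable:
    """Deduplicated alignment hits with stable first-appearance ordering.

    At most one hit is kept per (read, genome) pair — the maximum score wins,
    matching the view that the method's unit of evidence is the read-to-genome
    assignment, not the individual HSP.  Internally hits are stored columnar
    (integer read/genome indices plus a score vector) so the assignment and
    similarity stages can operate on whole arrays.
    """

    __slots__ = ("read_ids", "genome_ids", "read_idx", "genome_idx", "scores")

    def __init__(self, hits: Iterable[AlignmentHit] = ()):
        rind: dict[str, int] = {}
        gind: dict[str, int] = {}
        best: dict[tuple[int, int], float] = {}
        for h in hits:
            read_id, genome_id, score = h
            if not read_id or not genome_id:
                raise ValueError("read_id and genome_id must be non-empty")
            score = float(score)
            if score < 0:
                raise ValueError(f"negative score for ({read_id}, {genome_id})")
            r = rind.setdefault(read_id, len(rind))
            g = gind.setdefault(genome_id, len(gind))
            key = (r, g)
            prev = best.get(key)
            if prev is None or score > prev:
                best[key] = score
        self.read_ids: list[str] = list(rind)
        self.genome_ids: list[str] = list(gind)
        n = len(best)
        self.read_idx = np.empty(n, dtype=np.int64)
        self.genome_idx = np.empty(n, dtype=np.int64)
        self.scores = np.empty(n, dtype=np.float64)
        for i, ((r, g), s) in enumerate(best.items()):
            self.read_idx[i] = r
            self.genome_idx[i] = g
            self.scores[i] = s

    @classmethod
    def from_arrays(
        cls,
        read_ids: Sequence[str],
        genome_ids: Sequence[str],
        read_idx: np.ndarray,
        genome_idx: np.ndarray,
        scores: np.ndarray,
    ) -> "HitTable":
        """Build directly from columnar data with unique (read, genome) pairs.

        ``read_ids``/``genome_ids`` must cover exactly the indices used.
        """
        ht = cls.__new__(cls)
        ht.read_ids = list(read_ids)
        ht.genome_ids = list(genome_ids)
        ht.read_idx = np.asarray(read_idx, dtype=np.int64)
        ht.genome_idx = np.asarray(genome_idx, dtype=np.int64)
        ht.scores = np.asarray(scores, dtype=np.float64)
        if np.any(ht.scores < 0):
            raise ValueError("negative alignment score")
        return ht

    @property
    def n_hits(self) -> int:
        return len(self.scores)

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)

    @property
    def n_genomes(self) -> int:
        return len(self.genome_ids)

    def __len__(self) -> int:
        return self.n_hits

    def __iter__(self) -> Iterator[AlignmentHit]:
        for r, g, s in zip(self.read_idx, self.genome_idx, self.scores):
            yield AlignmentHit(self.read_ids[r], self.genome_ids[g], float(s))

    def hits_for_read(self, read_id: str) -> list[AlignmentHit]:
        r = self.read_ids.index(read_id)
        sel = self.read_idx == r
        return [
            AlignmentHit(read_id, self.genome_ids[g], float(s))
            for g, s in zip(self.genome_idx[sel], self.scores[sel])
        ]


def parse_blast_tabular(path: str | Path, score_column: int = 12) -> HitTable:
    """Parse BLAST tabular output (``-outfmt 6``) into a :class:`HitTable`.

    ``score_column`` is the 1-based column holding the alignment score;
    the default (12) is the bit score, which is length-normalized and hence
    comparable across subject genomes as the alpha-ratio rule requires.
    Lines starting with ``#`` are skipped.  Multiple HSPs of a read against
    one genome collapse to the maximum score.  An empty file yields an empty
    table.
    """
    path = Path(path)
    if score_column < 1:
        raise ValueError("score_column is 1-based and must be >= 1")
    hits: list[AlignmentHit] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12 or len(fields) < score_column:
                raise BlastParseError(
                    f"{path}: line {lineno}: expected >= 12 tab-separated "
                    f"fields, got {len(fields)}"
                )
            try:
                score = float(fields[score_column - 1])
            except ValueError as exc:
                raise BlastParseError(
                    f"{path}: line {lineno}: non-numeric score "
                    f"{fields[score_column - 1]!r}"
                ) from exc
            if score < 0:
                raise BlastParseError(f"{path}: line {lineno}: negative score")
            hits.append(AlignmentHit(fields[0], fields[1], score))
    return HitTable(hits)


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read genome records; ids are header tokens up to the first whitespace.

    Sequences are uppercased; characters outside {A,C,G,T,N} and duplicate
    ids are rejected.
    """
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaFormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        bad = set(seq) - _ALLOWED_BASES
        if bad:
            raise FastaFormatError(
                f"{path}: record {rec.id!r} contains illegal characters "
                f"{sorted(bad)}"
            )
        records.append(GenomeRecord(rec.id, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs as FASTA, 80 columns per line."""
    with Path(path).open("w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_abundance_table(estimates, path: str | Path, header_comments: Sequence[str] = ()) -> None:
    """Write the final abundance report as 3-column TSV.

    Rows are the non-dropped genomes sorted by descending relative abundance,
    ties broken by ascending genome_id.  ``header_comments`` lines are echoed
    as ``#`` comments (e.g. the effective configuration).
    """
    rows = [e for e in estimates if not getattr(e, "dropped_in_correction", False)]
    if not rows:
        raise ValueError("no estimates to write")
    total = sum(e.relative_abundance for e in rows)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"relative abundances sum to {total}, expected 1")
    rows.sort(key=lambda e: (-e.relative_abundance, e.genome_id))
    with Path(path).open("w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        fh.write("genome_id\tcorrected_read_count\trelative_abundance\n")
        for e in rows:
            fh.write(
                f"{e.genome_id}\t{e.corrected_count:.6f}\t"
                f"{e.relative_abundance:.10f}\n"
            )


def read_abundance_table(path: str | Path) -> dict[str, float]:
    """Read an abundance report; returns genome_id -> corrected read count."""
    counts: dict[str, float] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("genome_id\t"):
                continue
            fields = line.split("\t")
            counts[fields[0]] = float(fields[1])
    return counts


def write_truth_table(counts: dict[str, int], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("genome_id\ttrue_count\n")
        for gid, c in counts.items():
            fh.write(f"{gid}\t{c}\n")


def read_truth_table(path: str | Path) -> dict[str, float]:
    counts: dict[str, float] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("genome_id\t"):
                continue
            fields = line.split("\t")
            counts[fields[0]] = float(fields[1])
    return counts


# Similarity-matrix persistence.  Self-describing TSV: '#'-prefixed metadata
# (read_length, K0, alpha, threshold), then a header row of genome ids and one
# row per source genome.  Floats are written with repr precision so the
# read(write(M)) round trip is exact.

def write_similarity_matrix(matrix, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write(f"# read_length\t{matrix.read_length}\n")
        fh.write(f"# K0\t{matrix.K0}\n")
        fh.write(f"# alpha\t{matrix.alpha!r}\n")
        fh.write(f"# threshold\t{matrix.threshold!r}\n")
        fh.write("\t" + "\t".join(matrix.genome_ids) + "\n")
        for gid, row in zip(matrix.genome_ids, matrix.W):
            fh.write(gid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_similarity_matrix(path: str | Path):
    from .similarity import SimilarityMatrix

    path = Path(path)
    meta: dict[str, str] = {}
    header: list[str] | None = None
    row_ids: list[str] = []
    rows: list[list[float]] = []
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].strip().split("\t")
                if len(parts) == 2:
                    meta[parts[0]] = parts[1]
                continue
            fields = line.split("\t")
            if header is None:
                if fields[0] != "":
                    raise MatrixFormatError(
                        f"{path}: header row must start with an empty field"
                    )
                header = fields[1:]
                continue
            row_ids.append(fields[0])
            try:
                rows.append([float(v) for v in fields[1:]])
            except ValueError as exc:
                raise MatrixFormatError(f"{path}: non-numeric entry") from exc
    if header is None:
        raise MatrixFormatError(f"{path}: missing header row")
    n = len(header)
    if row_ids != header:
        raise MatrixFormatError(
            f"{path}: row ids do not match header ids"
        )
    if any(len(r) != n for r in rows) or len(rows) != n:
        raise MatrixFormatError(f"{path}: matrix body is not {n}x{n}")
    W = np.array(rows, dtype=np.float64)
    try:
        read_length = int(meta["read_length"])
        K0 = int(meta["K0"])
        alpha = float(meta["alpha"])
        threshold = float(meta["threshold"])
    except KeyError as exc:
        raise MatrixFormatError(f"{path}: missing metadata line {exc}") from exc
    return SimilarityMatrix(
        genome_ids=header,
        W=W,
        read_length=read_length,
        K0=K0,
        alpha=alpha,
        threshold=threshold,
    )
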