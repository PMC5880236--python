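"""Readers and writers for every external representation the pipeline touches.

All coordinates are 0-based half-open internally (BED-native); conversion to
1-based fully-closed happens only when rendering human-readable reports.
Every other module receives the in-memory types defined here, never raw paths.

Formats covered: BED3/BED6 (+ documented extra columns for repeats), FASTA,
newick, MEME minimal motif format, and a 9-column synteny block table
(chromA, startA, endA, chromB, startB, endB, strand, aligned_cols,
gapped_cols).
"""

from __future__ import annotations

import dataclasses
import io as _stdio
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs
from skbio import TreeNode

__all__ = [
    "GenomicInterval",
    "PWM",
    "SyntenyBlock",
    "ParseError",
    "ValidationError",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "read_newick",
    "write_newick",
    "read_pwm_meme",
    "read_block_table",
    "write_block_table",
    "write_tsv",
]

VALID_BASES = frozenset("ACGTN")


class ParseError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """Parsed data violate a domain invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    ``strand`` is one of ``+``, ``-`` or ``.`` (unstranded). ``name`` and
    ``score`` mirror BED columns 4-5 and may be ``None``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"negative start: {self}")
        if self.start >= self.end:
            raise ValidationError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def to_1based(self) -> str:
        """Render as 1-based fully-closed, for reports only."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"


class PWM:
    """A position weight matrix over A, C, G, T.

    Stores the probability matrix (rows = positions, columns = A,C,G,T in
    that order), the background distribution, and the pseudocount used when
    the matrix was built from counts. ``log_odds`` is the scanning matrix:
    log2 of position probability over background.
    """

    ALPHABET = "ACGT"

    def __init__(
        self,
        matrix: np.ndarray,
        background: Sequence[float] | None = None,
        pseudocount: float = 0.5,
        name: str = "motif",
    ) -> None:
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[1] != 4 or matrix.shape[0] < 1:
            raise ValidationError("PWM matrix must be (length >= 1) x 4")
        if np.any(matrix < 0):
            raise ValidationError("PWM entries must be nonnegative")
        self.pseudocount = float(pseudocount)
        # Accept either counts or probabilities; normalise rows to sum to 1,
        # adding the pseudocount only when rows look like counts (sum > 1+eps
        # or contain zeros).
        rows = matrix.sum(axis=1)
        if np.any(rows <= 0):
            raise ValidationError("PWM row with zero total weight")
        looks_like_probs = np.allclose(rows, 1.0, atol=1e-6)
        if looks_like_probs and np.all(matrix > 0):
            probs = matrix / rows[:, None]
        else:
            if looks_like_probs:
                # probability matrix with structural zeros: smooth lightly so
                # log-odds stay finite
                counts = matrix * 100.0
            else:
                counts = matrix
            counts = counts + self.pseudocount
            probs = counts / counts.sum(axis=1)[:, None]
        self.matrix = probs
        if background is None:
            background = np.full(4, 0.25)
        background = np.asarray(background, dtype=float)
        if background.shape != (4,) or not np.isclose(background.sum(), 1.0):
            raise ValidationError("background must be 4 frequencies summing to 1")
        self.background = background
        self.name = name

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.matrix / self.background[None, :])

    def consensus(self) -> str:
        return "".join(self.ALPHABET[i] for i in self.matrix.argmax(axis=1))


@dataclass(frozen=True)
class SyntenyBlock:
    """A pairwise orthologous segment linking intervals in two genomes.

    ``aligned_cols`` counts match/mismatch columns of the underlying
    alignment; ``gapped_cols`` counts gap columns. ``orientation`` is the
    relative strand of genome B with respect to genome A.
    """

    interval_a: GenomicInterval
    interval_b: GenomicInterval
    orientation: str = "+"
    aligned_cols: int = 0
    gapped_cols: int = 0

    def __post_init__(self) -> None:
        if self.orientation not in ("+", "-"):
            raise ValidationError(f"bad orientation {self.orientation!r}")
        if self.aligned_cols < 0 or self.gapped_cols < 0:
            raise ValidationError("column counts must be nonnegative")

    @property
    def gap_fraction(self) -> float:
        total = self.aligned_cols + self.gapped_cols
        return self.gapped_cols / total if total else 0.0


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3/BED6 file into intervals, preserving input order.

    Track lines, browser lines, comments (#) and blank lines are skipped.
    Extra columns beyond the sixth are ignored. Raises :class:`ParseError`
    naming the offending line on malformed input and
    :class:`ValidationError` on empty/inverted intervals.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if (
                not line.strip()
                or line.startswith("#")
                or line.startswith(("track", "browser"))
            ):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            try:
                out.append(
                    GenomicInterval(chrom, start, end, strand=strand, name=name, score=score)
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand != ".":
                fields.append(iv.name if iv.name is not None else ".")
                fields.append(
                    format(iv.score, "g") if iv.score is not None else "."
                )
                fields.append(iv.strand)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# FASTA


def _validate_sequence(name: str, seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValidationError(
            f"record {name!r} contains residues outside A/C/G/T/N: {sorted(bad)}"
        )
    return seq


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA into an ordered list of (id, uppercased sequence).

    The alphabet is validated as {A,C,G,T,N}, case-insensitive; unknown
    residues raise :class:`ValidationError` naming the offending record.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, _validate_sequence(rec.id, str(rec.seq))))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# newick


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# MEME minimal motif format


def read_pwm_meme(path: str | Path, pseudocount: float = 0.5) -> PWM:
    """Read the first motif of a MEME minimal-format file as a :class:`PWM`.

    Background frequencies are taken from the file's background block when
    present, otherwise uniform.
    """
    with open(path) as fh:
        try:
            parsed = motifs.parse(fh, "minimal")
        except Exception as exc:  # Bio raises bare ValueError subclasses
            raise ParseError(f"{path}: not a MEME minimal motif file: {exc}") from exc
    if not parsed:
        raise ParseError(f"{path}: no motifs found")
    m = parsed[0]
    mat = np.column_stack([m.pwm[b] for b in "ACGT"])
    bg = getattr(parsed, "background", None)
    background = (
        np.array([bg[b] for b in "ACGT"]) if bg else np.full(4, 0.25)
    )
    background = background / background.sum()
    return PWM(mat, background=background, pseudocount=pseudocount, name=m.name or "motif")


# ---------------------------------------------------------------------------
# synteny block table

_BLOCK_COLUMNS = [
    "chromA",
    "startA",
    "endA",
    "chromB",
    "startB",
    "endB",
    "strand",
    "aligned_cols",
    "gapped_cols",
]


def read_block_table(path: str | Path) -> list[SyntenyBlock]:
    """Read the 9-column TSV block table into :class:`SyntenyBlock` objects."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _BLOCK_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing block-table columns {missing}")
    blocks = []
    for row in df.itertuples(index=False):
        blocks.append(
            SyntenyBlock(
                interval_a=GenomicInterval(str(row.chromA), int(row.startA), int(row.endA)),
                interval_b=GenomicInterval(str(row.chromB), int(row.startB), int(row.endB)),
                orientation=str(row.strand),
                aligned_cols=int(row.aligned_cols),
                gapped_cols=int(row.gapped_cols),
            )
        )
    return blocks


def write_block_table(blocks: Iterable[SyntenyBlock], path: str | Path) -> None:
    rows = [
        (
            b.interval_a.chrom,
            b.interval_a.start,
            b.interval_a.end,
            b.interval_b.chrom,
            b.interval_b.start,
            b.interval_b.end,
            b.orientation,
            b.aligned_cols,
            b.gapped_cols,
        )
        for b in blocks
    ]
    pd.DataFrame(rows, columns=_BLOCK_COLUMNS).to_csv(path, sep="\t", index=False)


def write_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
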