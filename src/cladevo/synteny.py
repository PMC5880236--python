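"""Inter-chromosomal synteny breaks and break-count trees.

Large (default >= 3 Mb flanking blocks) inter-chromosomal synteny breaks are
detected from pairwise block tables, pairwise counts assembled into a
distance matrix, and a neighbor-joining tree built from it: the NJ branch
lengths estimate the number of breaks that occurred on each branch, and
dividing by the time span between split events gives a breaks-per-MY rate
profile — the quantity that reveals punctuated bursts of karyotype change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from skbio import TreeNode

from .io import GenomicInterval, SyntenyBlock, ValidationError
from .trees import nj

__all__ = [
    "BreakEvent",
    "BreakMatrix",
    "detect_breaks",
    "count_pairwise_breaks",
    "build_break_matrix",
    "nj_tree",
    "branch_length_between",
    "break_rate_per_interval",
]

DEFAULT_MIN_BLOCK_SIZE = 3_000_000


@dataclass(frozen=True)
class BreakEvent:
    """A detected inter-chromosomal synteny break on genome A.

    ``position`` is the midpoint between the two flanking blocks on genome
    A; ``partner_before``/``partner_after`` are the genome-B chromosomes on
    either side.
    """

    chrom: str
    position: int
    partner_before: str
    partner_after: str
    left_block_size: int
    right_block_size: int


@dataclass
class BreakMatrix:
    """Symmetric pairwise synteny-break counts over a fixed taxon order."""

    taxa: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        n = len(self.taxa)
        if self.counts.shape != (n, n):
            raise ValidationError("count matrix shape does not match taxa")
        if not np.allclose(self.counts, self.counts.T):
            raise ValidationError("break matrix must be symmetric")
        if np.any(np.diag(self.counts) != 0):
            raise ValidationError("break matrix diagonal must be zero")
        if np.any(self.counts < 0):
            raise ValidationError("break counts must be nonnegative")


def _sorted_blocks_by_a(blocks: Iterable[SyntenyBlock]) -> dict[str, list[SyntenyBlock]]:
    per_chrom: dict[str, list[SyntenyBlock]] = {}
    for b in blocks:
        per_chrom.setdefault(b.interval_a.chrom, []).append(b)
    for chrom, bl in per_chrom.items():
        bl.sort(key=lambda b: b.interval_a.start)
        for prev, nxt in zip(bl, bl[1:]):
            if nxt.interval_a.start < prev.interval_a.end:
                raise ValidationError(
                    f"overlapping blocks on genome A at {chrom}:"
                    f"{nxt.interval_a.start} (blocks must be non-overlapping)"
                )
    return per_chrom


def detect_breaks(
    blocks: Sequence[SyntenyBlock],
    min_block_size: int = DEFAULT_MIN_BLOCK_SIZE,
) -> list[BreakEvent]:
    """Detect inter-chromosomal breaks scanning genome A.

    A break is emitted at the midpoint between consecutive genome-A blocks
    whose genome-B partner chromosomes differ, provided both flanking blocks
    are at least ``min_block_size`` long (the size filter guards against
    assembly fragmentation masquerading as rearrangement). Intra-chromosomal
    inversions and transpositions are ignored by construction. Overlapping
    genome-A blocks raise :class:`ValidationError`.
    """
    events: list[BreakEvent] = []
    for chrom, bl in sorted(_sorted_blocks_by_a(blocks).items()):
        for prev, nxt in zip(bl, bl[1:]):
            if prev.interval_b.chrom == nxt.interval_b.chrom:
                continue
            if len(prev.interval_a) < min_block_size or len(nxt.interval_a) < min_block_size:
                continue
            midpoint = (prev.interval_a.end + nxt.interval_a.start) // 2
            events.append(
                BreakEvent(
                    chrom=chrom,
                    position=midpoint,
                    partner_before=prev.interval_b.chrom,
                    partner_after=nxt.interval_b.chrom,
                    left_block_size=len(prev.interval_a),
                    right_block_size=len(nxt.interval_a),
                )
            )
    return events


def _swap_blocks(blocks: Iterable[SyntenyBlock]) -> list[SyntenyBlock]:
    return [
        SyntenyBlock(b.interval_b, b.interval_a, b.orientation, b.aligned_cols, b.gapped_cols)
        for b in blocks
    ]


def count_pairwise_breaks(
    blocks: Sequence[SyntenyBlock],
    min_block_size: int = DEFAULT_MIN_BLOCK_SIZE,
) -> int:
    """Symmetric break count for a species pair.

    Junction scans see translocations and fissions from the A side but
    fusions only from the B side, so the count is the maximum of the two
    scan directions: exact for translocations and for any mix of fissions
    or fusions; chromosome-count-changing events are thereby counted once
    each.
    """
    a_side = len(detect_breaks(blocks, min_block_size))
    b_side = len(detect_breaks(_swap_blocks(blocks), min_block_size))
    return max(a_side, b_side)


def build_break_matrix(
    pair_counts: Mapping[tuple[str, str], int | float],
    taxa: Sequence[str] | None = None,
) -> BreakMatrix:
    """Assemble pairwise break counts into a symmetric matrix.

    ``pair_counts`` maps unordered species pairs to counts; every one of
    the C(n, 2) pairs must be present exactly once (a pair supplied in both
    orders with differing counts is an error).
    """
    canon: dict[frozenset, float] = {}
    for (x, y), c in pair_counts.items():
        key = frozenset((x, y))
        if len(key) != 2:
            raise ValidationError(f"self-pair in counts: {x}, {y}")
        if key in canon and canon[key] != c:
            raise ValidationError(f"conflicting counts for pair {x}-{y}")
        canon[key] = float(c)
    if taxa is None:
        taxa = tuple(sorted({s for pair in canon for s in pair}))
    else:
        taxa = tuple(taxa)
    n = len(taxa)
    expected = {frozenset((taxa[i], taxa[j])) for i in range(n) for j in range(i + 1, n)}
    missing = expected - set(canon)
    if missing:
        raise ValidationError(f"missing pair counts: {sorted(tuple(m) for m in missing)}")
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = canon[frozenset((taxa[i], taxa[j]))]
    return BreakMatrix(taxa=taxa, counts=mat)


def nj_tree(matrix: BreakMatrix) -> TreeNode:
    """Neighbor-joining tree whose branch lengths are break-count estimates.

    Standard Saitou-Nei NJ (see :func:`cladevo.trees.nj`): negative branch
    lengths are clamped to 0 with the deficit moved to the sister branch;
    ties break deterministically by lowest taxon index. Branch lengths are
    reported raw, without integer rounding.
    """
    if len(matrix.taxa) < 3:
        raise ValidationError("need at least 3 taxa for a tree")
    return nj(matrix.counts, matrix.taxa)


def branch_length_between(tree: TreeNode, tips_inside: Sequence[str]) -> float:
    """Length of the branch subtending exactly the given tip set.

    Looks for an internal node (in the tree as rooted by NJ's final
    trifurcation) whose tip set equals ``tips_inside``; for break trees this
    reads off the estimated number of breaks on that branch.
    """
    want = frozenset(tips_inside)
    for node in tree.non_tips(include_self=False):
        names = frozenset(t.name for t in node.tips())
        if names == want:
            return float(node.length or 0.0)
    for tip in tree.tips():
        if frozenset([tip.name]) == want:
            return float(tip.length or 0.0)
    raise KeyError(f"no branch subtends exactly {sorted(want)}")


def break_rate_per_interval(
    branch_lengths: Mapping[str, float] | Sequence[float],
    split_times: Sequence[float],
) -> list[dict]:
    """Breaks-per-MY across sequential inter-node time intervals.

    ``split_times`` are the node times in MY, youngest first (e.g. 3, 6,
    12.5), defining intervals [0, t1], [t1, t2], ... ``branch_lengths``
    gives the break-count estimate for each interval in the same order
    (a mapping is read in insertion order). Rate = breaks / interval
    duration.
    """
    times = [0.0] + [float(t) for t in split_times]
    if any(b >= a for a, b in zip(times[1:], times[:-1])):
        raise ValidationError("split times must be strictly increasing")
    if isinstance(branch_lengths, Mapping):
        lengths = list(branch_lengths.values())
        labels = list(branch_lengths.keys())
    else:
        lengths = list(branch_lengths)
        labels = [f"interval_{i}" for i in range(len(lengths))]
    if len(lengths) != len(split_times):
        raise ValidationError("need one branch length per time interval")
    out = []
    for label, length, lo, hi in zip(labels, lengths, times[:-1], times[1:]):
        if length < 0:
            raise ValidationError("negative branch length")
        out.append(
            {
                "label": label,
                "interval_my": (lo, hi),
                "breaks": float(length),
                "rate_per_my": float(length) / (hi - lo),
            }
        )
    return out
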