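"""Repeat and retrocopy molecular clocks, expansion waves, enrichment.

Repeat copies are dated by t = d / r_class, where d is the mismatch
fraction of the copy against its family consensus and r_class the
per-class neutral rate calibrated from ancestral repeats (copies shared by
all four genomes of the clade, assumed to predate the radiation and hence
to be clade-depth old). Retrocopies are dated by t = 2 d / (r_parent +
r_retrocopy) with d the mismatch fraction between the copy and its
parental gene. Both formulas are linear in d, which is why divergence is
kept as a raw mismatch proportion throughout.

Retrocopy detection reimplements, at desk scale, the usual
spliced-transcript-to-genome strategy: exact 12-mer seeding, diagonal
clustering, then alignment refinement, keeping intronless candidates that
span exon junctions outside the parental locus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
from scipy import stats

from .io import GenomicInterval, ValidationError
from .synthetic import Transcript, _revcomp

__all__ = [
    "ClassRate",
    "Retrocopy",
    "ExpansionProfile",
    "merge_fragments",
    "ancestral_repeat_rate",
    "repeat_age",
    "expansion_profile",
    "species_specific_enrichment",
    "detect_retrocopies",
    "retrocopy_age",
]


@dataclass
class ClassRate:
    """Per-class neutral substitution rate (per lineage-MY equivalent)."""

    genomic_class: str
    clade: str
    rate: float
    n_ancestral: int
    stderr: float

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValidationError("class rate must be positive")


@dataclass
class Retrocopy:
    """A detected intronless copy of a spliced transcript."""

    interval: GenomicInterval
    parent: str
    strand: str
    divergence: float
    identity: float
    junctions_spanned: int


@dataclass
class ExpansionProfile:
    """Binned age (or divergence) distribution with its modal peak."""

    bin_edges: np.ndarray
    counts: np.ndarray
    smoothed: np.ndarray
    peak: float | None
    peaks: list[float]
    no_peak: bool


# ---------------------------------------------------------------------------
# fragment merging and rate calibration


def merge_fragments(repeats: pd.DataFrame, max_gap: int = 200) -> pd.DataFrame:
    """Merge fragmented hits belonging to one repeat element.

    Hits with the same family on the same strand of the same chromosome
    separated by less than ``max_gap`` bp are merged into one element whose
    divergence is the length-weighted mean of the fragments. Simple repeats
    and microsatellites are assumed removed upstream.
    """
    if repeats.empty:
        return repeats.copy()
    rows = []
    for (chrom, family, strand), grp in repeats.groupby(
        ["chrom", "family", "strand"], sort=False
    ):
        grp = grp.sort_values("start")
        cur = None
        for r in grp.itertuples(index=False):
            rd = r._asdict()
            if cur is None or rd["start"] - cur["end"] >= max_gap:
                if cur is not None:
                    rows.append(cur)
                cur = dict(rd)
            else:
                w_old = cur["end"] - cur["start"]
                w_new = rd["end"] - rd["start"]
                cur["divergence"] = (
                    cur["divergence"] * w_old + rd["divergence"] * w_new
                ) / (w_old + w_new)
                cur["end"] = max(cur["end"], rd["end"])
        rows.append(cur)
    return pd.DataFrame(rows).reset_index(drop=True)


def ancestral_repeat_rate(
    shared_divergences: Sequence[float],
    clade_depth_my: float,
    genomic_class: str = "",
    clade: str = "",
    min_n: int = 20,
    n_bootstrap: int = 200,
    seed: int = 0,
) -> ClassRate:
    """Calibrate the class rate from ancestral (clade-shared) repeats.

    Ancestral repeats predate the radiation, so their mean divergence to
    consensus divided by the clade depth estimates the class rate:
    r = mean(d) / depth, with a bootstrap standard error over copies.
    Requires at least ``min_n`` shared copies.
    """
    d = np.asarray(shared_divergences, dtype=float)
    if len(d) < min_n:
        raise ValidationError(
            f"insufficient ancestral repeats: {len(d)} < {min_n}"
        )
    if clade_depth_my <= 0:
        raise ValidationError("clade depth must be positive")
    rate = float(d.mean() / clade_depth_my)
    rng = np.random.default_rng(seed)
    boots = [
        d[rng.integers(0, len(d), len(d))].mean() / clade_depth_my
        for _ in range(n_bootstrap)
    ]
    return ClassRate(genomic_class, clade, rate, len(d), float(np.std(boots, ddof=1)))


def repeat_age(divergence: float, rate: ClassRate | float) -> float:
    """Repeat age in MY: t = d / r_class."""
    r = rate.rate if isinstance(rate, ClassRate) else float(rate)
    if r <= 0:
        raise ValidationError("rate must be positive")
    if not 0 <= divergence <= 1:
        raise ValidationError("divergence must be in [0, 1]")
    return divergence / r


def retrocopy_age(divergence: float, rate_parent: float, rate_retrocopy: float) -> float:
    """Retrocopy age in MY: t = 2 d / (r_parent + r_retrocopy)."""
    if rate_parent + rate_retrocopy <= 0:
        raise ValidationError("rates must sum to a positive value")
    if not 0 <= divergence <= 1:
        raise ValidationError("divergence must be in [0, 1]")
    return 2.0 * divergence / (rate_parent + rate_retrocopy)


# ---------------------------------------------------------------------------
# expansion waves


def expansion_profile(
    values: Sequence[float],
    bin_width: float,
    flatness_factor: float = 1.5,
) -> ExpansionProfile:
    """Histogram of ages (or divergences) with smoothed modal peaks.

    Counts are smoothed with a 3-bin moving average; the primary peak is
    the midpoint of the modal smoothed bin (ties resolve to the younger
    bin). If the modal raw bin is below ``flatness_factor`` times the
    median raw bin the distribution is flagged flat (``no_peak``).
    Secondary expansion waves appear as additional local maxima of the
    smoothed profile that also pass the flatness criterion.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("no values to profile")
    if bin_width <= 0:
        raise ValidationError("bin width must be positive")
    hi = max(v.max(), bin_width)
    edges = np.arange(0.0, hi + 2 * bin_width, bin_width)
    counts, _ = np.histogram(v, bins=edges)
    smoothed = np.convolve(counts, np.ones(3) / 3, mode="same")
    mids = (edges[:-1] + edges[1:]) / 2
    median_bin = float(np.median(counts))
    threshold = flatness_factor * max(median_bin, 1e-12)
    modal = int(np.argmax(smoothed))
    no_peak = counts.max() < threshold
    peaks = []
    for i in range(len(smoothed)):
        left = smoothed[i - 1] if i > 0 else -np.inf
        right = smoothed[i + 1] if i < len(smoothed) - 1 else -np.inf
        if smoothed[i] > left and smoothed[i] >= right and counts[i] >= threshold:
            peaks.append(float(mids[i]))
    return ExpansionProfile(
        bin_edges=edges,
        counts=counts,
        smoothed=smoothed,
        peak=None if no_peak else float(mids[modal]),
        peaks=peaks,
        no_peak=bool(no_peak),
    )


# ---------------------------------------------------------------------------
# species-specific enrichment


def species_specific_enrichment(
    specific_focal: int,
    shared_focal: int,
    specific_other: int,
    shared_other: int,
) -> dict:
    """Fisher exact test for excess species-specific copies in one class.

    The 2x2 table crosses focal class vs other classes with
    species-specific vs shared status; the two-sided p-value sums all
    hypergeometric tables (fixed margins) with probability not exceeding
    the observed table's. Also reports the excess fraction: the difference
    in species-specific proportion between the focal class and the rest.
    """
    table = np.array([[specific_focal, shared_focal], [specific_other, shared_other]])
    if np.any(table < 0):
        raise ValidationError("counts must be nonnegative")
    res = stats.fisher_exact(table, alternative="two-sided")
    frac_focal = specific_focal / max(specific_focal + shared_focal, 1)
    frac_other = specific_other / max(specific_other + shared_other, 1)
    return {
        "odds_ratio": float(res.statistic),
        "p_value": float(res.pvalue),
        "excess_fraction": float(frac_focal - frac_other),
        "table": table,
    }


# ---------------------------------------------------------------------------
# retrocopy detection

SEED_K = 12


def _seed_index(genome: Mapping[str, str], k: int) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = {}
    for chrom, seq in genome.items():
        su = seq.upper()
        for i in range(len(su) - k + 1):
            index.setdefault(su[i : i + k], []).append((chrom, i))
    return index


def _candidate_windows(
    query: str, index, k: int, min_seeds: int, pad: int = 100
) -> list[tuple[str, int, int]]:
    """Cluster seed hits by diagonal into candidate genomic windows."""
    hits: dict[str, list[tuple[int, int]]] = {}
    qu = query.upper()
    for q in range(0, len(qu) - k + 1):
        for chrom, g in index.get(qu[q : q + k], ()):
            hits.setdefault(chrom, []).append((g - q, g))
    windows = []
    for chrom, hh in hits.items():
        hh.sort()
        cluster: list[tuple[int, int]] = []
        prev_diag = None
        for diag, g in hh + [(np.inf, 0)]:
            if prev_diag is not None and diag - prev_diag > 60:
                if len(cluster) >= min_seeds:
                    gs = [g2 for _, g2 in cluster]
                    windows.append(
                        (chrom, max(0, min(gs) - len(qu) - pad), max(gs) + len(qu) + pad)
                    )
                cluster = []
            cluster.append((diag, g))
            prev_diag = diag
    # merge overlapping windows on the same chromosome
    merged: list[tuple[str, int, int]] = []
    for w in sorted(windows):
        if merged and merged[-1][0] == w[0] and w[1] <= merged[-1][2]:
            merged[-1] = (w[0], merged[-1][1], max(merged[-1][2], w[2]))
        else:
            merged.append(w)
    return merged


def _alignment_stats(query: str, target: str) -> tuple[dict, int, int, list[int]] | None:
    """Infix-align query into target; return edlib result + match counts.

    Returns (result, matches, mismatches, query_column_map) where
    query_column_map[i] is the alignment column of query position i, or
    None when no alignment is found.
    """
    res = edlib.align(query, target, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    loc = res["locations"][0]
    nice = edlib.getNiceAlignment(res, query, target[loc[0] : loc[1] + 1])
    qa, match_line = nice["query_aligned"], nice["matched_aligned"]
    matches = match_line.count("|")
    mismatches = match_line.count(".")
    # alignment column of each query position (whole query aligns in HW mode)
    qmap = [col for col, ch in enumerate(qa) if ch != "-"]
    return res, matches, mismatches, qmap, len(qa)


def detect_retrocopies(
    transcripts: Sequence[Transcript],
    genome: Mapping[str, str],
    min_identity: float = 0.75,
    min_exons_spanned: int = 2,
    min_seeds: int = 5,
    max_junction_gap: int = 30,
) -> list[Retrocopy]:
    """Find intronless genomic copies of spliced transcripts.

    A candidate locus is a region outside the parental locus where the
    mature (intronless) transcript aligns end-to-end with identity at
    least ``min_identity`` (matches over alignment columns) and where at
    least ``min_exons_spanned`` exons are crossed without an intron-sized
    gap (no deletion run of ``max_junction_gap`` or more bp near a
    junction). Single-exon transcripts carry no junction evidence and are
    excluded; transcripts shorter than the seed length are skipped with a
    warning. Divergence ``d`` is the mismatch fraction over matched
    columns (indels excluded).
    """
    import logging

    log = logging.getLogger(__name__)
    index = _seed_index(genome, SEED_K)
    found: list[Retrocopy] = []
    for tr in transcripts:
        if len(tr.exons) < 2:
            continue
        mature = tr.mature_sequence(genome)
        if len(mature) < SEED_K:
            log.warning("transcript %s shorter than seed length, skipped", tr.name)
            continue
        junctions = np.cumsum([e - s for s, e in tr.exons])[:-1]
        parent_lo, parent_hi = tr.span
        for strand, query in (("+", mature), ("-", _revcomp(mature))):
            qjunc = (
                junctions if strand == "+" else len(mature) - junctions[::-1]
            )
            for chrom, wlo, whi in _candidate_windows(query, index, SEED_K, min_seeds):
                if chrom == tr.chrom and wlo < parent_hi + 1000 and whi > parent_lo - 1000:
                    continue  # self-overlap with the parental locus
                target = genome[chrom][wlo:whi]
                # a window may hold several tandem copies: mask each found
                # locus and realign until nothing passes the identity bar
                for _ in range(10):
                    stats_ = _alignment_stats(query, target)
                    if stats_ is None:
                        break
                    res, matches, mismatches, qmap, n_cols = stats_
                    aligned_cols = matches + mismatches
                    if aligned_cols == 0 or n_cols == 0:
                        break
                    identity = matches / n_cols
                    if identity < min_identity:
                        break
                    loc = res["locations"][0]
                    target = (
                        target[: loc[0]] + "N" * (loc[1] + 1 - loc[0]) + target[loc[1] + 1 :]
                    )
                    spanned = 1
                    for j in qjunc:
                        if j <= 0 or j >= len(query):
                            continue
                        gap_run = qmap[j] - qmap[j - 1] - 1
                        if gap_run < max_junction_gap:
                            spanned += 1
                    if spanned < min_exons_spanned:
                        continue
                    found.append(
                        Retrocopy(
                            interval=GenomicInterval(chrom, wlo + loc[0], wlo + loc[1] + 1),
                            parent=tr.name,
                            strand=strand,
                            divergence=mismatches / aligned_cols,
                            identity=identity,
                            junctions_spanned=spanned - 1,
                        )
                    )
    # deduplicate overlapping detections (same locus hit via both strands or
    # overlapping windows): keep the best identity
    found.sort(key=lambda r: (r.interval.chrom, r.interval.start, -r.identity))
    deduped: list[Retrocopy] = []
    for r in found:
        if deduped and deduped[-1].interval.overlaps(r.interval):
            if r.identity > deduped[-1].identity:
                deduped[-1] = r
            continue
        deduped.append(r)
    return deduped
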