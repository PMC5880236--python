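"""The SINE-driven CTCF binding-site expansion pipeline.

Stages: replicate-consistent ChIP peaks -> PWM motif scan with exact null
p-values -> bound fraction per transposable-element class -> consensus
filtering of the focal SINE subfamily -> consensus-anchored alignment and
neighbor-joining tree of the copies -> largest bound clade -> Fitch
parsimony ancestral state at a motif position (position 18 of the CTCF
motif in the motivating system, where a T->C substitution creates a
higher-affinity site) -> trinucleotide representation test at motif
positions 17-19 -> spatial relation of new sites to pre-existing ones.

The scanner computes the exact null score distribution by dynamic-
programming convolution of per-position log-odds score distributions under
the background model (scores discretised to 1e-3), the same construction
FIMO uses; per-window scores are plain log-odds sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode

from .io import GenomicInterval, PWM, ValidationError
from .rates import holm_correction
from .trees import fitch_sets, nj

__all__ = [
    "MotifHit",
    "BoundCladeReport",
    "consensus_peaks",
    "scan_pwm",
    "best_hit_score",
    "bound_mask",
    "bound_fraction_by_class",
    "run_b2_pipeline",
    "filter_b2",
    "sequence_nj_tree",
    "largest_bound_clade",
    "fitch_ancestral",
    "trinucleotide_enrichment",
    "distance_to_nearest",
]

_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}
_COMP = str.maketrans("ACGTN", "TGCAN")
SCORE_PRECISION = 1e-3


@dataclass(frozen=True)
class MotifHit:
    """A PWM match: source sequence, 0-based offset, strand, score, p."""

    source: str
    start: int
    end: int
    strand: str
    score: float
    p_value: float
    matched_seq: str  # on the match strand, so position k is matched_seq[k-1]

    def base_at(self, position_1based: int) -> str:
        """Base at a 1-based motif position on the match strand."""
        return self.matched_seq[position_1based - 1]


@dataclass
class BoundCladeReport:
    """The clade maximising bound-tip count under a purity constraint."""

    clade_tips: tuple[str, ...]
    bound_in_clade: int
    clade_size: int
    n_bound_total: int
    purity: float
    species_composition: dict[str, int]

    @property
    def fraction_of_bound(self) -> float:
        return self.bound_in_clade / self.n_bound_total if self.n_bound_total else 0.0


# ---------------------------------------------------------------------------
# replicate-consistent peaks


def consensus_peaks(
    replicates: Sequence[Sequence[GenomicInterval]], min_support: int = 2
) -> list[GenomicInterval]:
    """Union peaks supported by at least ``min_support`` replicates.

    Overlapping (>= 1 bp) peaks across replicates form connected
    components; a component backed by enough distinct replicates becomes
    one consensus peak spanning the component's union. Idempotent and
    invariant to replicate order.
    """
    tagged = [
        (iv.chrom, iv.start, iv.end, rep)
        for rep, peaks in enumerate(replicates)
        for iv in peaks
    ]
    tagged.sort()
    out: list[GenomicInterval] = []
    i = 0
    while i < len(tagged):
        chrom, start, end, rep = tagged[i]
        support = {rep}
        j = i + 1
        while j < len(tagged) and tagged[j][0] == chrom and tagged[j][1] < end:
            end = max(end, tagged[j][2])
            support.add(tagged[j][3])
            j += 1
        if len(support) >= min_support:
            out.append(GenomicInterval(chrom, start, end))
        i = j
    return out


# ---------------------------------------------------------------------------
# PWM scanning with an exact null


def _null_survival(pwm: PWM) -> tuple[np.ndarray, int]:
    """Exact null distribution of the discretised window score.

    Convolves the per-position score distributions under the background
    model (each position contributes one of four log-odds values with the
    background probabilities). Returns (survival, offset): survival[k] is
    P(score_bins >= k + offset). Cached on the PWM instance.
    """
    cached = getattr(pwm, "_null_cache", None)
    if cached is not None:
        return cached
    W = np.round(pwm.log_odds / SCORE_PRECISION).astype(np.int64)
    bg = pwm.background
    lo = int(W.min(axis=1).sum())
    hi = int(W.max(axis=1).sum())
    pmf = np.zeros(hi - lo + 1)
    # running support [cur_lo, cur_lo + len(cur)) built position by position
    cur = np.array([1.0])
    cur_lo = 0
    for i in range(len(pwm)):
        row = W[i]
        new_lo = cur_lo + int(row.min())
        new = np.zeros(len(cur) + int(row.max() - row.min()))
        for b in range(4):
            off = int(row[b]) - int(row.min())
            new[off : off + len(cur)] += bg[b] * cur
        cur, cur_lo = new, new_lo
    pmf[cur_lo - lo : cur_lo - lo + len(cur)] = cur
    survival = np.cumsum(pmf[::-1])[::-1]
    pwm._null_cache = (survival, lo)
    return survival, lo


def _score_pvalue(score: float, survival: np.ndarray, offset: int) -> float:
    k = int(round(score / SCORE_PRECISION)) - offset
    if k < 0:
        return 1.0
    if k >= len(survival):
        return float(survival[-1])
    return float(min(max(survival[k], 0.0), 1.0))


def _window_score(W: np.ndarray, window: str) -> float | None:
    """Sequential log-odds sum over one window; None if N/unknown base."""
    s = 0.0
    for i, ch in enumerate(window):
        idx = _BASE_INDEX.get(ch)
        if idx is None:
            return None
        s += W[i, idx]
    return s


def scan_pwm(
    sequences: Sequence[tuple[str, str]] | Mapping[str, str],
    pwm: PWM,
    p_threshold: float = 1e-4,
) -> list[MotifHit]:
    """Scan sequences on both strands, reporting hits with p <= threshold.

    P-values come from the exact null score distribution (see
    :func:`_null_survival`) and are monotone decreasing in score.
    Overlapping same-strand hits within a sequence are resolved to the
    best-scoring one. Windows containing N are skipped. Sequences shorter
    than the PWM yield no hits (with a logged warning).
    """
    import logging

    log = logging.getLogger(__name__)
    if isinstance(sequences, Mapping):
        sequences = list(sequences.items())
    W = pwm.log_odds
    L = len(pwm)
    survival, offset = _null_survival(pwm)
    hits: list[MotifHit] = []
    for name, seq in sequences:
        seq = seq.upper()
        if len(seq) < L:
            log.warning("sequence %s shorter than the PWM (%d < %d)", name, len(seq), L)
            continue
        rc = seq.translate(_COMP)[::-1]
        raw: list[MotifHit] = []
        for strand, s in (("+", seq), ("-", rc)):
            for i in range(len(s) - L + 1):
                window = s[i : i + L]
                score = _window_score(W, window)
                if score is None:
                    continue
                p = _score_pvalue(score, survival, offset)
                if p <= p_threshold:
                    if strand == "+":
                        start = i
                    else:
                        start = len(seq) - (i + L)
                    raw.append(
                        MotifHit(name, start, start + L, strand, score, p, window)
                    )
        # best-scoring wins among overlapping same-strand hits
        raw.sort(key=lambda h: (-h.score, h.start))
        kept: list[MotifHit] = []
        for h in raw:
            if any(
                k.strand == h.strand and k.start < h.end and h.start < k.end
                for k in kept
            ):
                continue
            kept.append(h)
        kept.sort(key=lambda h: (h.start, h.strand))
        hits.extend(kept)
    return hits


def best_hit_score(seq: str, pwm: PWM) -> float:
    """Best window log-odds score over both strands (-inf if no window)."""
    W = pwm.log_odds
    L = len(pwm)
    seq = seq.upper()
    best = -np.inf
    if len(seq) < L:
        return best
    for s in (seq, seq.translate(_COMP)[::-1]):
        for i in range(len(s) - L + 1):
            score = _window_score(W, s[i : i + L])
            if score is not None and score > best:
                best = score
    return best


# ---------------------------------------------------------------------------
# occupancy by class


def bound_mask(repeats: pd.DataFrame, peaks: Sequence[GenomicInterval]) -> np.ndarray:
    """Boolean array: which repeat rows overlap (>= 1 bp) any peak."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        ms, me = [], []
        for s, e in ivs:
            if ms and s < me[-1]:
                me[-1] = max(me[-1], e)
            else:
                ms.append(s)
                me.append(e)
        merged[chrom] = (np.array(ms), np.array(me))
    bound = np.zeros(len(repeats), dtype=bool)
    for k, r in enumerate(repeats.itertuples(index=False)):
        iv = merged.get(r.chrom)
        if iv is None:
            continue
        starts, ends = iv
        j = np.searchsorted(starts, r.end, side="left")
        bound[k] = j > 0 and ends[j - 1] > r.start
    return bound


def bound_fraction_by_class(
    repeats: pd.DataFrame, peaks: Sequence[GenomicInterval]
) -> pd.DataFrame:
    """Fraction of repeat copies overlapping (>= 1 bp) a consensus peak.

    ``repeats`` needs chrom/start/end/class columns; an optional
    ``species`` column adds per-species grouping. Returns a table with
    n_total, n_bound and bound_fraction per group.
    """
    tab = repeats.copy()
    tab["bound"] = bound_mask(repeats, peaks)
    keys = ["class"] + (["species"] if "species" in tab.columns else [])
    out = (
        tab.groupby(keys, sort=True)["bound"]
        .agg(n_total="size", n_bound="sum")
        .reset_index()
    )
    out["bound_fraction"] = out["n_bound"] / out["n_total"]
    return out


# ---------------------------------------------------------------------------
# subfamily filtering and trees


def filter_b2(
    records: Sequence[tuple[str, str]],
    consensus: str,
    max_div: float = 0.10,
    min_len: int = 150,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Apply the three subfamily-consensus filters conjunctively.

    A copy is removed when (1) shorter than ``min_len`` bp; (2) it contains
    an unknown nucleotide (N); or (3) its combined substitution + insertion
    + deletion count against the consensus (global alignment edit distance)
    exceeds ``max_div`` of the consensus length. Returns the kept records
    and a per-sequence report (length, divergence, reason kept/removed).
    """
    kept = []
    rows = []
    cons = consensus.upper()
    for name, seq in records:
        s = seq.upper()
        reason = ""
        div = np.nan
        if len(s) < min_len:
            reason = "short"
        elif "N" in s:
            reason = "unknown_base"
        else:
            dist = edlib.align(s, cons, mode="NW")["editDistance"]
            div = dist / len(cons)
            if div > max_div:
                reason = "diverged"
        if not reason:
            kept.append((name, s))
        rows.append((name, len(s), div, reason or "kept"))
    report = pd.DataFrame(rows, columns=["name", "length", "divergence", "status"])
    return kept, report


def _project_on_consensus(seq: str, consensus: str) -> np.ndarray:
    """Copy bases laid onto consensus coordinates via global alignment.

    Positions where the copy is deleted hold b"-"; insertions relative to
    the consensus are dropped (consensus-anchored alignment).
    """
    res = edlib.align(seq, consensus, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, seq, consensus)
    out = np.full(len(consensus), b"-", dtype="S1")
    cpos = 0
    for q, t in zip(nice["query_aligned"], nice["target_aligned"]):
        if t != "-":
            if q != "-":
                out[cpos] = q.encode()
            cpos += 1
    return out


def sequence_nj_tree(
    records: Sequence[tuple[str, str]], consensus: str
) -> TreeNode:
    """Consensus-anchored NJ tree of repeat copies.

    Each copy is globally aligned to the consensus; the pairwise distance
    is the mismatch fraction over consensus positions where both copies
    are non-gap (0 when no such position exists). NJ as in the break-count
    trees, with deterministic tie-breaking.
    """
    if len(records) < 3:
        raise ValidationError("need at least 3 sequences for a tree")
    names = [n for n, _ in records]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate sequence names")
    mat = np.vstack([_project_on_consensus(s.upper(), consensus.upper()) for _, s in records])
    non_gap = mat != b"-"
    n = len(records)
    D = np.zeros((n, n))
    for i in range(n):
        both = non_gap[i] & non_gap[i + 1 :]
        diff = (mat[i] != mat[i + 1 :]) & both
        denom = both.sum(axis=1)
        with np.errstate(invalid="ignore"):
            d = np.where(denom > 0, diff.sum(axis=1) / np.maximum(denom, 1), 0.0)
        D[i, i + 1 :] = d
        D[i + 1 :, i] = d
    return nj(D, names)


def largest_bound_clade(
    tree: TreeNode, bound: Sequence[str] | set, purity: float = 0.5
) -> BoundCladeReport:
    """Clade maximising the contained bound-tip count at given purity.

    All nodes (tips included) are candidates; a clade qualifies when
    bound tips make up at least ``purity`` of its tips. Ties resolve to
    the higher-purity clade, then to the first in postorder. Species
    composition is read from tip-name prefixes (text before the first
    underscore).
    """
    bound_set = set(bound)
    n_bound_total = sum(1 for t in tree.tips() if t.name in bound_set)
    best = None
    for node in tree.postorder():
        tips = [t.name for t in ([node] if node.is_tip() else node.tips())]
        nb = sum(1 for t in tips if t in bound_set)
        if nb == 0 or len(tips) == 0:
            continue
        pur = nb / len(tips)
        if pur < purity:
            continue
        if best is None or nb > best[0] or (nb == best[0] and pur > best[1]):
            best = (nb, pur, tips)
    if best is None:
        raise ValidationError("no clade satisfies the purity constraint")
    nb, pur, tips = best
    comp: dict[str, int] = {}
    for t in tips:
        sp = t.split("_", 1)[0]
        comp[sp] = comp.get(sp, 0) + 1
    return BoundCladeReport(
        clade_tips=tuple(tips),
        bound_in_clade=nb,
        clade_size=len(tips),
        n_bound_total=n_bound_total,
        purity=pur,
        species_composition=comp,
    )


def fitch_ancestral(tree: TreeNode, tip_states: Mapping[str, str]) -> dict[TreeNode, frozenset]:
    """Fitch parsimony state sets for every node (ambiguity preserved)."""
    return fitch_sets(tree, tip_states)


# ---------------------------------------------------------------------------
# trinucleotide representation


def trinucleotide_enrichment(
    bound_hits: Sequence[MotifHit],
    unbound_hits: Sequence[MotifHit],
    positions: tuple[int, int, int] = (17, 18, 19),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Representation of each trinucleotide at motif positions 17-19.

    For each partition (bound / unbound by the factor) and each of the 64
    trinucleotides: the observed count is compared with the expectation
    under the partition's per-position base composition (independence
    model); reported are log2(obs/exp), a two-sided binomial p-value and
    Holm-adjusted significance across the 128 tests. ``enriched`` flags
    significant overrepresentation. To repeat the test excluding hits
    inside a focal repeat family, filter the hit lists before calling.
    """
    parts = {"bound": list(bound_hits), "unbound": list(unbound_hits)}
    for label, hits in parts.items():
        if not hits:
            raise ValidationError(f"no hits in partition {label!r}")
    i0 = positions[0] - 1
    rows = []
    for label, hits in parts.items():
        tris = [h.matched_seq[i0 : i0 + 3].upper() for h in hits]
        tris = [t for t in tris if len(t) == 3 and set(t) <= set("ACGT")]
        if not tris:
            raise ValidationError(f"no scorable trinucleotides in {label!r}")
        n = len(tris)
        freq = [np.zeros(4) for _ in range(3)]
        for t in tris:
            for k, ch in enumerate(t):
                freq[k][_BASE_INDEX[ch]] += 1
        freq = [f / n for f in freq]
        counts: dict[str, int] = {}
        for t in tris:
            counts[t] = counts.get(t, 0) + 1
        for b1 in "ACGT":
            for b2 in "ACGT":
                for b3 in "ACGT":
                    tri = b1 + b2 + b3
                    p_exp = (
                        freq[0][_BASE_INDEX[b1]]
                        * freq[1][_BASE_INDEX[b2]]
                        * freq[2][_BASE_INDEX[b3]]
                    )
                    obs = counts.get(tri, 0)
                    exp = n * p_exp
                    if p_exp in (0.0, 1.0):
                        pval = 1.0
                    else:
                        pval = float(stats.binomtest(obs, n, p_exp).pvalue)
                    log2r = float(np.log2(obs / exp)) if obs > 0 and exp > 0 else -np.inf
                    rows.append((label, tri, obs, exp, log2r, pval))
    out = pd.DataFrame(
        rows,
        columns=["partition", "trinucleotide", "observed", "expected", "log2_ratio", "p_value"],
    )
    out["p_holm"] = holm_correction(out["p_value"].to_numpy())
    out["significant"] = out["p_holm"] <= alpha
    out["enriched"] = out["significant"] & (out["log2_ratio"] > 0)
    return out


# ---------------------------------------------------------------------------
# spatial relation to existing sites


def distance_to_nearest(
    new_sites: Sequence[GenomicInterval],
    existing_sites: Sequence[GenomicInterval],
    radius: int = 10_000,
) -> dict:
    """Distance from each new site to the nearest existing site.

    Distances are midpoint-to-midpoint on the same chromosome; new sites
    on chromosomes without any existing site are infinite and excluded
    from the quantiles (their count is reported). The summary holds the
    median, quartiles and the fraction of finite-distance sites within
    ``radius`` bp.
    """
    pts_by_chrom: dict[str, list[int]] = {}
    for iv in existing_sites:
        pts_by_chrom.setdefault(iv.chrom, []).append(iv.midpoint)
    by_chrom = {c: np.sort(np.asarray(v)) for c, v in pts_by_chrom.items()}
    dists = []
    n_inf = 0
    for iv in new_sites:
        pts = by_chrom.get(iv.chrom)
        if pts is None or len(pts) == 0:
            n_inf += 1
            continue
        mid = iv.midpoint
        j = np.searchsorted(pts, mid)
        cands = []
        if j < len(pts):
            cands.append(abs(int(pts[j]) - mid))
        if j > 0:
            cands.append(abs(mid - int(pts[j - 1])))
        dists.append(min(cands))
    dists = np.asarray(dists, dtype=float)
    if dists.size == 0:
        return {
            "n": 0, "n_infinite": n_inf, "median": np.inf,
            "q1": np.inf, "q3": np.inf, "fraction_within_radius": 0.0,
            "radius": radius, "distances": dists,
        }
    return {
        "n": int(dists.size),
        "n_infinite": n_inf,
        "median": float(np.median(dists)),
        "q1": float(np.percentile(dists, 25)),
        "q3": float(np.percentile(dists, 75)),
        "fraction_within_radius": float(np.mean(dists <= radius)),
        "radius": radius,
        "distances": dists,
    }


# ---------------------------------------------------------------------------
# end-to-end pipeline on the planted subfamily-expansion scenario


def run_b2_pipeline(scn, purity: float = 0.5, p_threshold: float = 1e-4) -> dict:
    """Run the full expansion analysis on a simulated subfamily scenario.

    ``scn`` is a :class:`cladevo.synthetic.B2Scenario`. Stages: consensus
    peaks; bound status per repeat copy and genomic motif instance; PWM
    scan; consensus filtering; NJ tree; largest bound clade; Fitch
    ancestral state at the variant motif position (tree rooted at the most
    consensus-divergent copy as outgroup); trinucleotide representation in
    bound vs unbound motif hits. Returns a dict of the stage outputs.
    """
    peaks = consensus_peaks(scn.replicate_peaks, min_support=2)
    inst = scn.instances.reset_index(drop=True)
    bound = bound_mask(inst, peaks)
    bound_by_name = dict(zip(inst["name"], bound))

    kept, filter_report = filter_b2(scn.records, scn.consensus)
    kept_names = {n for n, _ in kept}
    bound_kept = {n for n in kept_names if bound_by_name.get(n, False)}

    # the family consensus approximates the ancestral sequence, so it
    # joins the tree as the outgroup that roots it and polarises the
    # variant position; clades are read off the rooted tree (NJ's final
    # trifurcation is arbitrary)
    tree = sequence_nj_tree(list(kept) + [("consensus", scn.consensus)], scn.consensus)
    outgroup = next(t for t in tree.tips() if t.name == "consensus")
    rooted = tree.root_at(outgroup, above=True)  # binary root on the outgroup edge
    clade = largest_bound_clade(rooted, bound_kept, purity=purity)

    vpos = scn.motif_offset + scn.variant_position - 1
    tip_states = {"consensus": scn.consensus[vpos]}
    for name, seq in kept:
        proj = _project_on_consensus(seq, scn.consensus)
        tip_states[name] = proj[vpos].decode()
    # tips with an undetermined state (alignment gap at the position)
    # carry no signal and are sheared before the parsimony pass
    determined = sorted(n for n, s in tip_states.items() if s in "ACGT")
    fitch_tree = rooted
    if len(determined) != len(tip_states):
        fitch_tree = rooted.shear(determined)
    sets = fitch_ancestral(fitch_tree, tip_states)
    root_set = sets[fitch_tree]
    clade_set = None
    want = frozenset(clade.clade_tips) & set(determined)
    for node in fitch_tree.postorder():
        names = frozenset(
            t.name for t in ([node] if node.is_tip() else node.tips())
        )
        if names == want:
            clade_set = sets[node]
            break

    # one motif per region: keep the best-scoring hit per source sequence
    hits = scan_pwm(scn.records + scn.background, scn.pwm, p_threshold=p_threshold)
    best: dict[str, MotifHit] = {}
    for h in hits:
        if h.source not in best or h.score > best[h.source].score:
            best[h.source] = h
    hits = list(best.values())
    bound_hits = [h for h in hits if bound_by_name.get(h.source, False)]
    unbound_hits = [h for h in hits if not bound_by_name.get(h.source, False)]
    positions = (
        scn.variant_position,
        scn.variant_position + 1,
        scn.variant_position + 2,
    )
    trinuc = trinucleotide_enrichment(bound_hits, unbound_hits, positions=positions)

    truth = scn.copy_truth.copy()
    truth["bound"] = truth["name"].map(bound_by_name).fillna(False)
    return {
        "peaks": peaks,
        "bound_by_name": bound_by_name,
        "filter_report": filter_report,
        "tree": tree,
        "rooted_tree": rooted,
        "clade": clade,
        "root_state_set": root_set,
        "clade_state_set": clade_set,
        "tip_states": tip_states,
        "hits": hits,
        "trinucleotide": trinuc,
        "copy_truth": truth,
    }
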