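"""Synthetic 4-taxon clade datasets with a complete truth ledger.

The generators emulate the downstream representations of a comparative
genomics study of a murid-like clade: pairwise synteny block tables with
planted inter-chromosomal rearrangements, per-class divergence and
segmental-turnover summaries, repeat annotation tables with insertion
waves, repeat-family FASTA with a planted subfamily-defining substitution,
ChIP-like replicate peak sets coupled to motif score, retrocopy-bearing
genomes, and 4-species codon alignments for clock calibration.

Every emitted feature is traceable to a truth entry, so each downstream
estimator can be tested by parameter recovery. All generators are
deterministic functions of (parameters, seed).

The fixed topology is (((A,B),C),D): A and B split ``t1`` MY ago, their
ancestor split from C ``t2`` MY ago, and the whole ingroup split from the
outgroup D ``t3`` MY ago (defaults 3.0, 6.0, 12.5 — a murid-like clade
anchored on a 12.5-MY outermost split).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import GenomicInterval, PWM, SyntenyBlock

__all__ = [
    "SPECIES",
    "BRANCHES",
    "BranchEvent",
    "RepeatWave",
    "SubfamilyMutation",
    "CladeScenario",
    "CladeTruth",
    "SimulatedClade",
    "simulate_clade",
    "simulate_repeat_family",
    "simulate_peaks",
    "simulate_retrocopies",
    "simulate_retrocopy_scenario",
    "simulate_codon_alignment",
    "simulate_breakpoint_neighbourhood",
    "Transcript",
]

SPECIES = ("A", "B", "C", "D")
#: branches of (((A,B),C),D); terminal branches named after their tip
BRANCHES = ("A", "B", "AB", "C", "ABC", "D")

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")

REPEAT_CLASSES = ("SINE", "LINE", "LTR", "DNA")


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


# ---------------------------------------------------------------------------
# scenario and truth


@dataclass
class RepeatWave:
    """A lineage-restricted burst of repeat insertions.

    ``lineage`` names a branch of the tree (``A`` .. ``ABC``, ``D``); copies
    appear in every species descending from that branch. ``onset_my`` is the
    centre of the burst, ``sd_my`` its spread, ``intensity`` the number of
    copies planted per carrying species.
    """

    repeat_class: str
    family: str
    lineage: str
    onset_my: float
    intensity: int
    sd_my: float = 0.5


@dataclass
class SubfamilyMutation:
    """A planted subfamily-defining substitution in a repeat consensus.

    ``position`` is 0-based within the consensus. Copies of the carrier
    ``lineage`` younger than ``onset_my`` belong to the derived subfamily
    and carry ``to_base`` at the position, plus any ``diagnostic``
    founder substitutions (position, base) — real repeat subfamilies are
    defined by several diagnostic positions inherited from the founder
    copy, not a single one.
    """

    position: int
    from_base: str
    to_base: str
    lineage: str
    onset_my: float
    diagnostic: tuple[tuple[int, str], ...] = ()


@dataclass
class CladeScenario:
    """Full parameterisation of a synthetic 4-taxon clade.

    Rates are per lineage per MY, so the expected pairwise divergence of a
    class between species separated ``t`` MY ago is ``2 * t * rate``.
    ``per_branch_break_counts`` plants inter-chromosomal rearrangements;
    the default mirrors a murid-like history: a burst of 20 events on the
    (A,B)-ancestor branch and 19 on the outgroup branch.
    """

    split_times: tuple[float, float, float] = (3.0, 6.0, 12.5)
    anchor_time: float = 12.5
    per_class_rates: dict[str, float] = field(
        default_factory=lambda: {
            "genome": 0.008,
            "exon": 0.002,
            "LINE": 0.009,
            "SINE": 0.009,
            "LTR": 0.009,
            "DNA": 0.0085,
            "CTCF_motif": 0.004,
        }
    )
    per_branch_break_counts: dict[str, int] = field(
        default_factory=lambda: {"AB": 20, "D": 19}
    )
    turnover_rates: dict[str, float] = field(
        default_factory=lambda: {
            "genome": 0.005,
            "exon": 0.002,
            "LINE": 0.0075,
            "SINE": 0.006,
            "LTR": 0.006,
            "DNA": 0.005,
        }
    )
    repeat_waves: list[RepeatWave] = field(
        default_factory=lambda: [
            RepeatWave("LINE", "L1-like", "ABC", 8.5, 250, 0.5),
            RepeatWave("SINE", "B2-like", "AB", 4.0, 120, 0.8),
            RepeatWave("LTR", "ERV-like", "AB", 4.5, 100, 0.8),
        ]
    )
    n_chromosomes: int = 20
    markers_per_chromosome: int = 50
    marker_size: int = 1_000_000
    min_block_size: int = 3_000_000
    class_column_counts: dict[str, int] = field(
        default_factory=lambda: {
            "genome": 400_000,
            "exon": 50_000,
            "LINE": 100_000,
            "SINE": 80_000,
            "LTR": 60_000,
            "DNA": 40_000,
            "CTCF_motif": 10_000,
        }
    )
    segments_per_class: int = 400
    ancestral_repeats_per_class: int = 60
    repeat_consensus_length: int = 300
    block_gap_rate: float = 0.02
    boundary_jitter_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        t1, t2, t3 = self.split_times
        if not (0 < t1 < t2 < t3):
            raise ValueError("split times must be strictly increasing outward")
        for name, rate in {**self.per_class_rates, **self.turnover_rates}.items():
            if rate < 0:
                raise ValueError(f"negative rate for {name}")
        for br in self.per_branch_break_counts:
            if br not in BRANCHES:
                raise ValueError(f"unknown branch {br!r}")

    # branch time spans, MY before present: (younger end, older end)
    def branch_spans(self) -> dict[str, tuple[float, float]]:
        t1, t2, t3 = self.split_times
        return {
            "A": (0.0, t1),
            "B": (0.0, t1),
            "AB": (t1, t2),
            "C": (0.0, t2),
            "ABC": (t2, t3),
            "D": (0.0, t3),
        }

    def pair_time(self, x: str, y: str) -> float:
        """Divergence time (MY) of a species pair."""
        t1, t2, t3 = self.split_times
        pair = frozenset((x, y))
        if pair == frozenset("AB"):
            return t1
        if "D" in pair:
            return t3
        return t2

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["repeat_waves"] = [dataclasses.asdict(w) for w in self.repeat_waves]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CladeScenario":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["split_times"] = tuple(data["split_times"])
        data["repeat_waves"] = [RepeatWave(**w) for w in data.get("repeat_waves", [])]
        return cls(**data)


@dataclass
class BranchEvent:
    """One planted inter-chromosomal rearrangement.

    The event cuts the root-ancestral adjacency between marker
    ``adjacency_left`` and ``adjacency_left + 1`` and reattaches the
    detached tail to ``recipient_chrom`` (donor-genome chromosome indices at
    the time of the event).
    """

    branch: str
    kind: str  # translocation | fission | fusion
    age_my: float
    adjacency_left: int
    donor_chrom: int
    recipient_chrom: int
    #: (recipient's last marker, tail's first marker) at event time — the
    #: novel adjacency this event created
    junction: tuple[int, int] = (-1, -1)


@dataclass
class CladeTruth:
    """The generator's ledger of planted parameters and events."""

    events: list[BranchEvent]
    per_class_rates: dict[str, float]
    turnover_rates: dict[str, float]
    waves: list[RepeatWave]
    split_times: tuple[float, float, float]
    pair_unshared_expected: dict[tuple, float] = field(default_factory=dict)

    def events_on_branch(self, branch: str) -> list[BranchEvent]:
        return [e for e in self.events if e.branch == branch]

    def pairwise_break_count(self, x: str, y: str) -> int:
        """Number of planted events on the tree path between two tips."""
        paths = {
            "A": ("A", "AB", "ABC"),
            "B": ("B", "AB", "ABC"),
            "C": ("C", "ABC"),
            "D": ("D",),
        }
        px, py = set(paths[x]), set(paths[y])
        branches = px.symmetric_difference(py)
        return sum(1 for e in self.events if e.branch in branches)


@dataclass
class SimulatedClade:
    """Outputs of :func:`simulate_clade` plus the truth ledger."""

    scenario: CladeScenario
    genomes: dict[str, list[list[int]]]
    chromosome_lengths: dict[str, dict[str, int]]
    block_tables: dict[tuple[str, str], list[SyntenyBlock]]
    divergence_tables: dict[tuple[str, str], pd.DataFrame]
    sharing: dict[tuple, tuple[list[GenomicInterval], list[SyntenyBlock]]]
    repeat_tables: dict[str, pd.DataFrame]
    truth: CladeTruth


# ---------------------------------------------------------------------------
# marker-genome evolution

_DESCENDANTS = {
    "A": ("A",),
    "B": ("B",),
    "C": ("C",),
    "D": ("D",),
    "AB": ("A", "B"),
    "ABC": ("A", "B", "C"),
}


def _chrom_of(genome: list[list[int]]) -> dict[int, int]:
    return {m: ci for ci, chrom in enumerate(genome) for m in chrom}


def _apply_events(
    genome: list[list[int]],
    branch: str,
    n_events: int,
    span: tuple[float, float],
    blocked_adjacencies: set[int],
    min_markers: int,
    noncarrier_states: Mapping[str, list[list[int]]],
    rng: np.random.Generator,
) -> tuple[list[list[int]], list[BranchEvent]]:
    """Apply ``n_events`` tail-move translocations to a copy of ``genome``.

    Each event cuts a root-ancestral adjacency and appends the detached
    tail to the end of another chromosome. Placement is disciplined so
    planted event counts stay exactly additive along tree paths — the
    property the break-count estimators are tested against:

    * the tail must be an ancestral-contiguous suffix (consecutive marker
      ids), so the cut and the attachment are the event's only junctions;
    * cuts keep a marker-id distance greater than ``min_markers`` from
      every previous cut (on any branch) and from ancestral chromosome
      ends, so every synteny block in every pairwise comparison exceeds
      the size filter, and junction-adjacent markers can never be moved
      by later events on any branch;
    * the attachment (recipient end ``r``, tail start ``s``) must place
      ``r`` and ``s`` on different chromosomes in every non-carrier
      lineage's current state (their futures cannot move either marker),
      so the junction reads as inter-chromosomal in every comparison.
    """
    genome = [list(chrom) for chrom in genome]
    events: list[BranchEvent] = []
    lo, hi = span
    nc_maps = {name: _chrom_of(g) for name, g in noncarrier_states.items()}
    for _ in range(n_events):
        candidates = []
        for ci, chrom in enumerate(genome):
            for pos in range(len(chrom) - 1):
                left, right = chrom[pos], chrom[pos + 1]
                if right != left + 1 or left in blocked_adjacencies:
                    continue
                tail = chrom[pos + 1 :]
                if any(b - a != 1 for a, b in zip(tail, tail[1:])):
                    continue  # tail must be an ancestral-contiguous suffix
                candidates.append((ci, pos, left))
        if not candidates:
            raise ValueError(
                f"branch {branch}: no remaining cuttable adjacency "
                f"(requested events exceed genome capacity)"
            )
        order = rng.permutation(len(candidates))
        chosen = None
        for k in order:
            ci, pos, left = candidates[int(k)]
            tail = genome[ci][pos + 1 :]
            s = tail[0]
            recipients = []
            for ri, chrom in enumerate(genome):
                if ri == ci or not chrom:
                    continue
                r = chrom[-1]
                if r + 1 == s:
                    continue  # would recreate an ancestral adjacency
                if any(cm[r] == cm[s] for cm in nc_maps.values()):
                    continue  # junction invisible in some other lineage
                recipients.append(ri)
            if recipients:
                ri = recipients[int(rng.integers(len(recipients)))]
                chosen = (ci, pos, left, tail, ri)
                break
        if chosen is None:
            raise ValueError(f"branch {branch}: no cut admits a valid recipient")
        ci, pos, left, tail, ri = chosen
        junction = (genome[ri][-1], tail[0])
        genome[ci] = genome[ci][: pos + 1]
        genome[ri] = genome[ri] + tail
        for m in range(left - min_markers, left + min_markers + 1):
            blocked_adjacencies.add(m)
        age = float(rng.uniform(lo, hi))
        events.append(
            BranchEvent(
                branch=branch,
                kind="translocation",
                age_my=age,
                adjacency_left=left,
                donor_chrom=ci,
                recipient_chrom=ri,
                junction=junction,
            )
        )
    return genome, events


def _events_visible(
    genomes: dict[str, list[list[int]]], events: list["BranchEvent"]
) -> bool:
    """Check that every planted junction reads as inter-chromosomal.

    For each event, the cut adjacency (m, m+1) must sit on different final
    chromosomes in every carrier genome, and the created junction (r, s)
    on different final chromosomes in every non-carrier genome; otherwise
    some pairwise scan would miss the event (e.g. two relocations
    juxtaposing material of one ancestral chromosome).
    """
    chrom_of = {
        sp: {m: ci for ci, chrom in enumerate(g) for m in chrom}
        for sp, g in genomes.items()
    }
    for e in events:
        carriers = set(_DESCENDANTS[e.branch])
        m, s = e.adjacency_left, e.adjacency_left + 1
        r = e.junction[0]
        for sp in genomes:
            cm = chrom_of[sp]
            if sp in carriers:
                if cm[m] == cm[s]:
                    return False
            else:
                if cm[r] == cm[s]:
                    return False
    return True


def _marker_positions(genome: list[list[int]]) -> dict[int, tuple[int, int]]:
    return {
        marker: (ci, pi)
        for ci, chrom in enumerate(genome)
        for pi, marker in enumerate(chrom)
    }


def blocks_between(
    genome_x: list[list[int]],
    genome_y: list[list[int]],
    marker_size: int,
    rng: np.random.Generator,
    gap_rate: float = 0.02,
    boundary_jitter_fraction: float = 0.0,
) -> list[SyntenyBlock]:
    """Derive the pairwise synteny block table from two marker genomes.

    Maximal runs of markers consecutive in both genomes become blocks.
    ``boundary_jitter_fraction`` perturbs that fraction of internal block
    boundaries by up to +-0.4 marker sizes (both genomes consistently),
    emulating imprecise alignment ends without changing block adjacency.
    """
    pos_y = _marker_positions(genome_y)
    blocks: list[SyntenyBlock] = []
    for ci, chrom in enumerate(genome_x):
        if not chrom:
            continue
        run_start = 0
        for i in range(1, len(chrom) + 1):
            adjacent = False
            if i < len(chrom):
                cy0, py0 = pos_y[chrom[i - 1]]
                cy1, py1 = pos_y[chrom[i]]
                adjacent = cy0 == cy1 and py1 == py0 + 1
            if not adjacent:
                first, last = run_start, i - 1
                cy, py_first = pos_y[chrom[first]]
                start_a = first * marker_size
                end_a = i * marker_size
                start_b = py_first * marker_size
                end_b = (py_first + (last - first) + 1) * marker_size
                total = end_a - start_a
                gapped = int(rng.binomial(total, gap_rate))
                blocks.append(
                    SyntenyBlock(
                        GenomicInterval(f"chr{ci + 1}", start_a, end_a),
                        GenomicInterval(f"chr{cy + 1}", start_b, end_b),
                        orientation="+",
                        aligned_cols=total - gapped,
                        gapped_cols=gapped,
                    )
                )
                run_start = i
    if boundary_jitter_fraction > 0:
        blocks = _jitter_boundaries(blocks, marker_size, boundary_jitter_fraction, rng)
    return blocks


def _jitter_boundaries(
    blocks: list[SyntenyBlock],
    marker_size: int,
    fraction: float,
    rng: np.random.Generator,
) -> list[SyntenyBlock]:
    """Shift a fraction of shared block boundaries by up to 0.4 markers.

    Boundaries between genome-A-adjacent blocks move together on the A
    side, and boundaries between genome-B-adjacent blocks move together on
    the B side, so the jittered tables stay non-overlapping in both
    coordinate systems.
    """
    deltas_a = {}
    deltas_b = {}
    for side, deltas in (("a", deltas_a), ("b", deltas_b)):
        by_chrom: dict[str, list[int]] = {}
        for idx, b in enumerate(blocks):
            iv = b.interval_a if side == "a" else b.interval_b
            by_chrom.setdefault(iv.chrom, []).append(idx)
        for chrom, idxs in by_chrom.items():
            key = lambda k: (blocks[k].interval_a if side == "a" else blocks[k].interval_b).start
            idxs = sorted(idxs, key=key)
            for prev, nxt in zip(idxs, idxs[1:]):
                if rng.random() < fraction:
                    deltas[(prev, "end")] = deltas[(nxt, "start")] = int(
                        rng.uniform(-0.4, 0.4) * marker_size
                    )
    out = []
    for idx, b in enumerate(blocks):
        ia = GenomicInterval(
            b.interval_a.chrom,
            b.interval_a.start + deltas_a.get((idx, "start"), 0),
            b.interval_a.end + deltas_a.get((idx, "end"), 0),
        )
        ib = GenomicInterval(
            b.interval_b.chrom,
            b.interval_b.start + deltas_b.get((idx, "start"), 0),
            b.interval_b.end + deltas_b.get((idx, "end"), 0),
        )
        out.append(SyntenyBlock(ia, ib, b.orientation, b.aligned_cols, b.gapped_cols))
    return out


# ---------------------------------------------------------------------------
# clade simulation


def simulate_clade(scenario: CladeScenario) -> SimulatedClade:
    """Simulate the full 4-taxon clade dataset with its truth ledger.

    See the module docstring for the data products. Determinism: the output
    is a pure function of the scenario (including its seed).
    """
    K, M, S = (
        scenario.n_chromosomes,
        scenario.markers_per_chromosome,
        scenario.marker_size,
    )
    min_markers = max(1, int(np.ceil(scenario.min_block_size / S)))
    root = [list(range(c * M, (c + 1) * M)) for c in range(K)]
    spans = scenario.branch_spans()

    # Event placement is rejection-sampled (deterministically, from the
    # scenario seed) until every planted junction is visible as an
    # inter-chromosomal partner change in every relevant genome pair — a
    # structural property checked directly on the marker genomes, so the
    # guarantee is independent of the downstream break detector.
    genomes = events = None
    for attempt in range(50):
        rng = _rng([scenario.seed, attempt])
        blocked: set[int] = set()
        for c in range(K):
            lo_id, hi_id = c * M, (c + 1) * M - 1
            blocked.update(range(lo_id, lo_id + min_markers))
            blocked.update(range(hi_id - min_markers, hi_id))
        events = []

        def evolve(parent_genome, branch, noncarriers):
            n = scenario.per_branch_break_counts.get(branch, 0)
            genome, evs = _apply_events(
                parent_genome, branch, n, spans[branch], blocked, min_markers,
                noncarriers, rng,
            )
            events.extend(evs)
            return genome

        try:
            g_abc = evolve(root, "ABC", {"D": root})
            g_ab = evolve(g_abc, "AB", {"C": g_abc, "D": root})
            g_a = evolve(g_ab, "A", {"B": g_ab, "C": g_abc, "D": root})
            g_b = evolve(g_ab, "B", {"A": g_a, "C": g_abc, "D": root})
            g_c = evolve(g_abc, "C", {"A": g_a, "B": g_b, "D": root})
            g_d = evolve(root, "D", {"A": g_a, "B": g_b, "C": g_c})
        except ValueError as exc:
            if "no remaining cuttable adjacency" in str(exc):
                raise  # structurally infeasible scenario, not placement luck
            continue
        genomes = {"A": g_a, "B": g_b, "C": g_c, "D": g_d}
        if _events_visible(genomes, events):
            break
    else:
        raise RuntimeError("could not place events with full pairwise visibility")

    chromosome_lengths = {
        sp: {f"chr{i + 1}": len(chrom) * S for i, chrom in enumerate(g) if chrom}
        for sp, g in genomes.items()
    }

    block_tables = {}
    for i, x in enumerate(SPECIES):
        for y in SPECIES[i + 1 :]:
            block_tables[(x, y)] = blocks_between(
                genomes[x],
                genomes[y],
                S,
                rng,
                gap_rate=scenario.block_gap_rate,
                boundary_jitter_fraction=scenario.boundary_jitter_fraction,
            )

    # per-class nucleotide divergence summaries for each pair
    divergence_tables = {}
    for i, x in enumerate(SPECIES):
        for y in SPECIES[i + 1 :]:
            t = scenario.pair_time(x, y)
            rows = []
            for cls, rate in scenario.per_class_rates.items():
                cols = scenario.class_column_counts.get(cls, 100_000)
                p = min(2.0 * t * rate, 0.75)
                sub = int(rng.binomial(cols, p))
                rows.append((cls, cols, sub, sub / cols))
            divergence_tables[(x, y)] = pd.DataFrame(
                rows, columns=["class", "aligned_cols", "substituted_cols", "divergence"]
            )

    # segmental sharing: per pair x class, segments on the reference species
    # plus the alignment blocks that cover the shared ones
    sharing = {}
    expected_unshared = {}
    seg_len = 1000
    for i, x in enumerate(SPECIES):
        for y in SPECIES[i + 1 :]:
            t = scenario.pair_time(x, y)
            for cls, tau in scenario.turnover_rates.items():
                p_unshared = min(2.0 * t * tau, 0.95)
                expected_unshared[(x, y, cls)] = p_unshared
                segments, blocks = [], []
                n = scenario.segments_per_class
                lost = rng.random(n) < p_unshared
                aligned_anyway = rng.random(n) < 0.5  # lost via gappy alignment
                for k in range(n):
                    start = k * (seg_len * 2)
                    seg = GenomicInterval("chr1", start, start + seg_len)
                    segments.append(seg)
                    if lost[k] and not aligned_anyway[k]:
                        continue  # no alignment at all
                    gap_frac = (
                        rng.uniform(0.55, 0.95) if lost[k] else rng.uniform(0.02, 0.45)
                    )
                    total = seg_len
                    gapped = int(round(gap_frac * total))
                    blocks.append(
                        SyntenyBlock(
                            seg,
                            GenomicInterval("chr1", start, start + seg_len),
                            "+",
                            aligned_cols=total - gapped,
                            gapped_cols=gapped,
                        )
                    )
                sharing[(x, y, cls)] = (segments, blocks)

    repeat_tables = {sp: _repeat_table(scenario, sp, rng) for sp in SPECIES}

    truth = CladeTruth(
        events=events,
        per_class_rates=dict(scenario.per_class_rates),
        turnover_rates=dict(scenario.turnover_rates),
        waves=list(scenario.repeat_waves),
        split_times=scenario.split_times,
        pair_unshared_expected=expected_unshared,
    )
    return SimulatedClade(
        scenario=scenario,
        genomes=genomes,
        chromosome_lengths=chromosome_lengths,
        block_tables=block_tables,
        divergence_tables=divergence_tables,
        sharing=sharing,
        repeat_tables=repeat_tables,
        truth=truth,
    )


def _repeat_table(
    scenario: CladeScenario, species: str, rng: np.random.Generator
) -> pd.DataFrame:
    """Per-species repeat annotation table (BED-like plus divergence).

    Contains ancestral repeats (age = clade depth, shared by all species)
    and wave-planted lineage-restricted copies. Divergence to consensus is
    Binomial(L, rate * age) / L, the raw-mismatch bookkeeping used
    throughout.
    """
    L = scenario.repeat_consensus_length
    depth = scenario.split_times[-1]
    genome_span = scenario.markers_per_chromosome * scenario.marker_size
    rows = []
    for cls in REPEAT_CLASSES:
        rate = scenario.per_class_rates.get(cls, 0.005)
        n_anc = scenario.ancestral_repeats_per_class
        d_anc = rng.binomial(L, min(rate * depth, 0.9), size=n_anc) / L
        starts = rng.integers(0, genome_span - L, size=n_anc)
        for k in range(n_anc):
            rows.append(
                (
                    f"chr{(k % scenario.n_chromosomes) + 1}",
                    int(starts[k]),
                    int(starts[k]) + L,
                    "+",
                    cls,
                    f"{cls}_anc",
                    d_anc[k],
                    depth,
                    True,
                )
            )
    for wave in scenario.repeat_waves:
        if species not in _DESCENDANTS[wave.lineage]:
            continue
        rate = scenario.per_class_rates.get(wave.repeat_class, 0.005)
        ages = np.clip(
            rng.normal(wave.onset_my, wave.sd_my, size=wave.intensity), 0.01, None
        )
        d = rng.binomial(L, np.minimum(rate * ages, 0.9)) / L
        starts = rng.integers(0, genome_span - L, size=wave.intensity)
        shared = len(_DESCENDANTS[wave.lineage]) == len(SPECIES)
        for k in range(wave.intensity):
            rows.append(
                (
                    f"chr{(k % scenario.n_chromosomes) + 1}",
                    int(starts[k]),
                    int(starts[k]) + L,
                    "+",
                    wave.repeat_class,
                    wave.family,
                    d[k],
                    float(ages[k]),
                    shared,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start",
            "end",
            "strand",
            "class",
            "family",
            "divergence",
            "true_age_my",
            "shared",
        ],
    )


# ---------------------------------------------------------------------------
# repeat family with planted subfamily


def simulate_repeat_family(
    consensus: str,
    n_copies: Mapping[str, int],
    copy_age_ranges: Mapping[str, tuple[float, float]],
    per_my_rate: float = 0.005,
    subfamily: SubfamilyMutation | None = None,
    indel_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Simulate repeat copies of one family across the 3-taxon ingroup.

    Each copy is the consensus mutated at Poisson(rate * age * L) uniformly
    chosen positions (uniform alternative bases). Copies of the subfamily
    carrier lineage younger than the subfamily onset additionally carry the
    planted substitution. ``indel_fraction`` of copies receive one short
    (1-3 bp) deletion.

    Returns ``(records, truth)`` where records are (name, sequence) pairs
    and truth is a DataFrame with columns name, lineage, age_my, subfamily,
    n_substitutions.
    """
    rng = _rng(seed)
    L = len(consensus)
    cons = np.frombuffer(consensus.upper().encode(), dtype="S1").astype("U1")
    if subfamily is not None:
        if not (0 <= subfamily.position < L):
            raise ValueError("subfamily mutation position outside consensus")
        if cons[subfamily.position] != subfamily.from_base:
            raise ValueError(
                f"consensus has {cons[subfamily.position]} at position "
                f"{subfamily.position}, expected {subfamily.from_base}"
            )
    records: list[tuple[str, str]] = []
    truth_rows = []
    for lineage in sorted(n_copies):
        lo, hi = copy_age_ranges[lineage]
        for k in range(n_copies[lineage]):
            age = float(rng.uniform(lo, hi))
            n_sub = int(rng.poisson(per_my_rate * age * L))
            n_sub = min(n_sub, L)
            seq = cons.copy()
            if n_sub:
                sites = rng.choice(L, size=n_sub, replace=False)
                shifts = rng.integers(1, 4, size=n_sub)
                base_idx = np.searchsorted(_BASES, seq[sites])
                seq[sites] = _BASES[(base_idx + shifts) % 4]
            is_sub = (
                subfamily is not None
                and lineage == subfamily.lineage
                and age <= subfamily.onset_my
            )
            if is_sub:
                seq[subfamily.position] = subfamily.to_base
                for dpos, dbase in subfamily.diagnostic:
                    seq[dpos] = dbase
            s = "".join(seq)
            if indel_fraction and rng.random() < indel_fraction:
                dlen = int(rng.integers(1, 4))
                dpos = int(rng.integers(0, len(s) - dlen))
                s = s[:dpos] + s[dpos + dlen :]
            name = f"{lineage}_{k}"
            records.append((name, s))
            truth_rows.append((name, lineage, age, bool(is_sub), n_sub))
    truth = pd.DataFrame(
        truth_rows, columns=["name", "lineage", "age_my", "subfamily", "n_substitutions"]
    )
    return records, truth


# ---------------------------------------------------------------------------
# occupancy peaks coupled to motif score


def simulate_peaks(
    instances: pd.DataFrame,
    pwm: PWM,
    midpoint: float,
    slope: float,
    n_replicates: int = 2,
    noise_per_mb: float = 0.0,
    genome_length: int = 1_000_000,
    peak_pad: int = 20,
    seed: int = 0,
) -> tuple[list[list[GenomicInterval]], pd.DataFrame]:
    """Turn motif-bearing repeat instances into replicate ChIP-like peaks.

    ``instances`` needs columns chrom, start, end and either ``score`` (a
    precomputed motif log-odds score) or ``seq`` (scored here as the best
    log-odds window on either strand). Each instance becomes a peak in each
    replicate independently with probability
    ``logistic(slope * (score - midpoint))``; rows with a finite value in
    an optional ``p_bound`` column use that probability instead (occupancy
    dominated by chromatin context rather than motif strength).
    Replicate-independent false peaks are added at ``noise_per_mb`` per Mb.

    Returns the replicate peak sets and a truth table with per-instance
    occupancy probabilities and per-replicate bound flags.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    rng = _rng(seed)
    inst = instances.reset_index(drop=True).copy()
    if "score" not in inst.columns:
        from .ctcf import best_hit_score

        inst["score"] = [best_hit_score(s, pwm) for s in inst["seq"]]
    with np.errstate(over="ignore"):
        p_bound = 1.0 / (1.0 + np.exp(-slope * (inst["score"].to_numpy() - midpoint)))
    if "p_bound" in inst.columns:
        override = inst["p_bound"].to_numpy(dtype=float)
        p_bound = np.where(np.isfinite(override), override, p_bound)
        inst = inst.drop(columns=["p_bound"])
    replicates: list[list[GenomicInterval]] = []
    bound_flags = np.zeros((len(inst), n_replicates), dtype=bool)
    for r in range(n_replicates):
        peaks: list[GenomicInterval] = []
        bound = rng.random(len(inst)) < p_bound
        bound_flags[:, r] = bound
        for k in np.flatnonzero(bound):
            row = inst.iloc[k]
            peaks.append(
                GenomicInterval(
                    str(row["chrom"]),
                    max(0, int(row["start"]) - peak_pad),
                    int(row["end"]) + peak_pad,
                )
            )
        n_false = rng.poisson(noise_per_mb * genome_length / 1e6)
        for _ in range(n_false):
            s = int(rng.integers(0, max(1, genome_length - 200)))
            peaks.append(GenomicInterval("chr1", s, s + 200))
        replicates.append(sorted(peaks, key=lambda iv: (iv.chrom, iv.start)))
    truth = inst.copy()
    truth["p_bound"] = p_bound
    for r in range(n_replicates):
        truth[f"bound_rep{r + 1}"] = bound_flags[:, r]
    truth["bound_consensus"] = bound_flags.sum(axis=1) >= 2
    return replicates, truth


# ---------------------------------------------------------------------------
# retrocopies


@dataclass
class Transcript:
    """A spliced transcript: name, chromosome and exon intervals (0-based)."""

    name: str
    chrom: str
    exons: list[tuple[int, int]]

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def mature_sequence(self, genome: Mapping[str, str]) -> str:
        seq = genome[self.chrom]
        return "".join(seq[s:e] for s, e in self.exons)


def simulate_retrocopies(
    transcripts: Sequence[Transcript],
    genome: Mapping[str, str],
    n: int,
    age_sampler,
    rate_parent: float,
    rate_retrocopy: float,
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Insert intronless, divergence-bearing copies of spliced transcripts.

    A copy of age ``t`` carries mismatches at expected fraction
    ``t * (rate_parent + rate_retrocopy) / 2`` relative to the current
    parental mature sequence, so inverting the retrocopy clock formula
    recovers ``t``. Insertion points are uniform over the genome, excluding
    parental loci. ``age_sampler(rng)`` returns one age in MY.

    Returns the modified genome and a truth table (name, parent, chrom,
    start, end, strand, age_my, planted_divergence).
    """
    rng = _rng(seed)
    genome = {c: s for c, s in genome.items()}
    parent_spans = {
        t.name: (t.chrom, t.span[0], t.span[1]) for t in transcripts
    }
    # each insert: [k, chrom, pos_original, copy_seq, parent, strand, age, div]
    inserts: list[list] = []
    for k in range(n):
        tr = transcripts[int(rng.integers(len(transcripts)))]
        mature = tr.mature_sequence(genome)
        age = float(age_sampler(rng))
        p = min(age * (rate_parent + rate_retrocopy) / 2.0, 0.75)
        arr = np.frombuffer(mature.encode(), dtype="S1").astype("U1")
        n_sub = int(rng.binomial(len(arr), p))
        if n_sub:
            sites = rng.choice(len(arr), size=n_sub, replace=False)
            shifts = rng.integers(1, 4, size=n_sub)
            idx = np.searchsorted(_BASES, arr[sites])
            arr[sites] = _BASES[(idx + shifts) % 4]
        copy_seq = "".join(arr)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            copy_seq = _revcomp(copy_seq)
        # uniform insertion point downstream of every parental locus on the
        # chromosome, so transcript exon coordinates stay valid afterwards
        chroms = list(genome)
        chrom = chroms[int(rng.integers(len(chroms)))]
        floor = max(
            (e + 1000 for c, s, e in parent_spans.values() if c == chrom),
            default=0,
        )
        if floor >= len(genome[chrom]) - 1:
            raise ValueError(f"no insertion room on {chrom}")
        pos = int(rng.integers(floor, len(genome[chrom])))
        inserts.append([k, chrom, pos, copy_seq, tr.name, strand, age, n_sub / len(arr)])
    # apply per chromosome right-to-left so earlier positions stay valid,
    # recording final coordinates via cumulative offsets left-to-right
    truth_rows = [None] * n
    for chrom in genome:
        chrom_ins = sorted(
            (ins for ins in inserts if ins[1] == chrom), key=lambda t: t[2]
        )
        seq = genome[chrom]
        for ins in reversed(chrom_ins):
            seq = seq[: ins[2]] + ins[3] + seq[ins[2] :]
        genome[chrom] = seq
        off = 0
        for k, _, pos, copy_seq, parent, strand, age, div in chrom_ins:
            truth_rows[k] = (
                f"retro_{k}", parent, chrom, pos + off, pos + off + len(copy_seq),
                strand, age, div,
            )
            off += len(copy_seq)
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "name",
            "parent",
            "chrom",
            "start",
            "end",
            "strand",
            "age_my",
            "planted_divergence",
        ],
    )
    return genome, truth


_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def simulate_retrocopy_scenario(
    n_genes: int = 6,
    n_retro: int = 12,
    genome_length: int = 120_000,
    age_spike_my: float = 9.0,
    age_sd_my: float = 0.5,
    rate_parent: float = 0.004,
    rate_retrocopy: float = 0.006,
    exons_per_gene: tuple[int, int] = (3, 5),
    exon_length: tuple[int, int] = (150, 400),
    intron_length: tuple[int, int] = (300, 800),
    seed: int = 0,
):
    """Self-contained retrocopy scenario: genome + genes + planted copies.

    Builds a random genome, plants ``n_genes`` spliced genes, then inserts
    ``n_retro`` retrocopies with ages from a Gaussian spike (default 9 MY,
    emulating a recent wave of retrotransposition-driven integrations).
    Returns (genome, transcripts, truth).
    """
    rng = _rng(seed)
    genome = {"chr1": random_sequence(genome_length, rng)}
    transcripts = []
    cursor = 2000
    for g in range(n_genes):
        n_ex = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
        exons = []
        pos = cursor
        for _ in range(n_ex):
            elen = int(rng.integers(*exon_length))
            exons.append((pos, pos + elen))
            pos += elen + int(rng.integers(*intron_length))
        transcripts.append(Transcript(f"gene{g}", "chr1", exons))
        cursor = pos + 2000
    if cursor > genome_length:
        raise ValueError("genome too short for requested genes")

    def age_sampler(r):
        return max(0.1, r.normal(age_spike_my, age_sd_my))

    genome, truth = simulate_retrocopies(
        transcripts,
        genome,
        n_retro,
        age_sampler,
        rate_parent,
        rate_retrocopy,
        seed=int(rng.integers(2**31 - 1)),
    )
    return genome, transcripts, truth


# ---------------------------------------------------------------------------
# codon alignments for clock calibration

# 4-fold degenerate codon families: first two bases whose third position is
# free (includes the 4-fold subsets of Leu, Arg, Ser)
_FOURFOLD_PREFIXES = ("GC", "GG", "CC", "AC", "GT", "CT", "CG", "TC")
_NONDEGENERATE_CODONS = ("ATG", "TGG", "AAA", "GAA", "CAA", "TTC", "GAC", "AAC")


def simulate_codon_alignment(
    split_times: tuple[float, float, float] = (3.0, 6.0, 12.5),
    rate_4d: float = 0.01,
    conserved_fraction: float = 0.5,
    n_codons: int = 6000,
    fourfold_fraction: float = 0.7,
    seed: int = 0,
) -> tuple[dict[str, str], np.ndarray, dict]:
    """Simulate a 4-species codon alignment with neutral 4-fold sites.

    Third positions of conserved fourfold-degenerate codons evolve at
    ``rate_4d`` per lineage per MY under an infinite-sites discipline: each
    branch's substitutions hit distinct sites, so pairwise raw mismatch
    fractions are exactly additive along tree paths (the assumption behind
    the linear distance clock being tested). Codons in the non-conserved
    fraction receive amino-acid-changing first-position substitutions in one
    lineage, so conservation masking must exclude them.

    Returns (alignment, conserved_4d_codon_mask, truth) where truth records
    the eligible-site count and expected pairwise divergences.
    """
    rng = _rng(seed)
    t1, t2, t3 = split_times
    branch_my = {"A": t1, "B": t1, "AB": t2 - t1, "C": t2, "ABC": t3 - t2, "D": t3}
    n_conserved = int(round(conserved_fraction * n_codons))
    conserved = np.zeros(n_codons, dtype=bool)
    conserved[rng.choice(n_codons, size=n_conserved, replace=False)] = True
    fourfold = np.zeros(n_codons, dtype=bool)

    root_codons = []
    for i in range(n_codons):
        if rng.random() < fourfold_fraction:
            prefix = _FOURFOLD_PREFIXES[int(rng.integers(len(_FOURFOLD_PREFIXES)))]
            codon = prefix + _BASES[int(rng.integers(4))]
            fourfold[i] = True
        else:
            codon = _NONDEGENERATE_CODONS[int(rng.integers(len(_NONDEGENERATE_CODONS)))]
        root_codons.append(codon)

    eligible = np.flatnonzero(conserved & fourfold)
    L_e = len(eligible)
    # disjoint site assignment across branches (infinite-sites discipline)
    perm = rng.permutation(L_e)
    counts = {b: int(rng.binomial(L_e, min(rate_4d * t, 1.0))) for b, t in branch_my.items()}
    if sum(counts.values()) > L_e:
        raise ValueError("too few eligible sites for requested rates; raise n_codons")
    branch_sites: dict[str, np.ndarray] = {}
    cursor = 0
    for b in BRANCHES:
        branch_sites[b] = eligible[perm[cursor : cursor + counts[b]]]
        cursor += counts[b]
    derived_base = {
        b: {
            int(site): _BASES[
                (np.searchsorted(_BASES, root_codons[site][2]) + int(rng.integers(1, 4))) % 4
            ]
            for site in sites
        }
        for b, sites in branch_sites.items()
    }

    path = {
        "A": ("ABC", "AB", "A"),
        "B": ("ABC", "AB", "B"),
        "C": ("ABC", "C"),
        "D": ("D",),
    }
    alignment = {}
    for sp in SPECIES:
        codons = list(root_codons)
        for b in path[sp]:
            for site, base in derived_base[b].items():
                codons[site] = codons[site][:2] + base
        # amino-acid churn in non-conserved codons: first-position change in A
        if sp == "A":
            for i in np.flatnonzero(~conserved):
                c = codons[i]
                alt = _BASES[(np.searchsorted(_BASES, c[0]) + 1) % 4]
                codons[i] = alt + c[1:]
        alignment[sp] = "".join(codons)

    expected = {}
    for i, x in enumerate(SPECIES):
        for y in SPECIES[i + 1 :]:
            branches = set(path[x]).symmetric_difference(path[y])
            expected[(x, y)] = sum(branch_my[b] for b in branches) * rate_4d
    truth = {
        "n_eligible_codons": L_e,
        "conserved_mask": conserved,
        "expected_pairwise_divergence": expected,
        "branch_substitutions": {b: len(s) for b, s in branch_sites.items()},
    }
    return alignment, conserved & fourfold, truth


# ---------------------------------------------------------------------------
# the B2-like CTCF expansion scenario


def ctcf_like_pwm(seed: int = 7, length: int = 20, variant_position: int = 18) -> PWM:
    """A CTCF-like PWM with a C-preferring low-information variant position.

    Most positions put probability 0.85 on a consensus base; the variant
    position (1-based, default 18) prefers C (0.75) over T (0.10), so a
    T->C substitution there raises the log-odds score — the situation in
    which a single substitution in an expanding SINE creates new
    high-affinity sites. Positions ``variant_position``+1 and +2 are fixed
    to C and A, giving the ancestral TCA / derived CCA trinucleotide.
    """
    rng = _rng(seed)
    cons = [int(rng.integers(4)) for _ in range(length)]
    v = variant_position - 1
    mat = np.full((length, 4), 0.05)
    for i, b in enumerate(cons):
        mat[i] = 0.05
        mat[i, b] = 0.85
    # the variant trinucleotide sits in a low-information part of the
    # motif: the variant site prefers C over T, and the two following
    # positions are unconstrained
    mat[v] = [0.075, 0.75, 0.075, 0.10]  # A C G T
    if v + 1 < length:
        mat[v + 1] = [0.25, 0.25, 0.25, 0.25]
    if v + 2 < length:
        mat[v + 2] = [0.25, 0.25, 0.25, 0.25]
    return PWM(mat, pseudocount=0.0, name="ctcf_like")


@dataclass
class B2Scenario:
    """All pieces of the planted SINE/CTCF expansion, plus its truth."""

    pwm: PWM
    consensus: str
    motif_offset: int  # 0-based offset of the motif inside the consensus
    variant_position: int  # 1-based within the motif
    records: list[tuple[str, str]]  # SINE copies, all lineages
    copy_truth: pd.DataFrame
    background: list[tuple[str, str]]  # genome-wide non-SINE motif instances
    instances: pd.DataFrame  # one row per copy/background with interval+score
    replicate_peaks: list[list[GenomicInterval]]
    peak_truth: pd.DataFrame


def simulate_b2_scenario(
    seed: int = 0,
    n_subfamily: int = 60,
    n_background_per_lineage: int = 15,
    n_genomic_motifs: int = 300,
    genomic_occupancy: float = 0.45,
    consensus_length: int = 190,
    motif_offset: int = 60,
    variant_position: int = 18,
    per_my_rate: float = 0.005,
    subfamily_onset_my: float = 2.0,
    subfamily_age_range: tuple[float, float] = (0.3, 1.5),
    background_age_range: tuple[float, float] = (3.0, 9.0),
    n_replicates: int = 3,
    occupancy_slope: float = 4.0,
    noise_per_mb: float = 0.0,
) -> B2Scenario:
    """Simulate the focal-lineage SINE expansion that spreads CTCF sites.

    The family consensus carries the ancestral motif (T at the variant
    position); a young subfamily restricted to lineage A carries the
    derived C. Genome-wide background motif instances are sampled with
    independent bases per position (the independence null of the
    trinucleotide test), so coherent TCA/CCA-carrying SINE copies are the
    only source of positional dependence. SINE copies gain occupancy by a
    logistic in motif score, with the midpoint halfway between the
    ancestral and derived exact-motif scores; genomic background
    instances are bound with constant probability ``genomic_occupancy``
    (their occupancy is dominated by chromatin context), which keeps the
    bound background trinucleotide-diverse.
    """
    rng = _rng([seed, 101])
    pwm = ctcf_like_pwm()
    L = len(pwm)
    v = variant_position - 1
    # ancestral motif: T at the variant site, the coherent trinucleotide
    # tail (CA) at the two unconstrained positions
    motif_ancestral = pwm.consensus()
    motif_ancestral = motif_ancestral[:v] + "TCA" + motif_ancestral[v + 3 :]
    motif_ancestral = motif_ancestral[:L]
    consensus = (
        random_sequence(motif_offset, rng)
        + motif_ancestral
        + random_sequence(consensus_length - motif_offset - L, rng)
    )
    # two diagnostic founder substitutions outside the motif anchor the
    # subfamily as a coherent sequence cluster
    diag = []
    for dpos in (10, consensus_length - 10):
        old = consensus[dpos]
        new = "ACGT"[("ACGT".index(old) + 2) % 4]
        diag.append((dpos, new))
    sub = SubfamilyMutation(
        position=motif_offset + v,
        from_base="T",
        to_base="C",
        lineage="A",
        onset_my=subfamily_onset_my,
        diagnostic=tuple(diag),
    )
    n_copies = {
        "A": n_subfamily + n_background_per_lineage,
        "B": n_background_per_lineage,
        "C": n_background_per_lineage,
    }
    # lineage A mixes young subfamily and old background ages; handled by
    # drawing subfamily ages first, then re-labelling via the onset rule
    records: list[tuple[str, str]] = []
    truths = []
    rec_a, tr_a = simulate_repeat_family(
        consensus,
        {"A": n_subfamily},
        {"A": subfamily_age_range},
        per_my_rate=per_my_rate,
        subfamily=sub,
        seed=int(rng.integers(2**31 - 1)),
    )
    rec_bg, tr_bg = simulate_repeat_family(
        consensus,
        {"A": n_background_per_lineage, "B": n_copies["B"], "C": n_copies["C"]},
        {k: background_age_range for k in ("A", "B", "C")},
        per_my_rate=per_my_rate,
        subfamily=None,
        seed=int(rng.integers(2**31 - 1)),
    )
    rec_a = [(f"A_sub{i}", s) for i, (_, s) in enumerate(rec_a)]
    tr_a["name"] = [n for n, _ in rec_a]
    rec_bg = [(f"{n}bg", s) for n, s in rec_bg]
    tr_bg["name"] = [n for n, _ in rec_bg]
    tr_bg["subfamily"] = False
    records = rec_a + rec_bg
    copy_truth = pd.concat([tr_a, tr_bg], ignore_index=True)

    # genome-wide motif instances: bases independent across positions,
    # drawn from the PWM's per-position composition
    background = []
    for k in range(n_genomic_motifs):
        bases = [
            "ACGT"[rng.choice(4, p=pwm.matrix[i])] for i in range(L)
        ]
        background.append((f"bg_{k}", "".join(bases)))

    rows = []
    for i, (name, s) in enumerate(records):
        rows.append((name, "chr1", i * 1000, i * 1000 + len(s), s, "SINE_B2", np.nan))
    for i, (name, s) in enumerate(background):
        rows.append((name, "chr2", i * 500, i * 500 + L, s, "other", genomic_occupancy))
    instances = pd.DataFrame(
        rows, columns=["name", "chrom", "start", "end", "seq", "class", "p_bound"]
    )

    from .ctcf import best_hit_score

    score_t = best_hit_score(motif_ancestral, pwm)
    score_c = best_hit_score(
        motif_ancestral[:v] + "C" + motif_ancestral[v + 1 :], pwm
    )
    midpoint = (score_t + score_c) / 2
    replicate_peaks, peak_truth = simulate_peaks(
        instances,
        pwm,
        midpoint=midpoint,
        slope=occupancy_slope,
        n_replicates=n_replicates,
        noise_per_mb=noise_per_mb,
        genome_length=max(len(records) * 1000, 1),
        seed=int(rng.integers(2**31 - 1)),
    )
    return B2Scenario(
        pwm=pwm,
        consensus=consensus,
        motif_offset=motif_offset,
        variant_position=variant_position,
        records=records,
        copy_truth=copy_truth,
        background=background,
        instances=instances,
        replicate_peaks=replicate_peaks,
        peak_truth=peak_truth,
    )


# ---------------------------------------------------------------------------
# breakpoint neighbourhoods (positive/null controls for enrichment)


def simulate_breakpoint_neighbourhood(
    n_breakpoints: int = 10,
    chrom_length: int = 100_000_000,
    density_per_mb: float = 5.0,
    core_enrichment: float = 1.0,
    core_halfwidth: int = 2_000_000,
    span: int = 40_000_000,
    seed: int = 0,
) -> tuple[list[GenomicInterval], list[GenomicInterval], dict]:
    """Breakpoints plus repeats with an optional planted core enrichment.

    Repeats are placed uniformly at ``density_per_mb``; within
    ``core_halfwidth`` of each breakpoint the density is multiplied by
    ``core_enrichment`` (1.0 = null). Breakpoints are placed so the full
    +-``span`` window fits inside the chromosome. Returns (breakpoints,
    repeats, truth).
    """
    rng = _rng(seed)
    if chrom_length <= 2 * span:
        raise ValueError("chromosome too short for the requested span")
    bp_pos = np.sort(rng.integers(span, chrom_length - span, size=n_breakpoints))
    breakpoints = [GenomicInterval("chr1", int(p), int(p) + 1) for p in bp_pos]
    n_base = rng.poisson(density_per_mb * chrom_length / 1e6)
    starts = list(rng.integers(0, chrom_length - 300, size=n_base))
    n_extra_per_bp = rng.poisson(
        max(core_enrichment - 1.0, 0.0) * density_per_mb * 2 * core_halfwidth / 1e6,
        size=n_breakpoints,
    )
    for p, n_extra in zip(bp_pos, n_extra_per_bp):
        starts.extend(rng.integers(p - core_halfwidth, p + core_halfwidth, size=n_extra))
    repeats = [
        GenomicInterval("chr1", int(s), int(s) + 300)
        for s in sorted(starts)
    ]
    truth = {
        "core_enrichment": core_enrichment,
        "density_per_mb": density_per_mb,
        "breakpoint_positions": [int(p) for p in bp_pos],
    }
    return breakpoints, repeats, truth
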