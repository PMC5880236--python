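"""The generators: determinism, conservation, and planted truth."""

import numpy as np
import pandas as pd
import pytest

from cladevo.io import write_block_table
from cladevo.synthetic import (
    CladeScenario,
    SubfamilyMutation,
    Transcript,
    random_sequence,
    simulate_b2_scenario,
    simulate_clade,
    simulate_codon_alignment,
    simulate_peaks,
    simulate_repeat_family,
    simulate_retrocopies,
    simulate_retrocopy_scenario,
)


class TestScenario:
    def test_split_times_must_increase(self):
        with pytest.raises(ValueError):
            CladeScenario(split_times=(6.0, 3.0, 12.5))

    def test_unknown_branch_rejected(self):
        with pytest.raises(ValueError):
            CladeScenario(per_branch_break_counts={"XY": 3})

    def test_yaml_round_trip(self, tmp_path):
        sc = CladeScenario(seed=3, per_branch_break_counts={"AB": 5})
        p = tmp_path / "scenario.yaml"
        sc.to_yaml(p)
        assert CladeScenario.from_yaml(p) == sc

    def test_pair_times(self):
        sc = CladeScenario()
        assert sc.pair_time("A", "B") == 3.0
        assert sc.pair_time("B", "C") == 6.0
        assert sc.pair_time("C", "D") == 12.5


class TestSimulateClade:
    def test_truth_lists_exactly_planted_events(self, default_clade):
        truth = default_clade.truth
        assert len(truth.events_on_branch("AB")) == 20
        assert len(truth.events_on_branch("D")) == 19
        assert len(truth.events) == 39

    def test_pairwise_path_counts(self, default_clade):
        t = default_clade.truth
        assert t.pairwise_break_count("A", "B") == 0
        assert t.pairwise_break_count("A", "C") == 20
        assert t.pairwise_break_count("A", "D") == 39
        assert t.pairwise_break_count("C", "D") == 19

    def test_determinism_same_seed(self):
        sc = CladeScenario(seed=5)
        s1, s2 = simulate_clade(sc), simulate_clade(sc)
        assert s1.genomes == s2.genomes
        for pair in s1.block_tables:
            assert s1.block_tables[pair] == s2.block_tables[pair]
        for pair in s1.divergence_tables:
            pd.testing.assert_frame_equal(
                s1.divergence_tables[pair], s2.divergence_tables[pair]
            )

    def test_determinism_byte_identical_written_tables(self, tmp_path):
        sc = CladeScenario(seed=6)
        paths = []
        for run in (1, 2):
            sim = simulate_clade(sc)
            p = tmp_path / f"blocks_{run}.tsv"
            write_block_table(sim.block_tables[("A", "D")], p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_zero_events_zero_rates_degenerate(self):
        sc = CladeScenario(
            seed=1,
            per_branch_break_counts={},
            per_class_rates={k: 0.0 for k in CladeScenario().per_class_rates},
        )
        sim = simulate_clade(sc)
        # every pair aligns chromosome-to-chromosome in one block each
        for pair, blocks in sim.block_tables.items():
            assert len(blocks) == sc.n_chromosomes
            for b in blocks:
                assert b.interval_a == b.interval_b
        for tab in sim.divergence_tables.values():
            assert (tab["substituted_cols"] == 0).all()

    def test_event_overflow_raises(self):
        with pytest.raises(ValueError, match="cuttable"):
            simulate_clade(
                CladeScenario(
                    seed=0,
                    n_chromosomes=2,
                    markers_per_chromosome=10,
                    per_branch_break_counts={"AB": 50},
                )
            )

    def test_repeat_tables_conserve_planted_counts(self, default_clade):
        sc = default_clade.scenario
        for sp, tab in default_clade.repeat_tables.items():
            n_anc = (tab["shared"] & (tab["family"].str.endswith("_anc"))).sum()
            assert n_anc == sc.ancestral_repeats_per_class * 4
            for wave in sc.repeat_waves:
                carriers = {"AB": ("A", "B"), "ABC": ("A", "B", "C")}.get(
                    wave.lineage, (wave.lineage,)
                )
                n = (tab["family"] == wave.family).sum()
                assert n == (wave.intensity if sp in carriers else 0)


class TestRepeatFamily:
    def test_expected_substitution_count(self):
        # rate 0.005/MY, age 2 MY, length 190 -> Poisson mean 1.9 per copy
        cons = random_sequence(190, np.random.default_rng(0))
        _, truth = simulate_repeat_family(
            cons, {"A": 400}, {"A": (2.0, 2.0)}, per_my_rate=0.005, seed=1
        )
        mean = truth["n_substitutions"].mean()
        se = np.sqrt(1.9 / 400)
        assert abs(mean - 1.9) < 4 * se

    def test_age_zero_copies_identical_to_consensus(self):
        cons = random_sequence(150, np.random.default_rng(1))
        recs, _ = simulate_repeat_family(cons, {"B": 5}, {"B": (0.0, 0.0)}, seed=2)
        assert all(seq == cons for _, seq in recs)

    def test_subfamily_restricted_to_carrier_lineage(self):
        """The derived base appears in non-carrier copies only at the
        independent-hit rate (about rate*age*1/3 per copy at one site)."""
        rng = np.random.default_rng(3)
        cons = random_sequence(190, rng)
        cons = cons[:50] + "T" + cons[51:]
        sub = SubfamilyMutation(50, "T", "C", "A", onset_my=5.0)
        recs, truth = simulate_repeat_family(
            cons,
            {"A": 50, "C": 400},
            {"A": (0.5, 2.0), "C": (2.0, 6.0)},
            per_my_rate=0.005,
            subfamily=sub,
            seed=4,
        )
        by_name = dict(recs)
        a_carry = [by_name[n][50] == "C" for n in truth[truth.lineage == "A"]["name"]]
        assert all(a_carry)
        c_names = truth[truth.lineage == "C"]["name"]
        c_carry = sum(by_name[n][50] == "C" for n in c_names)
        # independent hit probability per copy <= rate*age_max/3 = 0.01
        assert c_carry <= np.ceil(400 * 0.01 + 4 * np.sqrt(400 * 0.01))

    def test_mutation_position_validation(self):
        cons = "ACGT" * 10
        with pytest.raises(ValueError):
            simulate_repeat_family(
                cons, {"A": 1}, {"A": (1, 1)},
                subfamily=SubfamilyMutation(100, "A", "C", "A", 1.0),
            )


class TestPeaks:
    def _instances(self, n, score):
        return pd.DataFrame(
            {
                "name": [f"i{k}" for k in range(n)],
                "chrom": "chr1",
                "start": np.arange(n) * 1000,
                "end": np.arange(n) * 1000 + 200,
                "score": score,
            }
        )

    def test_steep_slope_binds_everything_above_midpoint(self):
        inst = self._instances(50, 10.0)
        reps, truth = simulate_peaks(inst, None, midpoint=0.0, slope=1e3,
                                     n_replicates=2, seed=0)
        assert all(len(r) == 50 for r in reps)
        assert truth["bound_consensus"].all()

    def test_zero_probability_and_zero_noise_empty(self):
        inst = self._instances(50, -10.0)
        reps, _ = simulate_peaks(inst, None, midpoint=0.0, slope=1e3,
                                 n_replicates=2, noise_per_mb=0.0, seed=0)
        assert all(len(r) == 0 for r in reps)

    def test_binomial_occupancy_at_half(self):
        # p = 0.5 for 1000 instances in one replicate: binomial 99% interval
        inst = self._instances(1000, 0.0)
        reps, truth = simulate_peaks(inst, None, midpoint=0.0, slope=5.0,
                                     n_replicates=2, seed=1)
        k = truth["bound_rep1"].sum()
        lo, hi = 500 - 2.58 * np.sqrt(250), 500 + 2.58 * np.sqrt(250)
        assert lo < k < hi

    def test_needs_two_replicates(self):
        with pytest.raises(ValueError):
            simulate_peaks(self._instances(2, 0.0), None, 0, 1, n_replicates=1)


class TestRetrocopies:
    def test_zero_copies_leaves_genome_unchanged(self):
        rng = np.random.default_rng(0)
        genome = {"chr1": random_sequence(5000, rng)}
        tr = Transcript("g", "chr1", [(100, 300), (500, 700)])
        out, truth = simulate_retrocopies(
            [tr], genome, 0, lambda r: 1.0, 0.004, 0.006, seed=1
        )
        assert out == genome and truth.empty

    def test_planted_divergence_matches_formula(self):
        # age t with rates r_p, r_r -> expected divergence t*(r_p+r_r)/2
        rng = np.random.default_rng(1)
        genome = {"chr1": random_sequence(20_000, rng)}
        tr = Transcript("g", "chr1", [(100, 600), (900, 1400)])
        _, truth = simulate_retrocopies(
            [tr], genome, 30, lambda r: 10.0, 0.004, 0.006, seed=2
        )
        expected = 10.0 * (0.004 + 0.006) / 2
        assert abs(truth["planted_divergence"].mean() - expected) < 0.005

    def test_truth_age_spike_mode(self):
        _, _, truth = simulate_retrocopy_scenario(n_retro=40, seed=3,
                                                  genome_length=200_000)
        counts, edges = np.histogram(truth["age_my"], bins=np.arange(0, 15, 1.0))
        assert 9.0 >= edges[np.argmax(counts)] >= 8.0

    def test_truth_coordinates_match_modified_genome(self):
        genome, transcripts, truth = simulate_retrocopy_scenario(seed=4)
        for row in truth.itertuples(index=False):
            placed = genome[row.chrom][row.start : row.end]
            assert len(placed) == row.end - row.start
            parent = next(t for t in transcripts if t.name == row.parent)
            assert len(placed) == len(parent.mature_sequence(genome))


class TestCodonAlignment:
    def test_conserved_fraction_one_all_codons_eligible(self):
        aln, mask, truth = simulate_codon_alignment(
            conserved_fraction=1.0, fourfold_fraction=1.0, n_codons=300, seed=0
        )
        assert mask.all()
        assert truth["n_eligible_codons"] == 300

    def test_expected_divergence_clock_arithmetic(self):
        # rate 0.01/MY, A-D split 12.5 MY -> expected 4d divergence 0.25
        _, _, truth = simulate_codon_alignment(rate_4d=0.01, seed=1)
        assert truth["expected_pairwise_divergence"][("A", "D")] == pytest.approx(0.25)
        assert truth["expected_pairwise_divergence"][("A", "B")] == pytest.approx(0.06)

    def test_deterministic(self):
        a1 = simulate_codon_alignment(seed=2)[0]
        a2 = simulate_codon_alignment(seed=2)[0]
        assert a1 == a2


class TestB2Scenario:
    def test_subfamily_confined_to_focal_lineage(self):
        scn = simulate_b2_scenario(seed=0)
        t = scn.copy_truth
        assert (t[t.subfamily].lineage == "A").all()
        assert t.subfamily.sum() == 60

    def test_derived_base_planted_at_variant_position(self):
        scn = simulate_b2_scenario(seed=1)
        vpos = scn.motif_offset + scn.variant_position - 1
        by_name = dict(scn.records)
        sub = scn.copy_truth[scn.copy_truth.subfamily]["name"]
        assert all(by_name[n][vpos] == "C" for n in sub)
        assert scn.consensus[vpos] == "T"
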