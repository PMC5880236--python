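"""Divergence, turnover, regression, ANCOVA and the distance clock."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cladevo.io import GenomicInterval, SyntenyBlock, ValidationError
from cladevo.rates import (
    ancova_rates,
    calibrated_split_times,
    clade_ratio,
    extract_4d_sites,
    holm_correction,
    pairwise_divergence,
    rate_regression,
    segment_sharing,
)
from cladevo.synthetic import CladeScenario, simulate_clade, simulate_codon_alignment


def seg_block(start, end, gapped_frac, chrom="chr1"):
    total = end - start
    gapped = int(round(gapped_frac * total))
    return SyntenyBlock(
        GenomicInterval(chrom, start, end), GenomicInterval(chrom, start, end),
        "+", aligned_cols=total - gapped, gapped_cols=gapped,
    )


class TestPairwiseDivergence:
    def test_simple_ratio(self):
        tab = pd.DataFrame(
            {"class": ["exon"], "aligned_cols": [1000], "substituted_cols": [60]}
        )
        assert pairwise_divergence(tab, "exon").divergence == pytest.approx(0.06)

    def test_empty_class_is_error(self):
        tab = pd.DataFrame({"class": ["exon"], "aligned_cols": [10],
                            "substituted_cols": [1]})
        with pytest.raises(ValidationError, match="no aligned columns"):
            pairwise_divergence(tab, "LINE")

    def test_recovery_of_planted_rate(self, default_clade):
        """Planted per-MY rate r gives pairwise divergence ~ 2*t*r within
        the binomial 99% interval."""
        sc = default_clade.scenario
        for pair in [("A", "B"), ("A", "C")]:
            t = sc.pair_time(*pair)
            for cls, r in sc.per_class_rates.items():
                est = pairwise_divergence(
                    default_clade.divergence_tables[pair], cls, pair
                )
                p = 2 * t * r
                sd = np.sqrt(p * (1 - p) / est.aligned_cols)
                assert abs(est.divergence - p) < 2.58 * sd + 1e-9


class TestSegmentSharing:
    def test_gap_rule(self):
        seg = GenomicInterval("chr1", 0, 1000)
        assert segment_sharing([seg_block(0, 1000, 0.6)], [seg]).shared_segments == 0
        assert segment_sharing([seg_block(0, 1000, 0.4)], [seg]).shared_segments == 1

    def test_no_overlap_is_unshared(self):
        seg = GenomicInterval("chr1", 0, 1000)
        assert segment_sharing([seg_block(5000, 6000, 0.0)], [seg]).shared_segments == 0

    def test_hand_enumerated_set(self):
        """Ten segments with hand-assigned gap fractions: shared count
        equals the hand count under the <50% rule."""
        gap_fracs = [0.0, 0.1, 0.2, 0.3, 0.45, 0.5, 0.55, 0.7, 0.9, None]
        segments, blocks = [], []
        for i, gf in enumerate(gap_fracs):
            seg = GenomicInterval("chr1", i * 2000, i * 2000 + 1000)
            segments.append(seg)
            if gf is not None:
                blocks.append(seg_block(i * 2000, i * 2000 + 1000, gf))
        out = segment_sharing(blocks, segments)
        assert out.shared_segments == 5  # 0.0 .. 0.45 pass, 0.5+ and missing fail
        assert out.unshared_fraction == pytest.approx(0.5)

    def test_monotone_in_threshold(self, default_clade):
        segments, blocks = default_clade.sharing[("A", "D", "LINE")]
        shared = [
            segment_sharing(blocks, segments, gap_threshold=g).shared_segments
            for g in (0.2, 0.4, 0.5, 0.6, 0.9)
        ]
        assert all(a <= b for a, b in zip(shared, shared[1:]))

    def test_turnover_recovery(self, default_clade):
        """Unshared fraction recovers the planted 2*t*tau probability."""
        sc = default_clade.scenario
        for (x, y, cls), (segments, blocks) in default_clade.sharing.items():
            expected = default_clade.truth.pair_unshared_expected[(x, y, cls)]
            est = segment_sharing(blocks, segments).unshared_fraction
            sd = np.sqrt(expected * (1 - expected) / len(segments))
            assert abs(est - expected) < 4 * sd + 0.02


class TestRateRegression:
    def test_exact_line(self):
        est = rate_regression([(3, 0.06), (6, 0.12), (12.5, 0.25)])
        assert est.slope == pytest.approx(0.02)
        assert est.stderr == pytest.approx(0.0)

    def test_single_point_flagged(self):
        est = rate_regression([(6, 0.12)])
        assert est.slope == pytest.approx(0.02)
        assert est.stderr is None and est.ci95 is None

    def test_ci_covers_true_slope(self, rng):
        """95% CI covers the generating slope in >= 93/100 replicates."""
        hits = 0
        for _ in range(100):
            t = np.array([3.0, 6.0, 12.5, 3.0, 6.0, 12.5])
            y = 0.02 * t + rng.normal(0, 0.004, size=6)
            est = rate_regression(list(zip(t, y)))
            lo, hi = est.ci95
            hits += lo <= 0.02 <= hi
        assert hits >= 93

    def test_free_intercept_flag(self):
        est = rate_regression([(1, 1.1), (2, 2.1), (3, 3.1)], through_origin=False)
        assert est.slope == pytest.approx(1.0)


class TestAncova:
    def _frame(self, slopes, noise, rng, times=(3, 6, 12.5)):
        rows = []
        for g, s in slopes.items():
            for t in times:
                rows.append((t, s * t + rng.normal(0, noise), g))
        return pd.DataFrame(rows, columns=["time", "response", "group"])

    def test_identical_groups(self, rng):
        df = self._frame({"a": 0.02, "b": 0.02}, 0.0, rng)
        out = ancova_rates(df)
        assert out["F"] == pytest.approx(0.0, abs=1e-18)
        assert out["p_value"] == pytest.approx(1.0)

    def test_separated_slopes_significant(self, rng):
        df = self._frame({"mur": 0.12, "hom": 0.02}, 0.002, rng)
        assert ancova_rates(df)["p_value"] < 1e-3

    def test_df_bookkeeping_unbalanced(self, rng):
        df = self._frame({"a": 0.02, "b": 0.05}, 0.01, rng)
        df = df.drop(df.index[-1])  # 3 vs 2 points
        out = ancova_rates(df)
        assert out["df"] == (1, 3)  # g-1 = 1, n-g = 5-2

    def test_null_p_uniform(self, rng):
        """Under equal slopes and Gaussian noise the F-test p-value is
        uniform (KS test over 500 simulations)."""
        ps = []
        for _ in range(500):
            df = self._frame({"a": 0.02, "b": 0.02}, 0.005, rng)
            ps.append(ancova_rates(df)["p_value"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_too_small_group_rejected(self, rng):
        df = pd.DataFrame({"time": [1, 2, 3], "response": [1, 2, 3],
                           "group": ["a", "a", "b"]})
        with pytest.raises(ValidationError):
            ancova_rates(df)


class TestCladeRatio:
    def test_exact_ratio(self):
        a = rate_regression([(1, 0.06), (2, 0.12)])
        b = rate_regression([(1, 0.01), (2, 0.02)])
        assert clade_ratio(a, b)["ratio"] == pytest.approx(6.0)

    def test_zero_denominator(self):
        a = rate_regression([(1, 0.06)])
        b = rate_regression([(1, 0.0)])
        with pytest.raises(ValidationError, match="undefined"):
            clade_ratio(a, b)

    def test_recovery_of_planted_sixfold_ratio(self):
        """Two clades simulated with 6x different rates: the ratio of the
        fitted genome-wide slopes lands within 10% of 6."""
        fast = simulate_clade(CladeScenario(seed=21))
        slow_rates = {k: v / 6 for k, v in CladeScenario().per_class_rates.items()}
        slow = simulate_clade(CladeScenario(seed=22, per_class_rates=slow_rates))
        ests = []
        for sim in (fast, slow):
            pts = []
            for pair in [("A", "B"), ("A", "C"), ("A", "D")]:
                t = sim.scenario.pair_time(*pair)
                d = pairwise_divergence(
                    sim.divergence_tables[pair], "genome", pair
                ).divergence
                pts.append((t, d))
            ests.append(rate_regression(pts, genomic_class="genome"))
        ratio = clade_ratio(ests[0], ests[1])["ratio"]
        assert abs(ratio - 6.0) < 0.6


class TestHolm:
    def test_adjusted_values_monotone_and_bounded(self, rng):
        p = rng.uniform(size=20)
        adj = holm_correction(p)
        assert np.all(adj >= p - 1e-12) and np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestFourfoldSites:
    def test_alanine_column_emitted(self):
        aln = {"A": "GCT", "B": "GCC", "C": "GCA", "D": "GCG"}
        sites = extract_4d_sites(aln)
        assert sites == {"A": "T", "B": "C", "C": "A", "D": "G"}

    def test_gap_column_excluded(self):
        aln = {"A": "GCT", "B": "GC-", "C": "GCA", "D": "GCG"}
        assert extract_4d_sites(aln)["A"] == ""

    def test_nondegenerate_codon_excluded(self):
        aln = {"A": "ATG", "B": "ATG"}
        assert extract_4d_sites(aln)["A"] == ""

    def test_count_matches_generator_truth(self):
        aln, mask, truth = simulate_codon_alignment(n_codons=400, seed=9)
        sites = extract_4d_sites(aln, mask)
        assert len(sites["A"]) == truth["n_eligible_codons"]


class TestClock:
    def test_proportionality(self):
        sites = {"A": "A" * 94 + "C" * 6, "B": "A" * 100,
                 "R": "A" * 75 + "G" * 25}
        cal = calibrated_split_times(sites, ("B", "R"), 12.5, n_bootstrap=10, seed=0)
        assert cal.times[("A", "B")] == pytest.approx(12.5 * 0.06 / 0.25)

    def test_anchor_is_exact(self):
        aln, mask, _ = simulate_codon_alignment(seed=10, n_codons=2000)
        sites = extract_4d_sites(aln, mask)
        cal = calibrated_split_times(sites, ("A", "D"), 12.5, n_bootstrap=20, seed=1)
        assert cal.times[("A", "D")] == 12.5

    def test_bootstrap_covers_true_times(self):
        """BCa 95% CIs cover each generating split time in >= 93/100
        simulated alignments."""
        hits_ab = hits_ac = 0
        for s in range(100):
            aln, mask, _ = simulate_codon_alignment(seed=1000 + s, n_codons=8000)
            sites = extract_4d_sites(aln, mask)
            cal = calibrated_split_times(sites, ("A", "D"), 12.5,
                                         n_bootstrap=300, seed=s)
            lo1, hi1 = cal.ci95[("A", "B")]
            lo2, hi2 = cal.ci95[("A", "C")]
            hits_ab += lo1 <= 3.0 <= hi1
            hits_ac += lo2 <= 6.0 <= hi2
        assert hits_ab >= 93 and hits_ac >= 93
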