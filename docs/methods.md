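# Methods

`cladevo` reimplements, at desk scale, the comparative-genomics computations
used to characterise a rapidly evolving rodent clade: synteny-break trees,
breakpoint repeat enrichment, clade divergence and turnover rates, repeat and
retrocopy molecular clocks, and the analysis of a SINE subfamily whose single
motif substitution spread CTCF binding sites through one lineage. All stages
run against synthetic 4-taxon clades with a complete truth ledger, so every
estimator is validated by parameter recovery rather than against deposited
data.

## The clade model

The fixed topology is (((A,B),C),D) with split times 3.0, 6.0 and 12.5 MY —
a murid-like configuration (think *M. musculus* / *M. caroli* / *M. pahari* /
rat) anchored on a 12.5-MY fossil-calibrated outermost split. Default
per-class substitution rates are per lineage per MY, so a pair separated
`t` MY ago accrues `2·t·r` expected divergence. The defaults (genome 0.008,
exons 0.002, LINE/SINE/LTR 0.009, DNA 0.0085, CTCF motifs 0.004 per MY) give
a mouse–rat-like 20% genome-wide pairwise divergence at the 12.5-MY depth;
the hominid-like comparison clade is generated by dividing all rates by the
planted contrast (6 for nucleotide rates, 4.5 for turnover).

Substitutions follow a Jukes–Cantor-like uniform model without rate
heterogeneity, and divergences are kept as raw mismatch proportions with no
multiple-hit correction: the age formulas being tested are linear in
divergence, and scenario divergences stay below 0.25 where saturation bias
is small. In the codon simulator, branch substitutions are additionally
placed on disjoint sites (an infinite-sites discipline), which makes raw
pairwise divergence exactly additive along tree paths — the precise premise
of the linear distance clock.

## Synteny breaks and break-count trees

The ancestral karyotype is 20 chromosomes of 50 one-Mb markers. Planted
rearrangements are tail-move translocations: cut a root-ancestral marker
adjacency and append the detached tail to another chromosome's end. Three
placement rules make planted event counts exactly additive along tree paths,
which is what the estimators are tested against:

* a tail must be an ancestral-contiguous run of markers, so each event
  creates exactly one novel junction;
* cuts keep more than `min_block_size` worth of markers between themselves
  (across all branches) and away from chromosome ends, so every synteny
  block in every pairwise comparison passes the ≥3-Mb flank filter, and
  junction-adjacent markers can never be relocated by later events;
* the recipient's end segment must sit on a different chromosome than the
  tail's first marker in every other lineage's relevant state, so the
  junction reads as inter-chromosomal in every pairwise comparison.

A final structural check verifies these visibility conditions on the
finished genomes (independently of the break detector); placement is
deterministically re-sampled from the scenario seed in the rare case a
condition fails.

Break detection emits an event where consecutive genome-A blocks map to
different genome-B chromosomes and both flanks are ≥3 Mb. "Large" is
operationalised as *both* flanking blocks passing the threshold, which
guards against assembly fragmentation counting as rearrangement. Junction
scans see translocations and fissions from one side but fusions only from
the other, so the pairwise count is the maximum of the two scan directions —
exact for translocations and any mix of fissions *or* fusions; a fission and
a fusion between the same pair would be undercounted by one (the generator
never produces this).

Neighbor joining is the standard Saitou–Nei algorithm with two pinned-down
behaviours: ties in the Q criterion break to the lowest taxon-index pair,
and negative branch lengths are clamped to zero with the deficit moved to
the sister branch (preserving the joined pair's path length). Branch lengths
are reported raw, without rounding to integers. `skbio.tree.nj` serves as an
independent cross-check in tests, never as the implementation. Break rates
per time interval are branch length divided by the interval duration.

## Breakpoint repeat enrichment

The windowed profile counts repeat *starts* in tiled 200-kb windows over
±40 Mb around each breakpoint, averaged over breakpoints; assigning each
repeat to exactly one window makes the conservation check (sum over windows
× breakpoints = starts in spans) exact. Z-scores use the mean and sample SD
(ddof=1) of the non-core windows (core = ±2 Mb); core windows are scored
against that background. Breakpoints whose span does not fit inside their
chromosome are dropped with a warning.

The permutation test compares the repeat count in the ±2-Mb cores with
length-matched regions placed uniformly (chromosomes weighted by placeable
length, no overhangs); other breakpoints' cores are *not* excluded from the
null placements. The p-value is plus-one corrected,
`(1 + #{null ≥ obs})/(1 + n)`, which is super-uniform under the null by
construction and never exactly zero. The default is 10⁴ draws (the genuine
analysis scale of 10⁶ is a parameter away); the calibration tests use 199
draws per scenario across 200 scenarios. The gene-cluster variant supports
two comparators: length-matched windows from intergenic flanks, and random
single-gene sets matched for the cluster's gene count with a density
statistic.

## Divergence, turnover, and clade contrasts

Per-class divergence pools substituted/aligned column counts (indel columns
excluded from both) across blocks; segment sharing follows the rule that a
segment is shared iff it overlaps an alignment block with <50% gapped
columns, using block-level gap fractions. Rate fits regress the per-pair
response on divergence time *through the origin* — both responses are
structurally zero at t = 0 — with a free-intercept mode behind a flag.
Slope differences between groups are tested with an ANCOVA-style F-test
(full model: one slope per group; reduced: common slope; no intercepts),
whose null p-values are verified uniform. Clade contrasts are slope ratios
with delta-method intervals. Across-class p-values are Holm-adjusted.

## The distance clock

Fourfold-degenerate sites are third positions of codon columns whose first
two bases are identical across taxa and form a fourfold-degenerate box
(Ala, Gly, Pro, Thr, Val and the 4-fold subsets of Leu, Arg, Ser); columns
containing gaps or N are excluded, as are codons failing a conservation
mask. Split times are `t = 12.5 · d_pair / d_anchor` on raw mismatch
proportions, so the anchor pair's own estimate is exactly the anchor time.

Confidence intervals are BCa bootstrap over sites (bias correction from the
bootstrap distribution, acceleration from an analytic leave-one-site-out
jackknife). Plain percentile intervals measurably undercovered here
(~92–93% at ~1,400 sites) because the ratio estimator's bootstrap spread
scales with the point estimate; BCa restores second-order accuracy. The
synthetic alignments use 8,000 codons (~2,800 4d sites after masking) as a
desk-scale stand-in for genome-wide 4d collections, at which size the
intervals hold their nominal coverage in the acceptance checks. The full
Bayesian machinery used for the real dating (relaxed clocks, tree priors)
is out of scope by design; the distance clock is the quantity under test.

## Repeat and retrocopy clocks

Repeat ages are `t = d / r_class`, with `d` the mismatch fraction of a copy
against its family consensus and `r_class` calibrated as the mean divergence
of ancestral repeats (copies shared by all four genomes, taken to be
clade-depth old) divided by the clade depth, with a bootstrap SE and a
minimum of 20 calibrating copies. Retrocopy ages are
`t = 2d / (r_parent + r_retrocopy)`. The sources describing these clocks
write "sequence identity" where only a divergence makes dimensional sense
(an identity of 0.95 is not 190 MY of history at r = 0.005); both formulas
are implemented with divergence, and this reading is asserted by the
generator's inversion tests.

Fragmented annotation hits of the same family, strand and chromosome closer
than 200 bp are merged before use, with length-weighted divergence.
Expansion waves are read off age histograms smoothed with a 3-bin moving
average; the peak is the modal bin midpoint (ties resolve young), and a
profile whose modal bin is below 1.5× the median bin is flagged flat.
Species-specific excess of a repeat class uses the exact two-sided Fisher
test (scipy's implementation, verified in tests against integer-arithmetic
hypergeometric enumeration of every table with margins ≤30).

Retrocopy detection is a desk-scale reimplementation of the usual
spliced-alignment strategy: exact 12-mer seeds against the genome, seed
clustering by diagonal, then infix alignment of the mature transcript with
edlib, iterating with masking so tandem copies in one window are all found.
A candidate must lie outside the parental locus, align with ≥75% identity,
and cross exon junctions without an intron-sized (≥30 bp) deletion —
single-exon transcripts carry no junction evidence and are excluded.
Divergence is the mismatch fraction over aligned columns; because
minimal-edit alignment can explain clustered substitutions with a cheaper
local shift, this underestimates divergence by a few percent (the planted
9-MY retrocopy wave dates at ~8.5 MY), which stays within the one-bin
tolerance the recovery checks use and is inherent to any minimum-distance
aligner.

## The SINE/CTCF expansion pipeline

The scenario plants a young subfamily (default 60 copies, 0.3–1.5 MY)
restricted to lineage A within a 190-bp SINE family carrying a CTCF-like
motif; the subfamily founder carries a T→C substitution at motif position
18 plus two diagnostic substitutions outside the motif (real repeat
subfamilies are defined by several diagnostic positions, and they anchor
the subfamily as a sequence cluster). The synthetic 20-position PWM prefers
C over T at the variant position, with the two following positions
unconstrained, so the ancestral trinucleotide context is TCA and the
derived one CCA. SINE copies gain ChIP-like occupancy by a logistic in
motif score with the midpoint halfway between the ancestral and derived
exact-motif scores; genome-wide background motif instances (bases sampled
independently per position — the exact independence null of the
trinucleotide test) are bound with constant probability, standing for
occupancy dominated by chromatin context. Coherent TCA/CCA-carrying SINE
copies are therefore the only source of positional dependence, which is
the signal the trinucleotide test is supposed to isolate.

Pipeline choices, where the procedure was genuinely open:

* **Peaks**: consensus peaks are unions of overlapping replicate peaks
  supported by ≥2 replicates; "bound" means ≥1 bp overlap with a consensus
  peak (summit-vs-body being unspecified in the source procedure).
* **Scanner**: match p-values come from the exact null score distribution
  obtained by convolving per-position log-odds distributions under the
  background model, discretised to 10⁻³ (the FIMO construction); default
  threshold p ≤ 10⁻⁴. Overlapping same-strand hits resolve to the best
  scorer; downstream, one best hit per region is kept.
* **Tree**: copies passing the three consensus filters (≥150 bp, no N,
  ≤10% combined substitutions+indels against the consensus by global edit
  distance) are aligned to the consensus (consensus-anchored; insertions
  relative to the consensus are dropped) and distances are mismatch
  fractions over mutually non-gap consensus positions; the in-repo NJ
  builds the tree. The family consensus itself joins as a tip: it
  approximates the ancestral sequence, and rooting on its branch both
  orients clades and polarises the variant position. This replaces
  likelihood ancestral reconstruction with Fitch parsimony — adequate for
  a single near-binary site and verifiable by brute force.
* **Bound clade**: over all nodes of the rooted tree, the clade maximising
  the contained bound-tip count subject to ≥50% purity (ties to higher
  purity). Both the fraction of all bound tips captured and the clade's
  species composition are reported.
* **Trinucleotide test**: for each partition (bound/unbound) and each of
  the 64 trinucleotides at the variant positions, observed counts are
  compared against the partition's per-position base composition
  (independence model) with a two-sided binomial test, Holm-adjusted
  across all 128 tests; "enriched" = significant and overrepresented. The
  test can be repeated excluding hits inside the focal repeat family by
  filtering the hit lists.
* **Proximity**: distances from new sites to the nearest pre-existing site
  are midpoint-to-midpoint per chromosome; sites on chromosomes without
  any existing site are reported separately, not folded into quantiles.

## What the generators do and do not emulate

The generators reproduce the *downstream representations* the pipeline
consumes — block tables, repeat annotation tables with divergences, peak
intervals, copy sequences, codon alignments — with planted rates, waves,
events and mutations. They do not emulate read-level noise, alignment
artefacts, repeat-library ascertainment, rate heterogeneity across sites or
lineages, selection, GC-biased gene conversion, or realistic indel spectra.
Passing recovery tests therefore demonstrates that the estimators are
correct and calibrated under their stated assumptions, not that those
assumptions hold in real genomes.

## Numerical choices and scales

Desk-scale defaults keep the full test suite within minutes: 10⁴ permutation
draws (10⁶ in the emulated analysis), 300 bootstrap replicates, 8,000-codon
alignments, 20×50-Mb karyotypes, 100-seed repetition for the end-to-end
pipeline property. Degenerate inputs fail loudly: zero-variance Z-score
backgrounds, empty alignment classes, sub-minimum calibration sets,
zero-divergence anchors and empty hit partitions all raise validation
errors rather than returning silent defaults.
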