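# Methods

This note documents the models and procedures implemented in `mkregnet`,
the defaults chosen where a decision was genuinely open, and the limits of
what the synthetic benchmarks demonstrate.

## Coordinates and formats

All genomic coordinates are 0-based half-open internally. Conversions
happen only at file boundaries: BED is native, GTF and SAM are converted
from their 1-based conventions on read/write. A single internal convention
prevents off-by-one drift between stages.

## Peak calling

A mapped tag is the 5'-most coordinate of a sequenced fragment end plus a
strand. The caller:

1. collapses exact `(chrom, pos5, strand)` duplicates (tags at the same
   position on opposite strands are distinct);
2. extends each tag to the mean fragment length `frag_len` (default 200 bp)
   in the 3' direction of its strand, clipping at chromosome bounds;
3. counts, per `bin_size` bin (default 50 bp), fragments overlapping the
   bin by ≥1 bp, via a difference-array pileup;
4. thresholds the genome-wide per-bin coverage distribution: the threshold
   is the smallest integer `c` such that the fraction of bins with coverage
   ≥ `c` is at most `(100 − percentile)/100` (default percentile 99.9, the
   top 0.1 percentile). Zero bins are included in the distribution by
   default; both the tie rule (≥) and zero handling are configurable
   because reasonable conventions differ. A 1e-9 tolerance on the allowed
   bin count absorbs floating-point error in `100 − percentile`;
5. merges maximal runs of above-threshold bins into loci, optionally
   bridging ≤ `max_gap_bins` below-threshold bins (default 0). Each locus
   records its maximum bin coverage ("binding level", used for occupancy
   stratification; mean coverage is offered as an alternative) and a
   summit (center of the leftmost maximal bin — ties break leftward for
   determinism);
6. removes any locus with ≥1 bin at or above the control track's top-1.0-
   percentile threshold, the control being binned on an identical grid.
   An all-zero (degenerate) control raises an error rather than silently
   filtering nothing; `--no-control` skips the filter explicitly.

Replicates are pooled before calling by default; an intersect mode
(retain loci called in both replicates) is available through
`pooled_vs_single_loci`. Duplicate handling is exact-duplicate collapse;
multi-mapping reads are out of scope (inputs are already-mapped tags).

A structural property of quota-filling percentile thresholds is worth
stating: the threshold descends until the allowed bin quota is filled, so
when the quota exceeds the number of genuinely enriched bins the remainder
is taken from the background tail. Called-locus counts are therefore
bounded by the quota, and precision depends on a clear gap between signal
and background coverage. The recovery benchmark (below) is designed with
that gap; real data with diffuse enrichment will behave less cleanly.

## Annotation

The locus reference point is its midpoint (summit optional); midpoint is
robust to locus width. Distance to the nearest TSS is unsigned; ties
resolve to the lexicographically smallest gene id. Distance classes:
proximal ≤ 10 kb, distal 10–100 kb (closed at 100 kb), gene desert
> 100 kb. Genomic categories use precedence promoter > exon > intron >
intergenic, with the promoter window the 3-kb strand-aware upstream
interval `(TSS − 3 kb, TSS]` (mirrored for − genes). Membership is tested
at the midpoint, not by any-overlap. Loci on chromosomes without genes
carry a "no TSS" sentinel: they are excluded from distance statistics and
counted intergenic.

## Expression integration

The knockout effect per gene is the difference of replicate means in log2.
The test is a two-sample t-test with Benjamini–Hochberg FDR — the
transparent default for small replicate counts; genes constant in both
conditions get p = 1 when the means agree. Classification: activated when
effect ≤ −log2(1.5) at q < 0.05 (expression falls without the factor),
repressed symmetrically.

The density profile counts bound-locus midpoints per 20-kb TSS-distance
bin out to 200 kb, per response class, divided by class size (loci per
gene per bin). By default every (gene, locus) pair within range counts, so
one locus can contribute to several genes; a nearest-gene-only mode is
provided because either reading is defensible. Enrichment in a window is
the ratio of per-gene densities (class vs nonresponsive background); the
p-value is the exact conditional binomial test for comparing two Poisson
rates — given the total in-window count, the class count is
Binomial(total, n_class/(n_class+n_background)) under equal per-gene
rates. A gene-label permutation test (default 10,000 rounds) is available
as a model-free alternative. The activated-gene window is 0–20 kb and the
repressed-gene window 60–100 kb; a wider repressed window (up to 130 kb)
appears in some descriptions of this design, and the narrower one is used
here.

## Motifs

A PWM is a column-stochastic probability matrix with a 0.01 pseudocount
per cell before normalization and a uniform background by default (an
empirical mononucleotide background can be supplied). The approximated
binding energy of a region is the log of the sum, over all windows on both
strands, of the product of per-position likelihood ratios `P_j(b)/Q(b)`;
`N` bases contribute ratio 1. The log-sum-of-products form reproduces the
two qualitative behaviors the statistic is meant to have: a single
consensus site dominates a region's energy, while several weaker matches
can still combine into a medium score. Energies are in nats.

Discovery is discriminative and fully deterministic (seed enumeration plus
hard EM, no stochastic sampling):

- foreground = 500-bp windows on peak summits; background = both 500-bp
  flanks at 1 kb offset (pooling both flanks doubles the background
  sample; the offset must exceed the window so the sets are disjoint);
- k-mers (k = 6–8, both strands) are ranked by
  `log((c_fg+1)/N_fg) − log((c_bg+1)/N_bg)`; the top 50 seeds are kept,
  each reported in the orientation more frequent on the foreground
  forward strand (ties lexicographic);
- each seed's PWM is built from foreground occurrences within Hamming
  distance 1, then refined by ≤10 hard-EM iterations (best window per
  region, either strand, forward preferred on ties → rebuild columns);
- edge columns with information content < 0.3 bits are trimmed (minimum
  width 5), so seeds that straddle a planted core converge to the same
  consensus as the core itself;
- final ranking is by mean foreground energy minus mean background
  energy; consensuses within Hamming distance 1 (either strand) or in a
  substring relation collapse onto the better-ranked motif.

Occupancy stratification splits loci into coverage deciles (group count
configurable; reduced with a warning when loci are few) and reports
per-group energy quartiles plus the Spearman correlation of coverage vs
energy across loci.

The AP-1 motif used as a negative control in the simulator is the
canonical TRE consensus TGACTCA — a conventional choice made here, not a
value taken from any specific occupancy dataset.

## Co-binding

Two locus sets co-bind where intervals overlap by ≥ `min_overlap` bp
(default 1; a summit-distance criterion is available). Because overlaps
can be many-to-many, the Venn "both" count is reported in both
orientations (A loci with ≥1 overlapping B locus, and vice versa); the
primary co-bound region count merges overlapping pairwise intersections.
Gene assignment follows the annotation module's nearest-TSS rule.

## Synthetic data: what it emulates

The generator reproduces the statistical structure the analysis assumes:

- **Sites.** `n_sites` centers: background sites uniform over the genome,
  plus extra sites within 20 kb of activated-gene TSSs and within
  60–100 kb of repressed-gene TSSs, with expected densities
  `proximal_density_fold` (default 2.6) and `distal_density_fold`
  (default 1.4) times background. The three site-count components are
  drawn from a single multinomial whose weights solve the density
  equations exactly in expectation. Site strength is log-normal
  (σ = 0.5) so occupancy spans a multi-decile range; a `cobound_fraction`
  (default 0.13) of sites is flagged for the cofactor track; motif labels
  (RUNX/ETS/GATA at 60/35/5%) write the consensus into the sequence at
  the site center, with extra copies at strong sites so motif
  multiplicity co-varies with occupancy. Sites are planted on the forward
  strand by default (`motif_strand_random` flips half) — immaterial for
  double-stranded scoring but it fixes the reported orientation.
- **Tags.** Each tag is site-derived with probability `enrichment_pi`
  (site chosen strength-weighted; fragment center jittered by
  Normal(0, `frag_len_sd`); fragment length Normal(200, sd) truncated to
  [50, 500] bp; the tag is the fragment 5' end on a random strand) and
  uniform background otherwise. The control track uses `enrichment_pi` = 0;
  the cofactor track samples only co-bound sites. Duplicates arise
  naturally at depth and are left in place — deduplication is the
  pipeline's job.
- **Expression.** Gene baselines Normal(8, 1.5) log2; replicates add
  Normal(0, `noise_sd_log2` = 0.25); knockout replicates shift by the true
  effect, whose magnitude is uniform in [log2 1.5, 2.0] with activated
  genes negative. Three replicates per condition by default.
- **Genes.** TSSs at least 2 kb apart; on chromosomes ≥ 480 kb the final
  120 kb stays gene-free so gene deserts exist. 1–4 exons per gene built
  outward from the TSS.

Every stage draws from its own RNG stream derived from
`(seed, stage-salt)`, so outputs are byte-identical for a fixed config and
changing one stage's parameters does not scramble the others.

**What it does not emulate:** real base composition, mappability and
PCR-duplicate bias, fragment-size estimation error, multi-isoform TSS
structure, probe-level microarray noise, and correlated biological
replicates. Passing the recovery benchmarks therefore demonstrates the
pipeline's internal correctness (each stage recovers exactly the structure
planted under its own model assumptions), not its robustness to the
artifacts of real sequencing data.

## Benchmark problem sizes

The test suite and `scripts/acceptance.py` use sizes chosen to make each
recovery statistically decisive while staying desk-scale:

- peak recovery: one 2-Mb chromosome, 200 sites, 500k tags, tag-in-site
  probability 0.995 (sites far above the ≥10× background regime) and a
  permissive 96.0 signal percentile — the configuration gives the clean
  signal/background coverage gap the quota-filling threshold needs, and
  the caller recovers essentially all sites with no false loci;
- enrichment recovery: 50 simulations of 1,000 genes (500 activated, 250
  repressed) on 200 Mb with 2,000 sites, measured directly on the truth
  coordinates. The recovered proximal fold (~2.3) sits slightly below the
  planted 2.6 because genes that happen to neighbor an activated gene
  absorb part of its elevated density into the background class — a real
  property of the density-ratio estimator, not a bug;
- null calibration: 50 simulations with no planted effects (responsive
  rate ~0 under BH) and uniform sites (fold interval covers 1.0);
- motif recovery: 500 foreground / 1,000 background 500-bp regions, RUNX
  consensus planted in 60% and ETS in 35% of the foreground;
- defaults for the end-to-end demo: two 10-Mb chromosomes, 200 genes, 100
  sites, 1M tags per track — sized so that the number of genuinely
  enriched bins matches the top-0.1-percentile bin quota (~400 bins).

## Known limitations

- The percentile caller has no model-based background (no local lambda);
  closely spaced sites merge into one locus and diffuse enrichment is
  thresholded, not tested.
- The enrichment binomial treats (gene, locus) pairs as independent;
  overlapping gene windows violate this mildly (the permutation test does
  not).
- Discovery's Hamming-1 seeding cannot represent gapped or two-part
  motifs, and PWM columns are independent (no dinucleotide model).
- The gene-level co-binding table uses nearest-TSS assignment only — no
  regulatory-domain model.
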