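# mkregnet

Integrative analysis of a transcription factor's genome-wide occupancy
(ChIP-seq) against its knockout expression program — the kind of study that
maps where a factor such as RUNX1 binds in maturating megakaryocytes, which
genes respond when the factor is deleted, and how binding, coactivator
(p300-like) co-occupancy and sequence motifs line up with that response.

The package is aimed at computational biologists who want the complete
analysis chain as small, auditable, testable components rather than a black
box, together with a synthetic-data generator that plants known structure so
every stage can be validated against ground truth.

## What it computes

1. **Peak calling by coverage percentile.** Mapped tag 5' ends are
   deduplicated, extended to the mean fragment length (200 bp) by strand,
   piled up in 50-bp bins, and bins in the top 0.1 percentile of the
   genome-wide coverage distribution are merged into *bound loci*. Loci with
   any bin in the top 1.0 percentile of a non-immune-serum control track are
   removed.
2. **TSS annotation.** Each locus midpoint gets a nearest-TSS distance, a
   distance class (≤10 kb / 10–100 kb / >100 kb "gene desert"), and a genomic
   category with precedence promoter (3 kb strand-aware upstream) > exon >
   intron > intergenic.
3. **Knockout-effect integration.** Per gene, the effect is
   `mean(log2 knockout) − mean(log2 control)`; genes moving ≥1.5-fold at
   Benjamini–Hochberg FDR < 0.05 are *activated* (down in the knockout) or
   *repressed* (up). Bound-locus density per 20-kb TSS-distance bin, averaged
   within each class, yields fold enrichment against nonresponsive genes with
   an exact conditional binomial p-value.
4. **Motifs.** The match of a PWM `P` with background `Q` to a region is its
   *approximated binding energy*

   `E = log Σ_{i,strand} Π_j P_j(b_ij) / Q(b_ij)`

   summed over all windows on both strands — multiplicative, so one
   consensus-quality site dominates, while several weak sites can still add
   up. De-novo discovery ranks k-mer seeds (k = 6–8) by
   foreground/background log-odds on 500-bp peak regions vs 1-kb-offset
   flanks, refines the top seeds by hard EM, and ranks refined PWMs by mean
   foreground-minus-background energy.
5. **Co-binding.** TF and coactivator locus sets are intersected (≥1 bp by
   default), Venn counts reported in both orientations, co-bound regions
   assigned to nearest-TSS genes and cross-tabulated against response
   classes.
6. **Synthetic data.** A simulator generates genomes, gene models, planted
   binding sites whose density is 2.6× background within 20 kb of
   activated-gene TSSs and 1.4× at 60–100 kb of repressed-gene TSSs, RUNX
   (TGTGGTT) / ETS (CAGGAAG) / GATA (GATAAG) consensus motifs written at site
   centers, ~200-bp fragment ChIP tags for TF, cofactor and control tracks,
   and replicate expression matrices — plus truth tables for every quantity.

## Worked example

Run the whole pipeline on synthetic data and summarize it:

```bash
mkregnet run --seed 1 --out-dir results/demo
mkregnet report --result-dir results/demo
```

With the default study conditions (two 10-Mb chromosomes, 200 genes, 100
planted sites, 1M tags per track, seed 1) the report prints, among others:

```
"n_tf_loci": 99
"top_motifs": ["TGTGGTT", "GTGGTTT", "CAGGAAG", "CAGGAGGC", "TAACTGCT"]
"venn": {"n_a": 99, "n_b": 183, "both_a": 9, "a_only": 90, ...}
"distance_class_fractions": {"distal": 0.63, "proximal": 0.27, "gene_desert": 0.10}
```

Reading: 99 of the 100 planted sites were called as TF-bound loci; the top
de-novo motif is exactly the planted RUNX consensus, with the ETS consensus
in the top three; 9 TF loci overlap a cofactor locus, matching this seed's
planted truth of 9 co-bound sites; and most loci sit 10–100 kb from the
nearest TSS, as expected when sites are planted mostly in intergenic space.

Individual stages are available as `mkregnet synth|callpeaks|annotate|
integrate|motifs|cobind`, e.g.

```bash
mkregnet callpeaks --signal chip.bed --control nis.bed \
    --chrom-sizes chrom.sizes --percentile 99.9 --control-percentile 99.0 \
    --frag-len 200 --bin 50 --out loci.bed
```

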