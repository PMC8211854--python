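# dmrkit

Window-based differential-methylation (DMR) calling and interval genomics for
MeDIP-seq-style coverage data, with a synthetic-data generator so the whole
pipeline is testable at desk scale. The toolkit covers:

- **simulate** — synthetic genomes, replicate count matrices with planted
  fold-change DMRs (negative-binomial noise), annotation interval sets with
  known covered fractions, and variant tables with planted truth.
- **quant** — fragment 3′ extension, Poisson-tail duplicate capping,
  per-window fragment counting over a gapless genome tiling, RPKM, the
  background-methylome mask (sum of group-mean RPKM > 1.0), and PCA sample QC
  on the most variable windows.
- **dmr** — exact conditional count test per window (negative-binomial with a
  moment dispersion estimate; Poisson/binomial at dispersion 0), fold (≥1.5)
  and p (<0.01) gates, merging of book-ended same-direction windows, region
  masking, list concatenation and cross-list overlap partitions.
- **context** — classification of regions against genic / repeat-class /
  CpG-island–shore–shelf schemes by fixed precedence, chi-squared comparison
  to a background distribution, signed TSS distances, enhancer overlap.
- **enrich** — overlap summaries (count, 1-decimal percent), Monte-Carlo
  expected overlap from 10,000 random disjoint fixed-length proxy regions,
  and the exact two-sided binomial enrichment test with a Wilson CI.
- **profiles** — computeMatrix-style scaled-region matrices (6 kb flanks,
  3 kb scaled body, 200 bp bins ⇒ 75 bins) with mean-preserving body
  rescaling, and chromosome-matched shuffled baseline regions.
- **variants** — genotype calls from alt-read fractions (>90% hom, ≥30% het),
  the six-rule hard-filter cascade (simple-repeat periodicity, homopolymer,
  dinucleotide, mapping quality, annotated repeats, per-sample het clusters),
  case/control shared variants, and SNP/SV proximity annotation.

## CLI

```sh
dmrkit simulate --seed 1 --outdir sim            # synthetic inputs + truth
dmrkit quant --genome sim/genome.chrom.sizes \
    --fragments sim/fragments_A0.bed --group A \
    --fragments sim/fragments_B8.bed --group B --out counts.tsv
dmrkit dmr --counts counts.tsv --groups A,B --control A --case B \
    --mask chr13:58060780-80060780 --out dmrs.bed
dmrkit enrich --dmrs dmrs.bed --genome sim/genome.chrom.sizes \
    --reference sim/retention.bed --n-random 10000 --region-len 500 --seed 1
dmrkit profile --regions dmrs.bed --signal track.bedgraph \
    --genome sim/genome.chrom.sizes
dmrkit variants --vcf sim/variants.vcf --cases case1,case2 --controls ctrl1
dmrkit run --config pipeline.yaml                # end-to-end with manifest
```

`dmrkit run` takes a single YAML config (paths, group labels, stage
parameters, global seed, output directory), executes
quant → dmr → context → enrich → profile → variants, and writes a
`manifest.json` with per-stage status and row counts. Reruns with the same
config are byte-identical.

## Coordinates and conventions

All intervals are 0-based half-open internally; BED on disk. Overlap means
≥1 bp intersection everywhere (book-ended intervals do not overlap). The
final tiling window of each chromosome may be shorter than the window size
and RPKM uses its actual length.

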