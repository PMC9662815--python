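# hybridcre

Allele-specific *cis*-regulatory element (CRE) analysis for diploid
(F1-hybrid style) data. The package pairs maternal/paternal alleles of
summit-centered CREs and provides:

- **`hybridcre.synthetic`** — a diploid fixture generator: two haplotypes
  differing by SNPs/indels at configurable densities (wild-derived and
  classical strain presets), planted AP-1/TEAD/CTCF motifs near summits,
  targeted motif disruptions on the paternal allele, and
  negative-binomial per-allele counts whose means drop when a governing
  motif is disrupted. Ground truth is recorded for every locus.
- **`hybridcre.catalog`** — the filtered catalog of analyzable allele
  pairs: mappability (≥1 variant within ±60 bp of the summit), 1-kb
  summit deduplication (single-linkage, max pooled signal wins),
  per-group bottom-quintile signal floor, imprinted-region exclusion
  (±100 kb), and proximal/distal + active/primed classification.
- **`hybridcre.skew`** — allelic-imbalance testing (exact binomial, or
  beta-binomial with method-of-moments overdispersion for NB-dispersed
  counts), Benjamini–Hochberg FDR, fold-change magnitude bins
  (>2-fold / >4-fold, pseudocounted), and signal-matched subsampling of
  shared peaks.
- **`hybridcre.motifs`** — IUPAC degenerate k-mer expansion and scanning
  on both strands (reverse-complement-closed patterns reported once),
  JASPAR PWM log-odds scanning with a fraction-of-max threshold,
  per-allele motif disruption calls, AP-1 half-site (TGASVDB) counting,
  and core/flank variant-overlap classification.
- **`hybridcre.positions`** — variant offset distributions relative to
  summits or strand-oriented motif anchors (closest-nucleotide rule),
  central-window chi-squared contrasts, and nearest-feature distances.
- **`hybridcre.hierarchy`** — AP-1/TEAD co-binding classes by summit
  proximity, motif-mutation enrichment (two-sided Fisher exact by
  hypergeometric enumeration), partner-loss fractions, and per-class
  k-mer presence fractions.
- **`hybridcre.profiles`** — binned aggregate signal profiles (±1000 bp,
  10-bp bins) split by allele motif status, with selection of
  single-motif intact-vs-mutated allele pairs.

All coordinates are 0-based half-open internally; VCF conversion happens
at the I/O boundary. Everything is deterministic given a seed.

## CLI

```sh
hybridcre simulate --out fixture/ --seed 7          # synthetic diploid bundle
hybridcre catalog  --summits summits.bed --variants variants.vcf --out catalog.tsv
hybridcre skew     --counts counts.tsv --assay H3K27ac --fdr 0.1 --out skew.tsv
hybridcre motifs   --fasta ref.fa --pattern VTGACTCAB --out hits.bed
hybridcre positions --summits summits.bed --variants variants.vcf --out offsets.tsv
hybridcre hierarchy --fos skew_Fos.tsv --tead skew_Tead1.tsv --out hierarchy.json
hybridcre profile  --anchors anchors.bed --events events.tsv --out profile.tsv
hybridcre run      --config examples/demo_config.yaml   # full pipeline
```

`hybridcre run` executes simulate → catalog → skew → motifs → positions
→ hierarchy → profiles, writing per-stage TSVs and a `summary.json`
carrying filter counts, allele-specific fractions, enrichment tables,
the seed and a config hash.

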