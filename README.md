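# ercross

Cross-talk analysis of estrogen receptor subtype (ERα / ERβ) ChIP-Seq
binding maps integrated with differential expression.  The package
implements the downstream computational pipeline as tested, reusable
stages:

- **genomic_io** — BED3/6/12, gene tables, chromosome sizes, FASTA,
  expression TSV; all coordinates 0-based half-open.
- **interval_algebra** — the cartographic region construction: extend
  peaks ±1 kb, merge overlapping extensions into binding regions,
  partition region sets into heterodimer / homodimer groups, extract
  subtype-*prevalent* sites, the six-class co-binding taxonomy, and the
  mitochondrial tag-density filter (N/l ≥ 0.5).
- **motif_scan** — information-weighted core/matrix similarity scoring of
  position-weight matrices, a documented open full-element matrix built
  from the palindromic consensus `GGTCAnnnTGACC`, exact `RGGTCA`
  half-site matching, and ERE+/hERE+/none site classification.
- **tfbs_enrichment** — matrix over-representation against a genome
  background with a continuity-corrected binomial Z-score; filters
  Z ≥ 3.0 and fold ≥ 4.0; heat-grid report with `low-z` / `absent`
  sentinels.
- **expression_de** — quantile normalization, DiffScore ↔ p conversion
  (`p = 10^(-|ds|/10)`, |40| ↔ 1e-4), regulation calling (detected AND
  |DiffScore| ≥ 40), and the four regulation groups (wt-only / both
  concordant / β-only / opposite).
- **target_linking** — primary-target genes (≥ 1 region inside or within
  10 kb of the transcription unit), strand-aware promoter / exon /
  intron / upstream / downstream annotation, per-gene class or
  COMBINATION label.
- **mirna_bootstrap** — matched resampling null for site proximity to
  pre-miRNA loci: per-chromosome counts and length multisets preserved,
  uniform random starts, add-one empirical p-values.
- **synthetic_data** — deterministic generators for peaks (with planted
  six-class truth), site sequences (planted full/half elements, scrubbed
  backgrounds), expression tables, gene models and loci — so the whole
  pipeline is testable offline.

## CLI

One executable, one subcommand per stage:

```sh
ercross simulate --preset tiny --seed 1 -o bundle/
ercross regions  bundle/beta_peaks.bed bundle/chrom.sizes -o regions.bed
ercross classify bundle/beta_peaks.bed bundle/alpha_tap_peaks.bed \
                 bundle/alpha_wt_peaks.bed bundle/chrom.sizes -o classes.tsv
ercross motif    bundle/site_sequences.fa -o motif_classes.tsv
ercross de       bundle/expression.tsv -o groups.tsv
ercross link     bundle/genes.tsv regions.bed -o targets.tsv
ercross mirna    bundle/beta_peaks.bed bundle/mirna_loci.bed \
                 bundle/chrom.sizes --boot-reps 1000 --seed 1 -o boot.json
ercross mito     mito_sites.bed -o filtered.bed
```

Thresholds (`--flank`, `--window`, `--boot-reps`, `--core-thresh`,
`--mat-thresh`, `--z-min`, `--fold-min`, `--diffscore-min`,
`--density-min`) can also be set once in a YAML config passed with
`--config`; every stochastic stage takes `--seed`.

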