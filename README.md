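# occupeak

Analysis toolkit for temporal transcription-factor ChIP-seq occupancy.
Given peak sets from three differentiation stages, gene models, IP/Input
signal tracks, a binding-motif PWM, a base-wise conservation track and a
knockdown expression matrix, it runs an integrated analysis:

- **annotate** — classify every peak into one of six mutually exclusive
  genomic categories (promoter, upstream, exon, intron, TTS region,
  intergenic) with strand-aware windows, and associate peaks with genes.
- **temporal** — merge peaks across time points into consensus regions and
  assign the seven presence/absence clusters, with read counts normalized to
  10 million reads (log2 intensities).
- **enrichment** — category enrichment against random background intervals
  and Fisher-exact comparisons of category distributions between gene groups.
- **motifs** — PWM log-odds scanning on both strands with exact p-values
  (dynamic-programming null distribution), best-site-per-peak selection, and
  summit-distance profiles stratified by peak-score tertiles.
- **metagene** — per-gene 30-window schema (10 upstream kb, 10 gene-body
  deciles, 10 downstream kb), mean IP/Input ratios per window, per-window
  Wilcoxon rank-sum group tests, and binding-level quintile bins.
- **integrate** — empirical-Bayes moderated t-test DE classification
  (up / down / nonresponsive at >= 1.5-fold, FDR < 0.05), peaks-per-gene and
  per-category fold-change comparisons, and motif-site conservation analysis
  against length-matched control genes (Kolmogorov-Smirnov).
- **simulate** — a synthetic study generator (genome, genes, peak sets
  covering all 7x6 pattern/category combinations, signal tracks, planted
  motifs, conservation offsets, expression matrix) with machine-readable
  ground truth, used throughout the test suite.
- **stats** — exact/asymptotic Mann-Whitney, Fisher, KS and
  Benjamini-Hochberg implementations shared by all modules.

## CLI

```sh
# generate a synthetic study (writes inputs + a ready pipeline config)
occupeak --seed 1 simulate --out study/

# run the full pipeline; emits one TSV per report table plus manifest.json
occupeak run study/pipeline.yaml

# list the report tables produced
occupeak report study/pipeline_out
```

Individual stages are also exposed (`occupeak annotate|cluster|enrich|scan`),
each reading the standard formats (BED, BED12, bedGraph, FASTA, MEME minimal
motif, TSV expression matrix). The pipeline config is a YAML file naming all
inputs and the thresholds (peak significance -log10 p >= 10, motif p < 1e-4,
1.5-fold change, FDR 0.05).

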