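# regscreen

Analysis toolkit for pooled regulatory-element dropout screens and the
surrounding regulatory-genomics workflow:

- **Screen scoring** — counts-per-million normalization, per-construct
  log2 fold changes vs a reference pool, centering on non-targeting
  controls, gene-level sensitivity scores (log2 mean fold change of the
  k most depleted constructs, default k = 3) and region-level depletion
  scores (mean of the m most depleted constructs per region, default
  m = 2, averaged over tumour groups).
- **Permutation inference** — empirical p-values with add-one correction
  (floor 1/(N+1)), a region-screen test that reassigns constructs to
  region labels, TSS-window (±500 kb) peak enrichment against resampled
  gene sets, one-sided Fisher interval-overlap tests with Woolf CIs,
  identifier set overlaps and peak co-binding fractions.
- **Motif analysis** — JASPAR/MEME PWM parsing, log2-odds scanning of
  both strands, per-position information content, allele-delta scoring
  of regulatory variants, and two-motif geometry (tandem/convergent/
  divergent orientation + edge-to-edge spacing) statistics.
- **Allelic quantification** — allele fractions, odds-ratio
  normalization of IP vs input / RNA vs gDNA, and knockdown allelic-shift
  (per-allele fold changes and a selectivity index).
- **Time-course filtering** — sustained-downregulation gene filtering
  (significant at every required timepoint) and peak-to-gene TSS-window
  linking.
- **Synthetic data** — seed-deterministic generators for screens (plasmid
  skew, per-guide efficacy, fitness effects, per-tumour multinomial
  bottlenecks, negative-binomial sequencing), genome annotations with
  planted TSS-proximal peaks, sequences with planted motif pairs, and
  binomial allelic count tables.

## Command line

Every subcommand writes its outputs plus a `resolved_config.yaml`
provenance record (tool version, parameters, input digests). A YAML
config can be supplied with `--config`; command-line flags win.

```sh
# simulate a screen, then score it
regscreen simulate screen --outdir sim --seed 7 --n-regions 100
regscreen score-regions --counts sim/counts.tsv --library sim/library.tsv \
    --outdir out --n-perm 10000 --seed 7
regscreen score-genes --counts sim/counts.tsv --library sim/library.tsv \
    --outdir out-genes --k 3

# peak enrichment near a gene set's TSSs
regscreen simulate annotation --outdir ann --seed 4
regscreen enrich-tss --peaks ann/peaks.bed --tss ann/tss.tsv \
    --genes ann/gene_set.txt --outdir enr --window-bp 500000 --n-perm 1000

# motif-pair geometry and allele scoring
regscreen simulate sequences --outdir seqs --seed 9
regscreen motif-pairs --fasta seqs/sequences.fa --pwm-a seqs/motif_a.jaspar \
    --pwm-b seqs/motif_b.jaspar --outdir pairs
regscreen allele-delta --fasta seqs/sequences.fa --pwm seqs/motif_a.jaspar \
    --sequence-id seq_0001 --position 100 --ref-base T --alt-base C --outdir ad

# allelic ratios and the time-course filter
regscreen simulate allelic --outdir all --seed 6 --depth 10000
regscreen allelic --table all/allelic.tsv --outdir ratios
regscreen filter-timecourse --table timecourse.tsv --outdir filtered \
    --lfc-max 0 --padj-max 0.05 --timepoints 32,72
```

Exit codes: 0 success, 1 validation failure, 2 usage error.

## File formats

- Counts: TSV, first column `construct_id`, one column per sample, with a
  sidecar `<stem>.samples.tsv` (`sample_id role unit_id group_id
  reference`).
- Library: TSV with `construct_id protospacer_1 [protospacer_2] target_id
  target_class [chrom start end]`; `target_class` is one of `gene`,
  `region`, `nontargeting_control`, `essential_control`.
- Intervals: BED3/BED6, 0-based half-open throughout.
- PWMs: JASPAR raw counts or MEME minimal format; counts get a fractional
  pseudoweight (default 0.01 of each position total per cell).
- Allelic: TSV `label context condition allele1 allele2 replicate` with
  contexts `ip/input/rna/gdna`.
- Time course: TSV `gene timepoint log2fc padj`.

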