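# translatome

Analysis toolkit for two-fraction polysome-profiling experiments. From a
normalized expression matrix with paired polysomal and total-cytoplasmic
samples (knockdown vs control, replicated), it computes:

- per-replicate **condition ratios** per RNA fraction (knockdown / control),
- the **relative translatability** ratio-of-ratios `RR_i = poly_i / tot_i`
  with geometric-mean summaries,
- **concordance-thresholded calls** (UP if `RR >= 1.5` in all replicates,
  DOWN if `RR <= 0.67` in all replicates; thresholds configurable),
- a mutually exclusive **regulation taxonomy**: polysome-only changes,
  translational buffering (total changes, polysome load constant),
  opposite-direction changes, concomitant changes with unmodified
  translatability, and residual classes,
- **ddCt qPCR** quantification (reference-gene normalized, efficiency 2 by
  default) with a two-tailed one-sample t test of log ratios,
- **5'UTR feature comparison** (GC%, length) with class-binned distributions
  and two-sample Kolmogorov–Smirnov tests (exact p for small samples),
- generic **hypergeometric over-representation** with BH correction,
- a fully seeded **synthetic-data generator** that plants regulation
  classes, GC-shifted UTR sets and qPCR fold changes with known truth.

A 35-row candidate-gene fold-change table is bundled under
`translatome.load_candidate_genes()` for validation.

## CLI

```sh
# generate a synthetic input bundle with planted ground truth
translatome simulate --n-genes 2000 --seed 1 --out sim/

# full pipeline: filter -> ratios -> RR -> calls -> classification
translatome run --matrix sim/matrix.tsv --design sim/design.tsv \
    --flags sim/flags.tsv --out out/ --up 1.5 --down 0.67 --inclusive

# individual stages
translatome quantify --matrix sim/matrix.tsv --design sim/design.tsv --out tr.tsv
translatome classify --matrix sim/matrix.tsv --design sim/design.tsv --out summary.json
translatome qpcr --ct sim/ct.tsv --reference HPRT1 --out qpcr.tsv
translatome utr --positive sim/utr_positive.fasta --neutral sim/utr_neutral.fasta
translatome enrich --genes list.txt --sets sets.tsv --universe universe.txt
```

Input formats: expression matrix as a TSV (`gene_id` + one column per
sample), detection flags as a 0/1 TSV of the same shape, design as a TSV
with columns `sample_id condition fraction replicate`
(condition in `{knockdown, control}`, fraction in `{polysomal, total}`),
Ct tables as long-format TSV (`gene condition fraction experiment
tech_rep ct`), UTRs as FASTA.

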