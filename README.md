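# divomics

Multi-omic divergence analysis between two selected lines, built as a
tested, reusable pipeline: genotype QC and allele-based association with
permutation and BH-FDR, Weir–Cockerham Fst / windowed Tajima's D with a
ten-category selection-signature classification, fixed-allele detection,
CpG-loss ("CpG-SNP") and novel-CpG calling with 1/16-expectancy
enrichment statistics, CNV-seq-style two-library copy-number calling,
MeDIP-seq windowed differential-methylation (DMR) calling with
CpG-coupling normalisation, single-category feature annotation, and
cross-omic interval integration (hypergeometric overlap tests, Venn
counts, DMR-in-CNV confounding flags, repeat-class profiles).

A first-class synthetic-data module generates a complete two-line
dataset (genome, gene models, genotypes, MeDIP reads, pooled input
depth, repeats, QTLs) with a machine-readable truth manifest, so every
stage is testable end-to-end without downloads.

## Command line

```sh
divomics simulate --seed 1 --outdir data/                 # synthetic dataset + truth.json
divomics assoc    --vcf data/genotypes.vcf --groups data/groups.tsv --out assoc.tsv
divomics popgen   --vcf data/genotypes.vcf --groups data/groups.tsv --out popgen.tsv
divomics cpg      --vcf data/genotypes.vcf --groups data/groups.tsv \
                  --fasta data/genome.fa --gff data/genes.gff3 --out cpg.tsv
divomics annotate --gff data/genes.gff3 --queries peaks.bed --out ann.tsv
divomics cnv      --input-a data/input_A.bed --input-b data/input_B.bed \
                  --genome data/genome.fa --out-prefix cnv
divomics dmr      --reads-dir data --groups data/groups.tsv \
                  --genome data/genome.fa --out-prefix dmr
divomics integrate --snps sig.bed --cnvs cnv.calls.bed --dmrs dmr.dmrs.bed \
                  --qtls data/qtl.bed --repeats data/repeats.bed \
                  --genome data/genome.fa --out-prefix integrated
divomics run      --config pipeline.yaml                  # all stages + report.md
```

The pipeline YAML maps input paths (`genome`, `genes`, `vcf`, `groups`,
`input_a`, `input_b`, `reads_dir`, `qtls`, `repeats`), an `outdir`, a
`seed`, and optional per-stage blocks under `stages:` (e.g.
`stages: {cnv: {enabled: false}, dmr: {alpha: 0.05, min_row_sum: 10}}`).

## Conventions

- All internal coordinates are 0-based, half-open; VCF positions are
  converted at the read/write boundary.
- Half-missing diploid calls (`0/.`) are treated as fully missing.
- Reads are BED intervals (with strand and sample id), not BAM, keeping
  the pipeline testable as plain text.
- All simulation output is byte-reproducible from the config seed.
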