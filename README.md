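# dubscreen

Scoring and cross-validation pipeline for a pooled CRISPR dropout screen of
deubiquitylases, with the companion proteomic and transcriptomic readouts:

- **library_model** — sgRNA library manifest (98 DUB genes ×3 guides, 6
  essential-control genes ×3, 12 non-targeting guides) with CSV/FASTA I/O.
- **synthetic_data** — generators with known ground truth: negative-binomial
  screen counts under an exponential-growth model (expected log2 fold change
  = doublings × fitness × guide efficiency), FASTQ rendering, paired
  FLAG-IP/BioID intensity tables with intensity-dependent missingness, and
  ranked expression metrics with planted gene sets.
- **screen_quant** — FASTQ → guide×sample counts via an anchored
  exact/1-mismatch hash matcher (ambiguous reads are never assigned), plus
  QC (mapping rate, zero fraction, Gini).
- **screen_score** — counts-per-million normalization, per-guide T14/T0 log2
  fold changes, per-gene mean-log2 aggregation, pseudo-gene null from
  non-targeting guides (exhaustive C(12,3)=220 or resampled), empirical
  p-values with BH FDR, essential-control QC, competition-assay
  normalization.
- **proteomics_xval** — per-screen bait-vs-control log2 enrichment with
  floor imputation of missing controls, and the dual-screen filter:
  identified in both bait samples and enriched **strictly more than**
  2-fold in both.
- **enrichment** — weighted pre-ranked gene-set enrichment (running-sum ES,
  gene-set permutation, sign-stratified NES/FDR), the differential-regulation
  filter (|log2FC| ≥ 1 **and** adjusted p < 0.01), row z-transform
  (population SD), GMT I/O.
- **cli** — `dubscreen` command with `simulate-screen`, `simulate-ip`,
  `count`, `score`, `xval`, `gsea`, and `run-all` subcommands; every stage
  writes a provenance JSON (resolved parameters, hash, seed, version).

## CLI

End-to-end on synthetic data:

```bash
cat > config.yaml <<EOF
seed: 1
screen:
  depth: 100
  render_fastq: true
  fitness: {OTUD6B: -0.8, USP7: -0.5}
ip: {n_background: 150, n_true: 10}
gsea: {n_genes: 500, n_perm: 500}
EOF
dubscreen run-all --config config.yaml --out-dir out/
```

Individual stages, e.g.:

```bash
dubscreen simulate-screen --out-dir sim/ --render-fastq --fitness OTUD6B=-0.8 --seed 1
dubscreen count --out-dir counts/ --manifest sim/manifest.csv \
    --fastq T0_r1=sim/fastq/T0_r1.fastq --fastq T14_r1=sim/fastq/T14_r1.fastq
dubscreen score --out-dir score/ --manifest sim/manifest.csv --counts counts/counts.tsv
```

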