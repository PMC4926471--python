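# methylinfo

Information-thermodynamic statistics for methylome and SNP region analysis.

The package computes two region statistics over a shared genome partition —
**IR**, the information gained/lost between a reference and a subject
methylome (sum of per-site binary-entropy differences, in bits), and
**LCR**, the summed log2 normalized SNP supporting-read counts, read as the
uncertainty of *not* observing a SNP under a Boltzmann model — and drives a
full analysis chain on the resulting samples × regions matrices:

* region taxonomy by |IR| magnitude (LMR / VMR / HMR) and exceedance stats;
* Boltzmann model of SNP fixation: forward CDF, inverse uncertainty,
  CDF/MLE fitting and P-P diagnostic data;
* filter feature selection: multi-class (pairwise rank) AUC, Fayyad–Irani
  MDL discretization + chi-squared scoring, PCA at a variance threshold,
  PC-correlation region extraction, chi-squared power ratios;
* classifier chains (`auc+pca+lda`, `pca+svm`, …) with repeated stratified
  k-fold cross-validation (all stages refit per fold — no leakage) and
  quantile reporting;
* UPGMA dendrograms (Newick export) on linear-discriminant coordinates and
  a permutation Mantel test between distance matrices;
* a joint (IR, LCR) dependence model: Weibull and skew-Laplace marginals
  with an FGM copula, plus 2-D kernel densities;
* a synthetic-data module generating methylome/SNP cohorts with
  group-structured hotspots, Boltzmann-distributed SNP support and tunable
  FGM coupling — with analytic ground truth — in the exact file dialects the
  pipeline reads.

## File formats

* methylation TSV: `chrom  pos  strand  context  meth_reads  total_reads`
  (1-based positions; context CG/CHG/CHH; optional header; gzip ok)
* SNP TSV: `chrom  pos  ref_base  alt_base  quality  r  concordance`
* UCSC wiggle (`fixedStep` / `variableStep`) methylation-level tracks
* two-column chromosome sizes; `sample_id  label` tables;
  region matrices as TSV with a region-id header row.

## CLI

Every stage is a subcommand of `methylinfo`, driven by one YAML config and a
single master seed (fanned out per stage by name hashing, so stages are
independently reproducible):

```sh
methylinfo run-all -c config.yaml            # simulate + full analysis
methylinfo simulate -c config.yaml           # or stage by stage:
methylinfo ir -c config.yaml
methylinfo cv -c config.yaml                 # Table-style accuracy quantiles
methylinfo mantel -c config.yaml
```

A minimal config (all keys optional; defaults shown in
`methylinfo.cli.DEFAULT_CONFIG` — quality ≥ 25, 80% PCA variance,
1000×10-fold CV, 7000 Mantel permutations):

```yaml
seed: 1
outdir: results_run
simulation: {n_groups: 3, samples_per_group: 15, n_regions: 500, theta: 0.5}
chains: [auc+pca+lda, auc+pca+svm, auc+svm]
cv: {repeats: 100, folds: 10}
```

To run on your own data instead of a simulated cohort, point `paths` at
existing files (`methylation_dir`, `snp_dir`, `labels`, `chrom_sizes`,
`reference`) and skip the `simulate` stage.

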