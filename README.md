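# nicheomics

A tested, reusable pipeline for multi-omics analysis of bone-marrow stromal
niches. It covers the full path from raw counts to an interaction map:

- **simulate** — synthetic inputs with known ground truth: negative-binomial
  counts over 7 stromal populations × conditions (ctrl/AML) with embedded
  cluster archetypes and ternary deregulation effects, log-normal secretome
  intensities with a deregulated ligand subset, and a ligand-receptor pair
  table with planted coherent pairs.
- **normalization** — median-of-ratios size factors, regularized log10
  transform, per-stromal-type z-scored profiles, sample correlation matrix.
- **de** — two-group negative-binomial Wald tests (per-stromal condition
  contrasts and all pairwise stromal contrasts) with method-of-moments
  dispersions, Benjamini-Hochberg adjustment and DE calls.
- **clustering** — density-peak clustering of z-profiles (decision graph,
  chain assignment, halo exclusion), compactness scoring, hypergeometric
  cluster annotation, per-cluster condition shifts.
- **patterns** — per-gene ternary deregulation vectors and an EM-fitted
  ternary-emission mixture with symmetric flip noise grouping genes into
  shared or cell-type-specific deregulation patterns.
- **secretome** — quantile normalization, log2 transform, empirical-Bayes
  moderated t-tests with inverse-trigamma variance-prior estimation.
- **interactome** — joins significant secretome ligands with significant
  receptor genes per stromal type, applies the directional coherence filter,
  and builds a weighted bipartite stromal-type × pathway graph.
- **layout** — deterministic under-damped force dynamics (spring attraction,
  inverse-square repulsion, viscous damping) for 2-D graph layout.

## CLI

Every stage is a subcommand; `--seed`, `--fdr` and `--outdir` are global:

```bash
# end-to-end on synthetic data (byte-identical given the same seed)
nicheomics --seed 1 --outdir results/run run-all

# individual stages
nicheomics --seed 1 --outdir sim simulate --config cfg.yaml
nicheomics normalize --counts sim/counts.tsv --meta sim/metadata.tsv \
    --out normexpr.tsv --factors-out sf.tsv
nicheomics de --counts sim/counts.tsv --meta sim/metadata.tsv \
    --contrast AML:ctrl --out de/
nicheomics cluster --profiles normexpr.zprofiles.tsv --k 8 --dc auto --out clusters/
nicheomics patterns --de-dir de/ --mmax 20 --out patterns.tsv
nicheomics secretome --intensities sim/secretome.tsv \
    --meta sim/secretome_metadata.tsv --out secretome_de.tsv
nicheomics interactome --secretome secretome_de.tsv --de-dir de/ \
    --pairs sim/lr_pairs.tsv --out edges.tsv --graph graph.graphml
nicheomics --seed 3 layout --graph graph.graphml --out coords.tsv
```

All tabular formats are TSV (`#` comment lines ignored); graphs are written
as edge-list TSV and GraphML; gene sets load from GMT.

## Notes on scope

Raw read processing, tSNE/3D-PCA rendering, meta-analysis joins against
external datasets, and heatmap drawing are out of scope. The DE stage is a
deliberately compact reimplementation: no dispersion shrinkage-to-trend,
outlier filtering or independent filtering; the Wald statistic is referred
to a t distribution with residual degrees of freedom, which restores type-I
calibration under noisy per-gene dispersion estimates.
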