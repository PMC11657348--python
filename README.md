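# diffnet

Differential partial-correlation network analysis for two-condition omics
data (metabolomics-oriented, but any feature × sample abundance matrix
works). From a raw abundance table and a two-level condition label, the
pipeline:

1. **preprocess** — missingness filtering (default: drop features missing in
   >30% of samples), median imputation, optional covariate residualization
   (residuals shifted to min 0), natural-log transform, per-condition
   standardization, conditioning diagnostics (eigen-spectrum of the Pearson
   correlation matrix), and node-level differential analysis
   (pooled-variance Student's t with BH-FDR).
2. **aggregation** (optional) — collapse highly correlated and/or same-class
   features into aggregate features (correlation / knowledge / hybrid
   methods).
3. **estimation** — graphical-lasso precision estimation with BIC selection
   of a shared regularization parameter λ (exhaustive coarse-to-fine search,
   asymptotic c·√(ln m / n) grid, or user-supplied candidates).
4. **stability** — resampling-based edge selection probabilities
   (half-sampling without replacement, optional balancing of unequal
   groups), and the selection-probability-weighted penalty
   ρ_ij = λ/(ε + p_ij) used for the final fit.
5. **networks** — final per-condition networks in three modes
   (`stability_weighted`, `bic_per_group`, `approx` with
   λ_k = √(ln m / n_k)), partial correlations, shared/condition-specific
   edge classification, and edge-strength filtering.
6. **consensus clustering** — seven igraph community-detection algorithms
   vote; node pairs co-clustered by at least a fraction τ of them (τ ≥ 0.5,
   i.e. ≥ 4 of 7 at the default) and adjacent in the union graph form
   modules, iterated to a fixed point.
7. **enrichment** — a network-based mixed-model test per module: sample
   vectors are modeled as N(Λβ, σ_g²ΛΛᵀ + σ_0²I) with ΛΛᵀ = Θ⁻¹, variance
   components fitted by REML jointly over both conditions, module mean
   contrasts studentized and referred to a t distribution with
   Satterthwaite degrees of freedom, BH-FDR across modules.
8. **export** — Cytoscape-importable edge and node lists.

A fixture generator (`diffnet.simulate`) produces two-condition
multivariate-normal data with known sparse, partially shared precision
matrices (chain / hub / random / block graphs, differential edges, mean
shifts) plus exact recovery metrics.

## CLI

Each stage serializes its state into a run directory and can be executed
separately (`preprocess`, `aggregate`, `tune`, `stability`, `network`,
`cluster`, `enrich`, `export`) or chained:

```sh
diffnet run-all abundances.csv condition.csv --run-dir out/run1 \
    --tune-mode asymptotic_c --reps 1000 --subsample \
    --tau 0.5 --min-size 5 --seed 1 --workers 4
```

Input: CSV/TSV with features as rows (first column = feature ID, header =
sample IDs) plus a two-column sample→condition file. Stability selection is
bit-reproducible for a fixed `--seed` regardless of `--workers`.

## Notable conventions

- Natural log throughout; zeros/negatives under log are a hard error (apply
  a pseudo-count explicitly if you need one).
- Standardization uses the population (ddof=0) standard deviation so the
  per-condition sample covariance of standardized data has a unit diagonal.
- The selection-probability weighting is implemented as ρ = λ/(ε + p) with
  ε = 1e-4: never-selected edges are effectively forbidden (ρ = λ/ε),
  always-selected edges are penalized at ≈ λ.
- Enrichment operates on the log data standardized across *all* samples
  pooled (per-condition standardization would remove the group differences
  being tested), and re-estimates precision values on the selected support
  without L1 shrinkage before building the influence matrix.
- Network filtering is presentational: it prunes the edge table and partial
  correlations, never the precision matrices.
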