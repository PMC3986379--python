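# bloodmix

Two-stage *in silico* deconvolution of heterogeneous whole-blood
expression data.

Bulk expression of whole blood convolves two biological signals: how
the sample is composed of leukocyte sub-populations, and what each
sub-population is expressing. `bloodmix` separates them in two stages
under the linear mixing model

```
X = W · H + E
```

where `X` (samples × genes) is observed mixed expression, `W`
(samples × cell types) holds proportions on the probability simplex,
and `H` (cell types × genes) holds cell-type-specific expression.

1. **Reverse deconvolution** — estimate each sample's composition `w`
   from a marker **basis matrix** of isolated leukocyte profiles
   (neutrophils, eosinophils, monocytes, CD4 T, CD8 T, NK, B) by
   constrained least squares: `min ‖H w − x‖²` subject to `w ≥ 0`,
   `Σ w = 1`, solved by quadratic programming with per-sample KKT
   verification. Basis construction itself is part of the package:
   fold-change prefiltering plus a multinomial elastic-net selection
   path, with the candidate minimizing lymphocyte RMSE against
   clinical leukocyte differentials selected (ties to the sparsest
   basis).
2. **Forward deconvolution** — with composition in hand (measured or
   inferred), estimate group-wise cell-type expression by regressing
   each gene on `W` within each group, and call cell-type-specific
   differential expression with a label-permutation FDR for the
   one-tailed up/down hypotheses (csSAM-style, permissive FDR ≤ 0.30).
   Downstream: tissue-set hypergeometric enrichment with BH
   correction, `.rnk` export for pre-ranked GSEA, and a cross-platform
   **lymphocyte ratio score** (mean of up-regulated over mean of
   down-regulated signature genes) testable by Wilcoxon rank-sum.

The package is aimed at transcriptomics researchers who have bulk
blood (or other mixed-tissue) expression matrices and want per-sample
composition estimates and cell-type-resolved differential expression
without cell sorting. A synthetic-data generator with known ground
truth (`bloodmix.simulate`) backs every stage and is first-class,
tested code.

## Worked example

```python
import bloodmix as bm

panel, truth = bm.simulate_panel(K=7, p=1000, markers_per_type=20, replicates=5, seed=1)
markers = [g for genes in truth.marker_genes.values() for g in genes]
X, design, mix_truth = bm.simulate_mixtures(truth.profiles, n_per_group=25,
                                            noise_cv=0.2, seed=2)
basis = bm.BasisMatrix(truth.profiles.T.loc[markers], scale="linear")
result = bm.deconvolve(bm.ExpressionMatrix(X.values.loc[markers], scale="linear"), basis)
```

Running `python examples/01_mix_and_deconvolve.py` (the same
computation, with reporting) prints:

```
deconvolved 50 samples (50 solver-verified)
cell type       true mean   est mean     rmse
neutrophils         0.569      0.566   0.0323
eosinophils         0.038      0.037   0.0120
monocytes           0.125      0.125   0.0186
CD4 T cells         0.096      0.093   0.0141
CD8 T cells         0.072      0.071   0.0121
NK cells            0.052      0.053   0.0107
B cells             0.048      0.054   0.0199

lymphocyte aggregate (B + CD4 + CD8 + NK) rmse: 0.0272
```

Each RMSE is in proportion units: under 20% multiplicative measurement
noise, the estimated neutrophil fraction is off by about three
percentage points per sample, and the aggregated lymphocyte fraction by
under three — comparable to the measurement error of a clinical
leukocyte differential. The other examples walk through basis
construction (`02`), cell-type-specific differential expression with
spike-in recovery (`03`), and enrichment plus the ratio signature
(`04`).

## Command line

A thin CLI wraps the library for file-based pipelines:

```bash
bloodmix simulate    --n-per-group 24 --seed 1 --out-dir sim/
bloodmix deconvolve  --expr sim/mixtures.tsv --basis basis.tsv --scale linear --out W.tsv
bloodmix csdiff      --expr sim/mixtures.tsv --composition W.tsv \
                     --design sim/design.tsv --fdr 0.30 --out-dir de/
bloodmix enrich      --candidates lists.gmt --enrichment-matrix scores.tsv --out enrich.tsv
bloodmix ratio       --expr expr.tsv --signature sig.tsv --design design.tsv --out scores.tsv
```

All matrices travel as TSV; every run writes a provenance record with
the seed and input checksums.

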