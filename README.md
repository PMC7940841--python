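# pl21gpca

Robust, sparse, graph-regularized principal component analysis for
tumor expression data — with an evaluation harness (repeated K-means,
clustering accuracy and normalized mutual information), the planted
four-class synthetic benchmark, and downstream gene ranking plus
co-expression network-module discovery.

## The problem

Bulk and single-cell expression matrices are "high dimension, low
sample" (p genes ≫ n samples), noisy, and outlier-prone. Classical PCA
embeds the samples but (i) its squared loss is dominated by outliers,
(ii) its loadings are dense, so it cannot point at the genes that carry
the structure, and (iii) it ignores the local geometry of the samples.
This package implements a PCA variant addressing all three for the
standard workflow of unsupervised tumor-subtype clustering followed by
co-expression module analysis of the selected genes.

## The model

For X ∈ R^{p×n} (genes × samples), find loadings U (p × k) and an
orthonormal sample embedding V (n × k):

    min_{U,V}  ‖X − U Vᵀ‖_p + λ ‖U‖_{2,1} + α Tr(Vᵀ L V)
    s.t.       VᵀV = I,  0 < p < 1

* ‖·‖_p — elementwise Lp quasi-norm (robust loss; p = 0.5 default),
* ‖U‖_{2,1} = Σᵢ ‖uᵢ·‖₂ — row sparsity of the gene loadings,
* L = D − W — Laplacian of a k′-NN sample graph (k′ ≈ √n); Tr(VᵀLV)
  keeps similar samples close in the embedding.

Solved by an augmented-Lagrangian alternating-direction scheme:
row-scaled least squares for U, a smallest-k eigenproblem for V, a
generalized shrinkage step for the robust residual E, multiplier and
penalty updates (μ₀ = 10⁻², ρ = 1.2). See `docs/methods.md` for the
derivation, defaults, and numerical choices.

## Worked example

```python
import numpy as np
import pl21gpca as pl

# planted benchmark: 3000 x 80, four sample classes, sigma^2 = 0.6 noise
X, labels = pl.simulate(noise_variance=0.6, seed=0)

est = pl.PL21GPCA(n_components=4, random_state=0).fit(X.T)  # samples in rows
rep = pl.kmeans_harness(est.embedding_, 4, labels, n_runs=50, seed=0)

# gene ranking needs a small L2,1 weight (see docs/methods.md)
est_g = pl.PL21GPCA(n_components=4, lam=1.0, random_state=0).fit(X.T)
top = np.sort(pl.rank_genes(est_g.components_.T).top(600))
net = pl.build_network(X[top], gene_ids=top.tolist(), threshold=0.8)
```

This prints (via the obvious `print` calls):

```
converged: True | iterations: 98 | final relative residual: 7.7e-08
ACC_mean = 100.00%  ACC_max = 100.00%  NMI_mean = 100.00%
planted-informative genes in top-600: 72%
network: 4 modules, 105 connected genes, 1794 edges
```

Reading: the solver met its constraint tolerance in 98 sweeps; all 50
K-means restarts on the 4-dimensional embedding recover the four
planted classes exactly (the planted offsets dominate σ² = 0.6 noise);
72% of the 600 top-ranked genes are truly planted-informative rows
(chance would be 20%); and the thresholded |Pearson| ≥ 0.8 network on
those genes splits into 4 co-expression modules.

The estimator follows scikit-learn conventions (`fit`, `fit_transform`
returning the embedding, `get_params`/`set_params`, trailing-underscore
fitted attributes) and composes with sklearn pipelines and model
selection.

## Command line

```sh
pl21gpca simulate --sigma2 0.6 --seed 0 --out sim.tsv --labels-out labels.tsv
pl21gpca fit --input sim.tsv --k 4 --out run          # run_U.tsv, run_V.tsv, run_diag.json
pl21gpca evaluate --embedding run_V.tsv --labels labels.tsv --k 4 --runs 50
pl21gpca network --input sim.tsv --loadings run_U.tsv --top 600 --out edges.tsv
pl21gpca run --input matrix.tsv --labels labels.tsv --outdir out   # all-in-one
```

Input matrices are delimited text (tab or comma, auto-detected) with
gene identifiers in the first column and sample identifiers in the
header row.

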