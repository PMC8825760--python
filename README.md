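# pseudoshaper

Ensemble linear trajectory inference for single-cell RNA-seq.

Given a low-dimensional embedding of cells sampled from a linear dynamic
process (differentiation without branching or cycles), `pseudoshaper`
assigns each cell a **pseudotime** in [0, 1] — a scalar ordering the cells
along the process.  It targets exactly the setting where the widely used
principal-curves approach (SCORPIUS, Embeddr, Slingshot's final step)
struggles: trajectories that curl through the embedding, such as spirals,
where a principal curve initialised from the first principal component
collapses the ordering.

## The algorithm

For an embedding `X ∈ ℝ^{n×d}` and each `k ∈ [k_min, k_max]`
(default 2…100):

1. **Discrete pseudotime.**  Cluster `X` with k-means (one initialisation —
   deliberately non-robust, see below).  Compute the Euclidean distance
   matrix between the `k` centroids and find the *shortest Hamiltonian
   path* through them with a greedy Kruskal-style algorithm: admit edges in
   non-decreasing weight order, rejecting any that would close a cycle or
   give a vertex degree > 2 (a degree-constrained MST, which is a path).
   Rename cluster labels to their position along the path; the per-cell
   integer label is now a *discrete pseudotime* whose consecutive values
   are adjacent clusters on the trajectory.
2. **Ensemble via PCA.**  Stack the discrete pseudotimes as columns of
   `P ∈ ℝ^{n×m}`, standardize columns, and take the first two principal
   components.  Keep the columns with `|v₁ⱼ| > |v₂ⱼ|` (loadings on PC1 vs
   PC2) — the largest mutually correlated subset; columns measuring noise
   or a mis-permuted path land on PC2 and are dropped.  Min-max scale each
   kept column to [0, 1], flip those whose PC1 loading sign opposes the
   majority direction, and average per cell → a crude pseudotime.
3. **LOESS smoothing.**  Regress the crude pseudotime on its own rank with
   local quadratic regression (tri-cube weights, span 0.1) and min-max
   rescale the fit to [0, 1].

Single clusterings are unstable and the greedy path is sensitive to its
input, but those weaknesses are the point: with `nstart = 1` the columns of
`P` are dissimilar, each contributing independent information about
relative cell positions, and the PCA step keeps only the coherent majority.
The direction of the result is arbitrary; `flip_pseudotime` (1 − p) reverses
it once the user anchors the start, e.g. by marker genes.

Expression matrices are first reduced with PCA (50 components) followed by
a 3-D t-SNE at perplexity 30 — the common scRNA-seq workflow — or can be
passed as a precomputed embedding.

## Worked example

```python
import pseudoshaper as ps

ds = ps.simulate_trajectory("spiral2d", noise_sd=0.0)   # 1257 points on t·(cos t, sin t)
res = ps.infer_pseudotime(ds.coords, ps.PipelineConfig(dimred="none", seed=1))
r = ps.score(res.values, ds.t)
print(len(res.report["k_values"]), res.report["n_selected"])
print(f"{r.pearson_abs:.4f} {r.rmse:.4f} {r.spearman_abs:.4f}")
```

```
99 90
0.9996 0.0233 1.0000
```

The sweep produced 99 discrete pseudotimes (k = 2…100) of which the PCA
selection kept 90; the inferred pseudotime correlates with the generating
parameter t at |Pearson| 0.9996 (|Spearman| 1.0 — the ordering is exact)
with an RMSE of 0.023 on the [0, 1] scale after direction alignment.  A
principal curve started from PC1 cannot order this spiral at all.

The same pipeline is available from the shell:

```sh
pseudoshaper simulate --kind spiral2d --noise-sd 0.2 --seed 1 --output sim.csv
pseudoshaper run --embedding emb.csv --seed 1 --output pt.csv --report report.json
pseudoshaper evaluate --pseudotime pt.csv --truth sim.csv
```

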