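# nichecluster

Robust subclustering for single-cell RNA-seq data pooled across
datasets — built for the kind of integrative analysis used to map bone
marrow niche populations (endothelial and mesenchymal stromal cells)
across several studies, where plain community detection over-partitions
and batch effects masquerade as biology.

The toolkit provides, as a library and a thin `nichecluster` CLI:

* **Divide-and-conquer cluster trees** bounded by a high-resolution
  reference: a resolution-1 modularity partition of the
  shared-nearest-neighbor graph sets an upper limit; nodes split
  recursively via node-local re-embedding and a silhouette-selected
  resolution sweep, and stop when they occupy a single reference
  community (dotted names: A, A1, A2.1).
* **Bootstrap random-forest stability**: for every cluster pair, 5-fold
  splits repeated 10 times train a forest on the top 10 DEGs per
  cluster (Wilcoxon, average log2FC) and classify the held-out cells.
  Per cell this yields the *dominant* cluster per pair (assigned in
  more than half the runs), *recall* (correct fraction over all pairs
  and runs) and *#Correct* (pairs whose dominant is the cell's own
  cluster). Clusters in which more than 50% of cells are robustly
  misassigned at least once dissolve, their cells reassigned by a
  forest trained on the stable clusters:

      unstable(c)  ⇔  #{i ∈ c : ∃ pair with dominant_i ≠ c} / |c| > 0.5

* **Dataset-mixing entropy** per cluster, H_j = −Σ_d p_jd log p_jd,
  normalized by ln D.
* **Markers and added value**: one-vs-rest Wilcoxon marker tables
  (exact enumeration for tiny groups), recovered/FN/FP percentages of
  single-dataset vs integrated markers, Jaccard comparison of
  partitions, Spearman nearest-centroid annotation, hypergeometric
  over-representation.
* **Cross-species conservation**: for mouse cluster *i* with l_i DEGs,
  ES_i = observed / expected with
  expected = (|MVG_human ∩ MVG_mouse| / |MVG_mouse|) · l_i, plus a
  permutation null centered at ES = 1.
* **A synthetic-data generator** planting hierarchies, markers, batch
  effects and mito/immunoglobulin content in negative-binomial counts,
  so the whole pipeline is testable without downloads.

See `docs/methods.md` for the model details and design choices.

## Worked example

```python
import nichecluster as nc

# three simulated datasets sharing a planted 2 x 2 hierarchy
tree = nc.balanced_tree_spec((2, 2), n_markers=20, log2fc=3.0)
spec = nc.SimulationSpec(
    cluster_tree_spec=tree,
    cells_per_cluster_per_dataset={l.name: [60, 60, 60] for l in tree.leaves()},
    n_datasets=3, n_genes=1000, baseline_mean=1.0, batch_logfc_sd=0.2, seed=42,
)
ds, truth, _ = nc.simulate(spec)
ds = nc.normalize(ds)

ctree, part = nc.run_divide_and_conquer(ds, nc.ClusterConfig(n_mvg=500, seed=42))
print("leaves:", sorted({l.name for l in ctree.leaves()}))

genes = nc.select_mvg(ds, 300)
summary = nc.evaluate_stability(ds, part, seed=0, gene_universe=genes, n_trees=100)
print(summary.per_cluster.to_string(index=False))

ent = nc.dataset_entropy(part, dict(zip(ds.cell_ids, ds.dataset_ids)))
print(ent.per_cluster[["cluster", "entropy", "entropy_norm"]].round(3).to_string(index=False))
```

Output:

```
leaves: ['A', 'B', 'C', 'D']
cluster  frac_wrong_dominant  unstable
      A                  0.0     False
      B                  0.0     False
      C                  0.0     False
      D                  0.0     False
cluster  entropy  entropy_norm
      A    1.099           1.0
      B    1.099           1.0
      C    1.099           1.0
      D    1.099           1.0
```

The divide-and-conquer tree recovers the four planted populations
(adjusted Rand index 1.0 against the simulated truth). No cluster has
any robustly misassigned cells (`frac_wrong_dominant = 0`), so nothing
dissolves; each cluster's dataset-of-origin entropy sits at the ln 3 ≈
1.099 maximum, i.e. the three batches are perfectly mixed after
integration.

The same stages are scriptable from the shell:

```bash
nichecluster simulate --out sim/
nichecluster qc --counts sim/ --meta sim/cell_meta.tsv --out qc.tsv
nichecluster cluster --counts sim/ --meta sim/cell_meta.tsv \
    --out tree.json --partition-out partition.tsv
nichecluster stability --counts sim/ --meta sim/cell_meta.tsv \
    --partition partition.tsv --out report/
```

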