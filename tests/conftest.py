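"""Shared fixtures: tiny programmatic datasets for every pipeline stage."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import nichecluster as nc


def make_dataset(
    counts: np.ndarray,
    gene_ids=None,
    cell_ids=None,
    dataset_ids=None,
    labels=None,
) -> nc.ExpressionDataset:
    """Build an ExpressionDataset from a dense genes x cells array."""
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    gene_ids = gene_ids or [f"g{i+1}" for i in range(n_genes)]
    cell_ids = cell_ids or [f"c{i+1}" for i in range(n_cells)]
    meta = pd.DataFrame(
        {"dataset_id": dataset_ids or ["d1"] * n_cells}, index=cell_ids
    )
    if labels is not None:
        meta["label"] = labels
    return nc.ExpressionDataset(
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        counts=sp.csr_matrix(counts.astype(np.int64)),
        cell_meta=meta,
        gene_flags=nc.compute_gene_flags(gene_ids),
    )


def two_cluster_spec(
    n_markers: int = 20,
    log2fc: float = 2.5,
    cells=(60, 60),
    n_datasets: int = 2,
    n_genes: int = 500,
    seed: int = 0,
    **kwargs,
) -> nc.SimulationSpec:
    """Two well-separated planted populations X and Y."""
    tree = nc.TreeNodeSpec(
        children=[
            nc.TreeNodeSpec(name="X", n_markers=n_markers, log2fc=log2fc),
            nc.TreeNodeSpec(name="Y", n_markers=n_markers, log2fc=log2fc),
        ]
    )
    return nc.SimulationSpec(
        cluster_tree_spec=tree,
        cells_per_cluster_per_dataset={
            "X": [cells[0]] * n_datasets,
            "Y": [cells[1]] * n_datasets,
        },
        n_datasets=n_datasets,
        n_genes=n_genes,
        baseline_mean=1.0,
        seed=seed,
        **kwargs,
    )


@pytest.fixture(scope="session")
def separated_pair():
    """A normalized two-cluster dataset with strong markers (seed 0)."""
    ds, truth, _ = nc.simulate(two_cluster_spec(seed=0))
    return nc.normalize(ds), truth
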