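"""Joint embedding of multiple datasets and reference label transfer.

Integration here is deliberately simple and fully reproducible: each
gene is standardized within each dataset (removing per-dataset location
and scale, the first-order batch effect), the standardized matrices are
concatenated, and the pooled matrix is projected onto its top principal
axes.  The embedding step is pluggable — an externally computed
embedding (e.g. from an anchor-based tool) can be imported from TSV and
used by every downstream stage, which only ever consume coordinates.

Label transfer assigns each query cell the majority label among its k
nearest reference cells in the joint embedding.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io_formats import ExpressionDataset, ValidationError, concat_datasets, logger


@dataclass
class JointEmbedding:
    """Cells x n_dims coordinates with the gene basis and loadings used."""

    cell_ids: list[str]
    coords: np.ndarray
    gene_basis: list[str]
    loadings: np.ndarray  # genes x n_dims

    @property
    def n_dims(self) -> int:
        return self.coords.shape[1]

    def validate(self) -> None:
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("non-finite embedding coordinates")
        if self.n_dims > len(self.gene_basis):
            raise ValidationError("n_dims exceeds gene basis size")

    def coords_for(self, cells: Sequence[str]) -> np.ndarray:
        pos = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in cells if c not in pos]
        if missing:
            raise KeyError(f"cells missing from embedding: {missing[:10]}")
        return self.coords[[pos[c] for c in cells]]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coords, columns=[f"dim{i+1}" for i in range(self.n_dims)]
        )
        df.insert(0, "cell_id", self.cell_ids)
        return df


def standardized_matrix(
    ds: ExpressionDataset, genes: Sequence[str]
) -> np.ndarray:
    """Cells x genes matrix, z-scored per gene within each dataset.

    Genes with zero variance inside a dataset contribute zeros there
    (they carry no within-dataset information).
    """
    rows = ds.gene_index(genes)
    X = ds.norm_dense(rows).T  # cells x genes
    out = np.zeros_like(X)
    dids = ds.dataset_ids
    for did in pd.unique(dids):
        sel = dids == did
        block = X[sel]
        mu = block.mean(axis=0)
        sd = block.std(axis=0, ddof=0)
        ok = sd > 1e-12
        out[np.ix_(sel, ok)] = (block[:, ok] - mu[ok]) / sd[ok]
    return out


def joint_embed(
    datasets: Sequence[ExpressionDataset] | ExpressionDataset,
    genes: Sequence[str],
    n_dims: int = 20,
    seed: int = 0,
) -> JointEmbedding:
    """Embed all cells into a shared PCA space over the given gene basis.

    Per-dataset standardization precedes a pooled PCA; the sign of each
    axis is fixed by making its largest-magnitude gene loading positive,
    so the result is reproducible across runs and platforms.
    """
    ds = (
        datasets
        if isinstance(datasets, ExpressionDataset)
        else concat_datasets(list(datasets))
    )
    genes = list(genes)
    if not genes:
        raise ValidationError("empty gene basis")
    Z = standardized_matrix(ds, genes)
    max_dims = min(len(genes), max(ds.n_cells - 1, 1))
    if n_dims > max_dims:
        logger.warning("n_dims=%d clipped to %d", n_dims, max_dims)
        n_dims = max_dims
    pca = PCA(n_components=n_dims, svd_solver="full" if Z.shape[1] <= 500 else "randomized",
              random_state=seed)
    coords = pca.fit_transform(Z)
    loadings = pca.components_.T  # genes x n_dims
    # deterministic axis sign: largest-|loading| entry positive
    for j in range(n_dims):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            coords[:, j] *= -1.0
    emb = JointEmbedding(
        cell_ids=list(ds.cell_ids),
        coords=np.ascontiguousarray(coords),
        gene_basis=genes,
        loadings=loadings,
    )
    emb.validate()
    return emb


def write_embedding(emb: JointEmbedding, path: str | Path) -> None:
    emb.to_frame().to_csv(path, sep="\t", index=False)


def read_embedding(path: str | Path) -> JointEmbedding:
    df = pd.read_csv(path, sep="\t")
    coords = df.iloc[:, 1:].to_numpy(dtype=float)
    return JointEmbedding(
        cell_ids=df.iloc[:, 0].astype(str).tolist(),
        coords=coords,
        gene_basis=[f"external{i}" for i in range(coords.shape[1])],
        loadings=np.eye(coords.shape[1]),
    )


def transfer_labels(
    ref: ExpressionDataset,
    query: ExpressionDataset,
    emb: JointEmbedding,
    k: int = 30,
    min_score: float = 0.5,
) -> pd.DataFrame:
    """kNN majority-vote label transfer from reference to query cells.

    Each query cell takes the majority label among its k nearest
    reference cells (Euclidean distance in the embedding); the score is
    the majority fraction.  Ties are broken by smallest mean distance to
    the tied label's neighbors, then lexicographically.  Cells whose
    score falls below ``min_score`` are labeled ``"unassigned"``.
    """
    if "label" not in ref.cell_meta.columns:
        raise ValidationError("reference dataset has no label column")
    ref_labels = ref.cell_meta["label"].astype(str).to_numpy()
    ref_xy = emb.coords_for(ref.cell_ids)
    query_xy = emb.coords_for(query.cell_ids)
    if k > len(ref.cell_ids):
        logger.warning("k=%d clipped to %d reference cells", k, len(ref.cell_ids))
        k = len(ref.cell_ids)
    nn = NearestNeighbors(n_neighbors=k).fit(ref_xy)
    dist, idx = nn.kneighbors(query_xy)

    out_label, out_score = [], []
    for d_row, i_row in zip(dist, idx):
        labs = ref_labels[i_row]
        uniq, counts = np.unique(labs, return_counts=True)
        best = counts.max()
        tied = uniq[counts == best]
        if len(tied) > 1:
            mean_d = {l: d_row[labs == l].mean() for l in tied}
            m = min(mean_d.values())
            tied = sorted(l for l in tied if mean_d[l] <= m + 1e-12)
        label = str(tied[0])
        score = best / k
        if score < min_score:
            label = "unassigned"
        out_label.append(label)
        out_score.append(score)
    return pd.DataFrame(
        {"cell_id": query.cell_ids, "label": out_label, "score": out_score}
    )
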