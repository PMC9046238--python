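"""Iterative divide-and-conquer subclustering bounded by a high-resolution limit.

The procedure first computes a single high-resolution modularity
partition of all cells (resolution 1 on the shared-nearest-neighbor
graph) as the *cluster limit*: no node of the hierarchy is ever split
into more communities than the high-resolution reference supports
within that node, and a node whose cells occupy at most one reference
community is a terminal leaf.

Each node that may still split is re-analysed locally: variable genes
are re-selected among its own cells, a node-local embedding is
computed, and a resolution sweep over the node-local graph picks the
sub-partition with the best mean silhouette, subject to the reference
cap.  Leaves carry an explicit termination reason.  Cluster names
follow the dotted convention A, A1, A2.1, ...
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Sequence

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_score
from sklearn.neighbors import NearestNeighbors

from .integrate import JointEmbedding, joint_embed
from .io_formats import ExpressionDataset, Partition, ValidationError, logger
from .preprocess import select_mvg

TERMINATION_REASONS = ("highres_single", "max_level", "too_small", "no_substructure")


@dataclass
class ClusterConfig:
    """Knobs of the divide-and-conquer procedure (defaults documented)."""

    n_mvg: int = 2000            # variable genes re-selected per node
    n_dims: int = 20             # embedding dimensions
    knn_k: int = 20              # neighbors for the SNN graph
    snn_cutoff: float = 1.0 / 15.0   # Jaccard weight below which edges are pruned
    highres_resolution: float = 1.0  # resolution of the cluster-limit reference
    resolution_grid: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(1, 13))
    min_cells: int = 40          # nodes smaller than this are never split
    min_silhouette: float = 0.05  # quality floor: a split below this is refused
    max_levels: int = 4
    seed: int = 0


@dataclass
class ClusterNode:
    name: str
    cell_ids: list[str]
    level: int
    children: list["ClusterNode"] = field(default_factory=list)
    termination_reason: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self):
        yield self
        for ch in self.children:
            yield from ch.walk()

    def leaves(self) -> list["ClusterNode"]:
        return [n for n in self.walk() if n.is_leaf]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "level": self.level,
            "n_cells": len(self.cell_ids),
            "cell_ids": list(self.cell_ids),
            "termination_reason": self.termination_reason,
            "children": [c.to_dict() for c in self.children],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClusterNode":
        return cls(
            name=d["name"],
            cell_ids=list(d["cell_ids"]),
            level=int(d["level"]),
            children=[cls.from_dict(c) for c in d["children"]],
            termination_reason=d.get("termination_reason"),
        )


@dataclass
class ClusterTree:
    root: ClusterNode
    params: dict = field(default_factory=dict)

    def leaves(self) -> list[ClusterNode]:
        return self.root.leaves()

    def leaf_partition(self) -> Partition:
        cells, labels = [], []
        for leaf in self.leaves():
            cells.extend(leaf.cell_ids)
            labels.extend([leaf.name or "root"] * len(leaf.cell_ids))
        return Partition(cell_ids=cells, labels=labels)

    def validate(self) -> None:
        names = [n.name for n in self.root.walk()]
        if len(names) != len(set(names)):
            raise ValidationError("duplicate node names in tree")
        for node in self.root.walk():
            if node.children:
                child_cells = [c for ch in node.children for c in ch.cell_ids]
                if sorted(child_cells) != sorted(node.cell_ids):
                    raise ValidationError(f"children of {node.name!r} do not partition it")
            elif not node.cell_ids:
                raise ValidationError(f"empty leaf {node.name!r}")

    def to_dict(self) -> dict:
        return {"params": self.params, "root": self.root.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "ClusterTree":
        return cls(root=ClusterNode.from_dict(d["root"]), params=dict(d.get("params", {})))


def child_name(parent: str, index: int, level: int) -> str:
    """Dotted naming: level 1 = A, B, ...; level 2 = A1; level >= 3 = A2.1."""
    if level == 1:
        letters = string.ascii_uppercase
        if index - 1 < len(letters):
            return letters[index - 1]
        return f"Z{index - len(letters)}"
    if level == 2:
        return f"{parent}{index}"
    return f"{parent}.{index}"


# ---------------------------------------------------------------------------
# Graph construction and community detection
# ---------------------------------------------------------------------------

def knn_graph(
    emb: JointEmbedding | np.ndarray,
    k: int = 20,
    snn_cutoff: float = 1.0 / 15.0,
) -> ig.Graph:
    """Shared-nearest-neighbor graph with Jaccard edge weights.

    Candidate edges are the union of each cell's k nearest neighbors;
    each edge is weighted by the Jaccard overlap of the two cells'
    neighbor sets (self included) and pruned below ``snn_cutoff``.
    """
    coords = emb.coords if isinstance(emb, JointEmbedding) else np.asarray(emb, float)
    names = emb.cell_ids if isinstance(emb, JointEmbedding) else [str(i) for i in range(len(coords))]
    n = len(coords)
    if k >= n:
        raise ValidationError(f"k={k} must be smaller than the number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)  # first neighbor is the cell itself

    rows = np.repeat(np.arange(n), k + 1)
    A = sp.csr_matrix(
        (np.ones(n * (k + 1)), (rows, idx.ravel())), shape=(n, n)
    )
    A.data[:] = 1.0
    inter = A @ A.T  # |N(u) ∩ N(v)| for pairs sharing neighbors
    cand = ((A + A.T) > 0)  # kNN-union candidate edges
    shared = inter.multiply(cand).tocoo()

    upper = shared.row < shared.col
    u, v, c = shared.row[upper], shared.col[upper], shared.data[upper]
    jac = c / (2 * (k + 1) - c)
    keep = jac >= snn_cutoff
    g = ig.Graph(n=n, edges=list(zip(u[keep].tolist(), v[keep].tolist())))
    g.es["weight"] = jac[keep].tolist()
    g.vs["name"] = names
    return g


def graph_partition(graph: ig.Graph, resolution: float = 1.0, seed: int = 0) -> Partition:
    """Modularity community detection at a given resolution, seeded.

    Uses the Leiden optimizer on the resolution-parameterised modularity
    objective; disconnected components are handled independently.
    """
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight" if "weight" in graph.es.attributes() else None,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    membership = np.array(part.membership)
    return Partition(
        cell_ids=list(graph.vs["name"]),
        labels=[str(m) for m in membership],
    )


def highres_reference(
    emb: JointEmbedding,
    k: int = 20,
    resolution: float = 1.0,
    seed: int = 0,
    snn_cutoff: float = 1.0 / 15.0,
) -> Partition:
    """High-resolution partition used as the cluster-count upper bound."""
    g = knn_graph(emb, k=k, snn_cutoff=snn_cutoff)
    return graph_partition(g, resolution=resolution, seed=seed)


def occupied_highres_communities(cells: Sequence[str], highres: Partition) -> int:
    """Count reference communities with >50% of their cells inside ``cells``."""
    inside = set(cells)
    counts: dict[str, list[int]] = {}
    for c, l in zip(highres.cell_ids, highres.labels):
        tot_in = counts.setdefault(l, [0, 0])
        tot_in[0] += 1
        if c in inside:
            tot_in[1] += 1
    return sum(1 for tot, inn in counts.values() if inn > tot / 2)


# ---------------------------------------------------------------------------
# Node splitting
# ---------------------------------------------------------------------------

def split_node(
    node: ClusterNode,
    ds: ExpressionDataset,
    highres: Partition,
    config: ClusterConfig,
) -> list[ClusterNode]:
    """Split one node or mark it terminal; returns the (possibly new) children.

    Termination: nodes above ``max_levels``, smaller than ``min_cells``,
    or occupying <= 1 high-resolution community become leaves.  Otherwise
    the node is re-embedded locally and a resolution sweep picks the
    sub-partition with the best mean silhouette among candidates with
    2..n_occupied communities.
    """
    n = len(node.cell_ids)
    if node.level >= config.max_levels:
        node.termination_reason = "max_level"
        return []
    if n < config.min_cells:
        node.termination_reason = "too_small"
        return []
    occupied = occupied_highres_communities(node.cell_ids, highres)
    if occupied <= 1:
        node.termination_reason = "highres_single"
        return []

    sub = ds.subset_cells(node.cell_ids)
    genes = select_mvg(sub, n=min(config.n_mvg, sub.n_genes))
    emb = joint_embed(sub, genes, n_dims=config.n_dims, seed=config.seed)
    k = min(config.knn_k, n - 1)
    graph = knn_graph(emb, k=k, snn_cutoff=config.snn_cutoff)
    dist = squareform(pdist(emb.coords))

    best: tuple[float, float, np.ndarray] | None = None  # (sil, -res, labels)
    for res in config.resolution_grid:
        part = graph_partition(graph, resolution=res, seed=config.seed)
        labels = np.array(part.labels)
        ncl = len(set(labels))
        if ncl < 2 or ncl > occupied:
            continue
        sil = silhouette_score(dist, labels, metric="precomputed")
        if sil < config.min_silhouette:
            continue
        if best is None or sil > best[0] + 1e-12:
            best = (sil, res, labels)
    if best is None:
        node.termination_reason = "no_substructure"
        logger.debug("node %r: no valid sub-partition (occupied=%d)", node.name, occupied)
        return []

    sil, res, labels = best
    logger.debug(
        "node %r: split into %d at resolution %.1f (silhouette %.3f, cap %d)",
        node.name, len(set(labels)), res, sil, occupied,
    )
    # children ordered by size (largest first) for stable naming
    order = pd.Series(labels).value_counts().index.tolist()
    children = []
    for i, lab in enumerate(order, start=1):
        cells = [c for c, l in zip(node.cell_ids, labels) if l == lab]
        children.append(
            ClusterNode(
                name=child_name(node.name, i, node.level + 1),
                cell_ids=cells,
                level=node.level + 1,
            )
        )
    node.children = children
    return children


def run_divide_and_conquer(
    ds: ExpressionDataset | Sequence[ExpressionDataset],
    config: ClusterConfig | None = None,
) -> tuple[ClusterTree, Partition]:
    """Recursive divide-and-conquer clustering of all cells.

    Computes the global embedding and the high-resolution cluster-limit
    reference once, then splits nodes breadth-first until every node is
    a leaf.  Returns the tree and its flat leaf partition.
    """
    config = config or ClusterConfig()
    from .io_formats import concat_datasets

    if not isinstance(ds, ExpressionDataset):
        ds = concat_datasets(list(ds))
    if ds.norm is None:
        raise ValidationError("normalized layer missing; run normalize() first")

    genes = select_mvg(ds, n=min(config.n_mvg, ds.n_genes))
    emb = joint_embed(ds, genes, n_dims=config.n_dims, seed=config.seed)
    highres = highres_reference(
        emb,
        k=min(config.knn_k, ds.n_cells - 1),
        resolution=config.highres_resolution,
        seed=config.seed,
        snn_cutoff=config.snn_cutoff,
    )
    n_ref = len(set(highres.labels))
    logger.info("high-resolution reference: %d communities", n_ref)

    root = ClusterNode(name="", cell_ids=list(ds.cell_ids), level=0)
    frontier = [root]
    while frontier:
        node = frontier.pop()
        frontier.extend(split_node(node, ds, highres, config))

    tree = ClusterTree(
        root=root,
        params={
            "n_mvg": config.n_mvg,
            "n_dims": config.n_dims,
            "knn_k": config.knn_k,
            "highres_resolution": config.highres_resolution,
            "resolution_grid": list(config.resolution_grid),
            "min_cells": config.min_cells,
            "max_levels": config.max_levels,
            "seed": config.seed,
            "n_highres_communities": n_ref,
        },
    )
    tree.validate()
    part = tree.leaf_partition()
    logger.info("divide-and-conquer finished: %d leaves", len(tree.leaves()))
    return tree, part
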