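"""Synthetic multi-dataset scRNA-seq counts with planted structure.

The generator emulates the situation the pipeline is built for: several
datasets (batches) profiling the same tissue, a hierarchy of cell
populations with marker genes planted at each level of the hierarchy,
per-dataset batch effects, and mitochondrial / immunoglobulin gene
classes with controllable per-cell content so the QC filters have
something to act on.

Counts are negative binomial (gamma-Poisson): for gene g in cell c of
dataset d,

    mu[g,c] = baseline_mean * f_g * 2^(sum of marker log2FCs on the
              path to c's leaf that mark g) * 2^(batch shift of g in d),

with f_g a unit-mean lognormal per-gene factor, the batch shift drawn
N(0, batch_logfc_sd) per gene and dataset, and a shared NB dispersion
(size) across genes.  Mitochondrial/immunoglobulin gene means are
scaled per cell so the expected flagged-class count fraction matches a
per-cell target drawn from the configured distribution.

Everything is reproducible from the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .cluster_tree import ClusterNode, ClusterTree
from .io_formats import (
    ExpressionDataset,
    Partition,
    ValidationError,
    compute_gene_flags,
)


@dataclass
class TreeNodeSpec:
    """One node of the planted hierarchy: markers apply to the whole clade."""

    name: str = ""
    n_markers: int = 0
    log2fc: float = 0.0
    children: list["TreeNodeSpec"] = field(default_factory=list)

    def walk(self):
        yield self
        for ch in self.children:
            yield from ch.walk()

    def leaves(self) -> list["TreeNodeSpec"]:
        return [n for n in self.walk() if not n.children]


@dataclass
class SimulationSpec:
    """Study conditions of a synthetic multi-dataset experiment.

    cells_per_cluster_per_dataset maps each leaf name of the tree to a
    per-dataset cell count (zeros allowed to emulate populations missing
    from a dataset).  baseline_mean is the expected counts/gene/cell for
    an unmarked gene; dispersion is the NB size parameter (smaller =
    noisier); batch_logfc_sd is the per-gene, per-dataset log2 shift SD.
    pct_mito / pct_ig are (mean, sd) of the per-cell flagged-class
    fraction targets.
    """

    cluster_tree_spec: TreeNodeSpec
    cells_per_cluster_per_dataset: Mapping[str, Sequence[int]]
    n_datasets: int = 3
    n_genes: int = 2000
    baseline_mean: float = 0.5
    dispersion: float = 2.0
    batch_logfc_sd: float = 0.0
    gene_mean_sd: float = 1.0
    n_mito_genes: int = 10
    n_ig_genes: int = 5
    pct_mito: tuple[float, float] = (0.02, 0.005)
    pct_ig: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def validate(self) -> None:
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be > 0")
        if self.baseline_mean <= 0:
            raise ValidationError("baseline_mean must be > 0")
        if self.batch_logfc_sd < 0:
            raise ValidationError("batch_logfc_sd must be >= 0")
        leaves = {n.name for n in self.cluster_tree_spec.leaves()}
        table = set(self.cells_per_cluster_per_dataset)
        if leaves != table:
            raise ValidationError(
                f"cell table keys {sorted(table)} != tree leaves {sorted(leaves)}"
            )
        total = 0
        for name, counts in self.cells_per_cluster_per_dataset.items():
            counts = list(counts)
            if len(counts) != self.n_datasets:
                raise ValidationError(f"{name}: need {self.n_datasets} per-dataset counts")
            if any(c < 0 for c in counts):
                raise ValidationError(f"{name}: negative cell count")
            total += sum(counts)
        if total == 0:
            raise ValidationError("simulation has zero cells in total")
        for node in self.cluster_tree_spec.walk():
            if not np.isfinite(node.log2fc):
                raise ValidationError(f"node {node.name!r}: non-finite log2FC")
            if node.n_markers < 0:
                raise ValidationError(f"node {node.name!r}: negative marker count")
        n_markers = sum(n.n_markers for n in self.cluster_tree_spec.walk())
        if self.n_mito_genes + self.n_ig_genes + n_markers > self.n_genes:
            raise ValidationError("n_genes too small for flagged genes + markers")


def balanced_tree_spec(
    branching: Sequence[int], n_markers: int = 20, log2fc: float = 2.0
) -> TreeNodeSpec:
    """Convenience: a uniform hierarchy, e.g. branching=(2, 3) -> 6 leaves."""
    def build(name: str, level: int) -> TreeNodeSpec:
        node = TreeNodeSpec(
            name=name, n_markers=n_markers if level > 0 else 0,
            log2fc=log2fc if level > 0 else 0.0,
        )
        if level < len(branching):
            sep = "" if level <= 1 else "."
            node.children = [
                build(f"{name}{sep}{i + 1}" if level >= 1 else chr(65 + i), level + 1)
                for i in range(branching[level])
            ]
        return node
    return build("", 0)


def simulate(spec: SimulationSpec) -> tuple[ExpressionDataset, Partition, ClusterTree]:
    """Draw a multi-dataset count matrix with planted hierarchy and markers.

    Returns the merged dataset (with dataset_id metadata and gene
    flags), the ground-truth leaf partition, and the ground-truth
    cluster tree over the simulated cell ids.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    # gene universe: mito genes first, then immunoglobulin, then regular
    gene_ids = (
        [f"mt-Sim{i}" for i in range(spec.n_mito_genes)]
        + [f"Igh-sim{i}" for i in range(spec.n_ig_genes)]
        + [f"Gene{i:05d}" for i in range(spec.n_genes - spec.n_mito_genes - spec.n_ig_genes)]
    )
    n_flagged = spec.n_mito_genes + spec.n_ig_genes

    # assign marker gene indices clade by clade (disjoint blocks)
    marker_of: dict[str, list[int]] = {}
    cursor = n_flagged
    for node in spec.cluster_tree_spec.walk():
        marker_of[node.name] = list(range(cursor, cursor + node.n_markers))
        cursor += node.n_markers

    # per-leaf marker effects accumulated along the path from the root
    leaf_effects: dict[str, list[tuple[int, float]]] = {}

    def collect(node: TreeNodeSpec, acc: list[tuple[int, float]]) -> None:
        acc = acc + [(g, node.log2fc) for g in marker_of[node.name]]
        if node.children:
            for ch in node.children:
                collect(ch, acc)
        else:
            leaf_effects[node.name] = acc

    collect(spec.cluster_tree_spec, [])

    leaves = [n.name for n in spec.cluster_tree_spec.leaves()]
    datasets = [f"dataset{d + 1}" for d in range(spec.n_datasets)]

    # unit-mean lognormal per-gene baseline factors; marker genes draw from
    # the same law truncated to [0.5, 2]x baseline: markers of near-silent
    # genes would be markers in name only, and real marker genes are
    # moderately expressed rather than the most abundant transcripts
    s = spec.gene_mean_sd
    gene_factor = rng.lognormal(mean=-(s**2) / 2, sigma=s, size=spec.n_genes)
    marker_idx = np.array(
        [i for idxs in marker_of.values() for i in idxs], dtype=int
    )
    if marker_idx.size and s > 0:
        from scipy.stats import norm as _norm

        mu_ln = -(s**2) / 2
        lo = _norm.cdf((np.log(0.5) - mu_ln) / s)
        hi = _norm.cdf((np.log(2.0) - mu_ln) / s)
        u = rng.uniform(lo, hi, size=marker_idx.size)
        gene_factor[marker_idx] = np.exp(mu_ln + s * _norm.ppf(u))
    base = spec.baseline_mean * gene_factor

    # per-gene per-dataset batch shifts (log2 units)
    batch = (
        rng.normal(0.0, spec.batch_logfc_sd, size=(spec.n_datasets, spec.n_genes))
        if spec.batch_logfc_sd > 0
        else np.zeros((spec.n_datasets, spec.n_genes))
    )

    cell_ids: list[str] = []
    cell_dataset: list[str] = []
    cell_leaf: list[str] = []
    blocks: list[sp.csr_matrix] = []
    for d, did in enumerate(datasets):
        for leaf in leaves:
            n_cells = int(list(spec.cells_per_cluster_per_dataset[leaf])[d])
            if n_cells == 0:
                continue
            mu_gene = base * np.exp2(batch[d])
            for g, lfc in leaf_effects[leaf]:
                mu_gene[g] = mu_gene[g] * 2.0**lfc

            mu = np.tile(mu_gene[:, None], (1, n_cells))
            # flagged-class content: scale mito/ig means to per-cell targets
            reg_total = mu[n_flagged:, :].sum(axis=0)
            m_t = np.clip(rng.normal(*spec.pct_mito, size=n_cells), 0.0, 0.45)
            i_t = np.clip(rng.normal(*spec.pct_ig, size=n_cells), 0.0, 0.45)
            denom = np.maximum(1.0 - m_t - i_t, 1e-6)
            if spec.n_mito_genes:
                mu[: spec.n_mito_genes, :] = (
                    m_t / denom * reg_total / spec.n_mito_genes
                )[None, :]
            if spec.n_ig_genes:
                mu[spec.n_mito_genes:n_flagged, :] = (
                    i_t / denom * reg_total / spec.n_ig_genes
                )[None, :]

            lam = rng.gamma(spec.dispersion, mu / spec.dispersion)
            counts = rng.poisson(lam).astype(np.int64)
            blocks.append(sp.csr_matrix(counts))
            for j in range(n_cells):
                cell_ids.append(f"{did}:{leaf}:{j}")
            cell_dataset.extend([did] * n_cells)
            cell_leaf.extend([leaf] * n_cells)

    counts = sp.hstack(blocks, format="csr")
    meta = pd.DataFrame(
        {"dataset_id": cell_dataset, "label": cell_leaf}, index=cell_ids
    )
    ds = ExpressionDataset(
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        counts=counts,
        cell_meta=meta,
        gene_flags=compute_gene_flags(gene_ids),
    )
    truth = Partition(cell_ids=list(cell_ids), labels=list(cell_leaf))

    cells_by_leaf: dict[str, list[str]] = {}
    for c, l in zip(cell_ids, cell_leaf):
        cells_by_leaf.setdefault(l, []).append(c)

    def to_node(node_spec: TreeNodeSpec, level: int) -> ClusterNode:
        children = [to_node(ch, level + 1) for ch in node_spec.children]
        if children:
            cells = [c for ch in children for c in ch.cell_ids]
        else:
            cells = cells_by_leaf.get(node_spec.name, [])
        return ClusterNode(
            name=node_spec.name,
            cell_ids=cells,
            level=level,
            children=children,
            termination_reason=None if children else "highres_single",
        )

    tree = ClusterTree(root=to_node(spec.cluster_tree_spec, 0), params={"seed": spec.seed})
    return ds, truth, tree


def planted_marker_genes(spec: SimulationSpec) -> dict[str, list[str]]:
    """Marker gene names per clade, as :func:`simulate` assigns them."""
    gene_ids = (
        [f"mt-Sim{i}" for i in range(spec.n_mito_genes)]
        + [f"Igh-sim{i}" for i in range(spec.n_ig_genes)]
        + [f"Gene{i:05d}" for i in range(spec.n_genes - spec.n_mito_genes - spec.n_ig_genes)]
    )
    out: dict[str, list[str]] = {}
    cursor = spec.n_mito_genes + spec.n_ig_genes
    for node in spec.cluster_tree_spec.walk():
        out[node.name] = [gene_ids[i] for i in range(cursor, cursor + node.n_markers)]
        cursor += node.n_markers
    return out


# ---------------------------------------------------------------------------
# Cross-species fixture
# ---------------------------------------------------------------------------

@dataclass
class CrossSpeciesFixture:
    mouse_mvg: set
    human_mvg: set
    cluster_degs: dict[str, set]
    baseline_overlap_count: int
    expected: dict[str, float]  # expected shared count per cluster


def simulate_cross_species(
    n_universe: int,
    n_human_mvg: int,
    baseline_overlap: float,
    cluster_degs: Sequence[tuple[int, int]],
    seed: int = 0,
) -> CrossSpeciesFixture:
    """Gene sets with exact planted cross-species overlaps.

    The mouse variable-gene universe has ``n_universe`` symbols; the
    human set shares ``round(baseline_overlap * n_human_mvg)`` of them
    (under the case-rule ortholog mapping).  Each ``(l_i, planted)``
    entry yields a cluster DEG list of size l_i sharing exactly
    ``planted`` genes with the human set.
    """
    rng = np.random.default_rng(seed)
    overlap_count = int(round(baseline_overlap * n_human_mvg))
    if overlap_count > n_universe:
        raise ValidationError("baseline overlap exceeds universe size")
    if overlap_count > n_human_mvg:
        raise ValidationError("baseline overlap exceeds human set size")

    universe = [f"Sim{i:05d}" for i in range(n_universe)]
    shared_idx = rng.choice(n_universe, size=overlap_count, replace=False)
    shared = {universe[i] for i in shared_idx}
    nonshared = [g for g in universe if g not in shared]
    human = {g.upper() for g in shared} | {
        f"HUMANONLY{i}" for i in range(n_human_mvg - overlap_count)
    }

    degs: dict[str, set] = {}
    expected: dict[str, float] = {}
    shared_list = sorted(shared)
    for i, (l_i, planted) in enumerate(cluster_degs, start=1):
        if planted > l_i:
            raise ValidationError(f"cluster {i}: planted overlap {planted} > l_i {l_i}")
        if planted > overlap_count:
            raise ValidationError(f"cluster {i}: planted overlap exceeds baseline overlap")
        if l_i - planted > len(nonshared):
            raise ValidationError(f"cluster {i}: not enough non-shared genes")
        pick_s = rng.choice(len(shared_list), size=planted, replace=False)
        pick_n = rng.choice(len(nonshared), size=l_i - planted, replace=False)
        degs[f"C{i}"] = {shared_list[j] for j in pick_s} | {nonshared[j] for j in pick_n}
        expected[f"C{i}"] = overlap_count / n_universe * l_i
    return CrossSpeciesFixture(
        mouse_mvg=set(universe),
        human_mvg=human,
        cluster_degs=degs,
        baseline_overlap_count=overlap_count,
        expected=expected,
    )
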