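"""Marker detection and cluster characterization statistics.

Differential expression between cell groups uses the two-sided Wilcoxon
rank-sum test on the normalized layer: a tie-corrected normal
approximation in general, and exact enumeration over rank arrangements
when both groups have at most 10 cells.  Effect size is the average
log2 fold change of de-logged means with a pseudocount of 1.  Multiple
testing is controlled with Benjamini-Hochberg over the gene universe.

The module also provides the added-value comparison between integrated
and single-dataset marker sets, Jaccard comparison of partitions,
nearest-centroid Spearman annotation against reference profiles, a
generic hypergeometric over-representation test, and cluster-mean
expression summaries.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, mannwhitneyu, rankdata
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionDataset, Partition, ValidationError, logger

MARKER_COLUMNS = ["gene", "cluster", "avg_log2fc", "p", "p_adj", "pct_in", "pct_out"]

EXACT_MAX_GROUP = 10  # exact rank enumeration when both groups are this small


# ---------------------------------------------------------------------------
# Rank-sum machinery
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _rank_combinations(n: int, nx: int) -> np.ndarray:
    return np.array(list(combinations(range(n), nx)), dtype=np.intp)


def exact_ranksum_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Exact two-sided rank-sum p by enumerating all rank arrangements.

    p is the fraction of arrangements whose rank sum deviates from its
    null mean at least as much as the observed one; ties are handled by
    mid-ranks, which the enumeration respects exactly.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    nx, n = len(x), len(pooled)
    w_obs = ranks[:nx].sum()
    mu = nx * (n + 1) / 2.0
    combos = _rank_combinations(n, nx)
    w_all = ranks[combos].sum(axis=1)
    return float(np.mean(np.abs(w_all - mu) >= np.abs(w_obs - mu) - 1e-9))


def ranksum_p_matrix(Xa: np.ndarray, Xb: np.ndarray) -> np.ndarray:
    """Two-sided rank-sum p per row of two genes x cells matrices.

    Uses exact enumeration when both groups have <= 10 cells, otherwise
    the tie-corrected normal approximation.
    """
    na, nb = Xa.shape[1], Xb.shape[1]
    if na == 0 or nb == 0:
        raise ValidationError("empty group in rank-sum test")
    if na <= EXACT_MAX_GROUP and nb <= EXACT_MAX_GROUP:
        return np.array(
            [exact_ranksum_p(Xa[i], Xb[i]) for i in range(Xa.shape[0])]
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        res = mannwhitneyu(Xa, Xb, axis=1, alternative="two-sided", method="asymptotic")
        p = np.asarray(res.pvalue, dtype=float)
    return np.where(np.isfinite(p), p, 1.0)  # fully tied rows carry no evidence


def avg_log2fc(Xa: np.ndarray, Xb: np.ndarray) -> np.ndarray:
    """log2((mean(expm1(a)) + 1) / (mean(expm1(b)) + 1)) per gene."""
    ma = np.expm1(Xa).mean(axis=1)
    mb = np.expm1(Xb).mean(axis=1)
    return np.log2((ma + 1.0) / (mb + 1.0))


def wilcoxon_de(
    ds: ExpressionDataset,
    cells_a: Sequence[str],
    cells_b: Sequence[str],
    gene_universe: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum DE between two disjoint cell groups.

    Returns one row per universe gene with ``avg_log2fc`` (positive =
    higher in ``cells_a``), raw and BH-adjusted p, and detection rates.
    """
    cells_a, cells_b = list(cells_a), list(cells_b)
    if not cells_a or not cells_b:
        raise ValidationError("empty cell group in wilcoxon_de")
    if set(cells_a) & set(cells_b):
        raise ValidationError("cell groups overlap")
    genes = list(gene_universe) if gene_universe is not None else list(ds.gene_ids)
    rows = ds.gene_index(genes)
    X = ds.norm_dense(rows)
    ia = ds.cell_index(cells_a)
    ib = ds.cell_index(cells_b)
    Xa, Xb = X[:, ia], X[:, ib]

    p = ranksum_p_matrix(Xa, Xb)
    lfc = avg_log2fc(Xa, Xb)
    p_adj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene": genes,
            "avg_log2fc": lfc,
            "p": p,
            "p_adj": p_adj,
            "pct_in": (Xa > 0).mean(axis=1),
            "pct_out": (Xb > 0).mean(axis=1),
        }
    )


def cluster_markers(
    ds: ExpressionDataset,
    part: Partition,
    gene_universe: Sequence[str] | None = None,
    top_n: int = 30,
    p_adj_max: float = 0.05,
) -> pd.DataFrame:
    """One-vs-rest marker table: per cluster the ``top_n`` significant genes.

    Genes with ``p_adj < p_adj_max`` are ranked by decreasing average
    log2 fold change; a cluster with no significant gene contributes an
    empty block (with a warning).
    """
    names = part.cluster_names()
    if len(names) < 2:
        raise ValidationError("need at least 2 clusters for one-vs-rest markers")
    blocks = []
    for name in names:
        inside = part.members(name)
        outside = [c for c, l in zip(part.cell_ids, part.labels) if l != name]
        de = wilcoxon_de(ds, inside, outside, gene_universe)
        sig = de[de["p_adj"] < p_adj_max].sort_values(
            "avg_log2fc", ascending=False, kind="stable"
        )
        if sig.empty:
            logger.warning("cluster %s: no markers at p_adj < %g", name, p_adj_max)
        block = sig.head(top_n).copy()
        block.insert(1, "cluster", name)
        blocks.append(block)
    out = (
        pd.concat(blocks, ignore_index=True)
        if blocks
        else pd.DataFrame(columns=MARKER_COLUMNS)
    )
    return out[MARKER_COLUMNS] if len(out) else pd.DataFrame(columns=MARKER_COLUMNS)


# ---------------------------------------------------------------------------
# Added-value comparison of integrated vs single-dataset markers
# ---------------------------------------------------------------------------

def added_value_rates(
    integrated_markers: Mapping[str, set],
    single_dataset_markers: Mapping[str, Mapping[str, set]] | Mapping[str, set],
) -> pd.DataFrame:
    """Recovered / false-negative / false-positive percentages per cluster.

    The integrated marker set I is treated as the correct result; for a
    single-dataset set S: recovered = 100*|I∩S|/|I|, FN = 100*|I\\S|/|I|,
    FP = 100*|S\\I|/|S| (0 with a flag when S is empty).  Accepts either
    one dataset's per-cluster sets or a {dataset: {cluster: set}} nest.
    """
    nested = single_dataset_markers and all(
        isinstance(v, Mapping) for v in single_dataset_markers.values()
    )
    per_dataset = (
        single_dataset_markers if nested else {"dataset": single_dataset_markers}
    )
    rows = []
    for did, clusters in per_dataset.items():
        missing = set(integrated_markers) ^ set(clusters)
        if missing:
            raise ValidationError(f"cluster names not aligned for {did}: {sorted(missing)}")
        for cl in sorted(integrated_markers):
            I, S = set(integrated_markers[cl]), set(clusters[cl])
            if not I:
                raise ValidationError(f"integrated marker set for {cl} is empty")
            rec = 100.0 * len(I & S) / len(I)
            fn = 100.0 * len(I - S) / len(I)
            fp = 100.0 * len(S - I) / len(S) if S else 0.0
            rows.append(
                {
                    "cluster": cl,
                    "dataset": did,
                    "recovered_pct": rec,
                    "fn_pct": fn,
                    "fp_pct": fp,
                    "empty_single_set": not S,
                }
            )
    return pd.DataFrame(rows)


def jaccard_matrix(part1: Partition, part2: Partition) -> pd.DataFrame:
    """Jaccard index between every cluster pair of two partitions."""
    common = set(part1.cell_ids) & set(part2.cell_ids)
    if not common:
        raise ValidationError("partitions share no cells")
    if len(common) != len(part1.cell_ids) or len(common) != len(part2.cell_ids):
        logger.info("jaccard_matrix restricted to %d shared cells", len(common))
    l1 = {c: l for c, l in zip(part1.cell_ids, part1.labels) if c in common}
    l2 = {c: l for c, l in zip(part2.cell_ids, part2.labels) if c in common}
    names1 = sorted(set(l1.values()))
    names2 = sorted(set(l2.values()))
    sets1 = {n: {c for c, l in l1.items() if l == n} for n in names1}
    sets2 = {n: {c for c, l in l2.items() if l == n} for n in names2}
    mat = pd.DataFrame(0.0, index=names1, columns=names2)
    for a in names1:
        for b in names2:
            u = len(sets1[a] | sets2[b])
            mat.loc[a, b] = len(sets1[a] & sets2[b]) / u if u else 0.0
    return mat


# ---------------------------------------------------------------------------
# Signature-based annotation
# ---------------------------------------------------------------------------

def reference_profiles(
    ds: ExpressionDataset, part: Partition, genes: Sequence[str]
) -> pd.DataFrame:
    """Per-cluster mean normalized expression over a marker gene union."""
    rows = ds.gene_index(genes)
    X = ds.norm_dense(rows)
    lab = pd.Series(part.label_of()).reindex(ds.cell_ids)
    out = {}
    for name in sorted(lab.dropna().unique()):
        out[name] = X[:, (lab == name).to_numpy()].mean(axis=1)
    return pd.DataFrame(out, index=list(genes))


def signature_annotate(
    query: ExpressionDataset, ref_profiles: pd.DataFrame
) -> pd.DataFrame:
    """Label each query cell by its best-Spearman-correlated reference profile.

    Correlations are computed over the reference marker genes present in
    the query (at least 50% must be); ties resolve lexicographically.
    """
    if ref_profiles.shape[1] < 2:
        raise ValidationError("need at least 2 reference profiles")
    ref_genes = [str(g) for g in ref_profiles.index]
    present = [g for g in ref_genes if g in set(query.gene_ids)]
    if len(present) < 0.5 * len(ref_genes):
        missing = sorted(set(ref_genes) - set(present))
        raise ValidationError(
            f"only {len(present)}/{len(ref_genes)} marker genes present in query; "
            f"missing: {missing[:20]}"
        )
    P = ref_profiles.loc[present].to_numpy(dtype=float)
    labels = [str(c) for c in ref_profiles.columns]
    order = np.argsort(labels, kind="stable")  # lexicographic tie-break via argmax
    P = P[:, order]
    labels = [labels[i] for i in order]

    Q = query.norm_dense(query.gene_index(present))
    rq = rankdata(Q, axis=0)
    rp = rankdata(P, axis=0)

    def _standardize(M: np.ndarray) -> np.ndarray:
        mu = M.mean(axis=0)
        sd = M.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        return (M - mu) / sd

    corr = _standardize(rq).T @ _standardize(rp) / len(present)
    best = corr.argmax(axis=1)
    return pd.DataFrame(
        {
            "cell_id": query.cell_ids,
            "label": [labels[i] for i in best],
            "correlation": corr[np.arange(len(best)), best],
        }
    )


# ---------------------------------------------------------------------------
# Over-representation analysis
# ---------------------------------------------------------------------------

def ora_hypergeometric(
    query_genes: set, gene_set: set, universe: set
) -> tuple[float, float]:
    """Hypergeometric upper-tail over-representation test.

    Returns (p, fold enrichment) for the overlap between a query gene
    list and one gene set inside a common universe.
    """
    query_genes, gene_set, universe = set(query_genes), set(gene_set), set(universe)
    if not query_genes:
        raise ValidationError("empty query gene set")
    if not query_genes <= universe:
        raise ValidationError("query genes not all in universe")
    if not gene_set <= universe:
        raise ValidationError("gene set not contained in universe")
    M, K, n = len(universe), len(gene_set), len(query_genes)
    obs = len(query_genes & gene_set)
    p = float(hypergeom.sf(obs - 1, M, K, n))
    expected = n * K / M
    fold = obs / expected if expected > 0 else float("nan")
    return p, fold


def ora_batch(
    query_genes: set, gene_sets: Mapping[str, set], universe: set
) -> pd.DataFrame:
    """ORA over a collection of gene sets with BH adjustment across sets."""
    rows = []
    for name in sorted(gene_sets):
        p, fold = ora_hypergeometric(query_genes, gene_sets[name], universe)
        rows.append({"gene_set": name, "p": p, "fold_enrichment": fold})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df


def cluster_mean_expression(
    ds: ExpressionDataset, part: Partition, genes: Sequence[str]
) -> pd.DataFrame:
    """Mean normalized expression per cluster (rows, name-sorted) per gene."""
    known = [g for g in genes if g in set(ds.gene_ids)]
    unknown = [g for g in genes if g not in set(ds.gene_ids)]
    if unknown:
        logger.warning("cluster_mean_expression skipping unknown genes: %s", unknown[:20])
    if not known:
        raise ValidationError("no requested gene present in dataset")
    X = ds.norm_dense(ds.gene_index(known))
    lab = pd.Series(part.label_of()).reindex(ds.cell_ids)
    out = {}
    for name in sorted(lab.dropna().unique()):
        out[name] = X[:, (lab == name).to_numpy()].mean(axis=1)
    return pd.DataFrame(out, index=known).T
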