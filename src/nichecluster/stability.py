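"""Bootstrap random-forest quantification of cluster robustness.

For every unordered cluster pair, cells are repeatedly split into five
folds; on each training 80% the top differential genes between the two
clusters are selected (10 per cluster by average log2 fold change,
Wilcoxon tested) and a random forest is trained on them, then applied
to the held-out 20%.  After five folds every cell of the pair has been
classified exactly once; the whole procedure is repeated so each cell
accumulates ``n_repeats`` predictions per pair.

Summary metrics
---------------
* dominant cluster — per cell and pair, the label predicted in more
  than half the runs (none on an exact tie);
* recall per cell — correct predictions / all predictions over all
  pairs and runs;
* #Correct — number of pairs whose dominant equals the cell's cluster
  (at most #clusters - 1).

A cluster is *unstable* when more than half its cells have at least one
pair whose dominant cluster is not their own; unstable clusters are
dissolved and their cells reassigned to the remaining clusters by a
random forest trained on the stable cells, iterating until stable.

Dataset-mixing entropy: per cluster, the Shannon entropy (nats) of its
dataset-of-origin composition, maximal at ln(D) under perfect mixing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionDataset, Partition, ValidationError, logger
from .markers import avg_log2fc, ranksum_p_matrix

RECORD_COLUMNS = ["cell_id", "pair_a", "pair_b", "run", "predicted", "truth"]

#: Random-forest defaults: the classifier is named by the procedure but not
#: parameterised; these are configurable everywhere they are used.
RF_DEFAULTS = dict(n_estimators=500, max_depth=None, max_features="sqrt")


def _make_rf(n_trees: int, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_trees,
        max_depth=RF_DEFAULTS["max_depth"],
        max_features=RF_DEFAULTS["max_features"],
        random_state=seed,
        n_jobs=1,
    )


def _fold_assignment(n: int, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Random fold labels 0..n_folds-1, sizes differing by at most one."""
    folds = np.tile(np.arange(n_folds), n // n_folds + 1)[:n]
    rng.shuffle(folds)
    return folds


def _select_pair_features(
    Xa: np.ndarray, Xb: np.ndarray, genes_per_cluster: int, p_adj_max: float = 0.05
) -> np.ndarray:
    """Row indices of the top DE genes per side, by average log2 fold change.

    Genes significant after BH are ranked by avg log2FC (descending for
    the first cluster, ascending for the second).  If no gene reaches
    significance the ranking falls back to fold change alone so the
    classifier always has features (chance-level pairs then classify at
    chance, which is the desired behavior).
    """
    p = ranksum_p_matrix(Xa, Xb)
    lfc = avg_log2fc(Xa, Xb)
    p_adj = multipletests(p, method="fdr_bh")[1]
    sig = np.flatnonzero(p_adj < p_adj_max)
    if sig.size == 0:
        logger.debug("no significant DE genes between pair; ranking by fold change only")
        sig = np.arange(len(lfc))
    elif sig.size < genes_per_cluster:
        logger.warning(
            "only %d DE genes available (requested %d per cluster)", sig.size, genes_per_cluster
        )
    order = sig[np.argsort(-lfc[sig], kind="stable")]
    top_a = order[:genes_per_cluster]
    order_b = sig[np.argsort(lfc[sig], kind="stable")]
    top_b = order_b[:genes_per_cluster]
    return np.unique(np.concatenate([top_a, top_b]))


def pairwise_bootstrap(
    ds: ExpressionDataset,
    part: Partition,
    pair: tuple[str, str],
    n_folds: int = 5,
    n_repeats: int = 10,
    genes_per_cluster: int = 10,
    seed: int = 0,
    gene_universe: Sequence[str] | None = None,
    n_trees: int = RF_DEFAULTS["n_estimators"],
) -> pd.DataFrame:
    """Bootstrap classification records for one cluster pair.

    Returns one record per cell per repeat (``(|a|+|b|) * n_repeats``
    rows): the predicted and true cluster for each held-out cell.  The
    2 x ``genes_per_cluster`` classifier features are re-selected on each
    fold's training cells only: selecting them on the whole pair would
    leak the held-out cells' labels through the feature choice and bias
    hold-out predictions toward "correct" even for indistinguishable
    clusters.
    """
    a, b = pair
    cells_a = part.members(a)
    cells_b = part.members(b)
    for name, cells in ((a, cells_a), (b, cells_b)):
        if len(cells) < n_folds:
            raise ValidationError(
                f"cluster {name!r} has {len(cells)} < {n_folds} cells; merge or skip this pair"
            )
    genes = list(gene_universe) if gene_universe is not None else list(ds.gene_ids)
    rows = ds.gene_index(genes)
    X = ds.norm_dense(rows)
    ia = ds.cell_index(cells_a)
    ib = ds.cell_index(cells_b)
    Xp = X[:, np.concatenate([ia, ib])]  # genes x pair cells
    y = np.array([a] * len(ia) + [b] * len(ib))
    pair_cells = cells_a + cells_b
    rng = np.random.default_rng(seed)

    records = []
    for run in range(1, n_repeats + 1):
        folds = np.empty(len(pair_cells), dtype=int)
        folds[: len(ia)] = _fold_assignment(len(ia), n_folds, rng)
        folds[len(ia):] = _fold_assignment(len(ib), n_folds, rng)
        for f in range(n_folds):
            test = folds == f
            train = ~test
            feat = _select_pair_features(
                Xp[:, train & (y == a)], Xp[:, train & (y == b)], genes_per_cluster
            )
            clf = _make_rf(n_trees, int(rng.integers(2**31)))
            clf.fit(Xp[np.ix_(feat, train)].T, y[train])
            pred = clf.predict(Xp[np.ix_(feat, test)].T)
            for cell, p_lab, t_lab in zip(
                np.array(pair_cells)[test], pred, y[test]
            ):
                records.append((cell, a, b, run, p_lab, t_lab))
    return pd.DataFrame(records, columns=RECORD_COLUMNS)


def all_pairs_bootstrap(
    ds: ExpressionDataset,
    part: Partition,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Run :func:`pairwise_bootstrap` for every unordered cluster pair."""
    names = part.cluster_names()
    frames = []
    for i, (a, b) in enumerate(itertools.combinations(names, 2)):
        frames.append(
            pairwise_bootstrap(ds, part, (a, b), seed=seed + i, **kwargs)
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

@dataclass
class StabilitySummary:
    """Per-cell and per-cluster robustness summary of bootstrap records."""

    per_cell: pd.DataFrame       # cell_id, cluster, recall, n_correct
    dominant: pd.DataFrame       # cell_id, pair_a, pair_b, truth, dominant
    per_cluster: pd.DataFrame    # cluster, frac_wrong_dominant, unstable
    threshold: float = 0.5

    def unstable_clusters(self) -> list[str]:
        return self.per_cluster.loc[self.per_cluster["unstable"], "cluster"].tolist()

    def to_frame(self) -> pd.DataFrame:
        return self.per_cell


def summarize_stability(
    records: pd.DataFrame, part: Partition, threshold: float = 0.5
) -> StabilitySummary:
    """Reduce bootstrap records to the dominant / recall / #Correct metrics.

    Dominant per (cell, pair) requires a strictly greater than half share
    of the runs; exact ties yield no dominant (neither correct nor
    robustly wrong).  A cluster is unstable when the fraction of its
    cells with at least one *wrong* dominant exceeds ``threshold``.
    """
    names = part.cluster_names()
    expected_pairs = set(itertools.combinations(names, 2))
    present = set(map(tuple, records[["pair_a", "pair_b"]].drop_duplicates().to_numpy()))
    missing = expected_pairs - present
    if missing:
        raise ValidationError(f"records missing cluster pairs: {sorted(missing)}")

    correct = records["predicted"] == records["truth"]
    rec = records.assign(correct=correct)

    # dominant per (cell, pair)
    grp = rec.groupby(["cell_id", "pair_a", "pair_b"], sort=False)
    dom_rows = []
    for (cell, a, b), g in grp:
        n_runs = len(g)
        counts = g["predicted"].value_counts()
        top = counts.index[0]
        dominant = top if counts.iloc[0] > n_runs / 2 else None
        dom_rows.append(
            {
                "cell_id": cell,
                "pair_a": a,
                "pair_b": b,
                "truth": g["truth"].iloc[0],
                "dominant": dominant,
            }
        )
    dominant = pd.DataFrame(dom_rows)

    # per-cell recall and #Correct
    label_of = part.label_of()
    recall = rec.groupby("cell_id", sort=False)["correct"].mean()
    dom_ok = dominant.assign(
        is_correct=lambda d: d["dominant"].notna() & (d["dominant"] == d["truth"]),
        is_wrong=lambda d: d["dominant"].notna() & (d["dominant"] != d["truth"]),
    )
    n_correct = dom_ok.groupby("cell_id", sort=False)["is_correct"].sum()
    any_wrong = dom_ok.groupby("cell_id", sort=False)["is_wrong"].any()
    cells = list(recall.index)
    per_cell = pd.DataFrame(
        {
            "cell_id": cells,
            "cluster": [label_of[c] for c in cells],
            "recall": recall.to_numpy(),
            "n_correct": n_correct.reindex(cells).fillna(0).astype(int).to_numpy(),
        }
    )

    # per-cluster instability
    wrong_by_cluster = (
        pd.DataFrame({"cluster": [label_of[c] for c in any_wrong.index],
                      "wrong": any_wrong.to_numpy()})
        .groupby("cluster", sort=True)["wrong"]
        .mean()
    )
    per_cluster = pd.DataFrame(
        {
            "cluster": names,
            "frac_wrong_dominant": [float(wrong_by_cluster.get(n, 0.0)) for n in names],
        }
    )
    per_cluster["unstable"] = per_cluster["frac_wrong_dominant"] > threshold
    return StabilitySummary(
        per_cell=per_cell, dominant=dominant, per_cluster=per_cluster, threshold=threshold
    )


def evaluate_stability(
    ds: ExpressionDataset,
    part: Partition,
    seed: int = 0,
    threshold: float = 0.5,
    **bootstrap_kwargs,
) -> StabilitySummary:
    """Convenience: all-pairs bootstrap followed by summarization."""
    records = all_pairs_bootstrap(ds, part, seed=seed, **bootstrap_kwargs)
    return summarize_stability(records, part, threshold=threshold)


# ---------------------------------------------------------------------------
# Dissolution and reassignment
# ---------------------------------------------------------------------------

def dissolve_and_reassign(
    ds: ExpressionDataset,
    part: Partition,
    summary: StabilitySummary,
    seed: int = 0,
    gene_universe: Sequence[str] | None = None,
    genes_per_cluster: int = 10,
    n_trees: int = RF_DEFAULTS["n_estimators"],
    max_iter: int = 3,
    n_folds: int = 5,
    n_repeats: int = 10,
    threshold: float = 0.5,
) -> Partition:
    """Dissolve unstable clusters and reassign their cells, iterating.

    Each round removes the unstable clusters and assigns their cells
    among the stable ones with a random forest trained on the stable
    cells over the union of each stable cluster's top one-vs-rest DE
    genes; stability is then re-evaluated on the new partition, up to
    ``max_iter`` rounds.  Total cell count is conserved.
    """
    genes = list(gene_universe) if gene_universe is not None else list(ds.gene_ids)
    rows = ds.gene_index(genes)
    current = part
    cur_summary = summary
    rng = np.random.default_rng(seed)

    for it in range(max_iter):
        unstable = cur_summary.unstable_clusters()
        if not unstable:
            return current
        stable = [n for n in current.cluster_names() if n not in unstable]
        if not stable:
            raise ValidationError(
                "every cluster is unstable; re-cluster at a coarser resolution"
            )
        logger.info("dissolving unstable clusters %s (round %d)", unstable, it + 1)
        label_of = current.label_of()
        stable_cells = [c for c in current.cell_ids if label_of[c] in stable]
        moving_cells = [c for c in current.cell_ids if label_of[c] in unstable]

        if len(stable) == 1:
            new_labels = {c: stable[0] for c in moving_cells}
        else:
            X = ds.norm_dense(rows)
            ist = ds.cell_index(stable_cells)
            y = np.array([label_of[c] for c in stable_cells])
            feat: list[int] = []
            for name in stable:
                Xa = X[:, ist[y == name]]
                Xb = X[:, ist[y != name]]
                feat.extend(_select_pair_features(Xa, Xb, genes_per_cluster).tolist())
            feat_idx = np.unique(np.array(feat, dtype=int))
            clf = _make_rf(n_trees, int(rng.integers(2**31)))
            clf.fit(X[np.ix_(feat_idx, ist)].T, y)
            imv = ds.cell_index(moving_cells)
            pred = clf.predict(X[np.ix_(feat_idx, imv)].T)
            new_labels = dict(zip(moving_cells, pred))

        merged = {
            c: (new_labels[c] if c in new_labels else label_of[c])
            for c in current.cell_ids
        }
        current = Partition(
            cell_ids=list(current.cell_ids),
            labels=[str(merged[c]) for c in current.cell_ids],
        )
        if len(current.cluster_names()) < 2:
            return current  # single cluster left: nothing further to evaluate
        cur_summary = evaluate_stability(
            ds,
            current,
            seed=int(rng.integers(2**31)),
            threshold=threshold,
            gene_universe=genes,
            genes_per_cluster=genes_per_cluster,
            n_trees=n_trees,
            n_folds=n_folds,
            n_repeats=n_repeats,
        )
    remaining = cur_summary.unstable_clusters()
    if remaining:
        logger.warning("unstable clusters remain after %d rounds: %s", max_iter, remaining)
    return current


# ---------------------------------------------------------------------------
# Dataset-mixing entropy
# ---------------------------------------------------------------------------

@dataclass
class EntropyReport:
    """Per-cluster dataset composition and Shannon entropy (nats)."""

    per_cluster: pd.DataFrame  # cluster, n_cells, prop_<d>..., entropy, entropy_norm
    datasets: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return self.per_cluster


def shannon_entropy(proportions: Sequence[float]) -> float:
    """H = -sum p log p (natural log), with 0 * log 0 = 0."""
    p = np.asarray(proportions, float)
    if p.size and not np.isclose(p.sum(), 1.0):
        raise ValidationError("proportions must sum to 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def dataset_entropy(
    part: Partition, dataset_ids: Mapping[str, str] | Sequence[str]
) -> EntropyReport:
    """Shannon entropy of the dataset-of-origin mix within each cluster.

    ``dataset_ids`` maps cell to dataset (or is a sequence aligned with
    the partition's cells).  D is the number of datasets overall; the
    normalized column divides by ln(D).
    """
    if not isinstance(dataset_ids, Mapping):
        if len(dataset_ids) != len(part.cell_ids):
            raise ValidationError("dataset_ids length != partition size")
        dataset_ids = dict(zip(part.cell_ids, dataset_ids))
    missing = [c for c in part.cell_ids if c not in dataset_ids]
    if missing:
        raise ValidationError(f"cells without dataset_id: {missing[:10]}")
    datasets = sorted({str(dataset_ids[c]) for c in part.cell_ids})
    D = len(datasets)
    rows = []
    for name in part.cluster_names():
        members = part.members(name)
        if not members:
            logger.warning("empty cluster %s excluded from entropy", name)
            continue
        counts = pd.Series([str(dataset_ids[c]) for c in members]).value_counts()
        p = np.array([counts.get(d, 0) for d in datasets], float)
        p /= p.sum()
        h = shannon_entropy(p)
        row = {"cluster": name, "n_cells": len(members)}
        row.update({f"prop_{d}": p[i] for i, d in enumerate(datasets)})
        row["entropy"] = h
        row["entropy_norm"] = h / np.log(D) if D > 1 else 0.0
        rows.append(row)
    return EntropyReport(per_cluster=pd.DataFrame(rows), datasets=datasets)
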