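"""Bootstrap RF stability metrics, dissolution, and mixing entropy."""

import itertools
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nichecluster as nc
from nichecluster.stability import RECORD_COLUMNS

from conftest import two_cluster_spec


def _records(rows):
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def brute_force_summary(records: pd.DataFrame):
    """Independent plain-loop recount of recall, dominant and #Correct."""
    per_cell_preds: dict[str, list[bool]] = {}
    dominant: dict[tuple, str | None] = {}
    truth_of: dict[str, str] = {}
    for key, grp in records.groupby(["cell_id", "pair_a", "pair_b"]):
        votes = Counter(grp["predicted"])
        n = len(grp)
        top, top_n = votes.most_common(1)[0]
        dominant[key] = top if top_n * 2 > n else None
        truth_of[key[0]] = grp["truth"].iloc[0]
        per_cell_preds.setdefault(key[0], []).extend(
            (p == t) for p, t in zip(grp["predicted"], grp["truth"])
        )
    recall = {c: sum(v) / len(v) for c, v in per_cell_preds.items()}
    n_correct = Counter()
    any_wrong = {c: False for c in recall}
    for (cell, a, b), dom in dominant.items():
        if dom is None:
            continue
        if dom == truth_of[cell]:
            n_correct[cell] += 1
        else:
            any_wrong[cell] = True
    return recall, dict(n_correct), any_wrong


# -- pairwise bootstrap ------------------------------------------------------

def test_record_count_and_coverage(separated_pair):
    """Each cell of the pair is classified exactly once per repeat."""
    ds, truth = separated_pair
    genes = nc.select_mvg(ds, 200)
    rec = nc.pairwise_bootstrap(
        ds, truth, ("X", "Y"), n_repeats=3, seed=0,
        gene_universe=genes, n_trees=30,
    )
    n_pair = len(truth.members("X")) + len(truth.members("Y"))
    assert len(rec) == n_pair * 3
    per_cell = rec.groupby("cell_id")["run"].apply(list)
    assert all(sorted(v) == [1, 2, 3] for v in per_cell)


def test_small_cluster_rejected(separated_pair):
    ds, truth = separated_pair
    tiny = nc.Partition(
        cell_ids=list(truth.cell_ids),
        labels=["X" if i > 2 else "Y" for i in range(len(truth.cell_ids))],
    )
    with pytest.raises(nc.ValidationError, match="merge or skip"):
        nc.pairwise_bootstrap(ds, tiny, ("X", "Y"), n_folds=5, seed=0)


def test_separable_pair_high_recall(separated_pair):
    """20 strong markers per cluster: mean recall >= 0.95."""
    ds, truth = separated_pair
    genes = nc.select_mvg(ds, 200)
    rec = nc.pairwise_bootstrap(ds, truth, ("X", "Y"), seed=1,
                                gene_universe=genes, n_trees=60)
    assert (rec["predicted"] == rec["truth"]).mean() >= 0.95


def test_identical_distributions_chance_recall():
    """No planted difference between the halves: recall is at chance."""
    means = []
    for seed in range(3):
        tree = nc.TreeNodeSpec(children=[nc.TreeNodeSpec(name="X")])
        spec = nc.SimulationSpec(
            cluster_tree_spec=tree,
            cells_per_cluster_per_dataset={"X": [120]},
            n_datasets=1, n_genes=300, baseline_mean=1.0, seed=seed,
        )
        ds, truth, _ = nc.simulate(spec)
        ds = nc.normalize(ds)
        rng = np.random.default_rng(seed)
        labels = ["X1" if rng.random() < 0.5 else "X2" for _ in truth.cell_ids]
        part = nc.Partition(cell_ids=list(truth.cell_ids), labels=labels)
        rec = nc.pairwise_bootstrap(ds, part, ("X1", "X2"), seed=seed,
                                    gene_universe=nc.select_mvg(ds, 150),
                                    n_trees=50)
        means.append((rec["predicted"] == rec["truth"]).mean())
    assert 0.35 <= np.median(means) <= 0.65


# -- summarize_stability -----------------------------------------------------

def test_summary_definitions_all_correct():
    """Cell correct in all runs of both pairs (K=3): recall 1, #Correct 2."""
    rows = []
    for pair in (("A", "B"), ("A", "C")):
        for run in range(1, 11):
            rows.append(("cell1", *pair, run, "A", "A"))
    # minimal coverage for remaining cells/pairs
    for pair in (("A", "B"), ("A", "C"), ("B", "C")):
        for cell, truth in (("cellB", "B"), ("cellC", "C")):
            if truth in pair:
                for run in range(1, 11):
                    rows.append((cell, *pair, run, truth, truth))
    part = nc.Partition(cell_ids=["cell1", "cellB", "cellC"],
                        labels=["A", "B", "C"])
    summ = nc.summarize_stability(_records(rows), part)
    row = summ.per_cell.set_index("cell_id").loc["cell1"]
    assert row["recall"] == 1.0 and row["n_correct"] == 2
    assert not summ.per_cluster["unstable"].any()


def test_dominant_majority_and_tie_rules():
    """6/10 to the other cluster: wrong dominant; 5/10: no dominant."""
    rows = []
    for run in range(1, 11):
        rows.append(("c1", "A", "B", run, "B" if run <= 6 else "A", "A"))
        rows.append(("c2", "A", "B", run, "B" if run <= 5 else "A", "A"))
    part = nc.Partition(cell_ids=["c1", "c2"], labels=["A", "A"])
    # pair coverage needs both clusters; add a B cell
    for run in range(1, 11):
        rows.append(("c3", "A", "B", run, "B", "B"))
    part = nc.Partition(cell_ids=["c1", "c2", "c3"], labels=["A", "A", "B"])
    summ = nc.summarize_stability(_records(rows), part)
    dom = summ.dominant.set_index("cell_id")["dominant"]
    assert dom.loc["c1"] == "B"
    assert dom.loc["c2"] is None
    a_row = summ.per_cluster.set_index("cluster").loc["A"]
    assert a_row["frac_wrong_dominant"] == 0.5  # c1 wrong, c2 tie (not wrong)
    assert not a_row["unstable"]  # strict > threshold


def test_missing_pair_rejected():
    rows = [("c1", "A", "B", 1, "A", "A"), ("c2", "A", "B", 1, "B", "B")]
    part = nc.Partition(cell_ids=["c1", "c2", "c3"], labels=["A", "B", "C"])
    with pytest.raises(nc.ValidationError, match="missing"):
        nc.summarize_stability(_records(rows), part)


def test_summary_matches_brute_force(separated_pair):
    """Enumerable toy: pipeline summary equals a plain-loop recount."""
    ds, truth = separated_pair
    cells = truth.members("X")[:10] + truth.members("Y")[:10]
    sub = ds.subset_cells(cells)
    part = nc.Partition(cell_ids=cells, labels=["X"] * 10 + ["Y"] * 10)
    rec = nc.pairwise_bootstrap(sub, part, ("X", "Y"), seed=3,
                                n_trees=40, gene_universe=nc.select_mvg(sub, 100))
    summ = nc.summarize_stability(rec, part)
    recall, n_correct, any_wrong = brute_force_summary(rec)
    for _, row in summ.per_cell.iterrows():
        assert row["recall"] == pytest.approx(recall[row["cell_id"]])
        assert row["n_correct"] == n_correct.get(row["cell_id"], 0)
    for _, row in summ.per_cluster.iterrows():
        frac = np.mean([any_wrong[c] for c in part.members(row["cluster"])])
        assert row["frac_wrong_dominant"] == pytest.approx(frac)


def test_summary_invariant_to_name_permutation(separated_pair):
    ds, truth = separated_pair
    genes = nc.select_mvg(ds, 150)
    rec = nc.pairwise_bootstrap(ds, truth, ("X", "Y"), n_repeats=3, seed=0,
                                gene_universe=genes, n_trees=30)
    summ = nc.summarize_stability(rec, truth)
    ren = {"X": "Q2", "Y": "Q1"}
    rec2 = rec.copy()
    for col in ("predicted", "truth"):
        rec2[col] = rec2[col].map(ren)
    rec2["pair_a"], rec2["pair_b"] = "Q1", "Q2"
    part2 = nc.Partition(cell_ids=list(truth.cell_ids),
                         labels=[ren[l] for l in truth.labels])
    summ2 = nc.summarize_stability(rec2, part2)
    m1 = summ.per_cell.set_index("cell_id")
    m2 = summ2.per_cell.set_index("cell_id")
    assert np.allclose(m1["recall"], m2.loc[m1.index, "recall"])
    assert (m1["n_correct"] == m2.loc[m1.index, "n_correct"]).all()


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_recall_and_ncorrect_bounds_random_records(seed):
    """0 <= recall <= 1 and n_correct <= #clusters - 1 on random inputs."""
    rng = np.random.default_rng(seed)
    clusters = ["A", "B", "C"]
    cells = {f"c{i}": clusters[i % 3] for i in range(9)}
    rows = []
    for a, b in itertools.combinations(clusters, 2):
        for cell, t in cells.items():
            if t not in (a, b):
                continue
            for run in range(1, 6):
                rows.append((cell, a, b, run, rng.choice([a, b]), t))
    part = nc.Partition(cell_ids=list(cells), labels=list(cells.values()))
    summ = nc.summarize_stability(_records(rows), part)
    assert summ.per_cell["recall"].between(0, 1).all()
    assert (summ.per_cell["n_correct"] <= len(clusters) - 1).all()


# -- dissolution -------------------------------------------------------------

def test_dissolve_identity_when_stable(separated_pair):
    ds, truth = separated_pair
    genes = nc.select_mvg(ds, 150)
    summ = nc.evaluate_stability(ds, truth, seed=0, gene_universe=genes,
                                 n_trees=40, n_repeats=4)
    out = nc.dissolve_and_reassign(ds, truth, summ, seed=0,
                                   gene_universe=genes, n_trees=40)
    assert out.labels == truth.labels


def test_dissolve_conserves_cells_and_merges_oversplit():
    """An over-split half dissolves into its sibling, conserving cells."""
    ds, truth, _ = nc.simulate(two_cluster_spec(seed=5, cells=(60, 30),
                                                n_datasets=2))
    ds = nc.normalize(ds)
    rng = np.random.default_rng(0)
    labels = [l if l == "Y" else ("X1" if rng.random() < 2 / 3 else "X2")
              for l in truth.labels]
    part = nc.Partition(cell_ids=list(truth.cell_ids), labels=labels)
    genes = nc.select_mvg(ds, 200)
    summ = nc.evaluate_stability(ds, part, seed=1, gene_universe=genes,
                                 n_trees=50)
    assert set(summ.unstable_clusters()) <= {"X1", "X2"}
    assert len(summ.unstable_clusters()) >= 1
    out = nc.dissolve_and_reassign(ds, part, summ, seed=2,
                                   gene_universe=genes, n_trees=50)
    assert len(out.cell_ids) == len(part.cell_ids)
    # all X cells end in one cluster; Y survives
    lab = out.label_of()
    x_labels = {lab[c] for c in truth.members("X")}
    assert len(x_labels) == 1 and "Y" in out.cluster_names()


def test_all_unstable_is_error(separated_pair):
    ds, truth = separated_pair
    summary = nc.StabilitySummary(
        per_cell=pd.DataFrame(columns=["cell_id", "cluster", "recall", "n_correct"]),
        dominant=pd.DataFrame(columns=["cell_id", "pair_a", "pair_b", "truth", "dominant"]),
        per_cluster=pd.DataFrame(
            {"cluster": ["X", "Y"], "frac_wrong_dominant": [1.0, 1.0],
             "unstable": [True, True]}
        ),
    )
    with pytest.raises(nc.ValidationError, match="coarser"):
        nc.dissolve_and_reassign(ds, truth, summary, seed=0)


# -- entropy -----------------------------------------------------------------

def test_entropy_closed_forms():
    assert nc.shannon_entropy([1 / 3, 1 / 3, 1 / 3]) == pytest.approx(np.log(3))
    assert nc.shannon_entropy([1.0, 0.0, 0.0]) == 0.0
    assert nc.shannon_entropy([0.5, 0.5, 0.0]) == pytest.approx(np.log(2))


def test_dataset_entropy_report():
    part = nc.Partition(cell_ids=[f"c{i}" for i in range(6)],
                        labels=["A"] * 3 + ["B"] * 3)
    dids = {"c0": "d1", "c1": "d2", "c2": "d3",
            "c3": "d1", "c4": "d1", "c5": "d1"}
    rep = nc.dataset_entropy(part, dids)
    t = rep.per_cluster.set_index("cluster")
    assert t.loc["A", "entropy"] == pytest.approx(np.log(3))
    assert t.loc["A", "entropy_norm"] == pytest.approx(1.0)
    assert t.loc["B", "entropy"] == 0.0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.01, 10.0), min_size=2, max_size=6))
def test_entropy_maximal_iff_uniform(weights):
    p = np.array(weights) / np.sum(weights)
    h = nc.shannon_entropy(p)
    d = len(p)
    assert h <= np.log(d) + 1e-12
    if not np.allclose(p, 1 / d):
        assert h < np.log(d)
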