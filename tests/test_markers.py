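"""Wilcoxon DE, added-value rates, Jaccard, annotation, ORA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

import nichecluster as nc

from conftest import make_dataset, two_cluster_spec


# -- exact rank-sum ----------------------------------------------------------

def test_exact_p_reference_example():
    """[5,6,7] vs [1,2,3]: 2 of the C(6,3)=20 arrangements are as extreme."""
    assert nc.exact_ranksum_p([5, 6, 7], [1, 2, 3]) == pytest.approx(0.1)


def test_exact_p_with_ties_hand_computed():
    # ranks 3.5,3.5 vs 1.5,1.5; W=7, mu=5; arrangements with |W-5|>=2: 2/6
    assert nc.exact_ranksum_p([2, 2], [1, 1]) == pytest.approx(1 / 3)
    assert nc.exact_ranksum_p([1, 1], [1, 1]) == 1.0


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    nx=st.integers(2, 7),
    ny=st.integers(2, 7),
    seed=st.integers(0, 10_000),
)
def test_exact_p_matches_scipy_exact_oracle(nx, ny, seed):
    """Tie-free samples: enumeration agrees with scipy's exact rank-sum p."""
    rng = np.random.default_rng(seed)
    vals = rng.permutation(np.arange(nx + ny, dtype=float))  # no ties
    x, y = vals[:nx], vals[nx:]
    ours = nc.exact_ranksum_p(x, y)
    theirs = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
    assert ours == pytest.approx(theirs)


def test_wilcoxon_de_basic_properties():
    counts = np.array([[5, 6, 7, 1, 2, 3], [4, 4, 4, 4, 4, 4]])
    ds = make_dataset(counts)
    nc.attach_norm(ds, counts.astype(float))
    de = nc.wilcoxon_de(ds, ["c1", "c2", "c3"], ["c4", "c5", "c6"])
    g1 = de.set_index("gene").loc["g1"]
    assert g1["p"] == pytest.approx(0.1)
    g2 = de.set_index("gene").loc["g2"]
    assert g2["avg_log2fc"] == 0.0 and g2["p"] == 1.0
    # single-gene universe: BH with m=1 leaves p unchanged
    de1 = nc.wilcoxon_de(ds, ["c1", "c2", "c3"], ["c4", "c5", "c6"],
                         gene_universe=["g1"])
    assert de1.loc[0, "p_adj"] == de1.loc[0, "p"]


def test_wilcoxon_de_errors():
    ds = make_dataset(np.ones((2, 4), int))
    nc.attach_norm(ds, np.ones((2, 4)))
    with pytest.raises(nc.ValidationError):
        nc.wilcoxon_de(ds, [], ["c1"])
    with pytest.raises(nc.ValidationError):
        nc.wilcoxon_de(ds, ["c1", "c2"], ["c2", "c3"])


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_bh_adjustment_monotone(seed):
    """p_adj is non-decreasing when records are ordered by raw p."""
    rng = np.random.default_rng(seed)
    counts = rng.poisson(2.0, size=(25, 30))
    ds = make_dataset(counts)
    nc.attach_norm(ds, np.log1p(counts.astype(float)))
    de = nc.wilcoxon_de(ds, ds.cell_ids[:15], ds.cell_ids[15:])
    srt = de.sort_values("p")
    assert (np.diff(srt["p_adj"].to_numpy()) >= -1e-12).all()
    assert (de["p_adj"] >= de["p"] - 1e-12).all()


# -- cluster markers ---------------------------------------------------------

def test_planted_markers_rank_top(separated_pair):
    """Planted cluster markers dominate the top-30 one-vs-rest list."""
    recovered = []
    for seed in range(10):
        spec = two_cluster_spec(n_markers=20, log2fc=2.0, cells=(60, 60),
                                n_datasets=1, seed=seed)
        ds, truth, _ = nc.simulate(spec)
        ds = nc.normalize(ds)
        table = nc.cluster_markers(ds, truth, nc.select_mvg(ds, 200), top_n=30)
        planted = set(nc.planted_marker_genes(spec)["X"])
        top = set(table.loc[table["cluster"] == "X", "gene"])
        recovered.append(len(planted & top))
    assert np.median(recovered) >= 18


def test_marker_symmetry_under_swap(separated_pair):
    ds, truth = separated_pair
    genes = nc.select_mvg(ds, 200)
    table = nc.cluster_markers(ds, truth, genes, top_n=20)
    swapped = nc.Partition(
        cell_ids=list(truth.cell_ids),
        labels=["Y" if l == "X" else "X" for l in truth.labels],
    )
    table2 = nc.cluster_markers(ds, swapped, genes, top_n=20)
    for a, b in (("X", "Y"), ("Y", "X")):
        assert set(table.loc[table["cluster"] == a, "gene"]) == set(
            table2.loc[table2["cluster"] == b, "gene"]
        )


def test_no_de_cluster_yields_empty_block():
    rng = np.random.default_rng(0)
    counts = rng.poisson(2.0, size=(30, 40))
    ds = make_dataset(counts)
    nc.attach_norm(ds, np.log1p(counts.astype(float)))
    part = nc.Partition(cell_ids=list(ds.cell_ids),
                        labels=["A"] * 20 + ["B"] * 20)
    table = nc.cluster_markers(ds, part, top_n=10)
    assert len(table) == 0 or (table["p_adj"] < 0.05).all()


# -- added value -------------------------------------------------------------

def test_added_value_arithmetic():
    I = {"K": {"a", "b", "c", "d"}}
    S = {"K": {"a", "b", "e"}}
    row = nc.added_value_rates(I, S).iloc[0]
    assert row["recovered_pct"] == pytest.approx(50.0)
    assert row["fn_pct"] == pytest.approx(50.0)
    assert row["fp_pct"] == pytest.approx(100 / 3)

    same = nc.added_value_rates(I, {"K": set(I["K"])}).iloc[0]
    assert (same["recovered_pct"], same["fn_pct"], same["fp_pct"]) == (100.0, 0.0, 0.0)

    disj = nc.added_value_rates(I, {"K": {"x", "y"}}).iloc[0]
    assert (disj["recovered_pct"], disj["fn_pct"], disj["fp_pct"]) == (0.0, 100.0, 100.0)

    empty = nc.added_value_rates(I, {"K": set()}).iloc[0]
    assert empty["fp_pct"] == 0.0 and bool(empty["empty_single_set"])

    with pytest.raises(nc.ValidationError, match="aligned"):
        nc.added_value_rates(I, {"other": {"a"}})


# -- jaccard -----------------------------------------------------------------

def test_jaccard_matrix_values_and_symmetry():
    p1 = nc.Partition(cell_ids=list("abcdef"), labels=["1"] * 3 + ["2"] * 3)
    p2 = nc.Partition(cell_ids=list("abcdef"), labels=["u", "v", "v", "v", "w", "w"])
    m = nc.jaccard_matrix(p1, p2)
    assert m.loc["1", "v"] == pytest.approx(2 / 4)  # {b,c} over {a,b,c,d(v=bcd)}
    assert m.loc["2", "u"] == 0.0
    mt = nc.jaccard_matrix(p2, p1)
    assert np.allclose(m.to_numpy(), mt.to_numpy().T)

    ident = nc.jaccard_matrix(p1, p1)
    assert np.allclose(np.diag(ident.to_numpy()), 1.0)

    with pytest.raises(nc.ValidationError):
        nc.jaccard_matrix(
            p1, nc.Partition(cell_ids=list("xyz"), labels=["1", "1", "2"])
        )


# -- signature annotation ----------------------------------------------------

def test_signature_annotate_exact_and_anticorrelated():
    genes = [f"g{i+1}" for i in range(8)]
    up = np.arange(8, dtype=float)
    profiles = pd.DataFrame(
        {"pos": up, "neg": up[::-1], "flat_noise": np.ones(8)}, index=genes
    )
    query = make_dataset(np.tile(up[:, None], (1, 3)).astype(int),
                         gene_ids=genes, cell_ids=["q1", "q2", "q3"])
    nc.attach_norm(query, np.tile(up[:, None], (1, 3)))
    out = nc.signature_annotate(query, profiles[["pos", "neg"]])
    assert (out["label"] == "pos").all()
    assert np.allclose(out["correlation"], 1.0)


def test_signature_annotate_requires_gene_overlap():
    profiles = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]},
                            index=["missing1", "missing2"])
    query = make_dataset(np.ones((2, 2), int))
    nc.attach_norm(query, np.ones((2, 2)))
    with pytest.raises(nc.ValidationError, match="missing"):
        nc.signature_annotate(query, profiles)


def test_signature_annotate_recovers_simulated_clusters():
    """Queries drawn from the reference generative model label correctly."""
    accs = []
    for seed in range(10):
        ds, truth, _ = nc.simulate(
            two_cluster_spec(seed=seed, n_datasets=2, cells=(60, 60))
        )
        ds = nc.normalize(ds)
        split = ds.split_by_dataset()
        ref, query = split["dataset1"], split["dataset2"]
        ref_part = nc.Partition(
            cell_ids=list(ref.cell_ids),
            labels=[truth.label_of()[c] for c in ref.cell_ids],
        )
        table = nc.cluster_markers(ref, ref_part, nc.select_mvg(ref, 150), top_n=30)
        profiles = nc.reference_profiles(ref, ref_part, sorted(set(table["gene"])))
        out = nc.signature_annotate(query, profiles)
        lab = truth.label_of()
        accs.append(np.mean([lab[c] == l for c, l in
                             zip(out["cell_id"], out["label"])]))
    assert np.median(accs) >= 0.9


# -- ORA ---------------------------------------------------------------------

def test_ora_closed_form_and_fold():
    universe = {f"u{i}" for i in range(20)}
    gene_set = {f"u{i}" for i in range(5)}
    p, fold = nc.ora_hypergeometric(gene_set, gene_set, universe)
    assert p == pytest.approx(1 / 15504)
    assert fold == pytest.approx(5 / (5 * 5 / 20))

    # overlap equal to expectation -> fold 1
    q = {"u0", "u5", "u6", "u7"}  # |q∩s|=1, expected 4*5/20=1
    _, fold1 = nc.ora_hypergeometric(q, gene_set, universe)
    assert fold1 == pytest.approx(1.0)

    with pytest.raises(nc.ValidationError):
        nc.ora_hypergeometric(set(), gene_set, universe)
    with pytest.raises(nc.ValidationError):
        nc.ora_hypergeometric({"not_in_universe"}, gene_set, universe)


def test_ora_batch_bh():
    universe = {f"u{i}" for i in range(30)}
    sets = {"s1": {f"u{i}" for i in range(5)}, "s2": {f"u{i}" for i in range(10, 14)}}
    out = nc.ora_batch({f"u{i}" for i in range(5)}, sets, universe)
    assert list(out["gene_set"]) == ["s1", "s2"]
    assert (out["p_adj"] >= out["p"] - 1e-12).all()


# -- cluster means -----------------------------------------------------------

def test_cluster_mean_expression_cases():
    counts = np.array([[1, 2, 3], [0, 0, 0]])
    ds = make_dataset(counts)
    nc.attach_norm(ds, counts.astype(float))
    part = nc.Partition(cell_ids=["c1", "c2", "c3"], labels=["A", "B", "B"])
    m = nc.cluster_mean_expression(ds, part, ["g1", "g2", "unknown"])
    assert m.loc["A", "g1"] == 1.0          # single-cell cluster: its own value
    assert m.loc["B", "g1"] == 2.5
    assert (m["g2"] == 0.0).all()           # all-zero gene stays zero
    assert "unknown" not in m.columns
    # permuting cells leaves the result unchanged
    perm = ds.subset_cells(["c3", "c1", "c2"])
    m2 = nc.cluster_mean_expression(perm, part, ["g1", "g2"])
    assert np.allclose(m.to_numpy()[:, :2], m2.to_numpy())
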