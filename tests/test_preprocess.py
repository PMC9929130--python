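"""QC, normalization, clustering, marker and annotation tests."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from metaniche.preprocess import (
    QCThresholds, qc_filter, qc_metrics, normalize_log, cluster_cells,
    find_markers, annotate_clusters,
)
from tests.conftest import make_adata


# ---------------------------------------------------------------------------
# QC

def scripted_qc_fixture(seed=0):
    """100 cells with scripted (n_genes, n_umis, mito_fraction), including the
    200-gene and 50%-mito boundaries, realized as an actual count matrix."""
    rng = np.random.default_rng(seed)
    n_cells, n_genes = 100, 400
    n_mito = 20
    var_names = [f"MT-g{i}" if i < n_mito else f"g{i}" for i in range(n_genes)]
    target_genes = rng.integers(150, 380, n_cells)
    target_genes[0] = 150    # below min_genes -> removed
    target_genes[1] = 200    # exactly at the boundary -> kept (rule is '< 200')
    target_genes[2] = 199    # just below -> removed
    mito_frac = rng.uniform(0.0, 0.4, n_cells)
    mito_frac[3] = 0.80      # above 0.5 -> removed
    mito_frac[4] = 0.50      # exactly 0.5 -> kept (rule is '> 0.5')
    X = np.zeros((n_cells, n_genes))
    n_m = 5                  # every cell detects 5 mito genes
    for i in range(n_cells):
        g = int(target_genes[i])
        cols = rng.choice(np.arange(n_mito, n_genes), size=g - n_m, replace=False)
        X[i, cols] = 1.0 + rng.integers(0, 3, size=g - n_m)
        nonmito_total = X[i].sum()
        f = mito_frac[i]
        # mito UMI mass realizing exactly f when f has a small denominator
        mito_total = round(f / (1 - f) * nonmito_total) if f < 1 else 0
        base, rem = divmod(int(mito_total), n_m)
        X[i, :n_m] = base
        X[i, 0] += rem
        if base == 0 and rem < n_m:   # keep 5 detected mito genes
            X[i, :n_m] += 1
    return make_adata(X, var_names=var_names)


def brute_force_qc(metrics: pd.DataFrame, t: QCThresholds) -> set:
    """Independent plain-python application of the four stated rules."""
    survivors = set()
    genes = sorted(metrics["n_genes"])
    umis = sorted(metrics["n_umis"])

    def quantile_higher(sorted_vals, q):
        # smallest element with cumulative fraction >= q
        idx = math.ceil(q * (len(sorted_vals) - 1))
        return sorted_vals[idx]

    gcut = quantile_higher(genes, 1 - t.top_gene_fraction)
    ucut = quantile_higher(umis, 1 - t.top_umi_fraction)
    for bc, row in metrics.iterrows():
        if row["n_genes"] < t.min_genes:
            continue
        if row["n_genes"] > gcut or row["n_umis"] > ucut:
            continue
        if row["mito_fraction"] > t.max_mito_fraction:
            continue
        survivors.add(bc)
    return survivors


def test_qc_filter_matches_hand_enumeration():
    adata = scripted_qc_fixture()
    t = QCThresholds(per_sample=False)
    kept, anno = qc_filter(adata, t)
    expected = brute_force_qc(qc_metrics(adata), t)
    assert set(kept.obs_names) == expected
    # boundary semantics
    assert not anno.loc["c0", "qc_pass"]          # 150 genes
    assert not anno.loc["c2", "qc_pass"]          # 199 genes
    assert not anno.loc["c3", "qc_pass"]          # 80% mito
    assert not anno.loc["c4", "fail_mito"]        # exactly 50% mito kept by that rule
    # the annotation records which rule fired
    assert anno.loc["c0", "fail_min_genes"] and not anno.loc["c0", "fail_mito"]


def test_qc_filter_empty_matrix():
    adata = make_adata(np.zeros((0, 5)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kept, anno = qc_filter(adata)
    assert kept.n_obs == 0 and len(anno) == 0


def test_qc_filter_idempotent_with_original_cutoffs():
    adata = scripted_qc_fixture(seed=1)
    t = QCThresholds(per_sample=False)
    once, _ = qc_filter(adata, t)
    twice, _ = qc_filter(once, t, reference=adata)
    assert list(twice.obs_names) == list(once.obs_names)


def test_qc_unknown_mito_prefix_warns_and_zeroes():
    adata = make_adata(np.ones((5, 10)))
    with pytest.warns(UserWarning, match="mito"):
        m = qc_metrics(adata, mito_prefix="ZZ-")
    assert (m["mito_fraction"] == 0).all()


# ---------------------------------------------------------------------------
# normalization

def test_normalize_identities_and_hand_computation():
    X = np.array([[1.0, 2.0, 3.0],
                  [0.0, 0.0, 0.0],
                  [0.0, 7.0, 0.0]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        norm = normalize_log(make_adata(X))
    V = np.asarray(norm.X.toarray() if hasattr(norm.X, "toarray") else norm.X)
    # all-zero cell stays zero
    assert (V[1] == 0).all()
    # single expressed gene maps to log1p(target) regardless of its count
    assert V[2, 1] == pytest.approx(math.log1p(1e4), rel=1e-12)
    # hand computation for the first cell
    for j, c in enumerate([1, 2, 3]):
        assert V[0, j] == pytest.approx(math.log1p(c / 6 * 1e4), rel=1e-12)
    assert (V >= 0).all()


def test_normalize_preserves_within_cell_ranks(null_cohort):
    _, adata, _ = null_cohort
    norm = normalize_log(adata[:30].copy())
    raw = adata[:30].X.toarray()
    V = norm.X.toarray()
    for i in range(raw.shape[0]):
        assert np.array_equal(np.argsort(raw[i], kind="stable"),
                              np.argsort(V[i], kind="stable"))


# ---------------------------------------------------------------------------
# clustering

def two_blob_adata(n=120, g=40, gap=6.0, seed=0, shuffle=False):
    rng = np.random.default_rng(seed)
    X = rng.normal(2.0, 0.3, (n, g))
    X[: n // 2, : g // 2] += gap
    X = np.clip(X, 0, None)
    labels = ["A"] * (n // 2) + ["B"] * (n - n // 2)
    adata = make_adata(X, truth=labels)
    if shuffle:
        order = rng.permutation(n)
        adata = adata[order].copy()
    return adata


def test_cluster_recovers_separated_populations_and_is_deterministic():
    adata = two_blob_adata()
    lab1 = cluster_cells(adata, resolution=0.5, seed=0)
    lab2 = cluster_cells(adata, resolution=0.5, seed=0)
    assert (lab1 == lab2).all()
    assert adjusted_rand_score(adata.obs["truth"], lab1) == 1.0


def test_cluster_single_population_low_resolution_one_cluster():
    rng = np.random.default_rng(1)
    adata = make_adata(np.clip(rng.normal(2, 0.3, (80, 30)), 0, None))
    lab = cluster_cells(adata, resolution=0.1, seed=0)
    assert lab.nunique() == 1


def test_cluster_invariant_to_cell_order_up_to_relabel():
    a = two_blob_adata(seed=3)
    b = two_blob_adata(seed=3, shuffle=True)
    la = cluster_cells(a, resolution=0.5, seed=0)
    lb = cluster_cells(b, resolution=0.5, seed=0).reindex(a.obs_names)
    assert adjusted_rand_score(la, lb) == 1.0


def test_cluster_few_cells_reduces_k_with_warning():
    rng = np.random.default_rng(2)
    adata = make_adata(np.clip(rng.normal(2, 0.5, (8, 20)), 0, None))
    with pytest.warns(UserWarning, match="k_neighbors"):
        lab = cluster_cells(adata, k_neighbors=15, seed=0)
    assert len(lab) == 8


# ---------------------------------------------------------------------------
# markers & annotation

def marker_fixture(seed=0):
    """Two populations; gene 0 4-fold up in A; gene 1 expressed in only 5% of A."""
    rng = np.random.default_rng(seed)
    n = 200
    X = rng.poisson(3.0, (n, 30)).astype(float)
    labels = np.array(["A"] * 100 + ["B"] * 100)
    X[:100, 0] *= 4
    X[:, 1] = 0
    X[rng.choice(100, 5, replace=False), 1] = 5.0   # 5% of cluster A
    adata = make_adata(np.log1p(X))
    return adata, pd.Series(labels, index=adata.obs_names)


def test_find_markers_filters_and_detects_planted_marker():
    adata, labels = marker_fixture()
    table = find_markers(adata, labels)
    a_rows = table[table["cluster"] == "A"]
    assert "g0" in set(a_rows["gene"])
    row = a_rows[a_rows["gene"] == "g0"].iloc[0]
    assert row["log_fold_change"] > 0.25 and row["pct_in_cluster"] > 0.10
    # low-detection gene excluded by the 10% rule
    assert "g1" not in set(table["gene"])
    # every row satisfies the stated filters
    assert (table["pct_in_cluster"] > 0.10).all()
    assert (table["log_fold_change"] > 0.25).all()


def test_find_markers_null_identical_clusters_empty_at_fdr():
    rng = np.random.default_rng(5)
    X = np.log1p(rng.poisson(3.0, (300, 50)).astype(float))
    adata = make_adata(X)
    labels = pd.Series(rng.permutation(["A"] * 150 + ["B"] * 150), index=adata.obs_names)
    table = find_markers(adata, labels)
    assert (table["adjusted_p"] < 0.05).sum() == 0


def test_find_markers_requires_two_clusters():
    adata, labels = marker_fixture()
    with pytest.raises(ValueError):
        find_markers(adata, pd.Series("A", index=adata.obs_names))


def test_annotate_clusters_assigns_planted_types_and_unassigned():
    rng = np.random.default_rng(6)
    X = np.log1p(rng.poisson(1.0, (90, 10)).astype(float))
    X[:30, 0:2] += 3.0    # cluster 0: markers of 'cancer'
    X[30:60, 2:4] += 3.0  # cluster 1: markers of 'tcell'
    X[60:, :] = 0.0       # cluster 2: expresses nothing
    adata = make_adata(X)
    labels = pd.Series(["0"] * 30 + ["1"] * 30 + ["2"] * 30, index=adata.obs_names)
    db = {"cancer": ["g0", "g1"], "tcell": ["g2", "g3"]}
    anno = annotate_clusters(pd.DataFrame(), adata, labels, db)
    assert (anno.loc[labels == "0", "cell_type"] == "cancer").all()
    assert (anno.loc[labels == "1", "cell_type"] == "tcell").all()
    assert (anno.loc[labels == "2", "cell_type"] == "unassigned").all()


def test_annotate_clusters_tie_breaks_lexicographically_and_flags():
    X = np.ones((10, 2))
    adata = make_adata(X)
    labels = pd.Series(["0"] * 10, index=adata.obs_names)
    db = {"beta": ["g0", "g1"], "alpha": ["g0", "g1"]}  # identical marker lists
    anno = annotate_clusters(pd.DataFrame(), adata, labels, db)
    assert (anno["cell_type"] == "alpha").all()
    assert anno["assignment_tied"].all()
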