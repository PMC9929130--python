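"""CNV inference, scoring, malignancy calling, event calling and tree tests."""

import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from metaniche import cnv as cv
from metaniche.cnv import (
    infer_cnv, cnv_score, cluster_cnv_profiles, call_malignant,
    call_events, build_clonality_tree, CNVEvent,
)
from tests.conftest import make_adata


def brute_force_cnv(X, chroms, ref_mask, window=101, clip_sd=1.5,
                    min_cells=20, center_cells=False):
    """Independent naive reimplementation: per-gene loops and per-position
    window slices. Genes are assumed already in chromosome order."""
    X = np.asarray(X, float)
    keep = [(X[:, j] > 0).sum() > min_cells for j in range(X.shape[1])]
    X = X[:, keep]
    chroms = [c for c, k in zip(chroms, keep) if k]
    n, g = X.shape
    centered = np.empty_like(X)
    for j in range(g):
        col = X[:, j]
        c = col - col.mean()
        b = clip_sd * c.std()
        centered[:, j] = np.minimum(np.maximum(c, -b), b)
    smoothed = np.empty_like(centered)
    half = window // 2
    for c in sorted(set(chroms), key=chroms.index):
        idx = [j for j, cc in enumerate(chroms) if cc == c]
        L = len(idx)
        for pos, j in enumerate(idx):
            h = min(half, pos, L - 1 - pos)
            cols = idx[pos - h : pos + h + 1]
            smoothed[:, j] = centered[:, cols].mean(axis=1)
    if center_cells:
        smoothed = smoothed - np.median(smoothed, axis=1, keepdims=True)
    ref_profile = smoothed[ref_mask].mean(axis=0)
    return smoothed - ref_profile, keep


def _positions(chroms):
    pos, counter = [], {}
    for c in chroms:
        counter[c] = counter.get(c, -1) + 1
        pos.append(counter[c])
    return pos


@pytest.mark.parametrize("center_cells", [False, True])
def test_infer_cnv_matches_bruteforce_oracle(center_cells):
    rng = np.random.default_rng(0)
    n, g, window = 80, 250, 21
    X = rng.gamma(2.0, 1.0, (n, g))
    X[rng.random((n, g)) < 0.3] = 0.0
    chroms = ["chr1"] * 120 + ["chr2"] * 90 + ["chr3"] * 40  # chr3 < window
    adata = make_adata(X, var_names=[f"g{i}" for i in range(g)])
    gene_pos = pd.DataFrame({"gene_id": adata.var_names, "chromosome": chroms,
                             "start": _positions(chroms)})
    refs = list(adata.obs_names[:30])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prof = infer_cnv(adata, gene_pos, refs, window=window, min_cells=10,
                         center_cells=center_cells)
    ref_mask = np.zeros(n, bool); ref_mask[:30] = True
    expected, keep = brute_force_cnv(X, chroms, ref_mask, window=window,
                                     min_cells=10, center_cells=center_cells)
    assert prof.values.shape == expected.shape
    assert np.max(np.abs(prof.values - expected)) <= 1e-10


def test_infer_cnv_all_reference_is_null():
    rng = np.random.default_rng(1)
    X = rng.gamma(2.0, 1.0, (50, 120))
    chroms = ["chr1"] * 120
    adata = make_adata(X)
    gene_pos = pd.DataFrame({"gene_id": adata.var_names, "chromosome": chroms,
                             "start": list(range(120))})
    prof = infer_cnv(adata, gene_pos, list(adata.obs_names), window=11, min_cells=5)
    # subtracting the mean over all cells leaves zero-mean columns, not zeros;
    # the self-reference null is that the MEAN profile is exactly 0
    assert np.max(np.abs(prof.values.mean(axis=0))) <= 1e-12


def test_infer_cnv_constant_offset_cell():
    """One query cell whose centered, clipped values are a constant d while the
    reference is symmetric around 0 -> its smoothed central deviation is d."""
    g = 101
    ref = np.vstack([np.full(g, 1.0), np.full(g, 3.0)] * 25)  # mean 2 per gene, sd 1
    query = np.full((1, g), 2.0 + 0.5)                        # centered value +0.5 everywhere
    X = np.vstack([ref, query])
    adata = make_adata(X)
    gene_pos = pd.DataFrame({"gene_id": adata.var_names, "chromosome": "chr1",
                             "start": list(range(g))})
    prof = infer_cnv(adata, gene_pos, list(adata.obs_names[:-1]), window=101, min_cells=5)
    center = g // 2
    assert prof.values[-1, center] == pytest.approx(0.5, abs=1e-10)


def test_infer_cnv_shift_invariance():
    rng = np.random.default_rng(2)
    X = rng.gamma(2.0, 1.0, (40, 60))
    chroms = ["chr1"] * 60
    gene_pos = pd.DataFrame({"gene_id": [f"g{i}" for i in range(60)],
                             "chromosome": chroms, "start": list(range(60))})
    a1 = make_adata(X)
    a2 = make_adata(X + 5.0)
    refs = list(a1.obs_names[:15])
    p1 = infer_cnv(a1, gene_pos, refs, window=11, min_cells=5)
    p2 = infer_cnv(a2, gene_pos, refs, window=11, min_cells=5)
    assert np.allclose(p1.values, p2.values, atol=1e-12)


def test_infer_cnv_requires_reference():
    adata = make_adata(np.ones((5, 10)))
    gene_pos = pd.DataFrame({"gene_id": adata.var_names, "chromosome": "chr1",
                             "start": list(range(10))})
    with pytest.raises(ValueError, match="reference"):
        infer_cnv(adata, gene_pos, [])


def test_cnv_score_closed_forms():
    genes = pd.DataFrame({"gene_id": ["a", "b"], "chromosome": "chr1", "start": [0, 1]})
    prof = cv.CNVProfile(values=np.zeros((2, 2)), cell_ids=pd.Index(["x", "y"]),
                         genes=genes, reference_cell_ids=["x"])
    assert (cnv_score(prof) == 0).all()
    d = 0.3
    prof.values = np.full((2, 2), d)
    assert cnv_score(prof)["x"] == pytest.approx(np.log1p(d * d), rel=1e-12)


def test_monotonicity_in_planted_fold(cnv_cohort):
    """Mean on-segment deviation never decreases with the planted fold."""
    from metaniche.sim import SimConfig, CNVSegmentTruth, simulate_counts
    from metaniche.preprocess import normalize_log
    means = []
    for fold in (1.2, 1.5, 2.0):
        cfg = SimConfig(
            n_samples=1, organ_label_per_sample=("liver",),
            n_cells_per_type_per_sample={"cancer": 80, "T_cell": 60},
            n_genes=600, n_chromosomes=3,
            cnv_segments=[CNVSegmentTruth("chr1", 20, 140, fold, 1.0, None)],
            n_auto_markers_per_type=0, seed=55,
        )
        adata, truth = simulate_counts(cfg)
        norm = normalize_log(adata)
        refs = [b for b in norm.obs_names if truth.cells.loc[b, "cell_type"] == "T_cell"]
        prof = infer_cnv(norm, truth.gene_annotation, refs, center_cells=True)
        mal = truth.cells.loc[prof.cell_ids, "is_malignant"].to_numpy()
        seg = (prof.genes["chromosome"] == "chr1").to_numpy()
        seg &= prof.genes["start"].between(20, 140).to_numpy()
        means.append(prof.values[np.ix_(mal, seg)].mean())
    assert means[0] <= means[1] <= means[2]


def test_cluster_cnv_profiles_recovers_subclones_and_is_deterministic(cnv_cohort):
    _, norm, truth, refs = cnv_cohort
    prof = infer_cnv(norm, truth.gene_annotation, refs, center_cells=True)
    mal = truth.cells.loc[prof.cell_ids, "is_malignant"]
    lab1 = cluster_cnv_profiles(prof, k=2, cells=mal.index[mal])
    lab2 = cluster_cnv_profiles(prof, k=2, cells=mal.index[mal])
    assert (lab1 == lab2).all()
    ari = adjusted_rand_score(truth.cells.loc[lab1.index, "subclone"], lab1)
    assert ari > 0.8


def test_cluster_cnv_identical_rows_and_k_errors():
    genes = pd.DataFrame({"gene_id": ["a", "b"], "chromosome": "chr1", "start": [0, 1]})
    prof = cv.CNVProfile(values=np.ones((4, 2)), cell_ids=pd.Index(list("wxyz")),
                         genes=genes, reference_cell_ids=["w"])
    assert cluster_cnv_profiles(prof, k=1).nunique() == 1
    with pytest.raises(ValueError):
        cluster_cnv_profiles(prof, k=9)


def test_call_malignant_reference_median_and_null_rate():
    rng = np.random.default_rng(3)
    scores = pd.Series(rng.normal(0.02, 0.005, 500).clip(0),
                       index=[f"c{i}" for i in range(500)])
    clusters = pd.Series("HCL1", index=scores.index)
    calls = call_malignant(scores, scores, clusters)
    med_cell = (scores - scores.median()).abs().idxmin()
    assert not calls.loc[med_cell, "is_malignant"]
    assert calls["is_malignant"].mean() <= 0.01


def test_call_malignant_degenerate_reference_warns():
    scores = pd.Series([1.0, 1.0, 2.0], index=list("abc"))
    ref = pd.Series([1.0, 1.0], index=list("ab"))
    clusters = pd.Series(["x", "x", "y"], index=list("abc"))
    with pytest.warns(UserWarning, match="degenerate"):
        calls = call_malignant(scores, ref, clusters)
    assert calls.loc["c", "is_malignant"]


def _toy_profile(dev_rows, chroms):
    g = len(chroms)
    genes = pd.DataFrame({"gene_id": [f"g{i}" for i in range(g)],
                          "chromosome": chroms, "start": _positions(chroms)})
    V = np.asarray(dev_rows, float)
    return cv.CNVProfile(values=V, cell_ids=pd.Index([f"c{i}" for i in range(len(V))]),
                         genes=genes, reference_cell_ids=[])


def test_call_events_canonical_rule_and_neutral_case():
    chroms = ["chr1"] * 60
    # subclone A: all 10 cells carry a gain over genes 10..49
    gain = np.zeros(60); gain[10:50] = 0.4
    rows = [gain.copy() for _ in range(10)]
    # subclone B: only 6 of 10 cells carry it (60% -> noncanonical)
    rows += [gain.copy() if i < 6 else np.zeros(60) for i in range(10)]
    prof = _toy_profile(rows, chroms)
    sub = pd.Series(["A"] * 10 + ["B"] * 10, index=prof.cell_ids)
    events = call_events(prof, sub, min_span_genes=20)
    by_sub = {e.subclone_id: e for e in events}
    assert by_sub["A"].direction == "gain" and by_sub["A"].canonical
    assert by_sub["A"].cell_percent == 100.0
    assert by_sub["B"].cell_percent == 60.0 and not by_sub["B"].canonical
    # neutral profile -> no events
    assert call_events(_toy_profile(np.zeros((5, 60)), chroms),
                       pd.Series("A", index=[f"c{i}" for i in range(5)])) == []


def _ev(key, sub, pct=100.0, chrom="chr1", lo=0, hi=40, direction="gain"):
    return CNVEvent(chromosome=chrom, start_index=lo, end_index=hi,
                    direction=direction, subclone_id=sub, cell_percent=pct,
                    canonical=pct > 90, mean_deviation=0.3, key=key)


def test_tree_single_subclone_single_event():
    sub = pd.Series(["A"] * 7, index=[f"c{i}" for i in range(7)])
    tree = build_clonality_tree([_ev("E", "A")], sub)
    assert {e.key for e in tree.root.events} == {"E"}
    assert len(tree.root.children) == 1 and tree.root.children[0].name == "A"
    assert tree.leaf_cell_total() == 7


def test_tree_no_events_star():
    sub = pd.Series(["A"] * 3 + ["B"] * 4 + ["C"] * 5,
                    index=[f"c{i}" for i in range(12)])
    tree = build_clonality_tree([], sub)
    assert tree.root.events == []
    assert sorted(c.name for c in tree.root.children) == ["A", "B", "C"]
    assert tree.leaf_cell_total() == 12


def test_tree_nested_truth_topology():
    """Truth root->{A}, A->{A,B}, A->{A,C}: trunk event on root, private events
    on the two leaves."""
    sub = pd.Series(["s1"] * 6 + ["s2"] * 4, index=[f"c{i}" for i in range(10)])
    events = [
        _ev("trunk", "s1", chrom="chr1"), _ev("trunk", "s2", chrom="chr1"),
        _ev("privB", "s1", chrom="chr2"),
        _ev("privC", "s2", chrom="chr3", direction="loss"),
    ]
    tree = build_clonality_tree(events, sub)
    assert {e.key for e in tree.root.events} == {"trunk"}
    leaves = {c.name: c for c in tree.root.children}
    assert set(leaves) == {"s1", "s2"}
    assert {e.key for e in leaves["s1"].events} == {"privB"}
    assert {e.key for e in leaves["s2"].events} == {"privC"}
    assert all(e.canonical for n in [tree.root, *tree.root.children] for e in n.events)
    assert tree.leaf_cell_total() == 10
    # serializations are well formed
    assert tree.to_newick().endswith(";")
    assert "trunk" in tree.to_json()


def test_tree_event_sets_nest_along_branches(cnv_cohort):
    """Every non-root node's cumulative event set contains its parent's."""
    _, norm, truth, refs = cnv_cohort
    prof = infer_cnv(norm, truth.gene_annotation, refs, center_cells=True)
    mal = truth.cells.loc[prof.cell_ids, "is_malignant"]
    sub = cluster_cnv_profiles(prof, k=2, cells=mal.index[mal])
    events = call_events(prof, sub)
    tree = build_clonality_tree(events, sub)

    def check(node, inherited):
        cum = inherited | {e.key for e in node.events}
        assert inherited <= cum
        for ch in node.children:
            check(ch, cum)

    check(tree.root, set())
    assert tree.leaf_cell_total() == int(mal.sum())
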