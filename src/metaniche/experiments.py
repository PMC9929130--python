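"""End-to-end recovery experiments on planted synthetic cohorts.

Each function generates a cohort whose ground truth encodes one planted
phenomenon, runs the corresponding pipeline stage from scratch, and returns
the measured recovery quantities. These are the package's headline
computations: the analysis drivers narrate them and the acceptance machinery
re-runs them from a single seed.

Problem sizes are chosen so the full battery runs in a few minutes on one CPU
while keeping every planted effect at the study conditions (fold-2 copy-number
segments of >=100 genes, activation-fold-3 programs active in 40% of cells,
ligand-receptor effect fold 5, 1000-permutation tests).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .sim import (
    SimConfig, CNVSegmentTruth, ProgramTruth, LRTruth,
    simulate_counts, plant_dependency,
)
from . import preprocess as pp
from . import cnv as cv
from . import programs as pr
from . import interactions as ix
from . import signatures as sg


def _spread_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


# ---------------------------------------------------------------------------
# CNV windowing vs a naive reference implementation

def naive_cnv_reference(X, chroms, ref_mask, window=101, clip_sd=1.5, min_cells=20):
    """Plain per-gene/per-window reference implementation of the CNV pipeline
    (no cumulative sums), used as the independent check of the fast path."""
    X = np.asarray(X, float)
    keep = [(X[:, j] > 0).sum() > min_cells for j in range(X.shape[1])]
    X = X[:, [j for j, k in enumerate(keep) if k]]
    chroms = [c for c, k in zip(chroms, keep) if k]
    centered = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j] - X[:, j].mean()
        b = clip_sd * col.std()
        centered[:, j] = np.minimum(np.maximum(col, -b), b)
    smoothed = np.empty_like(centered)
    half = window // 2
    seen = []
    for c in chroms:
        if c not in seen:
            seen.append(c)
    for c in seen:
        idx = [j for j, cc in enumerate(chroms) if cc == c]
        L = len(idx)
        for posn, j in enumerate(idx):
            h = min(half, posn, L - 1 - posn)
            cols = idx[posn - h : posn + h + 1]
            smoothed[:, j] = centered[:, cols].mean(axis=1)
    return smoothed - smoothed[ref_mask].mean(axis=0)


def run_cnv_oracle_check(seed: int, n_cells: int = 300, n_genes: int = 400) -> dict:
    """Max |difference| between infer_cnv and the naive reference on a random
    sparse matrix spanning several chromosomes."""
    rng = np.random.default_rng(seed)
    X = rng.gamma(2.0, 1.0, (n_cells, n_genes))
    X[rng.random(X.shape) < 0.4] = 0.0
    per = n_genes // 4
    chroms = [f"chr{1 + min(j // per, 3)}" for j in range(n_genes)]
    starts, counter = [], {}
    for c in chroms:
        counter[c] = counter.get(c, -1) + 1
        starts.append(counter[c])
    import anndata as ad
    adata = ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=[f"c{i}" for i in range(n_cells)]),
        var=pd.DataFrame(index=[f"g{j}" for j in range(n_genes)]),
    )
    gene_pos = pd.DataFrame({"gene_id": adata.var_names, "chromosome": chroms,
                             "start": starts})
    refs = list(adata.obs_names[: n_cells // 3])
    prof = cv.infer_cnv(adata, gene_pos, refs, window=101, min_cells=20)
    ref_mask = np.zeros(n_cells, bool)
    ref_mask[: n_cells // 3] = True
    expected = naive_cnv_reference(X, chroms, ref_mask, window=101, min_cells=20)
    return {
        "max_abs_diff": float(np.max(np.abs(prof.values - expected))),
        "n": int(n_cells * n_genes),
    }


# ---------------------------------------------------------------------------
# malignancy recovery

def _cnv_cohort_config(seed: int) -> SimConfig:
    """40% malignant cells carrying a fold-2 truncal gain plus one private
    fold-2 gain / fold-0.5 loss (>=100 genes each) per subclone."""
    return SimConfig(
        n_samples=2, organ_label_per_sample=("liver", "brain"),
        n_cells_per_type_per_sample={"cancer": 100, "T_cell": 80, "B_cell": 70},
        n_genes=1200, n_chromosomes=6,
        cnv_segments=[
            CNVSegmentTruth("chr1", 10, 130, 2.0, 1.0, None),
            CNVSegmentTruth("chr2", 0, 110, 0.5, 1.0, "s1"),
            CNVSegmentTruth("chr3", 20, 140, 2.0, 1.0, "s2"),
        ],
        seed=seed,
    )


def _cnv_pipeline(seed: int):
    cfg = _cnv_cohort_config(seed)
    adata, truth = simulate_counts(cfg)
    norm = pp.normalize_log(adata)
    refs = [b for b in norm.obs_names
            if truth.cells.loc[b, "cell_type"] in ("T_cell", "B_cell")]
    prof = cv.infer_cnv(norm, truth.gene_annotation, refs, center_cells=True)
    scores = cv.cnv_score(prof)
    clusters = cv.cluster_cnv_profiles(prof, k=4)
    calls = cv.call_malignant(scores, scores[refs], clusters)
    return cfg, truth, prof, calls


def run_cnv_recovery(seed: int, n_seeds: int = 5) -> dict:
    sens, spec = [], []
    for s in _spread_seeds(seed, n_seeds):
        _, truth, _, calls = _cnv_pipeline(s)
        is_mal = truth.cells.loc[calls.index, "is_malignant"].to_numpy()
        sens.append(calls.loc[is_mal, "is_malignant"].mean())
        spec.append((~calls.loc[~is_mal, "is_malignant"]).mean())
    return {
        "sensitivity": float(np.mean(sens)),
        "specificity": float(np.mean(spec)),
        "min_sensitivity": float(np.min(sens)),
        "min_specificity": float(np.min(spec)),
        "n": n_seeds,
    }


def run_tree_recovery(seed: int, n_seeds: int = 5) -> dict:
    """Fraction of seeds where the trunk + two-private-subclone topology is
    recovered with the correct canonical flags."""
    recovered = 0
    for s in _spread_seeds(seed, n_seeds):
        cfg, truth, prof, _ = _cnv_pipeline(s)
        mal = truth.cells.loc[prof.cell_ids, "is_malignant"]
        sub = cv.cluster_cnv_profiles(prof, k=2, cells=mal.index[mal])
        events = cv.call_events(prof, sub)
        tree = cv.build_clonality_tree(events, sub)
        ok = (
            len(tree.root.children) == 2
            and {e.chromosome for e in tree.root.events} == {"chr1"}
            and all(e.direction == "gain" and e.canonical for e in tree.root.events)
        )
        if ok:
            leaf_keys = []
            for leaf in tree.root.children:
                if not leaf.events or not all(e.canonical for e in leaf.events):
                    ok = False
                    break
                leaf_keys.append({(e.chromosome, e.direction) for e in leaf.events})
            if ok:
                ok = (
                    {("chr2", "loss")} in leaf_keys and {("chr3", "gain")} in leaf_keys
                )
        recovered += bool(ok)
    return {"recovered_fraction": recovered / n_seeds, "n": n_seeds}


# ---------------------------------------------------------------------------
# expression-program recovery

def program_recovery_config(seed: int) -> SimConfig:
    """4 samples x 500 cancer cells, 3 disjoint 40-gene programs at
    activation fold 3 and active fraction 0.4."""
    def gr(a, b):
        return [f"G{i:04d}" for i in range(a, b)]
    return SimConfig(
        n_samples=4,
        organ_label_per_sample=("liver", "liver", "brain", "brain"),
        n_cells_per_type_per_sample={"cancer": 500},
        n_genes=1000, n_chromosomes=5,
        programs=[
            ProgramTruth("P1", gr(600, 640), 3.0, 0.4),
            ProgramTruth("P2", gr(700, 740), 3.0, 0.4),
            ProgramTruth("P3", gr(800, 840), 3.0, 0.4),
        ],
        seed=seed,
    )


def run_program_recovery(seed: int, n_seeds: int = 10) -> dict:
    """Per seed: discover recurrent meta-programs and match them to truth by
    the consensus-gene Jaccard index. Success = exactly 3 recurrent programs,
    each with Jaccard >= 0.7 against a distinct planted program."""
    successes, jaccards = 0, []
    for s in _spread_seeds(seed, n_seeds):
        cfg = program_recovery_config(s)
        adata, truth = simulate_counts(cfg)
        norm = pp.normalize_log(adata)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mods = pr.extract_modules(norm, malignant=truth.cells["is_malignant"], seed=s % 97)
            programs = [p for p in pr.aggregate_modules(mods) if p.recurrent]
        truth_sets = [set(p.gene_set) for p in cfg.programs]
        best = []
        for mp in programs:
            cg = set(mp.consensus_genes)
            best.append(max(len(cg & t) / len(cg | t) for t in truth_sets))
        jaccards.extend(best)
        successes += int(len(programs) == 3 and all(j >= 0.7 for j in best))
    return {
        "recovery_rate": successes / n_seeds,
        "mean_jaccard": float(np.mean(jaccards)) if jaccards else 0.0,
        "n": n_seeds,
    }


def run_dependency_classification(seed: int, n_seeds: int = 10, n_cells: int = 2000) -> dict:
    """Planted cooccur/exclude/independent pairs classified via the +/-0.1
    corrected log-odds thresholds."""
    correct = 0
    total = 0
    for s in _spread_seeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        for rule, expected in (("cooccur", "cooccurring"), ("exclude", "exclusive"),
                               ("independent", "neither")):
            a = rng.random(n_cells) < 0.4
            b = rng.random(n_cells) < 0.4
            na, nb = plant_dependency(a, b, rule, seed=s + 1)
            ind = pd.DataFrame({"p": na, "q": nb},
                               index=[f"c{i}" for i in range(n_cells)])
            _, cls = pr.dependency_log_odds(ind)
            correct += int(cls.loc["p", "q"].split("|")[0] == expected)
            total += 1
    # hand-computed 2x2 oracles with the 0.5 correction
    oracle_cooccur = float(np.log(40.5 * 40.5 / (10.5 * 10.5)))
    oracle_exclude = float(np.log(0.5 * 0.5 / (50.5 * 50.5)))
    ind1 = pd.DataFrame({
        "p": [True] * 50 + [False] * 50,
        "q": [True] * 40 + [False] * 10 + [True] * 10 + [False] * 40,
    })
    v1, _ = pr.dependency_log_odds(ind1)
    ind2 = pd.DataFrame({
        "p": [True] * 50 + [False] * 50,
        "q": [False] * 50 + [True] * 50,
    })
    v2, _ = pr.dependency_log_odds(ind2)
    return {
        "classification_accuracy": correct / total,
        "oracle_cooccur_diff": abs(float(v1.loc["p", "q"]) - oracle_cooccur),
        "oracle_exclude_diff": abs(float(v2.loc["p", "q"]) - oracle_exclude),
        "log_odds_cooccur_table": float(v1.loc["p", "q"]),
        "log_odds_exclude_table": float(v2.loc["p", "q"]),
        "n": total,
    }


# ---------------------------------------------------------------------------
# ligand-receptor permutation testing

def run_lr_calibration(seed: int, n_pairs: int = 50, n_perm: int = 1000) -> dict:
    """Type-I calibration under a fully null cohort (50 pairs over the 6
    ordered type pairs of 3 types) and power on a planted effect-fold-5 pair.

    The calibration cohort plants nothing at all — not even type markers —
    because label permutation assumes exchangeable cells: any type effect
    (markers shift each type's library-normalization factor) is real signal,
    not a type-I error."""
    cfg = SimConfig(
        n_samples=2, organ_label_per_sample=("liver", "brain"),
        n_cells_per_type_per_sample={"cancer": 150, "T_cell": 120, "myeloid": 120},
        n_genes=800, n_chromosomes=4,
        n_auto_markers_per_type=0,
        seed=seed,
    )
    adata, truth = simulate_counts(cfg)
    norm = pp.normalize_log(adata)
    rng = np.random.default_rng(seed + 1)
    genes = rng.choice(norm.var_names, size=2 * n_pairs, replace=False)
    db = pd.DataFrame({
        "pair_id": [f"null{i}" for i in range(n_pairs)],
        "ligand": genes[:n_pairs], "receptor": genes[n_pairs:],
    })
    res = ix.interaction_test(norm, truth.cells.loc[norm.obs_names, "cell_type"],
                              db, n_perm=n_perm, seed=seed + 2, include_self=False)
    tested = res[res["tested"]]
    frac = float((tested["p_value"] < 0.05).mean())
    se = float(np.sqrt(0.05 * 0.95 / len(tested)))

    # power: planted pair
    cfg2 = SimConfig(
        n_samples=2, organ_label_per_sample=("liver", "brain"),
        n_cells_per_type_per_sample={"cancer": 150, "T_cell": 120, "myeloid": 120},
        n_genes=800, n_chromosomes=4,
        lr_truth=[LRTruth("G0050", "G0051", "myeloid", "cancer", 5.0)],
        seed=seed + 3,
    )
    adata2, truth2 = simulate_counts(cfg2)
    norm2 = pp.normalize_log(adata2)
    db2 = pd.DataFrame({"pair_id": ["planted"], "ligand": ["G0050"], "receptor": ["G0051"]})
    res2 = ix.interaction_test(norm2, truth2.cells.loc[norm2.obs_names, "cell_type"],
                               db2, n_perm=n_perm, seed=seed + 4)
    row = res2[(res2.sender_type == "myeloid") & (res2.receiver_type == "cancer")].iloc[0]
    return {
        "null_fraction_p_lt_05": frac,
        "band_halfwidth": 3 * se,
        "n_null_tests": int(len(tested)),
        "planted_p": float(row["p_value"]),
        "planted_significant": bool(row["significant"]),
        "planted_stat": float(row["mean_stat"]),
        "n": int(n_perm),
    }


# ---------------------------------------------------------------------------
# cycling recovery

def run_cycle_recovery(seed: int) -> dict:
    def gr(a, b):
        return [f"G{i:04d}" for i in range(a, b)]
    s_genes, g2m_genes = gr(500, 540), gr(560, 600)
    cfg = SimConfig(
        n_samples=2, organ_label_per_sample=("liver", "brain"),
        n_cells_per_type_per_sample={"cancer": 300},
        n_genes=800, n_chromosomes=4,
        programs=[ProgramTruth("cycS", s_genes, 3.0, 0.5),
                  ProgramTruth("cycG2M", g2m_genes, 3.0, 0.5)],
        program_dependency={("cycS", "cycG2M"): "cooccur"},
        seed=seed,
    )
    adata, truth = simulate_counts(cfg)
    norm = pp.normalize_log(adata)
    ph = sg.assign_phase(sg.module_score(norm, s_genes, seed=seed + 1),
                         sg.module_score(norm, g2m_genes, seed=seed + 2))
    cycling = (truth.program_activity["cycS"] | truth.program_activity["cycG2M"])
    cycling = cycling.reindex(norm.obs_names)
    return {
        "cycling_called_cycling": float(ph.loc[cycling, "cycling"].mean()),
        "quiescent_called_g1": float((ph.loc[~cycling, "phase"] == "G1").mean()),
        "n": int(norm.n_obs),
    }


# ---------------------------------------------------------------------------
# full default cohort, end to end

CHECKPOINT_GENES = ["LAG3", "TIGIT", "CD96", "KLRB1", "PDCD1",
                    "NECTIN2", "LGALS3", "CD274"]


def default_study_config(seed: int) -> SimConfig:
    """The default study cohort: six samples (3 liver, 3 brain), six cell
    types, a truncal fold-2 gain plus two private subclone segments, three
    40-gene activity programs, one planted myeloid->cancer ligand-receptor
    pair, and a checkpoint-gene panel in which the inhibitory receptors
    LAG3/TIGIT/CD96/KLRB1 are elevated in T cells while PDCD1 stays at
    baseline, and NECTIN2/LGALS3 are elevated in cancer cells while CD274
    stays at baseline."""
    def gr(a, b):
        return [f"G{i:04d}" for i in range(a, b)]
    overrides = {860 + i: sym for i, sym in enumerate(CHECKPOINT_GENES)}
    t_markers = {g: 8.0 for g in gr(845, 850)}
    t_markers.update({"LAG3": 6.0, "TIGIT": 6.0, "CD96": 6.0, "KLRB1": 6.0,
                      "PDCD1": 1.0})
    c_markers = {g: 8.0 for g in gr(840, 845)}
    c_markers.update({"NECTIN2": 4.0, "LGALS3": 4.0, "CD274": 1.0})
    return SimConfig(
        cnv_segments=[
            CNVSegmentTruth("chr1", 20, 150, 2.0, 1.0, None),
            CNVSegmentTruth("chr2", 10, 140, 0.5, 1.0, "s1"),
            CNVSegmentTruth("chr3", 30, 160, 2.0, 1.0, "s2"),
        ],
        programs=[
            ProgramTruth("P1", gr(900, 940), 3.0, 0.4),
            ProgramTruth("P2", gr(1000, 1040), 3.0, 0.4),
            ProgramTruth("P3", gr(1100, 1140), 3.0, 0.4),
        ],
        lr_truth=[LRTruth("G0850", "G0851", "myeloid", "cancer", 5.0)],
        marker_genes_per_type={"T_cell": t_markers, "cancer": c_markers},
        gene_symbol_overrides=overrides,
        seed=seed,
    )


def run_default_cohort(seed: int) -> dict:
    """The whole pipeline on the default synthetic cohort: QC -> clustering ->
    annotation -> CNV/malignancy -> programs -> interactions -> signatures."""
    cfg = default_study_config(seed)
    adata, truth = simulate_counts(cfg)
    kept, anno = pp.qc_filter(adata)
    norm = pp.normalize_log(kept)
    labels = pp.cluster_cells(norm, resolution=1.2, seed=seed)
    markers = pp.find_markers(norm, labels)
    cells = pp.annotate_clusters(markers, norm, labels, truth.marker_db)
    truth_types = truth.cells.loc[norm.obs_names, "cell_type"]
    type_accuracy = float((cells["cell_type"] == truth_types).mean())

    refs = [b for b in norm.obs_names if cells.loc[b, "cell_type"] in ("T_cell", "B_cell")]
    prof = cv.infer_cnv(norm, truth.gene_annotation, refs, center_cells=True)
    scores = cv.cnv_score(prof)
    clusters = cv.cluster_cnv_profiles(prof, k=6)
    calls = cv.call_malignant(scores, scores[refs], clusters)
    is_mal_truth = truth.cells.loc[calls.index, "is_malignant"].to_numpy()
    sens = float(calls.loc[is_mal_truth, "is_malignant"].mean())
    spec = float((~calls.loc[~is_mal_truth, "is_malignant"]).mean())

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mods = pr.extract_modules(norm, malignant=calls["is_malignant"], seed=seed)
        programs = [p for p in pr.aggregate_modules(mods) if p.recurrent]
    mal_cells = norm[calls["is_malignant"].to_numpy()]
    n_sig_lr = 0
    if programs:
        assign = pr.assign_program_cells(mal_cells, programs)
    db = pd.DataFrame({"pair_id": ["planted"], "ligand": ["G0850"], "receptor": ["G0851"]})
    res = ix.interaction_test(norm, cells["cell_type"], db, n_perm=1000, seed=seed)
    n_sig_lr = int(res["significant"].sum())
    planted = res[(res.sender_type == "myeloid") & (res.receiver_type == "cancer")]
    return {
        "n_cells_post_qc": int(kept.n_obs),
        "n_clusters": int(labels.nunique()),
        "type_annotation_accuracy": type_accuracy,
        "malignant_sensitivity": sens,
        "malignant_specificity": spec,
        "n_recurrent_programs": len(programs),
        "planted_lr_significant": bool(planted["significant"].iloc[0]) if len(planted) else False,
        "n": int(adata.n_obs),
    }
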