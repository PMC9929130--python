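"""Reading 10x-style triplets, QC filtering, normalization, clustering,
marker detection and marker-based cluster annotation.

QC removes cells with fewer than 200 detected genes, cells in the top 2% by
detected genes or by total UMIs (a doublet surrogate, computed per sample),
and cells with more than 50% mitochondrial content. Clustering is PCA ->
kNN graph -> Leiden community detection at resolution 1.2 by default; markers
are one-vs-rest Wilcoxon rank-sum tests filtered to genes detected in >10% of
the cluster's cells with natural-log fold change > 0.25.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import anndata as ad
import scanpy as sc
from scipy import sparse, io as spio
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class QCThresholds:
    min_genes: int = 200
    top_gene_fraction: float = 0.02
    top_umi_fraction: float = 0.02
    max_mito_fraction: float = 0.5
    min_cells_per_gene_for_cnv: int = 20
    per_sample: bool = True

    def __post_init__(self):
        for f in (self.top_gene_fraction, self.top_umi_fraction, self.max_mito_fraction):
            if not 0 < f < 1:
                raise ValueError("QCThresholds fractions must be in (0, 1)")
        if self.min_genes < 0:
            raise ValueError("min_genes must be >= 0")


def read_tenx(indir: str | Path) -> ad.AnnData:
    """Read a matrix.mtx (genes x cells) + features.tsv + barcodes.tsv triplet.

    ``cell_metadata.tsv`` (barcode, sample, organ), if present, populates obs.
    """
    indir = Path(indir)
    X = sparse.csr_matrix(spio.mmread(indir / "matrix.mtx").T)
    feats = pd.read_csv(indir / "features.tsv", sep="\t", header=None)
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    adata = ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(feats[0].astype(str), name="gene_id")),
    )
    meta_path = indir / "cell_metadata.tsv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        for col in meta.columns:
            adata.obs[col] = meta.loc[adata.obs_names, col].astype("category")
    return adata


def qc_metrics(adata: ad.AnnData, mito_prefix: str = "MT-") -> pd.DataFrame:
    X = sparse.csr_matrix(adata.X)
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    n_umis = np.asarray(X.sum(axis=1)).ravel()
    mito_mask = adata.var_names.str.startswith(mito_prefix)
    if not mito_mask.any():
        warnings.warn(f"no genes match mito prefix {mito_prefix!r}; mito_fraction set to 0")
        mito = np.zeros(adata.n_obs)
    else:
        mito = np.asarray(X[:, mito_mask].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(n_umis > 0, mito / np.maximum(n_umis, 1), 0.0)
    return pd.DataFrame(
        {"n_genes": n_genes, "n_umis": n_umis, "mito_fraction": mito_frac},
        index=adata.obs_names,
    )


def _top_cutoffs(values: np.ndarray, groups: pd.Series | None, frac: float) -> pd.Series:
    """Per-group cutoff: the (1 - frac) quantile (method='higher'); cells
    strictly above it are the removed top fraction."""
    s = pd.Series(values)
    if groups is None:
        cut = float(np.quantile(values, 1 - frac, method="higher")) if len(values) else np.inf
        return pd.Series(cut, index=s.index)
    g = pd.Series(np.asarray(groups), index=s.index)
    cuts = s.groupby(g, observed=True).transform(
        lambda v: np.quantile(v, 1 - frac, method="higher") if len(v) else np.inf
    )
    return cuts


def qc_filter(
    adata: ad.AnnData,
    thresholds: QCThresholds | None = None,
    mito_prefix: str = "MT-",
    reference: ad.AnnData | None = None,
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Apply the four QC rules; returns (filtered matrix, per-cell annotation).

    The top-fraction cutoffs are quantiles of the ``reference`` matrix (the
    input itself by default). Passing the original matrix as ``reference``
    makes repeated filtering idempotent. The annotation records, per cell,
    which rule(s) fired.
    """
    t = thresholds or QCThresholds()
    if adata.n_obs == 0:
        warnings.warn("qc_filter: empty matrix")
        anno = pd.DataFrame(
            columns=["n_genes", "n_umis", "mito_fraction", "fail_min_genes",
                     "fail_top_genes", "fail_top_umis", "fail_mito", "qc_pass"]
        )
        return adata.copy(), anno
    metrics = qc_metrics(adata, mito_prefix)
    ref = adata if reference is None else reference
    ref_metrics = metrics if reference is None else qc_metrics(ref, mito_prefix)
    groups_ref = ref.obs["sample"] if (t.per_sample and "sample" in ref.obs) else None
    gene_cut_ref = _top_cutoffs(ref_metrics["n_genes"].to_numpy(), groups_ref, t.top_gene_fraction)
    umi_cut_ref = _top_cutoffs(ref_metrics["n_umis"].to_numpy(), groups_ref, t.top_umi_fraction)
    # map per-group cutoffs onto the cells being filtered
    if groups_ref is not None:
        gmap = pd.Series(gene_cut_ref.to_numpy(), index=np.asarray(groups_ref)).groupby(level=0).first()
        umap_ = pd.Series(umi_cut_ref.to_numpy(), index=np.asarray(groups_ref)).groupby(level=0).first()
        cell_groups = np.asarray(adata.obs["sample"])
        gene_cut = gmap.reindex(cell_groups).to_numpy()
        umi_cut = umap_.reindex(cell_groups).to_numpy()
    else:
        gene_cut = np.full(adata.n_obs, float(gene_cut_ref.iloc[0]))
        umi_cut = np.full(adata.n_obs, float(umi_cut_ref.iloc[0]))

    anno = metrics.copy()
    anno["fail_min_genes"] = metrics["n_genes"] < t.min_genes
    anno["fail_top_genes"] = metrics["n_genes"].to_numpy() > gene_cut
    anno["fail_top_umis"] = metrics["n_umis"].to_numpy() > umi_cut
    anno["fail_mito"] = metrics["mito_fraction"] > t.max_mito_fraction
    anno["qc_pass"] = ~(
        anno["fail_min_genes"] | anno["fail_top_genes"] | anno["fail_top_umis"] | anno["fail_mito"]
    )
    kept = adata[anno["qc_pass"].to_numpy()].copy()
    return kept, anno


def normalize_log(adata: ad.AnnData, target_sum: float = 1e4) -> ad.AnnData:
    """Library-size normalization to ``target_sum`` per cell, then log1p.

    All-zero cells are left as zeros (with a warning). Raw counts are kept in
    ``layers['counts']``.
    """
    out = adata.copy()
    out.layers["counts"] = sparse.csr_matrix(out.X).copy()
    totals = np.asarray(sparse.csr_matrix(out.X).sum(axis=1)).ravel()
    if (totals == 0).any():
        warnings.warn(f"normalize_log: {(totals == 0).sum()} all-zero cells left as zeros")
    sc.pp.normalize_total(out, target_sum=target_sum)
    sc.pp.log1p(out)
    return out


def cluster_cells(
    adata: ad.AnnData,
    resolution: float = 1.2,
    n_pcs: int = 30,
    k_neighbors: int = 15,
    seed: int = 0,
    key_added: str = "cluster",
) -> pd.Series:
    """PCA -> kNN graph -> Leiden modularity clustering at ``resolution``.

    Seeded and reproducible; k is reduced with a warning when there are fewer
    cells than neighbors. Returns per-cell labels (also stored in obs).
    """
    n = adata.n_obs
    if n < k_neighbors + 1:
        k_neighbors = max(2, n - 1)
        warnings.warn(f"cluster_cells: too few cells; reduced k_neighbors to {k_neighbors}")
    n_comps = int(min(n_pcs, n - 1, adata.n_vars - 1))
    work = adata.copy()
    sc.pp.pca(work, n_comps=n_comps, svd_solver="arpack", random_state=seed)
    sc.pp.neighbors(work, n_neighbors=k_neighbors, n_pcs=n_comps, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        sc.tl.leiden(work, resolution=resolution, random_state=seed,
                     key_added=key_added, flavor="leidenalg")
    labels = work.obs[key_added].astype(str).astype("category")
    labels.index = adata.obs_names
    adata.obs[key_added] = labels
    return labels


def find_markers(
    adata: ad.AnnData,
    labels: pd.Series | str = "cluster",
    min_pct: float = 0.10,
    min_logfc: float = 0.25,
    pseudocount: float = 1e-9,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum markers per cluster.

    logFC is the natural-log fold change of mean(expm1(norm)) + pseudocount,
    in-cluster vs out-cluster. Rows are filtered to pct_in_cluster > min_pct
    and log_fold_change > min_logfc, BH-adjusted, sorted by logFC descending
    within cluster.
    """
    lab = adata.obs[labels] if isinstance(labels, str) else labels
    lab = pd.Series(np.asarray(lab).astype(str), index=adata.obs_names)
    clusters = sorted(lab.unique())
    if len(clusters) < 2:
        raise ValueError("find_markers requires at least 2 clusters")
    X = sparse.csr_matrix(adata.X).toarray().astype(np.float64)
    expm1 = np.expm1(X)
    detected = X > 0
    rows = []
    for c in clusters:
        mask = (lab == c).to_numpy()
        n_in = int(mask.sum())
        if n_in < 2:
            warnings.warn(f"find_markers: cluster {c!r} has <2 cells; skipped")
            continue
        pct_in = detected[mask].mean(axis=0)
        pct_out = detected[~mask].mean(axis=0)
        mean_in = expm1[mask].mean(axis=0)
        mean_out = expm1[~mask].mean(axis=0)
        logfc = np.log(mean_in + pseudocount) - np.log(mean_out + pseudocount)
        keep = (pct_in > min_pct) & (logfc > min_logfc)
        if not keep.any():
            continue
        idx = np.flatnonzero(keep)
        with np.errstate(all="ignore"):
            res = stats.mannwhitneyu(X[mask][:, idx], X[~mask][:, idx],
                                     alternative="two-sided", axis=0)
        pvals = np.atleast_1d(res.pvalue)
        for j, gi in enumerate(idx):
            rows.append((c, adata.var_names[gi], logfc[gi], pct_in[gi], pct_out[gi], pvals[j]))
    table = pd.DataFrame(
        rows, columns=["cluster", "gene", "log_fold_change", "pct_in_cluster", "pct_outside", "p_value"]
    )
    if len(table):
        table["adjusted_p"] = multipletests(table["p_value"], method="fdr_bh")[1]
        table = (
            table.sort_values(["cluster", "log_fold_change"], ascending=[True, False])
            .reset_index(drop=True)
        )
    else:
        table["adjusted_p"] = pd.Series(dtype=float)
    return table


def annotate_clusters(
    markers: pd.DataFrame,
    adata: ad.AnnData,
    labels: pd.Series | str,
    marker_db: dict[str, list[str]],
) -> pd.DataFrame:
    """Assign each cluster the type whose marker list has the highest mean
    scaled (z-scored) expression in the cluster.

    Ties break lexicographically by type name (flagged); clusters with no
    marker expressed are 'unassigned'. Returns a per-cell frame with cluster,
    cell_type, assignment score and tie flag.
    """
    if not marker_db:
        raise ValueError("marker_db must be nonempty")
    lab = adata.obs[labels] if isinstance(labels, str) else labels
    lab = pd.Series(np.asarray(lab).astype(str), index=adata.obs_names)
    genes = sorted({g for gl in marker_db.values() for g in gl if g in adata.var_names})
    X = sparse.csr_matrix(adata[:, genes].X).toarray() if genes else np.zeros((adata.n_obs, 0))
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    Z = (X - mu) / np.where(sd > 0, sd, 1.0)
    gidx = {g: i for i, g in enumerate(genes)}
    records = {}
    for c in sorted(lab.unique()):
        mask = (lab == c).to_numpy()
        raw_any = X[mask].sum() > 0 if genes else False
        scores = {}
        for t in sorted(marker_db):
            cols = [gidx[g] for g in marker_db[t] if g in gidx]
            scores[t] = float(Z[np.ix_(mask, cols)].mean()) if cols else -np.inf
        if not raw_any:
            records[c] = ("unassigned", np.nan, False)
            continue
        best = max(scores.values())
        winners = sorted(t for t, s in scores.items() if s == best)
        records[c] = (winners[0], best, len(winners) > 1)
    out = pd.DataFrame(index=adata.obs_names)
    out["cluster"] = lab
    out["cell_type"] = [records[c][0] for c in lab]
    out["assignment_score"] = [records[c][1] for c in lab]
    out["assignment_tied"] = [records[c][2] for c in lab]
    return out
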