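"""Gene-set module scores, cell-cycle phase calls, expression entropy and
dot-plot summary statistics.

The module score is the classic bin-matched control scheme: the mean
expression of the set's genes minus the mean of control genes drawn, per set
gene, from the same average-expression bin, so a random set scores 0 in
expectation. Phase calls follow the two-score rule with G1 (noncycling) when
neither the S nor the G2M score is positive. Stemness is summarized by the
Shannon entropy of each cell's expression profile (ribosomal/spike-in genes
excluded) with a gene-bootstrap standard deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import anndata as ad
from scipy import sparse


@dataclass
class GeneSet:
    name: str
    genes: list[str]
    category: str = "custom"  # cycle_S | cycle_G2M | cytotoxicity | dysfunction | checkpoint | custom


def _dense(adata: ad.AnnData) -> np.ndarray:
    return sparse.csr_matrix(adata.X).toarray().astype(np.float64)


def module_score(
    adata: ad.AnnData,
    genes: list[str] | GeneSet,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
    control_genes: list[str] | None = None,
) -> pd.Series:
    """Bin-matched control gene-set score per cell.

    ``control_genes`` overrides the sampled controls (useful for calibration:
    a set used as its own control scores exactly 0).
    """
    if isinstance(genes, GeneSet):
        genes = genes.genes
    present = [g for g in genes if g in adata.var_names]
    if not present:
        raise ValueError("module_score: no set genes present in the matrix")
    if len(present) < 3:
        warnings.warn(f"module_score: set has only {len(present)} genes in the matrix")
    X = _dense(adata)
    gidx = {g: i for i, g in enumerate(adata.var_names)}
    set_cols = np.array([gidx[g] for g in present])
    set_mean = X[:, set_cols].mean(axis=1)
    if control_genes is not None:
        ctrl_cols = np.array([gidx[g] for g in control_genes if g in gidx])
    else:
        rng = np.random.default_rng(seed)
        means = X.mean(axis=0)
        n_bins_eff = min(n_bins, adata.n_vars)
        ranks = pd.Series(means).rank(method="first")
        bins = pd.qcut(ranks, n_bins_eff, labels=False, duplicates="drop").to_numpy()
        pools = {b: np.flatnonzero(bins == b) for b in np.unique(bins)}
        draws = [rng.choice(pools[bins[c]], size=n_ctrl, replace=True) for c in set_cols]
        ctrl_cols = np.concatenate(draws)
    ctrl_mean = X[:, ctrl_cols].mean(axis=1)
    return pd.Series(set_mean - ctrl_mean, index=adata.obs_names, name="module_score")


def assign_phase(s_score: pd.Series, g2m_score: pd.Series) -> pd.DataFrame:
    """Two-score cycle phase call: G1 (noncycling) unless a score is positive;
    the larger positive score wins; exact positive ties go to S, flagged."""
    s = pd.Series(s_score).astype(float)
    g = pd.Series(g2m_score).astype(float).reindex(s.index)
    phase = np.where(np.maximum(s, g) <= 0, "G1", np.where(s >= g, "S", "G2M"))
    tied = (s == g) & (s > 0)
    out = pd.DataFrame({
        "s_score": s,
        "g2m_score": g,
        "phase": pd.Categorical(phase, categories=["G1", "S", "G2M"]),
        "tie_flag": tied,
    }, index=s.index)
    out["cycling"] = out["phase"].isin(["S", "G2M"])
    return out


def expression_entropy(
    adata: ad.AnnData,
    exclude_prefixes: tuple[str, ...] = ("RPL", "RPS", "ERCC"),
    n_boot: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Shannon entropy of each cell's expression profile with bootstrap SD.

    p_g = expression_g / sum(expression); entropy = -sum p_g ln p_g over
    p_g > 0. The SD comes from resampling genes with replacement ``n_boot``
    times. All-zero cells get entropy 0 and a flag.
    """
    keep = ~adata.var_names.str.startswith(tuple(exclude_prefixes))
    if keep.sum() < 2:
        raise ValueError("expression_entropy: fewer than 2 genes after exclusion")
    X = _dense(adata[:, keep])

    def _entropy(M: np.ndarray) -> np.ndarray:
        tot = M.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(tot > 0, M / np.maximum(tot, 1e-300), 0.0)
            lg = np.where(p > 0, np.log(p), 0.0)
        return -(p * lg).sum(axis=1)

    ent = _entropy(X)
    zero = X.sum(axis=1) == 0
    ent[zero] = 0.0
    rng = np.random.default_rng(seed)
    G = X.shape[1]
    boots = np.empty((n_boot, X.shape[0]))
    for b in range(n_boot):
        idx = rng.integers(0, G, size=G)
        boots[b] = _entropy(X[:, idx])
    out = pd.DataFrame({
        "entropy": ent,
        "entropy_sd": boots.std(axis=0),
        "zero_cell": zero,
    }, index=adata.obs_names)
    return out


def dotplot_stats(
    adata: ad.AnnData,
    labels: pd.Series | str,
    genes: list[str],
) -> pd.DataFrame:
    """Per (cluster, gene): mean expression, z-scaled mean across clusters and
    fraction of cells expressing (>0); plus a within-cluster mean rank so
    statements like "gene A > gene B in cluster X" are machine-checkable.
    Missing genes yield NA rows with a warning."""
    lab = adata.obs[labels] if isinstance(labels, str) else labels
    lab = pd.Series(np.asarray(lab).astype(str), index=adata.obs_names)
    present = [g for g in genes if g in adata.var_names]
    missing = [g for g in genes if g not in adata.var_names]
    if missing:
        warnings.warn(f"dotplot_stats: missing genes {missing}")
    X = _dense(adata[:, present]) if present else np.zeros((adata.n_obs, 0))
    rows = []
    clusters = sorted(lab.unique())
    for c in clusters:
        mask = (lab == c).to_numpy()
        for j, g in enumerate(present):
            v = X[mask, j]
            rows.append((c, g, float(v.mean()), float((v > 0).mean())))
        for g in missing:
            rows.append((c, g, np.nan, np.nan))
    out = pd.DataFrame(rows, columns=["cluster", "gene", "mean_expression", "fraction_expressing"])
    # z across clusters per gene
    z = out.groupby("gene")["mean_expression"].transform(
        lambda v: (v - v.mean()) / v.std(ddof=0) if v.std(ddof=0) > 0 else v * 0.0
    )
    out["scaled_mean"] = z
    out["rank_in_cluster"] = out.groupby("cluster")["mean_expression"].rank(
        ascending=False, method="min"
    )
    return out
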