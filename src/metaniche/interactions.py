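"""Permutation testing of ligand-receptor interactions between cell types.

For every database pair and ordered (sender, receiver) type pair, the observed
statistic is the average of the ligand's mean log-normalized expression in the
sender type and the receptor's mean in the receiver type. The null is built by
permuting the cell-type labels (1000 permutations by default) and the p-value
uses the add-one estimator p = (1 + #{null >= observed}) / (n_perm + 1), so
p >= 1/(n_perm+1). A pair is significant when the statistic exceeds 0.1 and
p < 0.05. Pairs are only tested when the ligand is detected in more than a
configurable fraction (default 10%) of sender cells and the receptor in the
receiver cells.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import anndata as ad
from scipy import sparse


def _group_means(X: np.ndarray, codes: np.ndarray, n_types: int) -> np.ndarray:
    """types x genes mean matrix for integer-coded labels."""
    sums = np.zeros((n_types, X.shape[1]))
    np.add.at(sums, codes, X)
    counts = np.bincount(codes, minlength=n_types).astype(float)
    return sums / counts[:, None]


def interaction_test(
    adata: ad.AnnData,
    type_of_cell: pd.Series | str,
    db: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    min_cells: int = 10,
    expressed_fraction: float = 0.10,
    mean_threshold: float = 0.1,
    alpha: float = 0.05,
    statistic: str = "mean",
    include_self: bool = True,
) -> pd.DataFrame:
    """Permutation test of every (pair, sender, receiver) combination.

    ``db`` needs columns pair_id, ligand, receptor. Returns one row per tested
    combination with mean_stat, p_value and the significance flag; types below
    ``min_cells`` yield NA rows, pairs whose genes are absent are skipped with
    a warning. Deterministic under a fixed seed and invariant to cell order.
    """
    if n_perm < 1:
        raise ValueError("interaction_test: n_perm must be >= 1")
    if statistic not in ("mean", "min"):
        raise ValueError("interaction_test: statistic must be 'mean' or 'min'")
    types = adata.obs[type_of_cell] if isinstance(type_of_cell, str) else type_of_cell
    types = pd.Series(np.asarray(types).astype(str), index=adata.obs_names)
    order = np.argsort(adata.obs_names.to_numpy())  # canonical cell order
    type_names = sorted(types.unique())
    if len(type_names) < 2:
        raise ValueError("interaction_test: need at least 2 cell types")
    code_of = {t: i for i, t in enumerate(type_names)}
    codes = types.map(code_of).to_numpy()[order]
    sizes = pd.Series(codes).value_counts().reindex(range(len(type_names)), fill_value=0)
    eligible = {t for t in type_names if sizes[code_of[t]] >= min_cells}

    pairs = []
    genes_needed: list[str] = []
    for _, row in db.iterrows():
        lg, rg = str(row["ligand"]), str(row["receptor"])
        if lg not in adata.var_names or rg not in adata.var_names:
            warnings.warn(f"interaction_test: pair {row['pair_id']} has missing genes; skipped")
            continue
        pairs.append((str(row["pair_id"]), lg, rg))
        genes_needed += [lg, rg]
    genes_needed = sorted(set(genes_needed))
    gcol = {g: j for j, g in enumerate(genes_needed)}
    X = sparse.csr_matrix(adata[:, genes_needed].X).toarray().astype(np.float64)[order]

    n_types = len(type_names)
    T0 = _group_means(X, codes, n_types)
    F0 = _group_means((X > 0).astype(float), codes, n_types)

    rng = np.random.default_rng(seed)
    null_means = np.empty((n_perm, n_types, len(genes_needed)))
    for p in range(n_perm):
        perm = rng.permutation(codes)
        null_means[p] = _group_means(X, perm, n_types)

    combine = (lambda a, b: (a + b) / 2.0) if statistic == "mean" else np.minimum
    rows = []
    for pair_id, lg, rg in pairs:
        jl, jr = gcol[lg], gcol[rg]
        for s in type_names:
            for r in type_names:
                if s == r and not include_self:
                    continue
                if s not in eligible or r not in eligible:
                    rows.append((pair_id, lg, rg, s, r, np.nan, np.nan, False, False))
                    continue
                cs, cr = code_of[s], code_of[r]
                tested = (F0[cs, jl] > expressed_fraction) and (F0[cr, jr] > expressed_fraction)
                obs = float(combine(T0[cs, jl], T0[cr, jr]))
                if not tested:
                    rows.append((pair_id, lg, rg, s, r, obs, np.nan, False, False))
                    continue
                null = combine(null_means[:, cs, jl], null_means[:, cr, jr])
                pval = (1.0 + float((null >= obs).sum())) / (n_perm + 1.0)
                sig = (obs > mean_threshold) and (pval < alpha)
                rows.append((pair_id, lg, rg, s, r, obs, pval, True, sig))
    return pd.DataFrame(rows, columns=[
        "pair_id", "ligand", "receptor", "sender_type", "receiver_type",
        "mean_stat", "p_value", "tested", "significant",
    ])


def interaction_counts(results: pd.DataFrame, symmetrize: bool = False) -> pd.DataFrame:
    """types x types matrix of significant-interaction counts (sender rows,
    receiver columns); optionally the symmetrized view (s,r)+(r,s)."""
    types = sorted(set(results["sender_type"]) | set(results["receiver_type"]))
    mat = pd.DataFrame(0, index=types, columns=types, dtype=int)
    sig = results[results["significant"]]
    for (s, r), grp in sig.groupby(["sender_type", "receiver_type"]):
        mat.loc[s, r] = len(grp)
    if symmetrize:
        mat = mat + mat.T
    mat.index.name = "sender"
    mat.columns.name = "receiver"
    return mat
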