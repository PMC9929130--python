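"""Recurrent expression programs across samples.

Malignant cells are subclustered within each sample; each subcluster yields an
expression module whose signature is its top-100 marker genes and whose
per-cell score is a bin-matched control score. Modules are meta-clustered by
the Pearson correlation of their score vectors over all malignant cells
(average linkage, cut at r = 0.3 by default) into meta-programs with a
consensus gene set (genes in more than half the member signatures). A cell is
a program cell when it expresses strictly more than 70% of the program's
consensus genes; per-sample program scores are the exact proportions of
program cells, and pairwise program dependencies are Haldane-Anscombe
corrected log odds ratios classified co-occurring (> 0.1) or exclusive
(< -0.1).
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
import anndata as ad
from scipy import sparse, stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .preprocess import cluster_cells, find_markers
from .signatures import module_score


@dataclass
class ExpressionModule:
    module_id: str
    sample_id: str
    signature_genes: list[str]          # ordered, top 100 by logFC
    scores: pd.Series                   # over all malignant cells


@dataclass
class MetaProgram:
    program_id: str
    member_modules: list[str]
    consensus_genes: list[str]
    recurrent: bool
    label: str = ""


@dataclass
class ProgramAssignment:
    indicator: pd.DataFrame             # cells x programs boolean
    program_score: pd.DataFrame         # samples x programs, exact proportions
    sample_of_cell: pd.Series


def extract_modules(
    adata: ad.AnnData,
    sample_of_cell: pd.Series | str = "sample",
    malignant: pd.Series | np.ndarray | None = None,
    resolution: float = 1.0,
    min_cells: int = 50,
    n_signature: int = 100,
    min_signature: int = 10,
    seed: int = 0,
) -> list[ExpressionModule]:
    """Per-sample subclustering of malignant cells into expression modules.

    Samples with fewer than ``min_cells`` malignant cells are skipped with a
    warning; a sample collapsing to a single subcluster contributes one module
    whose signature is its top expressed genes. Module scores are computed
    over all malignant cells so modules are comparable across samples.
    """
    samples = adata.obs[sample_of_cell] if isinstance(sample_of_cell, str) else sample_of_cell
    samples = pd.Series(np.asarray(samples).astype(str), index=adata.obs_names)
    if malignant is None:
        mal = np.ones(adata.n_obs, bool)
    else:
        mal = np.asarray(pd.Series(malignant).reindex(adata.obs_names).fillna(False), bool)
    cancer = adata[mal].copy()
    samples_c = samples[mal]
    if samples_c.nunique() < 2:
        warnings.warn("extract_modules: fewer than 2 samples with malignant cells")
    modules: list[ExpressionModule] = []
    for k, s in enumerate(sorted(samples_c.unique())):
        sub = cancer[(samples_c == s).to_numpy()].copy()
        if sub.n_obs < min_cells:
            warnings.warn(f"extract_modules: sample {s} has {sub.n_obs} malignant cells < {min_cells}; skipped")
            continue
        labels = cluster_cells(sub, resolution=resolution, seed=seed, key_added="subcluster")
        uniq = sorted(labels.unique())
        if len(uniq) == 1:
            mean_expr = np.asarray(sparse.csr_matrix(sub.X).mean(axis=0)).ravel()
            order = np.argsort(mean_expr)[::-1][:n_signature]
            sigs = {uniq[0]: [sub.var_names[i] for i in order]}
        else:
            table = find_markers(sub, labels)
            sigs = {
                c: grp.sort_values("log_fold_change", ascending=False)["gene"].head(n_signature).tolist()
                for c, grp in table.groupby("cluster")
            }
        for c in uniq:
            sig = sigs.get(c, [])
            if len(sig) < min_signature:
                warnings.warn(f"extract_modules: subcluster {s}/{c} signature has {len(sig)} genes; skipped")
                continue
            mid = f"{s}_m{c}"
            c_num = int(c) if str(c).isdigit() else zlib.crc32(str(c).encode()) % 97
            sc_seed = (seed * 100003 + k * 101 + c_num) % (2**31 - 1)
            scores = module_score(cancer, sig, seed=sc_seed)
            modules.append(ExpressionModule(mid, s, sig, scores))
    return modules


def aggregate_modules(
    modules: list[ExpressionModule],
    correlation_cut: float = 0.3,
    min_consensus: int = 10,
) -> list[MetaProgram]:
    """Average-linkage meta-clustering of modules by score correlation.

    Modules whose score vectors correlate above ``correlation_cut`` merge into
    a meta-program; the consensus gene set is genes present in > 50% of member
    signatures (topped up by membership frequency to ``min_consensus``).
    """
    if len(modules) < 2:
        raise ValueError("aggregate_modules requires at least 2 modules")
    S = pd.DataFrame({m.module_id: m.scores for m in modules})
    R = np.corrcoef(S.to_numpy(), rowvar=False)
    D = 1.0 - R
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(D[np.triu_indices_from(D, 1)], method="average")
    lab = hierarchy.fcluster(Z, t=1.0 - correlation_cut, criterion="distance")
    if len(set(lab)) == len(modules):
        warnings.warn("aggregate_modules: no modules correlated above the cut; each is its own program")
    programs: list[MetaProgram] = []
    for g in sorted(set(lab)):
        members = [m for m, l in zip(modules, lab) if l == g]
        counts = pd.Series([gene for m in members for gene in m.signature_genes]).value_counts()
        frac = counts / len(members)
        consensus = sorted(frac.index[frac > 0.5])
        if len(consensus) < min_consensus:
            top = counts.sort_values(ascending=False).index.tolist()
            consensus = sorted(set(consensus) | set(top[:min_consensus]))
        programs.append(MetaProgram(
            program_id=f"MP{g}",
            member_modules=[m.module_id for m in members],
            consensus_genes=consensus,
            recurrent=len({m.sample_id for m in members}) >= 2,
        ))
    return programs


def assign_program_cells(
    adata: ad.AnnData,
    programs: list[MetaProgram],
    sample_of_cell: pd.Series | str = "sample",
    threshold: float = 0.70,
) -> ProgramAssignment:
    """Program-cell rule: a cell is a program cell iff it expresses (>0)
    strictly more than ``threshold`` of the program's consensus genes present
    in the matrix. Program scores are exact per-sample proportions."""
    samples = adata.obs[sample_of_cell] if isinstance(sample_of_cell, str) else sample_of_cell
    samples = pd.Series(np.asarray(samples).astype(str), index=adata.obs_names)
    X = sparse.csr_matrix(adata.X)
    gidx = {g: i for i, g in enumerate(adata.var_names)}
    ind = {}
    for p in programs:
        cols = [gidx[g] for g in p.consensus_genes if g in gidx]
        if not cols:
            raise ValueError(f"assign_program_cells: program {p.program_id} has no consensus genes in the matrix")
        expressed = np.asarray((X[:, cols] > 0).sum(axis=1)).ravel()
        ind[p.program_id] = expressed / len(cols) > threshold
    indicator = pd.DataFrame(ind, index=adata.obs_names)
    score = indicator.groupby(samples).mean()
    score.index.name = "sample"
    return ProgramAssignment(indicator=indicator, program_score=score, sample_of_cell=samples)


def dependency_log_odds(
    assignment: ProgramAssignment | pd.DataFrame,
    cooccur_threshold: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Haldane-Anscombe corrected log odds ratios of joint program
    membership, classified co-occurring (> 0.1), exclusive (< -0.1) or neither.

    Returns (log-odds matrix, classification matrix); diagonals are NA.
    Degenerate programs (no cells or all cells) are flagged 'low_information'.
    """
    ind = assignment.indicator if isinstance(assignment, ProgramAssignment) else assignment
    progs = list(ind.columns)
    if len(progs) < 2:
        raise ValueError("dependency_log_odds requires at least 2 programs")
    n = len(ind)
    vals = pd.DataFrame(np.nan, index=progs, columns=progs)
    cls = pd.DataFrame("", index=progs, columns=progs, dtype=object)
    degenerate = {p for p in progs if ind[p].sum() in (0, n)}
    for i, p in enumerate(progs):
        for q in progs[i + 1:]:
            a = int((ind[p] & ind[q]).sum())
            b = int((ind[p] & ~ind[q]).sum())
            c = int((~ind[p] & ind[q]).sum())
            d = n - a - b - c
            v = float(np.log((a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))))
            label = ("cooccurring" if v > cooccur_threshold
                     else "exclusive" if v < -cooccur_threshold else "neither")
            if p in degenerate or q in degenerate:
                label += "|low_information"
            vals.loc[p, q] = vals.loc[q, p] = v
            cls.loc[p, q] = cls.loc[q, p] = label
    return vals, cls


def contrast_program_cells(
    adata: ad.AnnData,
    assignment: ProgramAssignment,
    gene_sets: dict[str, list[str]],
    seed: int = 0,
) -> pd.DataFrame:
    """Program cells vs nonprogram cells per gene set: difference of mean
    module scores, rank-sum p and BH adjustment; z column for display.
    Sets with no genes in the matrix are skipped; programs with no program
    cells get NA rows."""
    rows = []
    set_scores = {}
    for name, genes in gene_sets.items():
        present = [g for g in genes if g in adata.var_names]
        if not present:
            warnings.warn(f"contrast_program_cells: set {name!r} has no genes in the matrix; skipped")
            continue
        set_scores[name] = module_score(adata, present, seed=seed).to_numpy()
    for p in assignment.indicator.columns:
        in_p = assignment.indicator[p].to_numpy()
        for name, sc_vec in set_scores.items():
            if in_p.sum() == 0 or in_p.all():
                rows.append((p, name, np.nan, np.nan))
                continue
            diff = float(sc_vec[in_p].mean() - sc_vec[~in_p].mean())
            pval = float(stats.ranksums(sc_vec[in_p], sc_vec[~in_p]).pvalue)
            rows.append((p, name, diff, pval))
    out = pd.DataFrame(rows, columns=["program", "gene_set", "effect", "p_value"])
    ok = out["p_value"].notna()
    out["adjusted_p"] = np.nan
    if ok.any():
        out.loc[ok, "adjusted_p"] = multipletests(out.loc[ok, "p_value"], method="fdr_bh")[1]
    out["z_effect"] = out.groupby("gene_set")["effect"].transform(
        lambda v: (v - v.mean()) / v.std(ddof=0) if v.std(ddof=0) > 0 else v * 0.0
    )
    return out
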