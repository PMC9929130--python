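"""Expression-derived copy-number inference, malignancy calling and clonality trees.

The inference follows the classic expression-window recipe: genes detected in
more than a minimum number of cells are ordered along chromosomes, each gene
is mean-centered across cells, centered values are clipped at +/-1.5 cross-cell
standard deviations, a 101-gene running mean smooths each chromosome (windows
truncate symmetrically at chromosome ends), and the mean profile of
presumed-diploid reference cells (T/B lymphocytes) is subtracted so 0 means
copy-neutral. Per-cell CNV burden is log1p of the mean squared deviation;
cells are called malignant against the 99th percentile of reference scores,
requiring both the cell and its CNV cluster to exceed it. Contiguous deviant
runs per subclone become gain/loss events; events carried by >90% of a
subclone's cells are canonical. Events are nested by carrier-set inclusion
into a clonality tree with truncal events at the root.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import anndata as ad
from scipy import sparse
from scipy.cluster import hierarchy


@dataclass
class CNVProfile:
    """Smoothed relative deviations (cells x ordered genes), 0 = neutral."""

    values: np.ndarray
    cell_ids: pd.Index
    genes: pd.DataFrame  # gene_id, chromosome, start — sorted (chromosome, start)
    reference_cell_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.genes["gene_id"])


@dataclass
class CNVEvent:
    chromosome: str
    start_index: int   # global index into the profile's ordered genes
    end_index: int     # inclusive
    direction: str     # "gain" | "loss"
    subclone_id: str
    cell_percent: float
    canonical: bool
    mean_deviation: float
    key: str = ""      # cross-subclone shared-event key, filled by matching


def infer_cnv(
    adata: ad.AnnData,
    gene_positions: pd.DataFrame,
    reference_cells: list[str] | np.ndarray,
    window: int = 101,
    clip_sd: float = 1.5,
    min_cells: int = 20,
    center_cells: bool = False,
) -> CNVProfile:
    """Windowed expression CNV profiles relative to reference cells.

    ``adata`` holds log-normalized expression; ``gene_positions`` has columns
    gene_id, chromosome, start. Chromosomes with fewer genes than ``window``
    are smoothed with the largest centered window available (warning).

    ``center_cells=True`` subtracts each cell's median smoothed value before
    the reference profile is removed. This cancels the depth-driven global
    offset of a cell's profile and is the recommended setting when profiles
    feed malignancy calling or event calling; the default off keeps the plain
    windowed pipeline (and makes a constant planted offset directly visible).
    """
    ref = pd.Index(reference_cells)
    if len(ref) == 0:
        raise ValueError("infer_cnv: reference_cells must be nonempty")
    missing = ref.difference(adata.obs_names)
    if len(missing):
        raise ValueError(f"infer_cnv: reference cells not in matrix: {list(missing[:3])}")
    X = sparse.csr_matrix(adata.X).toarray().astype(np.float64)

    # (1) drop genes detected in <= min_cells cells
    n_expr = (X > 0).sum(axis=0)
    keep = n_expr > min_cells
    pos = gene_positions.set_index("gene_id").loc[adata.var_names[keep]]
    X = X[:, keep]

    # (2) chromosome-then-position gene order
    order = np.lexsort((pos["start"].to_numpy(), pos["chromosome"].to_numpy()))
    X = X[:, order]
    sorted_pos = pos.iloc[order]
    genes = pd.DataFrame({
        "gene_id": np.asarray(sorted_pos.index, dtype=object),
        "chromosome": sorted_pos["chromosome"].to_numpy(),
        "start": sorted_pos["start"].to_numpy(),
    })
    if len(genes) < window:
        warnings.warn("infer_cnv: fewer retained genes than the window on every chromosome")

    # (3) center per gene; (4) clip at +/- clip_sd * per-gene SD
    centered = X - X.mean(axis=0)
    sd = centered.std(axis=0)
    bound = clip_sd * sd
    clipped = np.clip(centered, -bound, bound)

    # (5) running mean per chromosome, symmetric truncation at the ends
    smoothed = np.empty_like(clipped)
    half = window // 2
    for chrom, idx in genes.groupby("chromosome", sort=False).groups.items():
        idx = np.asarray(idx)
        L = idx.size
        if L < window:
            warnings.warn(f"infer_cnv: chromosome {chrom} has {L} genes < window {window}")
        block = clipped[:, idx]
        csum = np.concatenate([np.zeros((block.shape[0], 1)), np.cumsum(block, axis=1)], axis=1)
        i = np.arange(L)
        h = np.minimum(half, np.minimum(i, L - 1 - i))
        lo, hi = i - h, i + h
        smoothed[:, idx] = (csum[:, hi + 1] - csum[:, lo]) / (hi - lo + 1)

    # (5b, optional) cancel each cell's global offset
    if center_cells:
        smoothed = smoothed - np.median(smoothed, axis=1, keepdims=True)

    # (6) subtract the mean reference profile
    ref_rows = adata.obs_names.isin(ref)
    dev = smoothed - smoothed[ref_rows].mean(axis=0)
    return CNVProfile(values=dev, cell_ids=adata.obs_names, genes=genes,
                      reference_cell_ids=list(ref))


def cnv_score(profile: CNVProfile) -> pd.Series:
    """Per-cell log-scale CNV burden: log1p(mean over genes of deviation^2)."""
    s = np.log1p((profile.values ** 2).mean(axis=1))
    return pd.Series(s, index=profile.cell_ids, name="cnv_score")


def cluster_cnv_profiles(profile: CNVProfile, k: int, cells: pd.Index | None = None) -> pd.Series:
    """Ward/Euclidean agglomerative clustering of deviation profiles into k groups."""
    ids = profile.cell_ids if cells is None else pd.Index(cells)
    rows = profile.cell_ids.get_indexer(ids)
    V = profile.values[rows]
    if k > len(ids):
        raise ValueError(f"cluster_cnv_profiles: k={k} exceeds {len(ids)} cells")
    if k == 1 or len(ids) == 1:
        lab = np.ones(len(ids), int)
    else:
        Z = hierarchy.linkage(V, method="ward", metric="euclidean")
        lab = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return pd.Series([f"HCL{v}" for v in lab], index=ids, name="cnv_cluster")


def call_malignant(
    scores: pd.Series,
    reference_scores: pd.Series,
    clusters: pd.Series,
    quantile: float = 0.99,
) -> pd.DataFrame:
    """Malignant iff the cell's score and its CNV cluster's mean score both
    exceed the reference-score quantile. Both conditions are reported."""
    if len(reference_scores) == 0:
        raise ValueError("call_malignant: reference scores must be nonempty")
    ref = np.asarray(reference_scores, float)
    if np.allclose(ref, ref[0]):
        thr = float(ref[0]) + 1e-12
        warnings.warn("call_malignant: degenerate reference; threshold = value + eps")
    else:
        thr = float(np.quantile(ref, quantile))
    cl = clusters.reindex(scores.index)
    cluster_means = scores.groupby(cl, observed=True).mean()
    out = pd.DataFrame(index=scores.index)
    out["cnv_score"] = scores
    out["cnv_cluster"] = cl
    out["cell_above"] = scores > thr
    out["cluster_above"] = cl.map(cluster_means).to_numpy() > thr
    out["is_malignant"] = out["cell_above"] & out["cluster_above"]
    out.attrs["threshold"] = thr
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as (start, end) inclusive index pairs."""
    out = []
    i = 0
    n = mask.size
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            out.append((i, j))
            i = j + 1
        else:
            i += 1
    return out


def call_events(
    profile: CNVProfile,
    subclones: pd.Series,
    gain_threshold: float = 0.15,
    loss_threshold: float = -0.15,
    min_span_genes: int = 30,
) -> list[CNVEvent]:
    """Per-subclone contiguous deviant runs as gain/loss events.

    A run of >= ``min_span_genes`` genes whose subclone-mean deviation passes
    the threshold becomes an event; its ``cell_percent`` is the percentage of
    the subclone's cells whose own mean over the span passes half the
    threshold, and events above 90% are canonical.
    """
    events: list[CNVEvent] = []
    chrom = profile.genes["chromosome"].to_numpy()
    for sub in sorted(pd.Series(subclones).dropna().unique()):
        ids = subclones.index[subclones == sub]
        rows = profile.cell_ids.get_indexer(ids)
        V = profile.values[rows]
        m = V.mean(axis=0)
        for c in pd.unique(chrom):
            cidx = np.flatnonzero(chrom == c)
            for direction, thr in (("gain", gain_threshold), ("loss", loss_threshold)):
                mask = m[cidx] > thr if direction == "gain" else m[cidx] < thr
                for s, e in _runs(mask):
                    if e - s + 1 < min_span_genes:
                        continue
                    g0, g1 = int(cidx[s]), int(cidx[e])
                    span_means = V[:, g0 : g1 + 1].mean(axis=1)
                    half_thr = thr / 2.0
                    passes = span_means > half_thr if direction == "gain" else span_means < half_thr
                    pct = 100.0 * passes.mean()
                    events.append(CNVEvent(
                        chromosome=str(c), start_index=g0, end_index=g1,
                        direction=direction, subclone_id=str(sub),
                        cell_percent=float(pct), canonical=bool(pct > 90.0),
                        mean_deviation=float(m[g0 : g1 + 1].mean()),
                    ))
    return _match_events(events)


def _match_events(events: list[CNVEvent]) -> list[CNVEvent]:
    """Assign shared keys to events of the same chromosome/direction whose
    spans overlap, so subclone event sets are comparable."""
    groups: dict[tuple[str, str], list[CNVEvent]] = {}
    for ev in events:
        groups.setdefault((ev.chromosome, ev.direction), []).append(ev)
    for (c, d), evs in groups.items():
        # union-find over overlapping spans
        parent = list(range(len(evs)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(evs)):
            for j in range(i + 1, len(evs)):
                a, b = evs[i], evs[j]
                if a.start_index <= b.end_index and b.start_index <= a.end_index:
                    parent[find(i)] = find(j)
        comp: dict[int, list[CNVEvent]] = {}
        for i, ev in enumerate(evs):
            comp.setdefault(find(i), []).append(ev)
        for members in comp.values():
            lo = min(e.start_index for e in members)
            hi = max(e.end_index for e in members)
            key = f"{c}:{lo}-{hi}:{d}"
            for e in members:
                e.key = key
    return events


@dataclass
class TreeNode:
    name: str
    subclones: frozenset
    events: list[CNVEvent] = field(default_factory=list)
    children: list["TreeNode"] = field(default_factory=list)
    conflicts: list[str] = field(default_factory=list)
    n_cells: int = 0

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "subclones": sorted(self.subclones),
            "n_cells": self.n_cells,
            "events": [
                {"key": e.key, "chromosome": e.chromosome, "direction": e.direction,
                 "start_index": e.start_index, "end_index": e.end_index,
                 "cell_percent": round(e.cell_percent, 3), "canonical": e.canonical}
                for e in self.events
            ],
            "conflicts": self.conflicts,
            "children": [c.to_dict() for c in self.children],
        }


@dataclass
class SubcloneTree:
    root: TreeNode
    subclone_sizes: dict[str, int]

    def to_json(self) -> str:
        return json.dumps(self.root.to_dict(), indent=2)

    def to_newick(self) -> str:
        def rec(node: TreeNode) -> str:
            label = "+".join(sorted({e.key for e in node.events})) or node.name
            if not node.children:
                return f"{node.name}" if not node.events else f"{node.name}[{label}]"
            inner = ",".join(rec(c) for c in node.children)
            return f"({inner}){label}"
        return rec(self.root) + ";"

    def leaf_cell_total(self) -> int:
        total = 0
        stack = [self.root]
        while stack:
            n = stack.pop()
            if not n.children:
                total += n.n_cells
            stack.extend(n.children)
        return total


def build_clonality_tree(events: list[CNVEvent], subclones: pd.Series) -> SubcloneTree:
    """Nest subclones by event-set inclusion into a rooted clonality tree.

    Events shared by every subclone form the trunk (root). Remaining shared
    event keys, taken in decreasing carrier count, create internal nodes;
    carrier sets that violate nesting are attached at the deepest compatible
    node and flagged as conflicts rather than failing.
    """
    sizes = pd.Series(subclones).dropna().value_counts().to_dict()
    all_subs = frozenset(str(s) for s in sizes)
    key_to_events: dict[str, list[CNVEvent]] = {}
    for ev in events:
        key_to_events.setdefault(ev.key, []).append(ev)
    carriers = {k: frozenset(e.subclone_id for e in evs) for k, evs in key_to_events.items()}

    root = TreeNode(name="trunk", subclones=all_subs, n_cells=sum(sizes.values()))
    nodes = [root]

    def deepest_superset(cset: frozenset) -> TreeNode:
        node = root
        changed = True
        while changed:
            changed = False
            for ch in node.children:
                if cset <= ch.subclones:
                    node = ch
                    changed = True
                    break
        return node

    order = sorted(carriers, key=lambda k: (-len(carriers[k]), k))
    for key in order:
        cset = carriers[key]
        evs = key_to_events[key]
        rep = max(evs, key=lambda e: e.cell_percent)
        if cset == all_subs:
            root.events.append(rep)
            continue
        node = deepest_superset(cset)
        if cset == node.subclones:
            node.events.append(rep)
            continue
        partial = [ch for ch in node.children
                   if ch.subclones & cset and not ch.subclones <= cset and not cset <= ch.subclones]
        if partial:
            node.events.append(rep)
            node.conflicts.append(key)
            continue
        child = TreeNode(name=f"node_{len(nodes)}", subclones=cset,
                         n_cells=sum(sizes[s] for s in cset), events=[rep])
        absorbed = [ch for ch in node.children if ch.subclones <= cset]
        node.children = [ch for ch in node.children if ch not in absorbed] + [child]
        child.children.extend(absorbed)
        nodes.append(child)

    # ensure every subclone terminates in its own leaf
    def ensure_leaves(node: TreeNode):
        covered = set()
        for ch in node.children:
            ensure_leaves(ch)
            covered |= ch.subclones
        if node.children:
            for s in sorted(node.subclones - covered):
                node.children.append(TreeNode(name=str(s), subclones=frozenset([s]),
                                              n_cells=sizes[s]))
        elif len(node.subclones) > 1:
            for s in sorted(node.subclones):
                node.children.append(TreeNode(name=str(s), subclones=frozenset([s]),
                                              n_cells=sizes[s]))
        elif len(node.subclones) == 1 and node is not root:
            node.name = next(iter(node.subclones))
            node.n_cells = sizes[next(iter(node.subclones))]

    ensure_leaves(root)
    if not root.children and len(all_subs) == 1:
        s = next(iter(all_subs))
        root.children.append(TreeNode(name=s, subclones=frozenset([s]), n_cells=sizes[s]))
    return SubcloneTree(root=root, subclone_sizes={str(k): int(v) for k, v in sizes.items()})
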