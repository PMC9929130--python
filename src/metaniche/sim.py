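"""Synthetic multi-sample scRNA-seq cohorts with planted ground truth.

The generator emulates the design of a two-organ metastatic cohort: several
samples ("patients") from liver or brain lesions, discrete cell types with
marker genes, malignant cells carrying segmental expression-level copy-number
changes organised into subclones, sample-spanning activity programs with
controlled co-occurrence/exclusion, and ligand-receptor co-expression between
chosen type pairs. Counts are negative binomial with a lognormal library-size
factor and independent Bernoulli dropout. Every planted effect is recorded in
a :class:`GroundTruth` sidecar keyed by barcode so downstream detectors can be
scored against a recoverable truth.
"""

from __future__ import annotations

import json

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import anndata as ad
from scipy import sparse, io as spio


class ConfigurationError(ValueError):
    """Raised when a simulation config is internally inconsistent."""


@dataclass
class CNVSegmentTruth:
    """A planted segmental dosage change.

    ``fold_change`` multiplies the NB mean of the segment's genes in carrier
    cells (e.g. 1.5 for a gain, 0.5 for a loss). ``subclone_id=None`` marks a
    truncal segment carried by every malignant cell.
    Gene indices are 0-based within the chromosome's gene order, inclusive.
    """

    chromosome: str
    start_gene_index: int
    end_gene_index: int
    fold_change: float
    carrier_fraction: float = 1.0
    subclone_id: str | None = None


@dataclass
class ProgramTruth:
    """A planted expression program active in a fraction of malignant cells.

    ``active_cell_fraction_per_sample`` may be a single float applied to every
    sample or a mapping sample -> fraction.
    """

    program_id: str
    gene_set: list[str]
    activation_fold: float = 3.0
    active_cell_fraction_per_sample: float | dict[str, float] = 0.4


@dataclass
class LRTruth:
    """A planted ligand-receptor co-expression effect between two cell types."""

    ligand_gene: str
    receptor_gene: str
    sender_type: str
    receiver_type: str
    effect_fold: float = 5.0


def _default_cells_per_type() -> dict[str, int]:
    # cancer-dominant composition mirroring a metastatic lesion
    return {
        "cancer": 300,
        "T_cell": 120,
        "B_cell": 60,
        "myeloid": 120,
        "fibroblast": 50,
        "endothelial": 50,
    }


@dataclass
class SimConfig:
    """Full specification of a synthetic cohort.

    Defaults produce a ~4,200-cell, 2,000-gene cohort of six samples (three
    liver, three brain) with six cell types; effects (CNV segments, programs,
    LR pairs) are opt-in so the default cohort is a clean null unless planted.
    """

    n_samples: int = 6
    organ_label_per_sample: tuple[str, ...] = ("liver", "liver", "liver", "brain", "brain", "brain")
    n_cells_per_type_per_sample: dict[str, int] = field(default_factory=_default_cells_per_type)
    n_genes: int = 2000
    n_chromosomes: int = 10
    baseline_mean: float = 5.0
    gene_mean_sigma: float = 0.6
    nb_dispersion: float = 0.5
    library_size_lognormal_params: tuple[float, float] = (0.0, 0.25)
    dropout_rate: float = 0.10
    marker_genes_per_type: dict[str, dict[str, float]] = field(default_factory=dict)
    n_auto_markers_per_type: int = 10
    auto_marker_fold: float = 8.0
    cnv_segments: list[CNVSegmentTruth] = field(default_factory=list)
    programs: list[ProgramTruth] = field(default_factory=list)
    lr_truth: list[LRTruth] = field(default_factory=list)
    program_dependency: dict[tuple[str, str], str] = field(default_factory=dict)
    subclone_fractions: dict[str, float] | None = None
    malignant_type: str = "cancer"
    n_mito_genes: int = 20
    gene_symbol_overrides: dict[int, str] = field(default_factory=dict)
    seed: int = 0

    @property
    def genes_per_chromosome(self) -> int:
        return self.n_genes // self.n_chromosomes

    def sample_names(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_samples)]


@dataclass
class GroundTruth:
    """Planted truth joined to the matrix by barcode."""

    cells: pd.DataFrame          # index barcode: sample, organ, cell_type, is_malignant, subclone
    program_activity: pd.DataFrame  # cells x programs boolean
    gene_annotation: pd.DataFrame   # gene_id, chromosome, start (0-based index)
    marker_db: dict[str, list[str]]
    config: SimConfig


# ---------------------------------------------------------------------------
# validation

def _gene_index_map(config: SimConfig) -> tuple[list[str], pd.DataFrame]:
    """Gene ids + annotation table; genes evenly spaced along synthetic chromosomes."""
    n = config.n_genes
    per = config.genes_per_chromosome
    ids = [f"G{i:04d}" for i in range(n)]
    chroms, starts = [], []
    for i in range(n):
        c = min(i // per, config.n_chromosomes - 1)
        chroms.append(f"chr{c + 1}")
        starts.append(i - c * per if c < config.n_chromosomes - 1 else i - (config.n_chromosomes - 1) * per)
    ann = pd.DataFrame({"gene_id": ids, "chromosome": chroms, "start": starts})
    # mitochondrial surrogates: trailing genes of the last chromosome
    if config.n_mito_genes:
        for j in range(config.n_mito_genes):
            idx = n - 1 - j
            ids[idx] = f"MT-G{idx:04d}"
    for idx, sym in config.gene_symbol_overrides.items():
        if not 0 <= idx < n:
            raise ConfigurationError(f"gene_symbol_overrides: index {idx} out of range")
        ids[idx] = sym
    ann["gene_id"] = ids
    ann = ann.set_index("gene_id", drop=False)
    return ids, ann


def _validate(config: SimConfig, gene_ids: list[str], ann: pd.DataFrame) -> None:
    if config.n_samples != len(config.organ_label_per_sample):
        raise ConfigurationError("organ_label_per_sample: length must equal n_samples")
    if not set(config.organ_label_per_sample) <= {"liver", "brain"}:
        raise ConfigurationError("organ_label_per_sample: labels must be 'liver' or 'brain'")
    if not 0 <= config.dropout_rate < 1:
        raise ConfigurationError("dropout_rate: must be in [0, 1)")
    if config.nb_dispersion <= 0 or config.baseline_mean <= 0:
        raise ConfigurationError("baseline_mean/nb_dispersion: must be positive")
    types = set(config.n_cells_per_type_per_sample)
    gene_set = set(gene_ids)
    per_chrom = ann.groupby("chromosome").size()
    for k, seg in enumerate(config.cnv_segments):
        if seg.chromosome not in per_chrom.index:
            raise ConfigurationError(f"cnv_segments[{k}].chromosome: unknown {seg.chromosome!r}")
        ngenes_c = int(per_chrom[seg.chromosome])
        if not (0 <= seg.start_gene_index <= seg.end_gene_index < ngenes_c):
            raise ConfigurationError(
                f"cnv_segments[{k}].start_gene_index/end_gene_index: out of range for {seg.chromosome}"
            )
        if seg.fold_change <= 0:
            raise ConfigurationError(f"cnv_segments[{k}].fold_change: must be > 0")
        if not 0 < seg.carrier_fraction <= 1:
            raise ConfigurationError(f"cnv_segments[{k}].carrier_fraction: must be in (0, 1]")
    for p in config.programs:
        if not p.gene_set:
            raise ConfigurationError(f"programs[{p.program_id}].gene_set: empty")
        missing = set(p.gene_set) - gene_set
        if missing:
            raise ConfigurationError(f"programs[{p.program_id}].gene_set: unknown genes {sorted(missing)[:3]}")
        fr = p.active_cell_fraction_per_sample
        vals = fr.values() if isinstance(fr, dict) else [fr]
        if any(not 0 <= v <= 1 for v in vals):
            raise ConfigurationError(f"programs[{p.program_id}].active_cell_fraction_per_sample: out of [0,1]")
    for k, lr in enumerate(config.lr_truth):
        for fld, g in (("ligand_gene", lr.ligand_gene), ("receptor_gene", lr.receptor_gene)):
            if g not in gene_set:
                raise ConfigurationError(f"lr_truth[{k}].{fld}: unknown gene {g!r}")
        for fld, t in (("sender_type", lr.sender_type), ("receiver_type", lr.receiver_type)):
            if t not in types:
                raise ConfigurationError(f"lr_truth[{k}].{fld}: unknown type {t!r}")
        if lr.effect_fold < 1:
            raise ConfigurationError(f"lr_truth[{k}].effect_fold: must be >= 1")
    for fld, d in (("marker_genes_per_type", config.marker_genes_per_type),):
        for t, genes in d.items():
            if t not in types:
                raise ConfigurationError(f"{fld}: unknown type {t!r}")
            missing = set(genes) - gene_set
            if missing:
                raise ConfigurationError(f"{fld}[{t}]: unknown genes {sorted(missing)[:3]}")
    pids = {p.program_id for p in config.programs}
    for pair, rule in config.program_dependency.items():
        if rule not in ("cooccur", "exclude", "independent"):
            raise ConfigurationError(f"program_dependency[{pair}]: unknown rule {rule!r}")
        if not set(pair) <= pids:
            raise ConfigurationError(f"program_dependency[{pair}]: unknown program id")


# ---------------------------------------------------------------------------
# dependency planting

def plant_dependency(
    active_a: np.ndarray,
    active_b: np.ndarray,
    rule: str,
    seed: int | np.random.Generator = 0,
    target_joint: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Re-draw two boolean activity vectors to a target joint distribution.

    Marginal counts are preserved exactly; only which cells are active changes.
    ``cooccur`` maximises the overlap (joint above the product of marginals),
    ``exclude`` minimises it, ``independent`` sets it to the product. A
    ``target_joint`` count may override the default; infeasible requests raise
    :class:`ConfigurationError`.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = np.asarray(active_a, bool)
    b = np.asarray(active_b, bool)
    if a.shape != b.shape:
        raise ConfigurationError("plant_dependency: activity vectors must share cells")
    n = a.size
    na, nb = int(a.sum()), int(b.sum())
    lo, hi = max(0, na + nb - n), min(na, nb)
    if target_joint is None:
        if rule == "cooccur":
            j = hi
        elif rule == "exclude":
            j = lo
        elif rule == "independent":
            j = int(round(na * nb / n)) if n else 0
        else:
            raise ConfigurationError(f"plant_dependency: unknown rule {rule!r}")
    else:
        j = int(target_joint)
    if not lo <= j <= hi:
        raise ConfigurationError(
            f"plant_dependency: target_joint={j} infeasible for marginals {na}/{nb} over {n} cells"
        )
    order = rng.permutation(n)
    both = order[:j]
    a_only = order[j : j + (na - j)]
    b_only = order[j + (na - j) : j + (na - j) + (nb - j)]
    new_a = np.zeros(n, bool)
    new_b = np.zeros(n, bool)
    new_a[both] = new_a[a_only] = True
    new_b[both] = new_b[b_only] = True
    return new_a, new_b


# ---------------------------------------------------------------------------
# main generator

def simulate_counts(config: SimConfig) -> tuple[ad.AnnData, GroundTruth]:
    """Draw a cohort from ``config``; identical configs are bit-identical.

    Returns an :class:`anndata.AnnData` of raw integer counts (cells x genes,
    CSR) with ``obs['sample']``/``obs['organ']`` and the :class:`GroundTruth`.
    """
    gene_ids, ann = _gene_index_map(config)
    _validate(config, gene_ids, ann)
    rng = np.random.default_rng(config.seed)
    samples = config.sample_names()
    types = sorted(config.n_cells_per_type_per_sample)

    # --- cell frame
    rows = []
    for s, organ in zip(samples, config.organ_label_per_sample):
        for t in types:
            for _ in range(config.n_cells_per_type_per_sample[t]):
                rows.append((s, organ, t))
    cells = pd.DataFrame(rows, columns=["sample", "organ", "cell_type"])
    cells.index = [f"{s}_BC{i:06d}" for i, s in enumerate(cells["sample"])]
    n_cells = len(cells)
    cells["is_malignant"] = cells["cell_type"] == config.malignant_type

    # --- gene means & type markers
    gene_means = config.baseline_mean * rng.lognormal(0.0, config.gene_mean_sigma, config.n_genes)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    marker_db: dict[str, list[str]] = {}
    marker_fold = np.ones((len(types), config.n_genes))
    used: set[int] = set()
    for ti, t in enumerate(types):
        if t in config.marker_genes_per_type:
            mk = config.marker_genes_per_type[t]
        else:
            free = [i for i in range(config.n_genes) if i not in used]
            pick = rng.choice(free, size=min(config.n_auto_markers_per_type, len(free)), replace=False)
            mk = {gene_ids[i]: config.auto_marker_fold for i in pick}
        marker_db[t] = sorted(mk)
        for g, f in mk.items():
            gi = gene_pos[g]
            used.add(gi)
            marker_fold[ti, gi] = f

    type_idx = np.array([types.index(t) for t in cells["cell_type"]])
    log_mu = np.log(gene_means)[None, :] + np.log(marker_fold)[type_idx]

    # --- library size
    mu_l, sd_l = config.library_size_lognormal_params
    lib = rng.lognormal(mu_l, sd_l, n_cells)
    log_mu += np.log(lib)[:, None]

    # --- subclones & CNV segments
    malignant = cells["is_malignant"].to_numpy()
    subclone_ids = sorted({s.subclone_id for s in config.cnv_segments if s.subclone_id is not None})
    cells["subclone"] = pd.Series(pd.NA, index=cells.index, dtype="object")
    if malignant.any():
        if subclone_ids:
            fracs = config.subclone_fractions or {s: 1.0 / len(subclone_ids) for s in subclone_ids}
            probs = np.array([fracs[s] for s in subclone_ids], float)
            probs = probs / probs.sum()
            draw = rng.choice(len(subclone_ids), size=int(malignant.sum()), p=probs)
            cells.loc[malignant, "subclone"] = [subclone_ids[d] for d in draw]
        else:
            cells.loc[malignant, "subclone"] = "clone0"
    chrom_offset = {c: int(np.flatnonzero(ann["chromosome"].to_numpy() == c)[0]) for c in ann["chromosome"].unique()}
    for seg in config.cnv_segments:
        g0 = chrom_offset[seg.chromosome] + seg.start_gene_index
        g1 = chrom_offset[seg.chromosome] + seg.end_gene_index
        if seg.subclone_id is None:
            pool = np.flatnonzero(malignant)
        else:
            pool = np.flatnonzero(malignant & (cells["subclone"] == seg.subclone_id).to_numpy())
        k = int(round(seg.carrier_fraction * pool.size))
        carriers = rng.choice(pool, size=k, replace=False) if k < pool.size else pool
        log_mu[np.ix_(carriers, np.arange(g0, g1 + 1))] += np.log(seg.fold_change)

    # --- programs (+ planted dependency)
    activity: dict[str, np.ndarray] = {}
    for p in config.programs:
        act = np.zeros(n_cells, bool)
        for s in samples:
            in_s = malignant & (cells["sample"] == s).to_numpy()
            fr = p.active_cell_fraction_per_sample
            f = fr.get(s, 0.0) if isinstance(fr, dict) else fr
            pool = np.flatnonzero(in_s)
            k = int(round(f * pool.size))
            if k:
                act[rng.choice(pool, size=k, replace=False)] = True
        activity[p.program_id] = act
    for (pa, pb), rule in sorted(config.program_dependency.items()):
        if rule == "independent":
            continue
        activity[pa], activity[pb] = plant_dependency(activity[pa], activity[pb], rule, rng)
    for p in config.programs:
        gi = np.array([gene_pos[g] for g in p.gene_set])
        act = activity[p.program_id]
        if act.any():
            log_mu[np.ix_(np.flatnonzero(act), gi)] += np.log(p.activation_fold)

    # --- ligand-receptor effects
    for lr in config.lr_truth:
        send = (cells["cell_type"] == lr.sender_type).to_numpy()
        recv = (cells["cell_type"] == lr.receiver_type).to_numpy()
        log_mu[send, gene_pos[lr.ligand_gene]] += np.log(lr.effect_fold)
        log_mu[recv, gene_pos[lr.receptor_gene]] += np.log(lr.effect_fold)

    # --- NB draw + dropout
    mu = np.exp(log_mu)
    r = 1.0 / config.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu)).astype(np.int64)
    if config.dropout_rate > 0:
        counts[rng.random(counts.shape) < config.dropout_rate] = 0

    X = sparse.csr_matrix(counts)
    adata = ad.AnnData(
        X=X,
        obs=cells[["sample", "organ", "cell_type", "is_malignant"]].copy(),
        var=pd.DataFrame(index=pd.Index(gene_ids, name="gene_id")),
    )
    adata.obs["sample"] = adata.obs["sample"].astype("category")
    adata.obs["organ"] = adata.obs["organ"].astype("category")

    prog = pd.DataFrame(
        {p.program_id: activity[p.program_id] for p in config.programs},
        index=cells.index,
    )
    truth = GroundTruth(
        cells=cells,
        program_activity=prog,
        gene_annotation=ann.reset_index(drop=True),
        marker_db=marker_db,
        config=config,
    )
    if n_cells != adata.n_obs:
        raise AssertionError("cell-count conservation violated")
    return adata, truth


# ---------------------------------------------------------------------------
# serialization (10x-style triplet + sidecar tables)

def write_sim_outputs(adata: ad.AnnData, truth: GroundTruth, outdir: str | Path) -> None:
    """Write matrix.mtx (genes x cells), features/barcodes TSVs, gene positions,
    truth table and config JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(out / "matrix.mtx"), sparse.csr_matrix(adata.X).T.astype(int))
    feats = pd.DataFrame({
        "gene_id": adata.var_names,
        "gene_symbol": adata.var_names,
        "feature_type": "Gene Expression",
    })
    feats.to_csv(out / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(out / "barcodes.tsv", sep="\t", header=False, index=False)
    truth.gene_annotation[["gene_id", "chromosome", "start"]].to_csv(
        out / "gene_positions.tsv", sep="\t", index=False
    )
    tab = truth.cells.copy()
    tab.index.name = "barcode"
    for pid in truth.program_activity.columns:
        tab[f"program_{pid}"] = truth.program_activity[pid]
    tab.to_csv(out / "truth.tsv", sep="\t")
    cfg = asdict(truth.config)
    cfg["program_dependency"] = {"|".join(k): v for k, v in cfg["program_dependency"].items()}
    cfg["gene_symbol_overrides"] = {str(k): v for k, v in cfg["gene_symbol_overrides"].items()}
    with open(out / "config.json", "w") as fh:
        json.dump(cfg, fh, indent=2, default=str)
    with open(out / "marker_db.json", "w") as fh:
        json.dump(truth.marker_db, fh, indent=2)
    obs = adata.obs[["sample", "organ"]].copy()
    obs.index.name = "barcode"
    obs.to_csv(out / "cell_metadata.tsv", sep="\t")
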