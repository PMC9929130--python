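"""Shared fixtures: small synthetic cohorts reused across test modules."""

import numpy as np
import pandas as pd
import pytest
import anndata as ad

from metaniche.sim import SimConfig, CNVSegmentTruth, ProgramTruth, simulate_counts
from metaniche import preprocess as pp


def gene_range(a: int, b: int) -> list[str]:
    return [f"G{i:04d}" for i in range(a, b)]


def make_adata(X, obs_names=None, var_names=None, **obs_cols) -> ad.AnnData:
    """Small dense-matrix AnnData helper."""
    X = np.asarray(X, dtype=np.float64)
    n, g = X.shape
    adata = ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=obs_names or [f"c{i}" for i in range(n)]),
        var=pd.DataFrame(index=var_names or [f"g{i}" for i in range(g)]),
    )
    for k, v in obs_cols.items():
        adata.obs[k] = pd.Categorical(v) if isinstance(v[0], str) else v
    return adata


@pytest.fixture(scope="session")
def null_cohort():
    """Two samples, three cell types, no planted effects."""
    cfg = SimConfig(
        n_samples=2,
        organ_label_per_sample=("liver", "brain"),
        n_cells_per_type_per_sample={"cancer": 150, "T_cell": 100, "myeloid": 80},
        n_genes=600,
        n_chromosomes=4,
        seed=101,
    )
    adata, truth = simulate_counts(cfg)
    return cfg, adata, truth


@pytest.fixture(scope="session")
def null_norm(null_cohort):
    _, adata, truth = null_cohort
    return pp.normalize_log(adata), truth


@pytest.fixture(scope="session")
def cnv_cohort():
    """Trunk gain + two private subclone segments; T/B cells as reference."""
    cfg = SimConfig(
        n_samples=2,
        organ_label_per_sample=("liver", "brain"),
        n_cells_per_type_per_sample={"cancer": 120, "T_cell": 70, "B_cell": 40},
        n_genes=1000,
        n_chromosomes=5,
        cnv_segments=[
            CNVSegmentTruth("chr1", 20, 140, 2.0, 1.0, None),
            CNVSegmentTruth("chr2", 10, 130, 0.5, 1.0, "s1"),
            CNVSegmentTruth("chr3", 30, 150, 2.0, 1.0, "s2"),
        ],
        seed=202,
    )
    adata, truth = simulate_counts(cfg)
    norm = pp.normalize_log(adata)
    refs = [b for b in norm.obs_names
            if truth.cells.loc[b, "cell_type"] in ("T_cell", "B_cell")]
    return cfg, norm, truth, refs


@pytest.fixture(scope="session")
def program_cohort():
    """Three disjoint planted programs across two samples of cancer cells."""
    cfg = SimConfig(
        n_samples=3,
        organ_label_per_sample=("liver", "liver", "brain"),
        n_cells_per_type_per_sample={"cancer": 300},
        n_genes=800,
        n_chromosomes=4,
        programs=[
            ProgramTruth("P1", gene_range(500, 540), 3.0, 0.4),
            ProgramTruth("P2", gene_range(600, 640), 3.0, 0.4),
            ProgramTruth("P3", gene_range(700, 740), 3.0, 0.4),
        ],
        seed=303,
    )
    adata, truth = simulate_counts(cfg)
    return cfg, pp.normalize_log(adata), truth
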