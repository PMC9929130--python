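"""Generate the default synthetic study cohort and write it as a 10x-style
triplet plus ground-truth sidecars under results/cohort/.

The cohort emulates a two-organ metastatic study: six samples (three liver,
three brain), six cell types with marker genes, malignant cells carrying a
truncal fold-2 gain and two private subclone segments, three 40-gene activity
programs, one planted myeloid->cancer ligand-receptor pair, and a checkpoint
panel with LAG3/TIGIT/CD96/KLRB1 elevated in T cells but PDCD1 at baseline.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from metaniche.sim import simulate_counts, write_sim_outputs
from metaniche.experiments import default_study_config

SEED = 0
OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main():
    cfg = default_study_config(SEED)
    adata, truth = simulate_counts(cfg)
    write_sim_outputs(adata, truth, OUT)
    n_mal = int(truth.cells["is_malignant"].sum())
    print(f"cohort: {adata.n_obs} cells x {adata.n_vars} genes, "
          f"{cfg.n_samples} samples, {n_mal} malignant cells")
    print(f"planted: {len(cfg.cnv_segments)} CNV segments, "
          f"{len(cfg.programs)} programs, {len(cfg.lr_truth)} LR pair(s)")
    print(f"wrote triplet + truth to {OUT}")


if __name__ == "__main__":
    main()
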