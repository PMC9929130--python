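"""Discover recurrent expression programs in the malignant cells.

Subclusters malignant cells within each sample, turns each subcluster into an
expression module (top-100 marker signature + bin-matched control score over
all malignant cells), meta-clusters modules by Pearson correlation of their
score vectors (average linkage, cut r = 0.3), keeps the recurrent programs
(members from >=2 samples), assigns program cells by the strict >70%
expressed-consensus-genes rule, computes per-sample program scores, and
classifies pairwise dependencies by the +/-0.1 corrected log-odds thresholds.
Writes everything under results/programs/ and reports recovery vs truth.
"""

import json
import sys
import warnings
from pathlib import Path

import anndata as ad
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from metaniche import programs as pr  # noqa: E402

SEED = 0
IN_COHORT = ROOT / "results" / "cohort"
IN_PRE = ROOT / "results" / "preprocess"
IN_CNV = ROOT / "results" / "cnv"
OUT = ROOT / "results" / "programs"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    norm = ad.read_h5ad(IN_PRE / "normalized.h5ad")
    calls = pd.read_csv(IN_CNV / "cnv_calls.csv", index_col=0)
    truth = pd.read_csv(IN_COHORT / "truth.tsv", sep="\t", index_col=0)
    config = json.loads((IN_COHORT / "config.json").read_text())

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        modules = pr.extract_modules(norm, malignant=calls["is_malignant"], seed=SEED)
        all_programs = pr.aggregate_modules(modules)
    programs = [p for p in all_programs if p.recurrent]
    print(f"{len(modules)} per-sample modules -> {len(all_programs)} meta-programs, "
          f"{len(programs)} recurrent")

    truth_sets = {p["program_id"]: set(p["gene_set"]) for p in config["programs"]}
    for mp in programs:
        cg = set(mp.consensus_genes)
        jac = {pid: len(cg & s) / len(cg | s) for pid, s in truth_sets.items()}
        best = max(jac, key=jac.get)
        print(f"  {mp.program_id}: {len(mp.member_modules)} modules, "
              f"{len(cg)} consensus genes, best truth match {best} "
              f"(Jaccard {jac[best]:.2f})")

    mal_cells = norm[calls["is_malignant"].reindex(norm.obs_names).fillna(False).to_numpy(bool)]
    assign = pr.assign_program_cells(mal_cells, programs)
    vals, cls = pr.dependency_log_odds(assign)

    (OUT / "programs.json").write_text(json.dumps(
        {p.program_id: p.consensus_genes for p in programs}, indent=2))
    pd.DataFrame(
        [(m.module_id, m.sample_id, i + 1, g)
         for m in modules for i, g in enumerate(m.signature_genes)],
        columns=["module", "sample", "rank", "gene"],
    ).to_csv(OUT / "modules.csv", index=False)
    assign.indicator.to_csv(OUT / "program_cells.csv")
    assign.program_score.to_csv(OUT / "program_scores.csv")
    vals.to_csv(OUT / "dependency_log_odds.csv")
    cls.to_csv(OUT / "dependency_class.csv")

    print("per-sample program scores (proportion of program cells):")
    print(assign.program_score.round(3).to_string())
    pairs = [(p, q, vals.loc[p, q], cls.loc[p, q])
             for i, p in enumerate(vals.index) for q in vals.columns[i + 1:]]
    for p, q, v, c in pairs:
        print(f"  dependency {p}~{q}: log-odds {v:+.2f} -> {c}")
    print(f"wrote program outputs to {OUT}")


if __name__ == "__main__":
    main()
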