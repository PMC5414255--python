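"""Shared configuration for the analysis drivers.

All drivers operate on the default synthetic study written by
01_simulate.py into results/synthetic/, and write their tables under
results/.  Seeds are fixed so every script is reproducible; permutation and
cross-validation counts are chosen so each driver finishes in about a
minute on one CPU (1000 CV rounds, 999 ANOVA permutations, 1000 K
permutations).
"""

from pathlib import Path

from enamelgmm.pipeline import RunConfig

ROOT = Path(__file__).resolve().parent.parent
DATA_DIR = ROOT / "scratch" / "synthetic"     # raw study: large, regenerable
OUT_DIR = ROOT / "results"                    # small summary tables
BULK_DIR = ROOT / "scratch" / "pipeline"      # aligned tables, permutations
SEED = 20170405


def run_config() -> RunConfig:
    return RunConfig(
        tps_path=DATA_DIR / "specimens.tps",
        metadata_path=DATA_DIR / "metadata.csv",
        newick_path=DATA_DIR / "tree.nwk",
        outdir=OUT_DIR,
        bulk_outdir=BULK_DIR,
        cv_rounds=1000,
        anova_n_perm=999,
        kmult_n_perm=1000,
        seed=SEED,
        plot=True,
    )
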