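"""Shared plumbing for the analysis drivers: one deterministic synthetic study
(consortium-scale, seed 14) materialized under results/sim/."""

from pathlib import Path

from teloscore_mr.io import load_cohort, load_genotypes, write_cohort, write_genotypes
from teloscore_mr.simulate import SimConfig, default_panel_with_synthetic_weights, simulate_study

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
# per-subject tables are bulky and regenerated deterministically: keep them
# out of the curated results/ tree
SIM_DIR = ROOT / "scratch" / "sim"
SEED = 14

PANEL = default_panel_with_synthetic_weights()


def ensure_study():
    """Simulate (or reuse) the default study and return (genotypes, cohort)."""
    geno_path = SIM_DIR / "genotypes.tsv"
    cohort_path = SIM_DIR / "cohort.tsv"
    if not (geno_path.exists() and cohort_path.exists()):
        SIM_DIR.mkdir(parents=True, exist_ok=True)
        study = simulate_study(SimConfig(), seed=SEED)
        write_genotypes(study.genotypes, geno_path)
        write_cohort(study.cohort, cohort_path)
        import json
        (SIM_DIR / "truth.json").write_text(json.dumps(study.truth, indent=2))
    return load_genotypes(geno_path, PANEL), load_cohort(cohort_path)


def outdir(name: str) -> Path:
    out = RESULTS / name
    out.mkdir(parents=True, exist_ok=True)
    return out
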