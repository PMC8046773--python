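"""Build the teloscores: raw (100%-call-rate stratum) and scaled (all
subjects) unweighted/weighted variants, with control-based quintiles for the
risk analysis and complete-case quintiles for survival."""

import json

from _common import PANEL, SIM_DIR, ensure_study, outdir
from teloscore_mr.score import score_cohort

g, cohort = ensure_study()
out = outdir("scores")
subject_dir = SIM_DIR.parent / "scores"  # per-subject tables are bulky
subject_dir.mkdir(parents=True, exist_ok=True)

risk = score_cohort(g, PANEL, "risk", cohort)
risk.scores.to_csv(subject_dir / "scores_risk.tsv", sep="\t", index=False, na_rep="NA")
(out / "cuts_risk.json").write_text(json.dumps(
    {v: (list(c.cutpoints) if c else None) for v, c in risk.cuts.items()}, indent=2))

print("risk-analysis quintile cutpoints (reference: controls):")
for v, c in risk.cuts.items():
    print(f"  {v:18s} {c.cutpoints}  (reference n={c.reference_n})")
merged = risk.scores.merge(cohort, on="subject_id")
occ = merged.groupby(["q_weighted_scaled", "status"]).size().unstack()
occ.to_csv(out / "quintile_occupancy_weighted_scaled.tsv", sep="\t")
print("weighted-scaled quintile occupancy (ties kept in the lower quintile):")
print(occ.to_string())

for system in ("ds", "iss"):
    surv = score_cohort(g, PANEL, "survival", cohort, stage_system=system)
    surv.scores.to_csv(subject_dir / f"scores_survival_{system}.tsv", sep="\t",
                       index=False, na_rep="NA")
    ref_n = surv.cuts["weighted_scaled"].reference_n
    print(f"survival ({system.upper()}) reference stratum: {ref_n} complete cases")
print(f"summary tables in {out}; per-subject tables in {subject_dir}")
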