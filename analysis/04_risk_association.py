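"""Myeloma risk associations: per-SNP allelic/codominant logistic models and
score-quintile models, all adjusted for age, sex and country."""

from _common import PANEL, ensure_study, outdir
from teloscore_mr.assoc import score_risk_models, snp_models
from teloscore_mr.score import score_cohort

g, cohort = ensure_study()
out = outdir("risk")

snp = snp_models(g, cohort, PANEL)
threshold = snp.attrs["bonferroni_threshold"]
snp["significant"] = snp["p"] < threshold
snp.to_csv(out / "snp_risk.tsv", sep="\t", index=False)

print(f"Bonferroni threshold for the 11-SNP x 2-model scan: {threshold:.4f}")
hits = snp[snp["significant"]]
print(f"{len(hits)} association(s) below the threshold:")
for _, r in hits.iterrows():
    print(f"  {r.rsid} [{r.model}] OR={r.effect:.2f} ({r.ci_low:.2f}-{r.ci_high:.2f}) "
          f"p={r.p:.2e}")

scores = score_cohort(g, PANEL, "risk", cohort)
score_res = score_risk_models(scores, cohort)
score_res.to_csv(out / "score_risk.tsv", sep="\t", index=False)
print("\nscore-quintile models (OR per one-quintile increase):")
cont = score_res[score_res["model"] == "quintile-continuous"]
for _, r in cont.iterrows():
    print(f"  {r.variant:18s} OR={r.effect:.3f} ({r.ci_low:.3f}-{r.ci_high:.3f}) p={r.p:.2e}")
q5 = score_res[(score_res["model"] == "quintile-5")]
for _, r in q5.iterrows():
    print(f"  {r.variant:18s} Q5 vs Q1: OR={r.effect:.2f} ({r.ci_low:.2f}-{r.ci_high:.2f}) "
          f"p={r.p:.2e}")
print(f"tables in {out}")
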