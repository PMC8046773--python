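"""Genotyping quality control: call rates, duplicate concordance, HWE.

Reporting only -- no SNP or subject is dropped here.  Analyses choose their
strata explicitly (e.g. the 100%-call-rate stratum for raw scores).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeMatrix

__all__ = ["HweResult", "QcReport", "call_rates", "hwe_test", "hwe_report",
           "duplicate_concordance", "qc_report"]


@dataclass(frozen=True)
class HweResult:
    chi2: float
    p: float
    monomorphic: bool = False


@dataclass
class QcReport:
    per_snp_call_rate: pd.Series
    per_subject_call_rate: pd.Series
    mean_call_rate: float
    complete_subjects: np.ndarray  # ids with a 100% call rate
    duplicate_concordance: float | None = None
    hwe: pd.DataFrame | None = None

    def to_json(self) -> str:
        payload = {
            "mean_call_rate": self.mean_call_rate,
            "per_snp_call_rate": self.per_snp_call_rate.round(6).to_dict(),
            "n_subjects": int(len(self.per_subject_call_rate)),
            "n_complete_subjects": int(len(self.complete_subjects)),
            "duplicate_concordance": self.duplicate_concordance,
        }
        if self.hwe is not None:
            payload["hwe"] = self.hwe.round(6).set_index("rsid").to_dict("index")
        return json.dumps(payload, indent=2)

    def snp_table(self) -> pd.DataFrame:
        tab = self.per_snp_call_rate.rename("call_rate").rename_axis("rsid").reset_index()
        if self.hwe is not None:
            tab = tab.merge(self.hwe, on="rsid", how="left")
        return tab


def call_rates(g: GenotypeMatrix) -> QcReport:
    """Per-SNP and per-subject call rates, plus the complete-data stratum."""
    if g.n == 0:
        raise ValueError("empty genotype matrix")
    called = ~np.isnan(g.dosage)
    per_snp = pd.Series(called.mean(axis=0), index=list(g.rsids))
    per_subject = pd.Series(called.mean(axis=1), index=list(g.subject_ids))
    return QcReport(
        per_snp_call_rate=per_snp,
        per_subject_call_rate=per_subject,
        mean_call_rate=float(per_snp.mean()),
        complete_subjects=g.subject_ids[g.complete_mask],
    )


def hwe_test(n0: int, n1: int, n2: int) -> HweResult:
    """Pearson 1-df chi-square test of Hardy-Weinberg equilibrium.

    ``(n0, n1, n2)`` are genotype counts by effect-allele dosage.  Monomorphic
    SNPs return chi2 = 0, p = 1 with the ``monomorphic`` flag set.  The
    statistic is invariant under the allele relabeling d -> 2 - d.
    """
    n = n0 + n1 + n2
    if n < 1:
        raise ValueError("need at least one genotyped subject")
    p_hat = (2 * n2 + n1) / (2 * n)
    if p_hat in (0.0, 1.0):
        return HweResult(0.0, 1.0, monomorphic=True)
    expected = np.array([n * (1 - p_hat) ** 2, 2 * n * p_hat * (1 - p_hat), n * p_hat**2])
    observed = np.array([n0, n1, n2], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return HweResult(chi2, float(stats.chi2.sf(chi2, df=1)))


def hwe_report(g: GenotypeMatrix, subject_mask: np.ndarray | None = None) -> pd.DataFrame:
    """Per-SNP HWE chi-square/p over an optional subject stratum (typically
    the controls)."""
    dosage = g.dosage if subject_mask is None else g.dosage[np.asarray(subject_mask, bool)]
    rows = []
    for j, rsid in enumerate(g.rsids):
        col = dosage[:, j]
        col = col[~np.isnan(col)]
        counts = [(col == d).sum() for d in (0, 1, 2)]
        res = hwe_test(*counts)
        rows.append({"rsid": rsid, "n0": counts[0], "n1": counts[1], "n2": counts[2],
                     "hwe_chi2": res.chi2, "hwe_p": res.p, "monomorphic": res.monomorphic})
    return pd.DataFrame(rows)


def duplicate_concordance(g: GenotypeMatrix, pairs: list[tuple[str, str]]) -> float:
    """Fraction of jointly non-missing calls agreeing across duplicate pairs,
    pooled over pairs and SNPs."""
    pos = {s: i for i, s in enumerate(g.subject_ids)}
    agree = total = 0
    for a, b in pairs:
        if a not in pos or b not in pos:
            raise KeyError(f"duplicate pair ({a}, {b}): unknown subject id")
        da, db = g.dosage[pos[a]], g.dosage[pos[b]]
        joint = ~np.isnan(da) & ~np.isnan(db)
        total += int(joint.sum())
        agree += int((da[joint] == db[joint]).sum())
    if total == 0:
        warnings.warn("no jointly non-missing calls among duplicate pairs")
        return float("nan")
    return agree / total


def qc_report(
    g: GenotypeMatrix,
    cohort: pd.DataFrame | None = None,
    duplicate_pairs: list[tuple[str, str]] | None = None,
) -> QcReport:
    """Full QC report; HWE is computed in controls when a cohort is given
    (falling back to all subjects otherwise)."""
    report = call_rates(g)
    if cohort is not None:
        status = cohort.set_index("subject_id")["status"]
        mask = np.array([status.get(s) == "control" for s in g.subject_ids])
    else:
        mask = None
    report.hwe = hwe_report(g, mask)
    if duplicate_pairs:
        report.duplicate_concordance = duplicate_concordance(g, duplicate_pairs)
    return report
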