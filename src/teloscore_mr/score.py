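"""Telomere genetic scores ("teloscores") and quintile assignment.

Per subject, with dosage c_j = count of long-telomere alleles at SNP j and
configured per-allele bp effects w_j:

* unweighted  = sum_j c_j                 (0 .. 2L; complete data only)
* weighted_bp = sum_j c_j * w_j           (bp; complete data only)
* scaled      = the same sums over the *non-missing* SNPs, divided by the
  number of non-missing SNPs -- the "average" score that makes subjects with
  incomplete calls comparable.

Quintiles are cut on the empirical distribution of a stated reference stratum
(controls for the risk analysis; cases with complete stage/therapy/follow-up
for survival).  Cutpoint k is the smallest reference value whose empirical CDF
reaches k/5, and ties at a cutpoint fall in the lower quintile -- scores are
heavily tied integers, so ties are deliberately not split.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeMatrix
from .panel import SnpPanel

__all__ = [
    "QuintileCuts", "unweighted_score", "weighted_score", "scaled_scores",
    "loo_matrix", "quintile_cuts", "assign_quintiles", "score_matrix",
    "score_cohort", "CohortScores",
]

logger = logging.getLogger(__name__)

VARIANTS = ("unweighted", "weighted", "unweighted_scaled", "weighted_scaled")


@dataclass(frozen=True)
class QuintileCuts:
    """Four nondecreasing cutpoints from a reference distribution."""

    cutpoints: tuple[float, float, float, float]
    reference_n: int

    def __post_init__(self) -> None:
        if list(self.cutpoints) != sorted(self.cutpoints):
            raise ValueError("cutpoints must be nondecreasing")


def _as_matrix(dosage) -> np.ndarray:
    arr = np.asarray(dosage, dtype=float)
    return arr[None, :] if arr.ndim == 1 else arr


def unweighted_score(dosage) -> np.ndarray | float:
    """Sum of effect-allele dosages; missing unless all L SNPs are called."""
    arr = _as_matrix(dosage)
    out = np.where(np.isnan(arr).any(axis=1), np.nan, np.nansum(arr, axis=1))
    return float(out[0]) if np.asarray(dosage).ndim == 1 else out


def weighted_score(dosage, panel: SnpPanel) -> np.ndarray | float:
    """Sum of dosage * per-allele bp effect; missing unless complete."""
    arr = _as_matrix(dosage)
    w = panel.weights_bp
    if arr.shape[1] != len(w):
        raise ValueError("dosage row length does not match panel size")
    out = np.where(np.isnan(arr).any(axis=1), np.nan, np.nansum(arr * w, axis=1))
    return float(out[0]) if np.asarray(dosage).ndim == 1 else out


def scaled_scores(dosage, panel: SnpPanel | None = None) -> tuple:
    """Per-non-missing-SNP average scores (unweighted, weighted).

    The weighted component requires configured panel weights; subjects with no
    non-missing call get NaN (flagged via a warning by :func:`score_matrix`).
    """
    arr = _as_matrix(dosage)
    n_nonmiss = (~np.isnan(arr)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        unw = np.where(n_nonmiss > 0, np.nansum(arr, axis=1) / n_nonmiss, np.nan)
        if panel is not None:
            w = panel.weights_bp
            wgt = np.where(n_nonmiss > 0, np.nansum(arr * w, axis=1) / n_nonmiss, np.nan)
        else:
            wgt = np.full(arr.shape[0], np.nan)
    if np.asarray(dosage).ndim == 1:
        return float(unw[0]), float(wgt[0])
    return unw, wgt


def score_matrix(g: GenotypeMatrix, panel: SnpPanel, excluded_rsids=()) -> pd.DataFrame:
    """All score variants per subject, optionally on a leave-SNPs-out panel.

    Raw (unweighted/weighted) scores are present only for subjects complete on
    the reduced panel; scaled scores for every subject with >= 1 call.
    """
    excluded = set(excluded_rsids)
    if excluded:
        panel = panel.drop(excluded)
        keep = [j for j, r in enumerate(g.rsids) if r not in excluded]
        g = GenotypeMatrix(g.subject_ids, g.dosage[:, keep], [g.rsids[j] for j in keep])
    arr = g.dosage
    n_nonmiss = (~np.isnan(arr)).sum(axis=1)
    if (n_nonmiss == 0).any():
        warnings.warn(
            f"{int((n_nonmiss == 0).sum())} subject(s) with no non-missing call "
            "excluded from scoring"
        )
    df = pd.DataFrame({"subject_id": g.subject_ids, "n_nonmissing": n_nonmiss})
    df["unweighted"] = unweighted_score(arr)
    df["weighted"] = weighted_score(arr, panel) if panel.weights_configured else np.nan
    unw_s, wgt_s = scaled_scores(arr, panel if panel.weights_configured else None)
    df["unweighted_scaled"] = unw_s
    df["weighted_scaled"] = wgt_s
    return df


def loo_matrix(g: GenotypeMatrix, panel: SnpPanel, excluded_rsids) -> pd.DataFrame:
    """Leave-SNP-out sensitivity scores over the reduced panel."""
    excluded = set(excluded_rsids)
    if excluded >= set(panel.rsids):
        raise ValueError("cannot exclude every SNP")
    return score_matrix(g, panel, excluded)


def quintile_cuts(reference_scores) -> QuintileCuts:
    """Empirical-CDF quintile cutpoints from a reference stratum.

    Cutpoint k (k = 1..4) is the smallest reference value v with
    ECDF(v) >= k/5.
    """
    ref = np.asarray(reference_scores, dtype=float)
    ref = np.sort(ref[~np.isnan(ref)])
    n = len(ref)
    if n < 5:
        raise ValueError("need at least 5 non-missing reference values")
    cuts = tuple(float(ref[int(np.ceil(n * k / 5)) - 1]) for k in (1, 2, 3, 4))
    if len(set(cuts)) == 1 and cuts[0] == ref[-1]:
        warnings.warn("degenerate reference distribution: all quintile cutpoints equal")
    return QuintileCuts(cuts, n)


def assign_quintiles(scores, cuts: QuintileCuts) -> np.ndarray:
    """Quintile = 1 + #{cutpoints < score}; ties fall in the lower quintile."""
    arr = np.asarray(scores, dtype=float)
    cp = np.asarray(cuts.cutpoints)
    q = 1 + (arr[:, None] > cp[None, :]).sum(axis=1).astype(float)
    q[np.isnan(arr)] = np.nan
    return q


@dataclass
class CohortScores:
    """Per-subject scores with quintiles, plus the reference cuts used.

    ``scores`` has, per variant v in {unweighted, weighted, unweighted_scaled,
    weighted_scaled}, columns ``v`` and ``q_<v>``; ``cuts`` maps variant name
    to its :class:`QuintileCuts`.  Raw variants live on the 100%-call-rate
    stratum, scaled variants on all scoreable subjects.
    """

    scores: pd.DataFrame
    cuts: dict[str, QuintileCuts]
    reference: str


def _survival_complete(cohort: pd.DataFrame, stage_system: str) -> pd.Series:
    stage_col = f"stage_{stage_system}"
    return (
        (cohort["status"] == "case")
        & cohort[stage_col].notna()
        & cohort["therapy"].notna()
        & cohort["vital"].notna()
        & cohort["os_time"].notna()
    )


def score_cohort(
    g: GenotypeMatrix,
    panel: SnpPanel,
    analysis: str,
    cohort: pd.DataFrame,
    stage_system: str = "ds",
    excluded_rsids=(),
) -> CohortScores:
    """Score every subject and cut quintiles on the analysis-specific
    reference stratum.

    ``analysis="risk"``: cuts from the controls' distribution.
    ``analysis="survival"``: cuts from cases with complete stage (per
    ``stage_system``), therapy and follow-up; raw-score cuts additionally
    require a 100% call rate, mirroring the complete-data stratum.
    """
    if analysis not in {"risk", "survival"}:
        raise ValueError("analysis must be 'risk' or 'survival'")
    df = score_matrix(g, panel, excluded_rsids)
    merged = df.merge(cohort, on="subject_id", how="left", validate="one_to_one")
    if analysis == "risk":
        in_ref = (merged["status"] == "control").to_numpy()
    else:
        in_ref = _survival_complete(merged, stage_system).to_numpy()
    cuts: dict[str, QuintileCuts | None] = {}
    for variant in VARIANTS:
        vals = df[variant].to_numpy()
        ref_mask = in_ref & ~np.isnan(vals)
        try:
            cuts[variant] = quintile_cuts(vals[ref_mask])
        except ValueError:
            # e.g. heavy missingness leaving (almost) nobody with complete
            # calls: the scaled variants still run
            warnings.warn(f"{variant}: reference stratum too small; quintiles not assigned")
            cuts[variant] = None
            df[f"q_{variant}"] = np.nan
            continue
        df[f"q_{variant}"] = assign_quintiles(vals, cuts[variant])
    if all(c is None for c in cuts.values()):
        raise ValueError("empty reference stratum for every score variant")
    return CohortScores(df, cuts, reference="controls" if analysis == "risk"
                        else f"complete-{stage_system}-cases")
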