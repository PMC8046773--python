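"""Summary-statistic Mendelian randomization with the telomere-length panel.

Inputs are per-SNP effect pairs: (bx, bxse) of the instrument on the exposure
(telomere length per long-telomere allele, in kb by convention here) and
(by, byse) on the outcome (log-OR for disease risk, log-HR for survival).

Estimators: per-SNP Wald ratios, inverse-variance-weighted (IVW) regression
through the origin (fixed-effect and multiplicative-random-effects standard
errors), and MR-Egger weighted regression with an intercept that absorbs --
and tests for -- directional pleiotropy.  Heterogeneity via Cochran's Q;
instrument strength for Egger via Bowden's I2_GX (unweighted, plus the
outcome-weighted variant used with Egger weights).

First-order convention: exposure-side error is ignored in the point estimates
and outcome-side weights (standard two-sample summary MR practice); I2_GX is
the diagnostic for the resulting regression-dilution risk in MR-Egger.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .panel import SnpPanel

__all__ = ["MrSummarySet", "MrResult", "wald_ratio", "ivw", "mr_egger",
           "cochran_q", "i2_gx", "mr_report", "summary_from_tables"]


@dataclass(frozen=True)
class MrSummarySet:
    """Per-SNP summary statistics: instrument-exposure (bx, bxse) and
    instrument-outcome (by, byse), jointly oriented (flipping the coded allele
    negates bx and by together, leaving every estimator invariant)."""

    rsid: tuple[str, ...]
    bx: np.ndarray
    bxse: np.ndarray
    by: np.ndarray
    byse: np.ndarray

    def __post_init__(self) -> None:
        for name in ("bx", "bxse", "by", "byse"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        k = len(self.rsid)
        if not (len(self.bx) == len(self.bxse) == len(self.by) == len(self.byse) == k):
            raise ValueError("all summary vectors must share the same length")
        if k < 1:
            raise ValueError("need at least one instrument")
        if (self.byse <= 0).any() or (np.nan_to_num(self.bxse, nan=1.0) <= 0).any():
            raise ValueError("standard errors must be strictly positive")

    @property
    def k(self) -> int:
        return len(self.rsid)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MrSummarySet":
        return cls(tuple(df["rsid"]), df["bx"].to_numpy(), df["bxse"].to_numpy(),
                   df["by"].to_numpy(), df["byse"].to_numpy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"rsid": self.rsid, "bx": self.bx, "bxse": self.bxse,
                             "by": self.by, "byse": self.byse})


@dataclass
class MrResult:
    method: str
    slope: float
    slope_se: float
    slope_ci95: tuple[float, float]
    slope_p: float
    k: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_ci95: tuple[float, float] | None = None
    intercept_p: float | None = None
    q: float | None = None
    q_df: int | None = None
    q_p: float | None = None
    i2_gx: float | None = None

    def to_dict(self) -> dict:
        d = {"method": self.method, "slope": self.slope, "slope_se": self.slope_se,
             "slope_ci95": list(self.slope_ci95), "slope_p": self.slope_p, "k": self.k}
        for key in ("intercept", "intercept_se", "intercept_p", "q", "q_df", "q_p", "i2_gx"):
            v = getattr(self, key)
            if v is not None:
                d[key] = v
        if self.intercept_ci95 is not None:
            d["intercept_ci95"] = list(self.intercept_ci95)
        return d


def _ci(est: float, se: float) -> tuple[float, float]:
    return (est - 1.96 * se, est + 1.96 * se)


def _p(est: float, se: float) -> float:
    return float(2 * stats.norm.sf(abs(est) / se)) if se > 0 else float("nan")


def wald_ratio(bx: float, bxse: float, by: float, byse: float) -> tuple[float, float]:
    """Single-instrument causal estimate by/bx with first-order se |byse/bx|."""
    if bx == 0:
        raise ValueError("Wald ratio undefined for bx = 0")
    return by / bx, abs(byse / bx)


def cochran_q(s: MrSummarySet, slope: float, intercept: float = 0.0,
              df_loss: int = 1) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity of the per-instrument fits.

    Q = sum byse_j^-2 (by_j - intercept - slope * bx_j)^2, df = K - df_loss
    (1 for IVW, 2 for Egger), p from the chi-square upper tail."""
    df = s.k - df_loss
    if df <= 0:
        raise ValueError("nonpositive degrees of freedom for Cochran's Q")
    q = float(np.sum(s.byse**-2 * (s.by - intercept - slope * s.bx) ** 2))
    return q, df, float(stats.chi2.sf(q, df))


def ivw(s: MrSummarySet, mode: str = "fixed") -> MrResult:
    """Inverse-variance-weighted regression of by on bx through the origin.

    ``mode="fixed"`` uses the fixed-effect se; ``"mre"`` multiplies it by
    max(1, sqrt(Q/(K-1))) (multiplicative random effects).  The slope is
    identical in both modes; with K = 1 it reduces to the Wald ratio."""
    if mode not in {"fixed", "mre"}:
        raise ValueError("mode must be 'fixed' or 'mre'")
    w = s.byse**-2
    denom = float(np.sum(w * s.bx**2))
    if denom == 0:
        raise ValueError("all bx are zero; IVW slope undefined")
    slope = float(np.sum(w * s.bx * s.by)) / denom
    se = denom**-0.5
    q = q_df = q_p = None
    if s.k >= 2:
        q, q_df, q_p = cochran_q(s, slope, df_loss=1)
        if mode == "mre":
            se *= max(1.0, np.sqrt(q / q_df))
    return MrResult(method=f"ivw-{'fixed' if mode == 'fixed' else 'mre'}",
                    slope=slope, slope_se=se, slope_ci95=_ci(slope, se),
                    slope_p=_p(slope, se), k=s.k, q=q, q_df=q_df, q_p=q_p)


def mr_egger(s: MrSummarySet) -> MrResult:
    """MR-Egger: byse^-2-weighted regression of by on bx with intercept, after
    orienting every instrument to bx >= 0 (the intercept's sign convention
    depends on this orientation).  Standard errors are inflated by
    max(1, sqrt(Q_egger/(K-2)))."""
    if s.k < 3:
        raise ValueError("MR-Egger needs at least 3 instruments")
    sign = np.where(s.bx < 0, -1.0, 1.0)
    bx, by = s.bx * sign, s.by * sign
    if np.ptp(bx) == 0:
        raise ValueError("constant bx: Egger slope and intercept are not separable")
    w = s.byse**-2
    X = np.column_stack([np.ones_like(bx), bx])
    xtw = X.T * w
    cov = np.linalg.inv(xtw @ X)
    beta = cov @ (xtw @ by)
    oriented = MrSummarySet(s.rsid, bx, s.bxse, by, s.byse)
    q, q_df, q_p = cochran_q(oriented, beta[1], intercept=beta[0], df_loss=2)
    infl = max(1.0, np.sqrt(q / q_df))
    se = np.sqrt(np.diag(cov)) * infl
    i2 = i2_gx(s.bx, s.bxse) if np.isfinite(s.bxse).all() else None
    return MrResult(
        method="egger", slope=float(beta[1]), slope_se=float(se[1]),
        slope_ci95=_ci(float(beta[1]), float(se[1])), slope_p=_p(float(beta[1]), float(se[1])),
        k=s.k, intercept=float(beta[0]), intercept_se=float(se[0]),
        intercept_ci95=_ci(float(beta[0]), float(se[0])),
        intercept_p=_p(float(beta[0]), float(se[0])),
        q=q, q_df=q_df, q_p=q_p, i2_gx=i2,
    )


def i2_gx(bx, bxse) -> float:
    """Bowden's I2_GX instrument-strength diagnostic for MR-Egger.

    Q_GX = sum bxse_j^-2 (bx_j - mean_w(bx))^2 with inverse-variance weights;
    I2_GX = max(0, (Q_GX - (K-1)) / Q_GX), truncated at zero.  Values near 1
    mean exposure-effect estimation error is negligible relative to the spread
    of the bx (little regression dilution in Egger)."""
    bx = np.asarray(bx, dtype=float)
    bxse = np.asarray(bxse, dtype=float)
    if len(bx) < 2:
        raise ValueError("I2_GX needs at least 2 instruments")
    if (bxse <= 0).any():
        raise ValueError("bxse must be strictly positive")
    w = bxse**-2
    mean = np.sum(w * bx) / np.sum(w)
    q_gx = float(np.sum(w * (bx - mean) ** 2))
    if q_gx == 0:
        warnings.warn("identical bx across instruments: I2_GX = 0 (weak instruments for Egger)")
        return 0.0
    return max(0.0, (q_gx - (len(bx) - 1)) / q_gx)


def summary_from_tables(snp_assoc: pd.DataFrame, panel: SnpPanel,
                        exposure_unit_bp: float = 1000.0) -> MrSummarySet:
    """Bridge per-SNP allelic association results into MR inputs.

    ``snp_assoc`` needs columns rsid/model/effect/ci_low/ci_high with allelic
    effects per *minor* allele (the reporting convention of the association
    tables); they are re-oriented here to the long-telomere allele so that bx
    (the configured per-allele bp effect, rescaled to ``exposure_unit_bp``,
    default kb) is nonnegative.  byse is recovered from the CI width on the
    log scale: (ln hi - ln lo) / (2 * 1.96).  SNPs lacking a CI are dropped
    with a warning.
    """
    allelic = snp_assoc[snp_assoc["model"] == "allelic"].set_index("rsid")
    rsids, bx, bxse, by, byse = [], [], [], [], []
    for snp in panel:
        if snp.rsid not in allelic.index:
            warnings.warn(f"{snp.rsid}: no allelic estimate; dropped from MR")
            continue
        row = allelic.loc[snp.rsid]
        if not np.isfinite(row["ci_low"]) or not np.isfinite(row["ci_high"]) \
                or row["ci_low"] <= 0:
            warnings.warn(f"{snp.rsid}: missing/invalid CI; dropped from MR")
            continue
        log_or = float(np.log(row["effect"]))
        if not snp.effect_allele_is_minor:
            log_or = -log_or  # reported per minor allele; flip to the long-telomere allele
        rsids.append(snp.rsid)
        by.append(log_or)
        byse.append(float((np.log(row["ci_high"]) - np.log(row["ci_low"])) / (2 * 1.96)))
        bx.append(snp.weight_bp / exposure_unit_bp if snp.weight_bp is not None else np.nan)
        bxse.append(snp.weight_se_bp / exposure_unit_bp if snp.weight_se_bp is not None else np.nan)
    if any(np.isnan(bx)):
        raise ValueError("panel weights must be configured to assemble MR inputs")
    return MrSummarySet(tuple(rsids), np.array(bx), np.array(bxse),
                        np.array(by), np.array(byse))


def _isq(est: np.ndarray, se: np.ndarray) -> float:
    w = se**-2.0
    mean = np.sum(w * est) / np.sum(w)
    q = float(np.sum(w * (est - mean) ** 2))
    return max(0.0, (q - (len(est) - 1)) / q) if q > 0 else 0.0


def mr_report(s: MrSummarySet) -> dict:
    """Run the full estimator battery and emit plot-ready tables.

    Returns ``results`` (ivw-fixed, ivw-mre, egger), ``i2_gx`` /
    ``i2_gx_outcome_weighted`` (the latter computed on bx/byse as used with
    Egger weights), ``scatter`` (per-SNP points with error bars and fitted
    lines) and ``forest`` (per-SNP Wald ratios plus the pooled estimates)."""
    if s.k < 3:
        raise ValueError("mr_report needs at least 3 instruments")
    results = {r.method: r for r in (ivw(s, "fixed"), ivw(s, "mre"), mr_egger(s))}
    have_bxse = np.isfinite(s.bxse).all()
    i2_plain = i2_gx(s.bx, s.bxse) if have_bxse else None
    i2_weighted = _isq(s.bx / s.byse, s.bxse / s.byse) if have_bxse else None
    egger = results["egger"]
    scatter = s.to_frame()
    scatter["ivw_fit"] = results["ivw-fixed"].slope * s.bx
    scatter["egger_fit"] = egger.intercept + egger.slope * np.abs(s.bx)
    ratios = [wald_ratio(bx, bxse, by, byse)
              for bx, bxse, by, byse in zip(s.bx, s.bxse, s.by, s.byse)]
    forest = pd.DataFrame({
        "label": list(s.rsid) + ["IVW (fixed)", "IVW (mre)", "MR-Egger"],
        "estimate": [r[0] for r in ratios] + [results["ivw-fixed"].slope,
                                              results["ivw-mre"].slope, egger.slope],
        "se": [r[1] for r in ratios] + [results["ivw-fixed"].slope_se,
                                        results["ivw-mre"].slope_se, egger.slope_se],
    })
    forest["ci_low"] = forest["estimate"] - 1.96 * forest["se"]
    forest["ci_high"] = forest["estimate"] + 1.96 * forest["se"]
    return {"results": results, "i2_gx": i2_plain, "i2_gx_outcome_weighted": i2_weighted,
            "scatter": scatter, "forest": forest}
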