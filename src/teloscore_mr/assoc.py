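"""Covariate-adjusted association models.

Risk: unconditional logistic regression (case/control) per SNP under allelic
(log-additive) and codominant codings, and per score quintile (categorical
Q2-Q5 vs Q1, plus the quintile index as a numeric trend term).  Survival:
Cox proportional hazards on overall survival with the same exposure codings,
adjusted additionally for disease stage and first-line therapy.

Conventions: allelic SNP effects are reported per *minor* allele (the
common-vs-rare contrast); Wald CIs and p-values throughout; Breslow tie
handling in Cox by default (Efron available).  Country enters as
reference-coded indicators, reference = first category alphabetically.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .io import GenotypeMatrix
from .panel import SnpPanel
from .score import VARIANTS, CohortScores, _survival_complete

__all__ = [
    "ConvergenceError", "LogisticFit", "CoxFit", "fit_logistic", "fit_cox",
    "snp_models", "score_risk_models", "os_endpoint", "snp_survival_models",
    "score_survival_models", "bonferroni_threshold",
]

logger = logging.getLogger(__name__)

RISK_COVARIATES = ("age", "sex", "country")
SURVIVAL_COVARIATES = ("age", "sex", "country", "stage", "therapy")


class ConvergenceError(RuntimeError):
    """Raised when an iterative fit fails to converge (never silent)."""


def bonferroni_threshold(n_snps: int, n_models: int = 2, alpha: float = 0.05) -> float:
    """Per-test significance level for the SNP scan: alpha / (L * models)."""
    return alpha / (n_snps * n_models)


def _check_design(X: pd.DataFrame) -> None:
    arr = np.asarray(X, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("design matrix contains missing values")
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        _, r = np.linalg.qr(arr)
        diag = np.abs(np.diag(r))
        bad = [X.columns[i] for i in np.flatnonzero(diag < 1e-8 * max(diag.max(), 1.0))]
        raise ValueError(f"design matrix is rank deficient; collinear column(s): {bad}")


@dataclass
class LogisticFit:
    params: pd.Series
    cov: pd.DataFrame
    n: int
    llf: float
    converged: bool


@dataclass
class CoxFit:
    params: pd.Series
    cov: pd.DataFrame
    n: int
    n_events: int
    llf: float
    converged: bool
    n_iter: int


def fit_logistic(y, X: pd.DataFrame) -> LogisticFit:
    """Maximum-likelihood logistic regression (Newton, tol 1e-8).

    ``y`` is 0/1; ``X`` must include its own intercept column.  Errors on a
    constant outcome, rank deficiency (naming the collinear columns) and
    perfect separation.
    """
    y = np.asarray(y, dtype=float)
    X = pd.DataFrame(X).astype(float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome is constant; logistic model is undefined")
    _check_design(X)
    try:
        res = sm.Logit(y, X).fit(method="newton", maxiter=100, tol=1e-8, disp=0)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        sep = _separating_terms(y, X)
        raise ValueError(
            "perfect separation in logistic model"
            + (f"; suspect term(s): {sep}" if sep else "")
        ) from exc
    if not res.mle_retvals.get("converged", True):
        raise ConvergenceError("logistic regression did not converge in 100 iterations")
    return LogisticFit(res.params, res.cov_params(), int(len(y)), float(res.llf), True)


def _separating_terms(y, X: pd.DataFrame) -> list[str]:
    out = []
    for c in X.columns:
        v = X[c].to_numpy()
        if np.ptp(v) == 0:
            continue
        if v[y == 1].min() >= v[y == 0].max() or v[y == 0].min() >= v[y == 1].max():
            out.append(c)
    return out


def _cox_sums(order_x, exp_eta, starts, ends):
    cum0 = np.cumsum(exp_eta)
    cum1 = np.cumsum(order_x * exp_eta[:, None], axis=0)
    outer = order_x[:, :, None] * order_x[:, None, :]
    cum2 = np.cumsum(outer * exp_eta[:, None, None], axis=0)
    return cum0[ends], cum1[ends], cum2[ends]


def fit_cox(time, event, X: pd.DataFrame, ties: str = "breslow",
            tol: float = 1e-8, max_iter: int = 100) -> CoxFit:
    """Cox proportional-hazards partial-likelihood fit via Newton-Raphson.

    Breslow tie handling by default (``ties="efron"`` available).  Requires at
    least one event and a full-rank design without constant columns (constants
    cancel from the partial likelihood).  Monotone partial likelihood (risk
    score separating events) surfaces as :class:`ConvergenceError`.
    """
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=float)
    X = pd.DataFrame(X).astype(float)
    xa = np.asarray(X)
    n, p = xa.shape
    if d.sum() < 1:
        raise ValueError("no events; Cox model is undefined")
    if (t <= 0).any():
        raise ValueError("event/censoring times must be positive")
    if (np.ptp(xa, axis=0) == 0).any():
        const = [X.columns[j] for j in np.flatnonzero(np.ptp(xa, axis=0) == 0)]
        raise ValueError(f"constant column(s) {const} are inestimable in a Cox model")
    _check_design(X)
    if ties not in {"breslow", "efron"}:
        raise ValueError("ties must be 'breslow' or 'efron'")

    order = np.argsort(-t, kind="stable")
    ts, ds, xs = t[order], d[order], xa[order]
    # tie groups are contiguous in the descending sort
    change = np.flatnonzero(np.diff(ts)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change - 1, [n - 1]))
    d_g = np.add.reduceat(ds, starts)
    s_g = np.add.reduceat(xs * ds[:, None], starts, axis=0)
    has_event = d_g > 0

    scale = xs.std(axis=0)
    beta = np.zeros(p)

    def loglik_grad_hess(beta):
        eta = np.clip(xs @ beta, -500, 500)
        w = np.exp(eta)
        S0, S1, S2 = _cox_sums(xs, w, starts, ends)
        ll = float(np.sum(s_g[has_event] @ beta))
        grad = np.zeros(p)
        hess = np.zeros((p, p))
        if ties == "breslow":
            Dg, S0g, S1g, S2g = d_g[has_event], S0[has_event], S1[has_event], S2[has_event]
            ll -= float(np.sum(Dg * np.log(S0g)))
            mu = S1g / S0g[:, None]
            grad = s_g[has_event].sum(axis=0) - (Dg[:, None] * mu).sum(axis=0)
            hess = -(
                np.einsum("g,gij->ij", Dg, S2g / S0g[:, None, None])
                - np.einsum("g,gi,gj->ij", Dg, mu, mu)
            )
        else:  # efron
            T0 = np.add.reduceat(w * ds, starts)
            T1 = np.add.reduceat(xs * (w * ds)[:, None], starts, axis=0)
            T2 = np.add.reduceat(xs[:, :, None] * xs[:, None, :] * (w * ds)[:, None, None],
                                 starts, axis=0)
            grad = s_g[has_event].sum(axis=0)
            for g in np.flatnonzero(has_event):
                dg = int(round(d_g[g]))
                for l in range(dg):
                    f = l / dg
                    D0 = S0[g] - f * T0[g]
                    D1 = S1[g] - f * T1[g]
                    D2 = S2[g] - f * T2[g]
                    ll -= np.log(D0)
                    m = D1 / D0
                    grad -= m
                    hess -= D2 / D0 - np.outer(m, m)
        return ll, grad, hess

    ll, grad, hess = loglik_grad_hess(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular Hessian in Cox fit") from exc
        new_beta = beta + step
        new_ll, new_grad, new_hess = loglik_grad_hess(new_beta)
        halvings = 0
        while not np.isfinite(new_ll) or new_ll < ll - 1e-12:
            halvings += 1
            if halvings > 30:
                raise ConvergenceError("Cox step-halving failed; likelihood not improving")
            step = step / 2
            new_beta = beta + step
            new_ll, new_grad, new_hess = loglik_grad_hess(new_beta)
        delta = new_ll - ll
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if np.abs(beta * scale).max() > 50:
            raise ConvergenceError(
                "monotone partial likelihood (a covariate separates the events); "
                "estimate diverges"
            )
        if abs(delta) < tol * (abs(ll) + 1e-10):
            converged = True
            break
    if not converged:
        raise ConvergenceError(f"Cox fit did not converge in {max_iter} iterations")
    cov = np.linalg.inv(-hess)
    names = list(X.columns)
    return CoxFit(pd.Series(beta, index=names), pd.DataFrame(cov, index=names, columns=names),
                  n, int(d.sum()), ll, converged, it)


def _wald_rows(params: pd.Series, cov: pd.DataFrame, terms: dict[str, str],
               n_used: int, rsid: str | None = None, variant: str | None = None) -> list[dict]:
    rows = []
    for term, model in terms.items():
        est = float(params[term])
        se = float(np.sqrt(cov.loc[term, term]))
        z = est / se if se > 0 else np.nan
        with np.errstate(over="ignore"):  # a diverging bound prints as inf
            rows.append({
                "rsid": rsid, "variant": variant, "term": term, "model": model,
                "estimate": est, "se": se, "effect": float(np.exp(est)),
                "ci_low": float(np.exp(est - 1.96 * se)),
                "ci_high": float(np.exp(est + 1.96 * se)),
                "p": float(2 * stats.norm.sf(abs(z))),
                "n_used": n_used,
            })
    return rows


def build_covariates(cohort: pd.DataFrame, covariates, stage_system: str = "ds") -> pd.DataFrame:
    """Reference-coded covariate design (no intercept column)."""
    cols = {}
    for cov in covariates:
        if cov == "age":
            cols["age"] = cohort["age"].astype(float)
        elif cov == "sex":
            cols["sex_male"] = (cohort["sex"] == "male").astype(float).where(cohort["sex"].notna())
        elif cov == "country":
            levels = sorted(cohort["country"].dropna().unique())
            for lev in levels[1:]:
                cols[f"country_{lev}"] = (cohort["country"] == lev).astype(float).where(
                    cohort["country"].notna())
        elif cov == "stage":
            stage = cohort[f"stage_{stage_system}"]
            for lev in (2, 3):
                cols[f"stage{stage_system}_{lev}"] = (stage == lev).astype(float).where(stage.notna())
        elif cov == "therapy":
            cols["therapy_new"] = (cohort["therapy"] == "new").astype(float).where(
                cohort["therapy"].notna())
        else:
            raise ValueError(f"unknown covariate {cov!r}")
    return pd.DataFrame(cols, index=cohort.index)


def _merged(g: GenotypeMatrix, cohort: pd.DataFrame) -> pd.DataFrame:
    return g.to_frame().merge(cohort, on="subject_id", how="inner", validate="one_to_one")


def snp_models(g: GenotypeMatrix, cohort: pd.DataFrame, panel: SnpPanel,
               covariates=RISK_COVARIATES, alpha: float = 0.05) -> pd.DataFrame:
    """Allelic and codominant logistic models per SNP, adjusted for
    age/sex/country.  Effects are per minor allele (allelic) or per
    heterozygous / rare-homozygous genotype vs the common homozygote.

    The returned frame carries ``attrs['bonferroni_threshold'] =
    alpha / (2 L)`` for the two-models-per-SNP scan.
    """
    df = _merged(g, cohort)
    if df["status"].nunique() < 2:
        raise ValueError("cohort must contain both cases and controls")
    y_all = (df["status"] == "case").astype(float)
    covs = build_covariates(df, covariates)
    rows: list[dict] = []
    for snp in panel:
        dose = df[snp.rsid].astype(float)
        minor = dose if snp.effect_allele_is_minor else 2.0 - dose
        base = pd.concat([pd.Series(1.0, index=df.index, name="const"), covs], axis=1)
        keep = minor.notna() & base.notna().all(axis=1)
        if minor[keep].nunique() < 2:
            warnings.warn(f"{snp.rsid}: monomorphic in analyzable subjects; skipped")
            continue
        # allelic (log-additive), dosage of the minor allele
        Xa = base[keep].copy()
        Xa["dosage"] = minor[keep]
        try:
            fit = fit_logistic(y_all[keep], Xa)
            rows += _wald_rows(fit.params, fit.cov, {"dosage": "allelic"}, fit.n,
                               rsid=snp.rsid)
        except (ValueError, ConvergenceError) as exc:
            warnings.warn(f"{snp.rsid}: allelic model skipped ({exc})")
        # codominant: het and rare-homozygous indicators
        Xc = base[keep].copy()
        Xc["het"] = (minor[keep] == 1).astype(float)
        n_hom = int((minor[keep] == 2).sum())
        terms = {"het": "codominant-het"}
        if n_hom > 0:
            Xc["hom"] = (minor[keep] == 2).astype(float)
            terms["hom"] = "codominant-hom"
        else:
            warnings.warn(f"{snp.rsid}: no rare homozygotes; codominant hom term dropped")
        try:
            fit = fit_logistic(y_all[keep], Xc)
            rows += _wald_rows(fit.params, fit.cov, terms, fit.n, rsid=snp.rsid)
        except (ValueError, ConvergenceError) as exc:
            warnings.warn(f"{snp.rsid}: codominant model skipped ({exc})")
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_threshold"] = bonferroni_threshold(len(panel), 2, alpha)
    return out


def _quintile_models(y_or_surv, data: pd.DataFrame, q: pd.Series, base: pd.DataFrame,
                     variant: str, fitter: str) -> list[dict]:
    rows: list[dict] = []
    if q.notna().sum() == 0:
        warnings.warn(f"{variant}: no quintile assignments; models skipped")
        return rows
    keep = q.notna() & base.notna().all(axis=1)
    if fitter == "cox":
        keep &= data["os_time"].notna() & data["vital"].notna()
    qk = q[keep]
    const = pd.Series(1.0, index=data.index, name="const")
    # categorical: indicators for quintiles 2-5 vs 1
    Xq = base[keep].copy()
    terms = {}
    for k in (2, 3, 4, 5):
        if (qk == k).sum() == 0:
            warnings.warn(f"{variant}: empty quintile {k}; contrast omitted")
            continue
        Xq[f"q{k}"] = (qk == k).astype(float)
        terms[f"q{k}"] = f"quintile-{k}"
    Xc = base[keep].copy()
    Xc["quintile"] = qk.astype(float)
    if fitter == "logistic":
        fit = fit_logistic(y_or_surv[keep], pd.concat([const[keep], Xq], axis=1))
        rows += _wald_rows(fit.params, fit.cov, terms, fit.n, variant=variant)
        fit = fit_logistic(y_or_surv[keep], pd.concat([const[keep], Xc], axis=1))
        rows += _wald_rows(fit.params, fit.cov, {"quintile": "quintile-continuous"},
                           fit.n, variant=variant)
    else:
        time = data.loc[keep, "os_time"].astype(float)
        event = (data.loc[keep, "vital"] == "deceased").astype(float)
        fit = fit_cox(time, event, Xq)
        rows += _wald_rows(fit.params, fit.cov, terms, fit.n, variant=variant)
        fit = fit_cox(time, event, Xc)
        rows += _wald_rows(fit.params, fit.cov, {"quintile": "quintile-continuous"},
                           fit.n, variant=variant)
    return rows


def score_risk_models(scores: CohortScores, cohort: pd.DataFrame,
                      covariates=RISK_COVARIATES) -> pd.DataFrame:
    """Quintile-categorical and quintile-trend logistic models for every score
    variant (un/weighted x raw/scaled), adjusted for age/sex/country."""
    df = scores.scores.merge(cohort, on="subject_id", how="inner", validate="one_to_one")
    y = (df["status"] == "case").astype(float)
    base = build_covariates(df, covariates)
    rows: list[dict] = []
    for variant in VARIANTS:
        rows += _quintile_models(y, df, df[f"q_{variant}"], base, variant, "logistic")
    return pd.DataFrame(rows)


def os_endpoint(cohort: pd.DataFrame) -> pd.DataFrame:
    """(time, event) vectors for overall survival among cases.

    event = 1 for deceased, 0 for alive at last follow-up; cases missing vital
    status or follow-up time are excluded (logged)."""
    cases = cohort[cohort["status"] == "case"]
    ok = cases["vital"].notna() & cases["os_time"].notna()
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("os_endpoint: %d case(s) without vital status/follow-up excluded", n_dropped)
    sub = cases[ok]
    bad = sub["os_time"] <= 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} case(s) with nonpositive follow-up dropped")
        sub = sub[~bad]
    return pd.DataFrame({
        "subject_id": sub["subject_id"],
        "time": sub["os_time"].astype(float),
        "event": (sub["vital"] == "deceased").astype(float),
    })


def _survival_frame(df: pd.DataFrame, stage_system: str) -> pd.DataFrame:
    keep = _survival_complete(df, stage_system)
    sub = df[keep]
    if (sub["vital"] == "deceased").sum() < 2:
        raise ValueError("fewer than 2 events in the complete-data survival stratum")
    return sub


def snp_survival_models(g: GenotypeMatrix, cohort: pd.DataFrame, panel: SnpPanel,
                        stage_system: str = "ds",
                        covariates=SURVIVAL_COVARIATES, ties: str = "breslow") -> pd.DataFrame:
    """Per-SNP allelic/codominant Cox models on overall survival among cases
    with complete stage (chosen system), therapy and follow-up."""
    df = _survival_frame(_merged(g, cohort), stage_system)
    covs = build_covariates(df, covariates, stage_system)
    time = df["os_time"].astype(float)
    event = (df["vital"] == "deceased").astype(float)
    rows: list[dict] = []
    for snp in panel:
        dose = df[snp.rsid].astype(float)
        minor = dose if snp.effect_allele_is_minor else 2.0 - dose
        keep = minor.notna() & covs.notna().all(axis=1)
        if minor[keep].nunique() < 2:
            warnings.warn(f"{snp.rsid}: monomorphic in survival stratum; skipped")
            continue
        Xa = covs[keep].copy()
        Xa["dosage"] = minor[keep]
        try:
            fit = fit_cox(time[keep], event[keep], Xa, ties=ties)
            rows += _wald_rows(fit.params, fit.cov, {"dosage": "allelic"}, fit.n,
                               rsid=snp.rsid)
        except (ValueError, ConvergenceError) as exc:
            warnings.warn(f"{snp.rsid}: allelic survival model skipped ({exc})")
        Xc = covs[keep].copy()
        Xc["het"] = (minor[keep] == 1).astype(float)
        terms = {"het": "codominant-het"}
        if int((minor[keep] == 2).sum()) > 0:
            Xc["hom"] = (minor[keep] == 2).astype(float)
            terms["hom"] = "codominant-hom"
        else:
            warnings.warn(f"{snp.rsid}: no rare homozygotes in survival stratum; hom dropped")
        try:
            fit = fit_cox(time[keep], event[keep], Xc, ties=ties)
            rows += _wald_rows(fit.params, fit.cov, terms, fit.n, rsid=snp.rsid)
        except (ValueError, ConvergenceError) as exc:
            warnings.warn(f"{snp.rsid}: codominant survival model skipped ({exc})")
    out = pd.DataFrame(rows)
    out.attrs["stage_system"] = stage_system
    return out


def score_survival_models(scores: CohortScores, cohort: pd.DataFrame,
                          stage_system: str = "ds",
                          covariates=SURVIVAL_COVARIATES) -> pd.DataFrame:
    """Score-quintile Cox models (categorical and trend) under DS or ISS
    stage adjustment."""
    df = scores.scores.merge(cohort, on="subject_id", how="inner", validate="one_to_one")
    df = _survival_frame(df, stage_system)
    base = build_covariates(df, covariates, stage_system)
    rows: list[dict] = []
    for variant in VARIANTS:
        rows += _quintile_models(None, df, df[f"q_{variant}"], base, variant, "cox")
    out = pd.DataFrame(rows)
    out.attrs["stage_system"] = stage_system
    return out
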