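"""Synthetic case-control + survival cohorts with the causal structure the
analysis assumes.

The generative model, per subject i with effect-allele dosages c_ij:

* genotypes: c_ij ~ Binomial(2, f_j) independently across SNPs and subjects
  (Hardy-Weinberg, no LD -- the panel SNPs sit on distinct chromosomes);
* telomere length (bp): TL_i = baseline + sum_j c_ij w_j + eps_i with
  eps ~ N(0, sigma^2) and sigma^2 chosen from the *realized* score variance so
  the weighted score explains ``target_score_r2`` of TL variance (default
  2.28%, the published panel-wide estimate);
* case status: logistic liability on TL in kb (theta_risk = log-odds per kb),
  optional covariate terms, with the intercept root-solved so the expected
  case fraction matches n_cases/(n_cases + n_controls);
* survival (cases): Weibull proportional hazards with log-hazard
  gamma_os * TL_kb (centered) + stage and therapy terms, independent
  exponential censoring plus an administrative cap;
* missingness: each genotype call independently missing at rate
  ``missing_rate`` (default 3.7%, matching a 96.3% mean call rate).

Covariate margins (sex, age, country, stage availability, follow-up
availability) default to the published study's Table-1-style margins; their
*effects* on risk default to zero, so confounding is opt-in.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from . import published
from .io import GenotypeMatrix
from .panel import SnpPanel, builtin_panel, load_weights
from .score import weighted_score

__all__ = ["SimConfig", "SimStudy", "default_panel_with_synthetic_weights",
           "simulate_genotypes", "simulate_ltl", "simulate_status",
           "simulate_survival", "inject_missing", "simulate_study"]


def default_panel_with_synthetic_weights() -> SnpPanel:
    """Built-in panel carrying the bundled SYNTHETIC bp weights (stand-ins
    with realistic magnitudes, not published estimates)."""
    from importlib.resources import files

    path = files("teloscore_mr.data") / "synthetic_weights.yaml"
    return builtin_panel(load_weights(path))


@dataclass
class SimConfig:
    """Generator settings; defaults emulate the published study's margins."""

    n_cases: int = 2407
    n_controls: int = 1741
    panel: SnpPanel = field(default_factory=default_panel_with_synthetic_weights)
    target_score_r2: float = 0.0228
    ltl_baseline_bp: float = 5500.0
    theta_risk: float = 1.175        # log-odds of MM per kb of TL
    gamma_os: float = -0.44          # log-hazard per kb of TL
    pleiotropy: Mapping[str, float] = field(default_factory=dict)  # rsid -> direct log-odds per allele
    age_beta: float = 0.0            # log-odds per year (confounding opt-in)
    sex_beta: float = 0.0
    stage_loghr: tuple[float, float, float] = (0.0, 0.35, 0.70)
    therapy_new_loghr: float = -0.40
    missing_rate: float = 0.037
    weibull_shape: float = 1.2
    os_scale_months: float = 128.0   # Weibull scale at stage 1 / old therapy / mean TL
    censor_mean_months: float = 45.0
    admin_cap_months: float = 120.0
    p_followup: float = 1273 / 2407
    p_stage_ds: float = 1235 / 2407
    p_iss_given_ds: float = 984 / 1235
    p_iss_given_no_ds: float = 38 / 1172
    p_therapy: float = 0.90
    stage_correlation: float = 0.6

    def __post_init__(self) -> None:
        if not 0 < self.target_score_r2 < 1:
            raise ValueError("target_score_r2 must lie in (0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if min(self.n_cases, self.n_controls) < 1:
            raise ValueError("need at least one case and one control")

    @property
    def case_fraction(self) -> float:
        return self.n_cases / (self.n_cases + self.n_controls)


@dataclass
class SimStudy:
    genotypes: GenotypeMatrix            # with injected missingness
    genotypes_complete: GenotypeMatrix   # pre-missingness truth
    cohort: pd.DataFrame
    ltl_bp: np.ndarray
    truth: dict


def simulate_genotypes(cfg: SimConfig, rng: np.random.Generator,
                       n: int | None = None) -> GenotypeMatrix:
    """Independent HWE genotypes: dosage ~ Binomial(2, effect-allele freq)."""
    n = (cfg.n_cases + cfg.n_controls) if n is None else n
    freqs = cfg.panel.effect_allele_freqs
    dosage = rng.binomial(2, freqs, size=(n, len(freqs))).astype(float)
    ids = np.array([f"S{i:06d}" for i in range(1, n + 1)], dtype=object)
    return GenotypeMatrix(ids, dosage, cfg.panel.rsids)


def simulate_ltl(g: GenotypeMatrix, cfg: SimConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """TL_i = baseline + weighted score + Gaussian noise scaled so the score
    explains ``target_score_r2`` of the realized TL variance."""
    score = np.asarray(weighted_score(g.dosage, cfg.panel))
    if np.isnan(score).any():
        raise ValueError("simulate_ltl requires complete genotypes")
    var_s = float(np.var(score))
    if var_s == 0:
        raise ValueError("degenerate weights: score variance is zero")
    sigma2 = var_s * (1.0 / cfg.target_score_r2 - 1.0)
    return cfg.ltl_baseline_bp + score + rng.normal(0.0, np.sqrt(sigma2), size=len(score))


def _liability(tl_bp: np.ndarray, covariates: pd.DataFrame | None,
               cfg: SimConfig, dosage: np.ndarray | None = None) -> np.ndarray:
    eta = cfg.theta_risk * (tl_bp - tl_bp.mean()) / 1000.0
    if covariates is not None:
        if cfg.age_beta and "age" in covariates:
            eta = eta + cfg.age_beta * (covariates["age"] - covariates["age"].mean()).to_numpy()
        if cfg.sex_beta and "sex" in covariates:
            eta = eta + cfg.sex_beta * (covariates["sex"] == "male").to_numpy()
    if cfg.pleiotropy and dosage is not None:
        for rsid, beta in cfg.pleiotropy.items():
            j = cfg.panel.rsids.index(rsid)
            eta = eta + beta * dosage[:, j]
    return eta


def simulate_status(tl_bp: np.ndarray, covariates: pd.DataFrame | None,
                    cfg: SimConfig, rng: np.random.Generator,
                    dosage: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Draw case/control labels from the logistic liability; returns the
    labels and the root-solved intercept."""
    if not 0 < cfg.case_fraction < 1:
        raise ValueError("case fraction must lie strictly in (0, 1)")
    eta = _liability(tl_bp, covariates, cfg, dosage)
    alpha0 = brentq(lambda a: expit(a + eta).mean() - cfg.case_fraction, -40.0, 40.0)
    labels = rng.random(len(eta)) < expit(alpha0 + eta)
    return labels, float(alpha0)


def _correlated_stages(n: int, cfg: SimConfig, rng: np.random.Generator):
    """Latent-severity model: DS and ISS stages are cuts of correlated
    normals at the published stage-distribution quantiles."""
    from scipy.stats import norm

    m = published.study_margins()
    z = rng.normal(size=n)
    rho = cfg.stage_correlation
    z2 = rho * z + np.sqrt(1 - rho**2) * rng.normal(size=n)

    def cut(latent, counts):
        total = sum(counts.values())
        q1 = counts[1] / total
        q2 = (counts[1] + counts[2]) / total
        c1, c2 = norm.ppf(q1), norm.ppf(q2)
        return 1 + (latent > c1).astype(int) + (latent > c2).astype(int)

    return cut(z, m["stage_ds_counts"]), cut(z2, m["stage_iss_counts"])


def simulate_survival(tl_bp: np.ndarray, stage_ds: np.ndarray, therapy_new: np.ndarray,
                      cfg: SimConfig, rng: np.random.Generator):
    """Weibull proportional-hazards event times with exponential + administrative
    censoring.  Returns (os_time months, deceased flags)."""
    eta = (
        cfg.gamma_os * (tl_bp - tl_bp.mean()) / 1000.0
        + np.asarray(cfg.stage_loghr)[np.asarray(stage_ds, int) - 1]
        + cfg.therapy_new_loghr * np.asarray(therapy_new, float)
    )
    u = rng.random(len(eta))
    t_event = cfg.os_scale_months * (-np.log(u) * np.exp(-eta)) ** (1.0 / cfg.weibull_shape)
    c = np.minimum(rng.exponential(cfg.censor_mean_months, size=len(eta)),
                   cfg.admin_cap_months)
    os_time = np.minimum(t_event, c)
    deceased = t_event <= c
    # follow-up times of exactly zero are not observable
    os_time = np.maximum(os_time, 1e-3)
    return os_time, deceased


def inject_missing(g: GenotypeMatrix, cfg: SimConfig,
                   rng: np.random.Generator) -> GenotypeMatrix:
    """Set each call independently missing with probability ``missing_rate``
    (missing completely at random)."""
    if cfg.missing_rate == 0:
        return GenotypeMatrix(g.subject_ids, g.dosage.copy(), g.rsids)
    mask = rng.random(g.dosage.shape) < cfg.missing_rate
    dosage = g.dosage.copy()
    dosage[mask] = np.nan
    return GenotypeMatrix(g.subject_ids, dosage, g.rsids)


def _covariate_table(n: int, status: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    m = published.study_margins()
    cc = published.country_counts()
    probs = (cc["cases"] + cc["controls"]) / (cc["cases"] + cc["controls"]).sum()
    country = rng.choice(cc["country"], size=n, p=probs)
    sex = np.where(rng.random(n) < 0.53, "male", "female")
    # between the case and control medians; single distribution (no default
    # age effect on liability, so margins coincide)
    age = np.clip(rng.normal(57.0, 11.0, size=n), 25, 92)
    return pd.DataFrame({"sex": sex, "age": np.round(age, 1), "country": country})


def simulate_study(cfg: SimConfig | None = None, seed: int = 0) -> SimStudy:
    """Full synthetic study: genotypes (with missingness), phenotype table and
    a truth record of every generative parameter.

    Deterministic given (cfg, seed); all randomness flows through
    ``numpy.random.default_rng(seed)``.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(seed)
    n = cfg.n_cases + cfg.n_controls

    g_complete = simulate_genotypes(cfg, rng, n)
    tl = simulate_ltl(g_complete, cfg, rng)
    covars = _covariate_table(n, None, rng)
    is_case, alpha0 = simulate_status(tl, covars, cfg, rng, g_complete.dosage)

    cohort = pd.DataFrame({
        "subject_id": g_complete.subject_ids,
        "status": np.where(is_case, "case", "control"),
        "sex": covars["sex"],
        "age": covars["age"],
        "country": covars["country"],
    })
    cohort["stage_ds"] = pd.array([pd.NA] * n, dtype="Int64")
    cohort["stage_iss"] = pd.array([pd.NA] * n, dtype="Int64")
    cohort["therapy"] = pd.Series([pd.NA] * n, dtype="string")
    cohort["vital"] = pd.Series([pd.NA] * n, dtype="string")
    cohort["os_time"] = np.nan

    case_idx = np.flatnonzero(is_case)
    n_case = len(case_idx)
    if n_case:
        ds, iss = _correlated_stages(n_case, cfg, rng)
        therapy_new = rng.random(n_case) < 0.5
        os_time, deceased = simulate_survival(tl[case_idx], ds, therapy_new, cfg, rng)
        # availability masks (MCAR), matching the published availability margins
        has_ds = rng.random(n_case) < cfg.p_stage_ds
        has_iss = np.where(has_ds,
                           rng.random(n_case) < cfg.p_iss_given_ds,
                           rng.random(n_case) < cfg.p_iss_given_no_ds)
        has_therapy = rng.random(n_case) < cfg.p_therapy
        has_fu = rng.random(n_case) < cfg.p_followup
        cohort.loc[case_idx[has_ds], "stage_ds"] = ds[has_ds]
        cohort.loc[case_idx[has_iss], "stage_iss"] = iss[has_iss]
        cohort.loc[case_idx[has_therapy], "therapy"] = np.where(
            therapy_new[has_therapy], "new", "old")
        cohort.loc[case_idx[has_fu], "vital"] = np.where(
            deceased[has_fu], "deceased", "alive")
        cohort.loc[case_idx[has_fu], "os_time"] = np.round(os_time[has_fu], 2)

    g_missing = inject_missing(g_complete, cfg, rng)

    score = np.asarray(weighted_score(g_complete.dosage, cfg.panel))
    resid = tl - score
    realized_r2 = float(np.var(score) / np.var(tl))
    truth = {
        "seed": seed,
        "n_cases_target": cfg.n_cases, "n_controls_target": cfg.n_controls,
        "n_cases_realized": int(is_case.sum()),
        "n_controls_realized": int(n - is_case.sum()),
        "theta_risk": cfg.theta_risk, "gamma_os": cfg.gamma_os,
        "target_score_r2": cfg.target_score_r2, "realized_score_r2": realized_r2,
        "ltl_baseline_bp": cfg.ltl_baseline_bp,
        "ltl_noise_sd_bp": float(np.std(resid)),
        "alpha0": alpha0,
        "missing_rate": cfg.missing_rate,
        "weights_bp": dict(zip(cfg.panel.rsids, cfg.panel.weights_bp.tolist())),
        "stage_loghr": list(cfg.stage_loghr),
        "therapy_new_loghr": cfg.therapy_new_loghr,
        "weibull_shape": cfg.weibull_shape,
        "os_scale_months": cfg.os_scale_months,
        "censor_mean_months": cfg.censor_mean_months,
        "admin_cap_months": cfg.admin_cap_months,
        "pleiotropy": dict(cfg.pleiotropy),
    }
    return SimStudy(g_missing, g_complete, cohort, tl, truth)
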