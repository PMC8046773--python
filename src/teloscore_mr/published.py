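"""Published summary results from the European multiple-myeloma case-control
consortium study (2407 MM cases, 1741 controls; eight countries) whose
analysis this package reproduces on synthetic data.

These printed tables serve three purposes: bookkeeping cross-checks of the
pipeline's stratum accounting, 2x2 oracle inputs for the logistic fitter, and
outcome-side summary statistics (allelic ORs/HRs with 95% CIs, reported per
minor allele) for summary-statistic Mendelian randomization.  Exposure-side
per-allele bp effects are NOT published in the main tables and must be
supplied via a weight config.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "country_counts", "risk_quintile_counts", "snp_risk_allelic",
    "snp_os_allelic_ds", "study_margins",
]


def country_counts() -> pd.DataFrame:
    """Cases/controls per country of origin (columns sum to 2407 / 1741)."""
    rows = [
        ("Denmark", 277, 494), ("France", 330, 176), ("Hungary", 83, 75),
        ("Israel", 89, 72), ("Italy", 231, 227), ("Poland", 1043, 262),
        ("Portugal", 126, 120), ("Spain", 228, 315),
    ]
    return pd.DataFrame(rows, columns=["country", "cases", "controls"])


def risk_quintile_counts() -> dict[str, pd.DataFrame]:
    """Control/case counts per score quintile for the four score variants of
    the published risk analysis (raw variants: 100%-call-rate stratum,
    1207 controls / 1769 cases; scaled variants: all 4148 subjects)."""
    blocks = {
        "unweighted": ([342, 250, 226, 180, 209], [438, 344, 327, 293, 367]),
        "unweighted_scaled": ([478, 356, 338, 252, 317], [522, 449, 448, 440, 548]),
        "weighted": ([244, 248, 234, 241, 240], [293, 315, 363, 387, 411]),
        "weighted_scaled": ([356, 342, 348, 348, 347], [361, 386, 493, 546, 621]),
    }
    return {
        name: pd.DataFrame({"quintile": [1, 2, 3, 4, 5], "controls": ctl, "cases": cas})
        for name, (ctl, cas) in blocks.items()
    }


def snp_risk_allelic() -> pd.DataFrame:
    """Published allelic (log-additive) odds ratios for MM risk with 95% CIs,
    per minor allele, adjusted for age, sex and country."""
    rows = [
        ("rs11125529", 0.99, 0.86, 1.16), ("rs6772228", 0.81, 0.62, 1.07),
        ("rs10936599", 0.79, 0.70, 0.90), ("rs7675998", 0.94, 0.83, 1.06),
        ("rs2736100", 1.07, 0.96, 1.18), ("rs9420907", 1.17, 1.03, 1.35),
        ("rs3027234", 0.89, 0.79, 1.00), ("rs8105767", 1.14, 1.02, 1.27),
        ("rs412658", 1.01, 0.91, 1.12), ("rs6028466", 1.23, 1.08, 1.50),
        ("rs755017", 1.10, 0.93, 1.29),
    ]
    df = pd.DataFrame(rows, columns=["rsid", "effect", "ci_low", "ci_high"])
    df["model"] = "allelic"
    return df


def snp_os_allelic_ds() -> pd.DataFrame:
    """Published allelic hazard ratios for MM overall survival with 95% CIs,
    per minor allele, adjusted for age, sex, country, Durie-Salmon stage and
    first-line therapy."""
    rows = [
        ("rs11125529", 0.90, 0.71, 1.13), ("rs6772228", 1.30, 0.89, 1.89),
        ("rs10936599", 1.20, 1.00, 1.43), ("rs7675998", 1.18, 0.98, 1.42),
        ("rs2736100", 1.05, 0.89, 1.22), ("rs9420907", 0.96, 0.78, 1.17),
        ("rs3027234", 1.03, 0.86, 1.23), ("rs8105767", 1.01, 0.85, 1.19),
        ("rs412658", 0.98, 0.83, 1.15), ("rs6028466", 1.15, 0.86, 1.52),
        ("rs755017", 0.86, 0.67, 1.09),
    ]
    df = pd.DataFrame(rows, columns=["rsid", "effect", "ci_low", "ci_high"])
    df["model"] = "allelic"
    return df


def study_margins() -> dict:
    """Marginal characteristics of the published study population, used as the
    synthetic-cohort generator's default targets."""
    return {
        "n_cases": 2407,
        "n_controls": 1741,
        "male_fraction": {"case": 0.5326, "control": 0.5192},
        "median_age": {"case": 61.47, "control": 52.59},
        "age_iqr": {"case": (55, 68), "control": (42, 65)},
        "stage_ds_counts": {1: 179, 2: 299, 3: 757},       # 1235 cases staged
        "stage_iss_counts": {1: 324, 2: 332, 3: 366},      # 1022 cases staged
        "n_both_staged": 984,
        "vital_counts": {"alive": 902, "deceased": 371},   # 1273 with follow-up
        "complete_call_rate_stratum": {"case": 1769, "control": 1207},
        "mean_call_rate": 0.963,
        "score_r2_ltl": 0.0228,
    }
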