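"""End-to-end orchestration: data -> QC -> scores -> associations -> MR.

``run`` executes the enabled stages in order on either simulated or loaded
data, writes every result table as tab-delimited text plus a JSON manifest
(config echo, per-stage subject counts, warnings, output checksums), and
stamps the Bonferroni threshold alpha/(2L) used for the per-SNP scan.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, assoc, mr, qc, score
from .io import GenotypeMatrix, load_cohort, load_genotypes, write_cohort, write_genotypes
from .panel import SnpPanel, builtin_panel, load_weights
from .simulate import SimConfig, simulate_study

logger = logging.getLogger(__name__)

ALL_ANALYSES = ("qc", "risk", "survival-ds", "survival-iss", "mr-risk", "mr-survival")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("run config must be a YAML mapping")
    return cfg


def _panel_from_config(config: dict) -> SnpPanel:
    weights = config.get("weights")
    if isinstance(weights, str):
        weights = load_weights(weights)
    return builtin_panel(weights)


def _mr_result_table(report: dict) -> pd.DataFrame:
    rows = [r.to_dict() for r in report["results"].values()]
    df = pd.DataFrame(rows)
    df["i2_gx_outcome_weighted"] = report["i2_gx_outcome_weighted"]
    return df


def run(config: dict, out_dir, seed: int | None = None) -> dict:
    """Execute the configured analyses; returns the manifest dict.

    ``config`` keys: ``simulate`` (SimConfig overrides) or ``inputs``
    (``genotypes``/``cohort``/``format`` paths), optional ``weights`` (path or
    rsID mapping), ``analyses`` (subset of qc/risk/survival-ds/survival-iss/
    mr-risk/mr-survival), ``alpha`` (default 0.05), ``seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    analyses = tuple(config.get("analyses", ALL_ANALYSES))
    unknown = set(analyses) - set(ALL_ANALYSES)
    if unknown:
        raise ValueError(f"unknown analyses: {sorted(unknown)}")
    if not analyses:
        raise ValueError("at least one analysis must be enabled")
    alpha = float(config.get("alpha", 0.05))
    seed = int(config.get("seed", 0) if seed is None else seed)

    manifest: dict = {"version": __version__, "config": {k: v for k, v in config.items()},
                      "seed": seed, "n_used": {}, "warnings": [], "outputs": {}}
    outputs: list[Path] = []

    def emit(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=False, na_rep="NA")
        outputs.append(path)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        if "simulate" in config:
            sim_kwargs = dict(config["simulate"] or {})
            panel = _panel_from_config(config) if "weights" in config else None
            if panel is not None and panel.weights_configured:
                sim_kwargs["panel"] = panel
            sim_cfg = SimConfig(**sim_kwargs)
            panel = sim_cfg.panel
            study = simulate_study(sim_cfg, seed=seed)
            g, cohort = study.genotypes, study.cohort
            write_genotypes(g, out / "genotypes.tsv")
            write_cohort(cohort, out / "cohort.tsv")
            (out / "truth.json").write_text(json.dumps(study.truth, indent=2))
            outputs += [out / "genotypes.tsv", out / "cohort.tsv", out / "truth.json"]
        elif "inputs" in config:
            panel = _panel_from_config(config)
            inputs = config["inputs"]
            g = load_genotypes(inputs["genotypes"], panel, inputs.get("format"))
            cohort = load_cohort(inputs["cohort"])
        else:
            raise ValueError("config needs a 'simulate' or an 'inputs' block")

        threshold = assoc.bonferroni_threshold(len(panel), 2, alpha)
        manifest["bonferroni_threshold"] = threshold
        manifest["n_used"]["total_subjects"] = int(g.n)

        if "qc" in analyses:
            report = qc.qc_report(g, cohort)
            emit(report.snp_table(), "qc_snps.tsv")
            (out / "qc.json").write_text(report.to_json())
            outputs.append(out / "qc.json")
            manifest["n_used"]["complete_call_rate_stratum"] = int(len(report.complete_subjects))
            manifest["mean_call_rate"] = report.mean_call_rate

        snp_risk = None
        if "risk" in analyses:
            risk_scores = score.score_cohort(g, panel, "risk", cohort)
            emit(risk_scores.scores, "scores_risk.tsv")
            manifest["quintile_cuts_risk"] = {
                v: list(c.cutpoints) for v, c in risk_scores.cuts.items()}
            snp_risk = assoc.snp_models(g, cohort, panel, alpha=alpha)
            snp_risk["significant"] = snp_risk["p"] < threshold
            emit(snp_risk, "snp_risk.tsv")
            score_risk = assoc.score_risk_models(risk_scores, cohort)
            emit(score_risk, "score_risk.tsv")
            manifest["n_used"]["risk"] = int(snp_risk["n_used"].max())

        snp_surv: dict[str, pd.DataFrame] = {}
        for system in ("ds", "iss"):
            if f"survival-{system}" not in analyses:
                continue
            surv_scores = score.score_cohort(g, panel, "survival", cohort, stage_system=system)
            emit(surv_scores.scores, f"scores_survival_{system}.tsv")
            snp_surv[system] = assoc.snp_survival_models(g, cohort, panel, stage_system=system)
            emit(snp_surv[system], f"snp_survival_{system}.tsv")
            score_surv = assoc.score_survival_models(surv_scores, cohort, stage_system=system)
            emit(score_surv, f"score_survival_{system}.tsv")
            manifest["n_used"][f"survival_{system}"] = int(snp_surv[system]["n_used"].max())

        if "mr-risk" in analyses:
            if snp_risk is None:
                raise ValueError("mr-risk requires the risk analysis to be enabled")
            summary = mr.summary_from_tables(snp_risk, panel)
            report = mr.mr_report(summary)
            emit(summary.to_frame(), "mr_risk_inputs.tsv")
            emit(_mr_result_table(report), "mr_risk_results.tsv")
            emit(report["scatter"], "mr_risk_scatter.tsv")
            emit(report["forest"], "mr_risk_forest.tsv")
        if "mr-survival" in analyses:
            system = "ds" if "ds" in snp_surv else "iss"
            if system not in snp_surv:
                raise ValueError("mr-survival requires a survival analysis to be enabled")
            summary = mr.summary_from_tables(snp_surv[system], panel)
            report = mr.mr_report(summary)
            emit(summary.to_frame(), "mr_survival_inputs.tsv")
            emit(_mr_result_table(report), "mr_survival_results.tsv")
            emit(report["scatter"], "mr_survival_scatter.tsv")
            emit(report["forest"], "mr_survival_forest.tsv")

        manifest["warnings"] = sorted({str(w.message) for w in caught})

    manifest["outputs"] = {p.name: _checksum(p) for p in outputs}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
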