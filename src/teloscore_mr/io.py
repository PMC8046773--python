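"""Genotype and phenotype file handling.

Genotypes arrive either as delimited text (one row per subject, one column per
rsID, cells as two-character allele pairs like ``CT`` or as integer dosages)
or as VCF.  All calls are oriented to the panel's *long-telomere* allele, so
the in-memory dosage is the per-subject count of effect alleles in {0, 1, 2},
NaN when missing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import SnpPanel

__all__ = [
    "GenotypeMatrix",
    "load_genotypes",
    "write_genotypes",
    "load_cohort",
    "write_cohort",
    "validate_cohort",
]

logger = logging.getLogger(__name__)

MISSING_TOKENS = {"", "NA", "./.", ".|.", "--", ".", "NN"}

COHORT_COLUMNS = [
    "subject_id", "status", "sex", "age", "country",
    "stage_ds", "stage_iss", "therapy", "vital", "os_time",
]


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs matrix of effect-allele (long-telomere) dosages.

    ``dosage`` is float with entries in {0, 1, 2} or NaN for missing calls;
    columns follow ``rsids`` (panel order).
    """

    subject_ids: np.ndarray
    dosage: np.ndarray
    rsids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.rsids = tuple(self.rsids)
        if self.dosage.shape != (len(self.subject_ids), len(self.rsids)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.rsids)} SNPs"
            )
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosage entries must be 0, 1, 2 or NaN")

    @property
    def n(self) -> int:
        return len(self.subject_ids)

    @property
    def n_snps(self) -> int:
        return len(self.rsids)

    @property
    def complete_mask(self) -> np.ndarray:
        """Subjects with a 100% call rate (no missing call at any SNP)."""
        return ~np.isnan(self.dosage).any(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.dosage, columns=list(self.rsids))
        df.insert(0, "subject_id", self.subject_ids)
        return df

    def subset_subjects(self, mask_or_ids) -> "GenotypeMatrix":
        if np.asarray(mask_or_ids).dtype == bool:
            idx = np.flatnonzero(mask_or_ids)
        else:
            pos = {s: i for i, s in enumerate(self.subject_ids)}
            idx = np.array([pos[s] for s in mask_or_ids])
        return GenotypeMatrix(self.subject_ids[idx], self.dosage[idx], self.rsids)


def _read_delimited(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", dtype=str,
                       keep_default_na=False)


def _parse_genotype_column(cells: pd.Series, snp) -> tuple[np.ndarray, int]:
    """Parse one rsID column: dosage ints and/or allele pairs, auto-detected
    per cell.  Returns (effect-allele dosage, #inconsistent calls)."""
    valid = {snp.major_allele, snp.minor_allele}
    out = np.full(len(cells), np.nan)
    bad = 0
    for i, raw in enumerate(cells):
        cell = raw.strip().upper()
        if cell in MISSING_TOKENS:
            continue
        if cell in {"0", "1", "2"}:
            out[i] = float(cell)
            continue
        pair = cell.replace("/", "").replace("|", "")
        if len(pair) == 2 and set(pair) <= valid:
            out[i] = pair.count(snp.effect_allele)
        else:
            bad += 1
            warnings.warn(
                f"{snp.rsid}: call {raw!r} inconsistent with alleles "
                f"{snp.major_allele}/{snp.minor_allele}; set to missing",
                stacklevel=3,
            )
    return out, bad


def _load_genotype_table(path, panel: SnpPanel) -> GenotypeMatrix:
    df = _read_delimited(path)
    if df.columns[0].lower() in {"subject_id", "id", "sample"}:
        subject_ids = df.iloc[:, 0].to_numpy(dtype=object)
        geno_cols = list(df.columns[1:])
    else:
        raise ValueError("first column must be the subject identifier (subject_id)")
    unknown = [c for c in geno_cols if c not in panel]
    if unknown:
        raise ValueError(f"unknown rsID column(s) not in panel: {unknown}")
    absent = [r for r in panel.rsids if r not in geno_cols]
    if absent:
        raise ValueError(f"panel rsID(s) missing from {path}: {absent}")
    dosage = np.empty((len(df), len(panel)))
    for j, snp in enumerate(panel):
        col, bad = _parse_genotype_column(df[snp.rsid], snp)
        n_called = int((~pd.Series(df[snp.rsid]).str.strip().str.upper().isin(MISSING_TOKENS)).sum())
        if n_called and bad / n_called > 0.5:
            raise ValueError(
                f"{snp.rsid}: {bad}/{n_called} calls inconsistent with panel alleles "
                "(likely strand or allele-label mismatch)"
            )
        dosage[:, j] = col
    return GenotypeMatrix(subject_ids, dosage, panel.rsids)


def _load_genotype_vcf(path, panel: SnpPanel) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subject_ids = np.array(vcf.samples, dtype=object)
    dosage = np.full((len(subject_ids), len(panel)), np.nan)
    seen = set()
    for variant in vcf:
        rsid = variant.ID
        if rsid is None or rsid not in panel:
            continue
        snp = panel[rsid]
        if len(variant.ALT) != 1:
            raise ValueError(f"{rsid}: multi-allelic record; panel is strictly biallelic")
        ref, alt = variant.REF.upper(), variant.ALT[0].upper()
        if {ref, alt} != {snp.major_allele, snp.minor_allele}:
            raise ValueError(
                f"{rsid}: VCF alleles {ref}/{alt} do not match panel "
                f"{snp.major_allele}/{snp.minor_allele}"
            )
        j = panel.rsids.index(rsid)
        # genotype array: columns are allele indices plus a phasing flag
        gts = np.asarray(variant.genotype.array())[:, :2]
        called = (gts >= 0).all(axis=1)
        alt_count = (gts == 1).sum(axis=1).astype(float)
        eff = alt_count if alt == snp.effect_allele else 2.0 - alt_count
        dosage[called, j] = eff[called]
        seen.add(rsid)
    absent = [r for r in panel.rsids if r not in seen]
    if absent:
        raise ValueError(f"panel rsID(s) not found in VCF {path}: {absent}")
    return GenotypeMatrix(subject_ids, dosage, panel.rsids)


def load_genotypes(path, panel: SnpPanel, format: str | None = None) -> GenotypeMatrix:
    """Load genotypes from delimited text or VCF, oriented to effect alleles.

    ``format`` is ``"table"`` or ``"vcf"``; by default inferred from the file
    extension (``.vcf``/``.vcf.gz`` -> VCF).
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.name.endswith((".vcf", ".vcf.gz")) else "table"
    if format == "vcf":
        return _load_genotype_vcf(path, panel)
    if format == "table":
        return _load_genotype_table(path, panel)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(g: GenotypeMatrix, path) -> None:
    """Write dosages as tab-delimited text (missing -> ``NA``); round-trips
    exactly through :func:`load_genotypes`."""
    df = g.to_frame()
    for c in g.rsids:
        df[c] = df[c].map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    df.to_csv(path, sep="\t", index=False)


_CATEGORICAL = {
    "status": {"case", "control"},
    "sex": {"male", "female"},
    "therapy": {"new", "old"},
    "vital": {"alive", "deceased"},
}


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Coerce a raw phenotype table to typed cohort columns.

    Unparseable cells become missing (logged); rows where exactly one of
    ``vital``/``os_time`` is present have both blanked to keep the pair
    consistent; nonpositive follow-up times are blanked with a warning.
    """
    if "subject_id" not in df.columns or "status" not in df.columns:
        raise ValueError("cohort table must contain 'subject_id' and 'status' columns")
    out = pd.DataFrame(index=df.index)
    out["subject_id"] = df["subject_id"].astype(str)
    n_bad = 0
    for col, levels in _CATEGORICAL.items():
        if col in df.columns:
            vals = df[col].astype(str).str.strip().str.lower()
            ok = vals.isin(levels)
            n_bad += int((~ok & ~vals.isin({"", "na", "nan", "none"})).sum())
            out[col] = vals.where(ok)
        else:
            out[col] = pd.Series(pd.NA, index=df.index, dtype="string")
    for col, lo in [("age", 0.0), ("os_time", 0.0)]:
        if col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            n_bad += int((vals.isna() & df[col].notna()
                          & ~df[col].astype(str).str.strip().str.lower().isin({"", "na", "nan"})).sum())
            bad_range = vals <= lo
            if col == "os_time" and bad_range.any():
                warnings.warn(f"{int(bad_range.sum())} nonpositive os_time value(s) set to missing")
            out[col] = vals.where(~bad_range.fillna(False))
        else:
            out[col] = np.nan
    for col in ("stage_ds", "stage_iss"):
        if col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            out[col] = vals.where(vals.isin([1, 2, 3])).astype("Int64")
        else:
            out[col] = pd.Series(pd.NA, index=df.index, dtype="Int64")
    out["country"] = (df["country"].astype(str).str.strip().replace({"": pd.NA, "nan": pd.NA, "NA": pd.NA})
                      if "country" in df.columns else pd.Series(pd.NA, index=df.index, dtype="string"))
    if out["status"].isna().any():
        raise ValueError("every subject needs a case/control status")
    # os_time present iff vital present
    mismatch = out["vital"].notna() ^ out["os_time"].notna()
    if mismatch.any():
        logger.info("blanking vital/os_time on %d subject(s) with only one of the pair",
                    int(mismatch.sum()))
        out.loc[mismatch, ["vital"]] = pd.NA
        out.loc[mismatch, "os_time"] = np.nan
    if n_bad:
        logger.info("cohort load: %d unparseable cell(s) set to missing", n_bad)
    return out[COHORT_COLUMNS]


def load_cohort(path) -> pd.DataFrame:
    """Read a delimited phenotype table (header must name cohort fields)."""
    return validate_cohort(_read_delimited(path))


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False, na_rep="NA")
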