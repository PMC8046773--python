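"""The 11-SNP telomere-length instrument panel.

Genome-wide association studies of leukocyte telomere length (LTL) identified
eleven independent biallelic SNPs that jointly explain about 2.28% of LTL
variability.  Counted per subject, the alleles associated with longer
telomeres form a genetic score ("teloscore") that proxies genetically
determined telomere length and serves as a Mendelian-randomization instrument.

The panel bundled here carries, per SNP: rsID, nearest gene, major/minor
alleles, the long-telomere (effect) allele, and the minor-allele frequency in
the study controls.  Per-allele effects on LTL in base pairs (the score
weights) are *configuration-supplied* -- published estimates live in GWAS
supplements and differ between sources -- via :func:`load_weights` or the
``weights`` argument of :func:`builtin_panel`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Mapping

import numpy as np
import yaml

__all__ = ["SnpRecord", "SnpPanel", "builtin_panel", "load_weights"]

_NUCLEOTIDES = frozenset("ACGT")


@dataclass(frozen=True)
class SnpRecord:
    """One biallelic SNP of the telomere-length panel.

    ``effect_allele`` is the allele associated with *longer* telomeres; it may
    be either the major or the minor allele.  ``weight_bp`` is the per-allele
    effect on LTL in base pairs (nonnegative by orientation), ``weight_se_bp``
    its standard error; both are optional until configured.
    """

    rsid: str
    gene: str
    major_allele: str
    minor_allele: str
    effect_allele: str
    maf: float
    weight_bp: float | None = None
    weight_se_bp: float | None = None

    def __post_init__(self) -> None:
        for a in (self.major_allele, self.minor_allele):
            if a not in _NUCLEOTIDES:
                raise ValueError(f"{self.rsid}: allele {a!r} is not a nucleotide")
        if self.major_allele == self.minor_allele:
            raise ValueError(f"{self.rsid}: major and minor alleles are identical")
        if self.effect_allele not in (self.major_allele, self.minor_allele):
            raise ValueError(
                f"{self.rsid}: effect allele {self.effect_allele!r} is not one of "
                f"{self.major_allele}/{self.minor_allele}"
            )
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"{self.rsid}: MAF {self.maf} outside (0, 0.5]")
        if self.weight_bp is not None and self.weight_bp < 0:
            raise ValueError(f"{self.rsid}: weight_bp must be nonnegative")
        if self.weight_se_bp is not None and self.weight_se_bp <= 0:
            raise ValueError(f"{self.rsid}: weight_se_bp must be positive")

    @property
    def other_allele(self) -> str:
        return self.minor_allele if self.effect_allele == self.major_allele else self.major_allele

    @property
    def effect_allele_is_minor(self) -> bool:
        return self.effect_allele == self.minor_allele

    @property
    def effect_allele_freq(self) -> float:
        """Population frequency of the long-telomere allele."""
        return self.maf if self.effect_allele_is_minor else 1.0 - self.maf


class SnpPanel:
    """Ordered, immutable collection of :class:`SnpRecord` with unique rsIDs."""

    def __init__(self, snps: Iterable[SnpRecord]):
        self.snps: tuple[SnpRecord, ...] = tuple(snps)
        if not self.snps:
            raise ValueError("panel must contain at least one SNP")
        rsids = [s.rsid for s in self.snps]
        if len(set(rsids)) != len(rsids):
            raise ValueError("duplicate rsIDs in panel")
        self._index = {s.rsid: i for i, s in enumerate(self.snps)}

    def __len__(self) -> int:
        return len(self.snps)

    def __iter__(self) -> Iterator[SnpRecord]:
        return iter(self.snps)

    def __getitem__(self, key: int | str) -> SnpRecord:
        if isinstance(key, str):
            return self.snps[self._index[key]]
        return self.snps[key]

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    @property
    def rsids(self) -> tuple[str, ...]:
        return tuple(s.rsid for s in self.snps)

    @property
    def weights_configured(self) -> bool:
        return all(s.weight_bp is not None for s in self.snps)

    @property
    def weights_bp(self) -> np.ndarray:
        """Per-allele bp effects, erroring when any SNP is unconfigured."""
        missing = [s.rsid for s in self.snps if s.weight_bp is None]
        if missing:
            raise ValueError(f"weights not configured for: {', '.join(missing)}")
        return np.array([s.weight_bp for s in self.snps], dtype=float)

    @property
    def weight_ses_bp(self) -> np.ndarray:
        missing = [s.rsid for s in self.snps if s.weight_se_bp is None]
        if missing:
            raise ValueError(f"weight SEs not configured for: {', '.join(missing)}")
        return np.array([s.weight_se_bp for s in self.snps], dtype=float)

    @property
    def effect_allele_freqs(self) -> np.ndarray:
        return np.array([s.effect_allele_freq for s in self.snps])

    def with_weights(self, weights: Mapping[str, float | Mapping[str, float]]) -> "SnpPanel":
        """Return a new panel with per-allele bp effects attached.

        ``weights`` maps rsID to either a bare bp value or a mapping with keys
        ``beta_bp`` and optionally ``se_bp``.
        """
        unknown = set(weights) - set(self.rsids)
        if unknown:
            raise KeyError(f"weights for rsIDs not in panel: {sorted(unknown)}")
        out = []
        for s in self.snps:
            w = weights.get(s.rsid)
            if w is None:
                out.append(s)
            elif isinstance(w, Mapping):
                out.append(
                    replace(s, weight_bp=float(w["beta_bp"]),
                            weight_se_bp=float(w["se_bp"]) if "se_bp" in w else None)
                )
            else:
                out.append(replace(s, weight_bp=float(w)))
        return SnpPanel(out)

    def drop(self, rsids: Iterable[str]) -> "SnpPanel":
        excluded = set(rsids)
        unknown = excluded - set(self.rsids)
        if unknown:
            raise KeyError(f"cannot exclude rsIDs not in panel: {sorted(unknown)}")
        kept = [s for s in self.snps if s.rsid not in excluded]
        if not kept:
            raise ValueError("excluding every SNP leaves an empty panel")
        return SnpPanel(kept)


# rsid, gene, major, minor, effect allele, control MAF
_BUILTIN = [
    ("rs11125529", "ACYP2", "C", "A", "A", 0.11),
    ("rs6772228", "PXK", "T", "A", "T", 0.04),
    ("rs10936599", "TERC", "C", "T", "C", 0.24),
    ("rs7675998", "NAF1", "G", "A", "G", 0.24),
    ("rs2736100", "TERT", "A", "C", "C", 0.50),
    ("rs9420907", "OBFC1", "A", "C", "C", 0.13),
    ("rs3027234", "CTC1", "C", "T", "C", 0.22),
    ("rs8105767", "ZNF208", "A", "G", "G", 0.28),
    ("rs412658", "ZNF676", "C", "T", "T", 0.35),
    ("rs6028466", "DHX35", "G", "A", "A", 0.07),
    ("rs755017", "ZBTB46", "A", "G", "G", 0.12),
]


def builtin_panel(weights: Mapping[str, float | Mapping[str, float]] | None = None) -> SnpPanel:
    """The 11-SNP LTL panel (ZNF676, TERT, CTC1, DHX35, PXK, NAF1, ZNF208,
    OBFC1, ACYP2, TERC, ZBTB46) with published control MAFs.

    Score weights (per-allele bp effects) default to unconfigured; pass
    ``weights`` or use :meth:`SnpPanel.with_weights`.
    """
    panel = SnpPanel(
        SnpRecord(rsid, gene, major, minor, ea, maf)
        for rsid, gene, major, minor, ea, maf in _BUILTIN
    )
    if weights is not None:
        panel = panel.with_weights(weights)
    return panel


def load_weights(path) -> dict:
    """Read a YAML weight config keyed by rsID.

    Accepted per-SNP forms::

        rs10936599: 117.0            # bp per long-telomere allele
        rs10936599: {beta_bp: 117.0, se_bp: 16.0}
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ValueError(f"{path}: weight config must be a mapping keyed by rsID")
    return dict(raw)
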