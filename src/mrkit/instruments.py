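"""Instrumental-variable selection, strength and directionality.

The selection chain mirrors standard two-sample MR practice: keep SNPs below
an association p-value threshold (locus-wide significance 1e-5 by default in
the pipeline), thin them by greedy LD clumping (r-squared < 0.001 within a
10,000 kb window by default), and enforce the exposure-to-outcome causal
direction per SNP with a Steiger filter.  Instrument strength is summarised
by the F statistic F = R^2 (n - k - 1) / (k (1 - R^2)); F < 10 conventionally
flags a weak instrument.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DomainError, ValidationError
from .gwas_io import HarmonizedVariant, VariantAssociation

logger = logging.getLogger(__name__)

WEAK_F_THRESHOLD = 10.0


@dataclass(frozen=True)
class LDMatrix:
    """Pairwise squared-correlation (r-squared) matrix over named SNPs."""

    snp_ids: tuple[str, ...]
    r2: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "snp_ids", tuple(self.snp_ids))
        r2 = np.asarray(self.r2, dtype=float)
        object.__setattr__(self, "r2", r2)
        n = len(self.snp_ids)
        if r2.shape != (n, n):
            raise ValidationError(f"LD matrix shape {r2.shape} != ({n}, {n})")
        if not np.allclose(r2, r2.T):
            raise ValidationError("LD matrix is not symmetric")
        if not np.allclose(np.diag(r2), 1.0):
            raise ValidationError("LD matrix diagonal must be 1")
        if (r2 < 0).any() or (r2 > 1).any():
            raise ValidationError("LD r2 entries must lie in [0, 1]")
        object.__setattr__(
            self, "_index", {s: i for i, s in enumerate(self.snp_ids)}
        )

    def r2_between(self, a: str, b: str) -> float:
        idx = self._index  # type: ignore[attr-defined]
        try:
            return float(self.r2[idx[a], idx[b]])
        except KeyError as missing:
            raise ConfigurationError(f"SNP {missing.args[0]!r} absent from LD matrix")

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index  # type: ignore[attr-defined]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LDMatrix":
        """Read a square TSV with SNP ids as both header row and first column."""
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        return cls(snp_ids=tuple(str(s) for s in df.columns), r2=df.to_numpy(float))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.r2, index=list(self.snp_ids), columns=list(self.snp_ids)).to_csv(
            path, sep="\t"
        )


@dataclass(frozen=True)
class InstrumentStrength:
    """F statistic for a set of k instruments jointly explaining r2 of the exposure."""

    r2: float
    n: int
    k: int
    F: float

    @property
    def weak(self) -> bool:
        return self.F < WEAK_F_THRESHOLD


@dataclass(frozen=True)
class SteigerRecord:
    """Per-SNP causal-direction evidence: variance explained in each trait."""

    snp_id: str
    r2_exp: float
    r2_out: float
    direction_ok: bool
    p: float


def filter_by_pvalue(
    records: Sequence[VariantAssociation], threshold: float
) -> list[VariantAssociation]:
    """Keep records with ``pval < threshold`` (strict), order preserved."""
    if not (0 < threshold <= 1):
        raise ConfigurationError(f"p-value threshold {threshold} outside (0, 1]")
    kept = [r for r in records if r.pval < threshold]
    logger.info("p-value filter: %d of %d SNPs retained", len(kept), len(records))
    return kept


def ld_clump(
    records: Sequence[VariantAssociation],
    ld: LDMatrix,
    r2_threshold: float = 0.001,
    window_kb: int = 10_000,
) -> list[VariantAssociation]:
    """Greedy p-value-ordered LD clumping.

    Repeatedly take the unclaimed SNP with the smallest p-value as an index
    SNP, then discard every unclaimed SNP on the same chromosome within
    +/- ``window_kb`` whose r-squared with the index is >= ``r2_threshold``.
    Ties in p are broken by lexicographic SNP id.  Returns index SNPs sorted
    by p ascending.
    """
    if not (0 < r2_threshold <= 1):
        raise ConfigurationError(f"r2 threshold {r2_threshold} outside (0, 1]")
    if window_kb <= 0:
        raise ConfigurationError(f"window {window_kb} kb must be positive")
    for r in records:
        if r.snp_id not in ld:
            raise ConfigurationError(f"SNP {r.snp_id!r} absent from LD matrix")

    window_bp = window_kb * 1000
    pending = sorted(records, key=lambda r: (r.pval, r.snp_id))
    claimed: set[str] = set()
    index_snps: list[VariantAssociation] = []
    for cand in pending:
        if cand.snp_id in claimed:
            continue
        index_snps.append(cand)
        claimed.add(cand.snp_id)
        for other in pending:
            if other.snp_id in claimed:
                continue
            if other.chrom != cand.chrom:
                continue
            if abs(other.pos - cand.pos) > window_bp:
                continue
            if ld.r2_between(cand.snp_id, other.snp_id) >= r2_threshold:
                claimed.add(other.snp_id)
    logger.info("LD clumping: %d of %d SNPs retained", len(index_snps), len(records))
    return index_snps


def f_statistic(r2: float, n: int, k: int = 1) -> InstrumentStrength:
    """F = r2 (n - k - 1) / (k (1 - r2)); F < 10 flags a weak instrument."""
    if not (0 <= r2 < 1):
        raise DomainError(f"r2 {r2} outside [0, 1)")
    if k < 1:
        raise DomainError(f"k must be >= 1, got {k}")
    if n <= k + 1:
        raise DomainError(f"need n > k + 1, got n={n}, k={k}")
    F = r2 * (n - k - 1) / (k * (1.0 - r2))
    return InstrumentStrength(r2=r2, n=n, k=k, F=F)


def snp_r2(beta: float, se: float, n: int, eaf: Optional[float] = None) -> float:
    """Variance of a standardized trait explained by a single SNP.

    With the effect-allele frequency available this is 2 beta^2 f (1 - f)
    (the standardized-trait approximation).  Without a frequency it falls
    back to z^2 / (z^2 + n - 2) with z = beta / se, which needs neither
    frequency nor case prevalence and behaves sensibly for binary traits on
    the log-odds scale.  The result is clipped to [0, 1).
    """
    if se <= 0:
        raise DomainError(f"se must be positive, got {se}")
    if n <= 2:
        raise DomainError(f"need n > 2, got {n}")
    if eaf is not None:
        r2 = 2.0 * beta * beta * eaf * (1.0 - eaf)
    else:
        z = beta / se
        r2 = z * z / (z * z + n - 2)
    return float(min(max(r2, 0.0), math.nextafter(1.0, 0.0)))


def steiger_filter(
    pairs: Sequence[HarmonizedVariant],
    use_eaf: bool = True,
) -> tuple[list[HarmonizedVariant], list[SteigerRecord]]:
    """Retain SNPs that explain more variance in the exposure than the outcome.

    Per SNP the variance explained in each trait comes from :func:`snp_r2`;
    retention requires the strict inequality r2_exp > r2_out.  The p-value is
    the two-sample Fisher-z comparison of the implied correlations
    r = sqrt(r2): z = (atanh(r_exp) - atanh(r_out)) /
    sqrt(1/(n_exp - 3) + 1/(n_out - 3)), two-sided normal.

    ``use_eaf=False`` forces the frequency-free z-based estimator on both
    sides, which keeps the two traits' r2 on a common footing when only one
    table carries frequencies.
    """
    retained: list[HarmonizedVariant] = []
    records: list[SteigerRecord] = []
    for h in pairs:
        if h.n_exp <= 3 or h.n_out <= 3:
            raise DomainError(f"{h.snp_id}: Steiger test needs n > 3 on both sides")
        r2_exp = snp_r2(h.beta_exp, h.se_exp, h.n_exp, h.eaf_exp if use_eaf else None)
        r2_out = snp_r2(h.beta_out, h.se_out, h.n_out, h.eaf_out if use_eaf else None)
        z = (math.atanh(math.sqrt(r2_exp)) - math.atanh(math.sqrt(r2_out))) / math.sqrt(
            1.0 / (h.n_exp - 3) + 1.0 / (h.n_out - 3)
        )
        p = float(2.0 * stats.norm.sf(abs(z)))
        ok = r2_exp > r2_out
        records.append(
            SteigerRecord(snp_id=h.snp_id, r2_exp=r2_exp, r2_out=r2_out, direction_ok=ok, p=p)
        )
        if ok:
            retained.append(h)
    logger.info("Steiger filter: %d of %d SNPs retained", len(retained), len(pairs))
    return retained, records


def read_clumps_file(path: str | Path) -> list[str]:
    """Read a precomputed clumps file: one index-SNP id per line.

    Bypass mode for users who clumped against an external reference panel.
    """
    ids = [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
    if not ids:
        raise ConfigurationError(f"{path}: no index SNPs listed")
    return ids
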