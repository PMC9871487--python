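"""GWAS summary-statistics I/O and exposure/outcome harmonization.

Summary statistics travel as tab-separated text with a header; the canonical
column names are ``SNP CHR POS EA OA EAF BETA SE P N`` (effect allele EA,
other allele OA, effect-allele frequency EAF).  A ``column_map`` lets callers
read tables with arbitrary headers (FinnGen-style ``rsids/alt/ref/...``,
MR-Base exports, ...) by mapping canonical names to the file's names.

Harmonization aligns the outcome association of each shared SNP onto the
exposure's effect allele.  When the outcome's alleles are swapped relative to
the exposure, the outcome beta is negated and the frequency complemented;
when they are on the opposite strand, the outcome alleles are complemented
before matching.  Palindromic variants (A/T, C/G) cannot be strand-resolved
from alleles alone and are dropped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import (
    ConfigurationError,
    EmptyInputError,
    ValidationError,
)

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]
REQUIRED_COLUMNS = [c for c in CANONICAL_COLUMNS if c != "EAF"]

_BASES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _complement(allele: str) -> str:
    return _COMPLEMENT[allele]


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's summary association with one trait.

    ``beta`` is the per-effect-allele estimate (log-odds for binary traits),
    ``se`` its standard error, ``eaf`` the effect-allele frequency (may be
    absent), ``n`` the GWAS sample size.  Positions are 1-based; chromosome
    labels are compared as strings after stripping a ``chr`` prefix.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    n: int
    eaf: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", str(self.chrom).removeprefix("chr"))
        object.__setattr__(self, "effect_allele", self.effect_allele.upper())
        object.__setattr__(self, "other_allele", self.other_allele.upper())
        if self.effect_allele not in _BASES:
            raise ValidationError(
                f"{self.snp_id}: effect allele {self.effect_allele!r} is not a single base"
            )
        if self.other_allele not in _BASES:
            raise ValidationError(
                f"{self.snp_id}: other allele {self.other_allele!r} is not a single base"
            )
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.snp_id}: identical alleles")
        if not (self.se > 0) or not math.isfinite(self.se):
            raise ValidationError(f"{self.snp_id}: se must be positive, got {self.se}")
        if not (0 < self.pval <= 1):
            raise ValidationError(f"{self.snp_id}: p-value {self.pval} outside (0, 1]")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise ValidationError(f"{self.snp_id}: eaf {self.eaf} outside (0, 1)")
        if self.pos < 1:
            raise ValidationError(f"{self.snp_id}: position must be 1-based positive")
        if self.n < 1:
            raise ValidationError(f"{self.snp_id}: sample size must be positive")

    @property
    def is_palindromic(self) -> bool:
        """True for A/T and C/G variants, whose strand is unresolvable."""
        return self.other_allele == _complement(self.effect_allele)


@dataclass(frozen=True)
class HarmonizedVariant:
    """Exposure and outcome effects aligned to a shared effect allele.

    ``flipped`` records whether the outcome association was re-oriented
    (allele swap and/or strand complement) during harmonization.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    n_exp: int
    n_out: int
    eaf_exp: Optional[float] = None
    eaf_out: Optional[float] = None
    flipped: bool = False


def read_summary_stats(
    path: str | Path,
    column_map: Optional[Mapping[str, str]] = None,
    sep: str = "\t",
) -> list[VariantAssociation]:
    """Read a delimited summary-statistics table into validated records.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    column_map
        Mapping from canonical names (``SNP``, ``CHR``, ..., ``N``) to the
        file's column names.  Omitted canonical names are looked up verbatim.
        ``EAF`` is optional; all other columns are required.
    sep
        Field delimiter, tab by default.

    Raises
    ------
    ConfigurationError
        If a required column cannot be resolved.
    ValidationError
        If a row violates a record invariant; the message names the row.
    EmptyInputError
        If the table has no data rows.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep, dtype={"CHR": str}, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: no data") from None
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")
    return records_from_frame(df, column_map=column_map, source=str(path))


def records_from_frame(
    df: pd.DataFrame,
    column_map: Optional[Mapping[str, str]] = None,
    source: str = "<frame>",
) -> list[VariantAssociation]:
    """Convert an in-memory summary-statistics table into validated records.

    Same column resolution and row validation as :func:`read_summary_stats`.
    """
    if df.empty:
        raise EmptyInputError(f"{source}: no data rows")
    path = source
    column_map = dict(column_map or {})
    resolved: dict[str, str] = {}
    for canon in CANONICAL_COLUMNS:
        name = column_map.get(canon, canon)
        if name in df.columns:
            resolved[canon] = name
        elif canon in REQUIRED_COLUMNS:
            raise ConfigurationError(
                f"{path}: required column {canon!r} (mapped to {name!r}) not found; "
                f"available: {list(df.columns)}"
            )

    records: list[VariantAssociation] = []
    has_eaf = "EAF" in resolved
    for idx, row in enumerate(df.itertuples(index=False)):
        get = lambda canon: getattr(row, resolved[canon])  # noqa: E731
        eaf = None
        if has_eaf:
            raw = get("EAF")
            if raw is not None and not (isinstance(raw, float) and math.isnan(raw)):
                eaf = float(raw)
        try:
            records.append(
                VariantAssociation(
                    snp_id=str(get("SNP")),
                    chrom=str(get("CHR")),
                    pos=int(get("POS")),
                    effect_allele=str(get("EA")),
                    other_allele=str(get("OA")),
                    beta=float(get("BETA")),
                    se=float(get("SE")),
                    pval=float(get("P")),
                    n=int(get("N")),
                    eaf=eaf,
                )
            )
        except ValidationError as err:
            raise ValidationError(f"{path}: row {idx}: {err}") from None
    return records


def write_summary_stats(records: Sequence[VariantAssociation], path: str | Path) -> None:
    """Write records as canonical TSV; inverse of :func:`read_summary_stats`."""
    df = pd.DataFrame(
        {
            "SNP": [r.snp_id for r in records],
            "CHR": [r.chrom for r in records],
            "POS": [r.pos for r in records],
            "EA": [r.effect_allele for r in records],
            "OA": [r.other_allele for r in records],
            "EAF": [r.eaf for r in records],
            "BETA": [r.beta for r in records],
            "SE": [r.se for r in records],
            "P": [r.pval for r in records],
            "N": [r.n for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def _orient_outcome(
    exp: VariantAssociation, out: VariantAssociation
) -> Optional[tuple[float, Optional[float], bool]]:
    """Align ``out`` onto ``exp``'s effect allele.

    Returns ``(beta_out, eaf_out, flipped)`` or None when the allele pairs
    cannot be reconciled.  Strand flips are resolved by complementing the
    outcome alleles before matching; if direct and complement interpretations
    disagree the SNP is ambiguous and dropped (only possible for palindromes,
    which the caller removes first).
    """
    ea, oa = exp.effect_allele, exp.other_allele
    candidates: set[tuple[float, Optional[float], bool]] = set()
    for o_ea, o_oa, complemented in (
        (out.effect_allele, out.other_allele, False),
        (_complement(out.effect_allele), _complement(out.other_allele), True),
    ):
        if (o_ea, o_oa) == (ea, oa):
            candidates.add((out.beta, out.eaf, complemented))
        elif (o_ea, o_oa) == (oa, ea):
            flipped_eaf = None if out.eaf is None else 1.0 - out.eaf
            candidates.add((-out.beta, flipped_eaf, True))
    signs = {c[0] for c in candidates}
    if not candidates:
        return None
    if len(signs) > 1:
        return None  # ambiguous: direct and complement matches disagree
    beta, eaf, _ = next(iter(candidates))
    flipped = all(c[2] for c in candidates)
    return beta, eaf, flipped


def harmonize_pair(
    exposure: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    palindrome_policy: str = "drop",
) -> list[HarmonizedVariant]:
    """Align an exposure/outcome pair onto shared effect alleles.

    Only SNPs present in both inputs are retained.  Swapped outcome alleles
    negate the outcome beta and complement its frequency; palindromic SNPs
    are removed under the (only) policy ``drop``; irreconcilable allele pairs
    are dropped with a logged reason.  Output is sorted by SNP id.

    Raises
    ------
    ValidationError
        On duplicate SNP ids within either input.
    ConfigurationError
        On an unknown palindrome policy.
    """
    if palindrome_policy != "drop":
        raise ConfigurationError(f"unknown palindrome policy {palindrome_policy!r}")
    for name, side in (("exposure", exposure), ("outcome", outcome)):
        ids = [r.snp_id for r in side]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate snp_id in {name}: {dupes}")

    out_by_id = {r.snp_id: r for r in outcome}
    harmonized: list[HarmonizedVariant] = []
    n_missing = n_palindromic = n_irreconcilable = 0
    for exp in exposure:
        out = out_by_id.get(exp.snp_id)
        if out is None:
            n_missing += 1
            continue
        if exp.is_palindromic or out.is_palindromic:
            n_palindromic += 1
            logger.info("%s dropped: palindromic alleles", exp.snp_id)
            continue
        oriented = _orient_outcome(exp, out)
        if oriented is None:
            n_irreconcilable += 1
            logger.info(
                "%s dropped: alleles %s/%s vs %s/%s irreconcilable",
                exp.snp_id,
                exp.effect_allele,
                exp.other_allele,
                out.effect_allele,
                out.other_allele,
            )
            continue
        beta_out, eaf_out, flipped = oriented
        harmonized.append(
            HarmonizedVariant(
                snp_id=exp.snp_id,
                effect_allele=exp.effect_allele,
                other_allele=exp.other_allele,
                beta_exp=exp.beta,
                se_exp=exp.se,
                beta_out=beta_out,
                se_out=out.se,
                n_exp=exp.n,
                n_out=out.n,
                eaf_exp=exp.eaf,
                eaf_out=eaf_out,
                flipped=flipped,
            )
        )
    logger.info(
        "harmonized %d SNPs (%d not shared, %d palindromic, %d irreconcilable)",
        len(harmonized),
        n_missing,
        n_palindromic,
        n_irreconcilable,
    )
    if not harmonized:
        logger.warning("empty intersection after harmonization")
    return sorted(harmonized, key=lambda h: h.snp_id)
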