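"""Synthetic two-sample GWAS summary statistics.

The generator realizes the instrumental-variable assumptions of a
two-sample MR design as an explicit generative model, so every pipeline
stage can be exercised without external downloads:

- causal SNP j carries a true effect gamma_j ~ N(0, gamma_sd^2) on the
  exposure, and true_beta * gamma_j + alpha_j on the outcome, where alpha_j
  is an optional horizontal-pleiotropy (direct) effect;
- null SNPs have gamma_j = 0 in both traits;
- sampling noise follows the standardized-trait approximation
  se = 1 / sqrt(2 n f (1 - f)) for allele frequency f and sample size n;
- pleiotropy is ``none``, ``balanced`` (alpha mean forced to 0) or
  ``directional``; the InSIDE condition (alpha independent of gamma) holds
  by construction unless ``corr_pleio_gamma`` is set, which exists to
  demonstrate MR-Egger's failure mode;
- LD is block-diagonal: disjoint blocks of constant within-block r-squared,
  positioned so a block fits inside the clumping window while distinct
  blocks do not.

One master seed drives separate deterministic sub-streams per component
(frequencies, effects, pleiotropy, noise, alleles), so enlarging the SNP
panel never reshuffles earlier draws.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .instruments import LDMatrix

# non-palindromic effect/other allele pairs, cycled deterministically
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "T")]
_PALINDROMIC_PAIRS = [("A", "T"), ("C", "G")]

_BLOCK_SPACING_BP = 20_000_000  # distinct blocks sit beyond a 10,000 kb window
_WITHIN_BLOCK_SPACING_BP = 5_000


@dataclass(frozen=True)
class SimConfig:
    """Generative-model parameters for a synthetic exposure/outcome GWAS pair.

    Attributes
    ----------
    n_causal, n_null
        Counts of exposure-associated instruments and of null SNPs.
    true_beta
        Causal effect of the exposure on the outcome, log-odds scale.
    gamma_sd
        SD of the true SNP-exposure effects gamma_j.
    pleiotropy_mode, pleio_mean, pleio_sd, pleio_fraction
        Direct-effect regime: ``none``, ``balanced`` (mean forced to 0) or
        ``directional``; ``pleio_fraction`` of causal SNPs receive a direct
        effect alpha_j ~ N(pleio_mean, pleio_sd^2).
    corr_pleio_gamma
        Correlation between alpha_j and gamma_j (0 preserves InSIDE).
    n_exp, n_out
        GWAS sample sizes of the two cohorts.
    maf_range
        Uniform sampling interval for allele frequencies, within (0, 0.5].
    ld_blocks
        Sequence of (block_size, within_block_r2) consumed from the start of
        the SNP panel; SNPs outside blocks are unlinked.
    palindromic_fraction
        Fraction of SNPs given A/T or C/G alleles, for harmonization tests.
    seed
        Master seed for all randomness.
    """

    n_causal: int = 50
    n_null: int = 0
    true_beta: float = 0.1
    gamma_sd: float = 0.05
    pleiotropy_mode: str = "none"
    pleio_mean: float = 0.0
    pleio_sd: float = 0.0
    pleio_fraction: float = 1.0
    corr_pleio_gamma: float = 0.0
    n_exp: int = 100_000
    n_out: int = 100_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_blocks: tuple[tuple[int, float], ...] = ()
    palindromic_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_causal < 0 or self.n_null < 0 or self.n_causal + self.n_null == 0:
            raise ConfigurationError("need at least one SNP")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ConfigurationError(f"unknown pleiotropy mode {self.pleiotropy_mode!r}")
        if self.pleiotropy_mode == "balanced" and self.pleio_mean != 0:
            raise ConfigurationError("balanced pleiotropy forces pleio_mean = 0")
        if self.gamma_sd < 0 or self.pleio_sd < 0:
            raise ConfigurationError("standard deviations must be >= 0")
        if not (0.0 <= self.pleio_fraction <= 1.0):
            raise ConfigurationError("pleio_fraction must lie in [0, 1]")
        if not (-1.0 <= self.corr_pleio_gamma <= 1.0):
            raise ConfigurationError("corr_pleio_gamma must lie in [-1, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range {self.maf_range} must sit within (0, 0.5]")
        if self.n_exp < 4 or self.n_out < 4:
            raise ConfigurationError("sample sizes must be > 3")
        if not (0.0 <= self.palindromic_fraction <= 1.0):
            raise ConfigurationError("palindromic_fraction must lie in [0, 1]")
        blocks = tuple((int(s), float(r)) for s, r in self.ld_blocks)
        object.__setattr__(self, "ld_blocks", blocks)
        if sum(s for s, _ in blocks) > self.n_causal + self.n_null:
            raise ConfigurationError("LD block sizes exceed the SNP count")
        for _, r2 in blocks:
            if not (0.0 <= r2 <= 1.0):
                raise ConfigurationError(f"block r2 {r2} outside [0, 1]")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of one simulated pair: causal effect and per-SNP effects."""

    true_beta: float
    table: pd.DataFrame  # columns: SNP, gamma, alpha


def _positions(m: int, blocks: Sequence[tuple[int, float]]) -> np.ndarray:
    """Chromosome-1 positions: blocks contiguous, everything else far apart."""
    pos = np.empty(m, dtype=int)
    cursor = 1_000_000
    i = 0
    for size, _ in blocks:
        for j in range(size):
            pos[i] = cursor + j * _WITHIN_BLOCK_SPACING_BP
            i += 1
        cursor += _BLOCK_SPACING_BP
    while i < m:
        pos[i] = cursor
        cursor += _BLOCK_SPACING_BP
        i += 1
    return pos


def simulate_gwas_pair(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Draw one exposure/outcome summary-statistics pair.

    Returns two DataFrames in the canonical column layout
    (``SNP CHR POS EA OA EAF BETA SE P N``) plus the ground truth.  Causal
    SNPs come first, then null SNPs; all tables are byte-reproducible for a
    given config.
    """
    m = config.n_causal + config.n_null
    ss = np.random.SeedSequence(config.seed)
    rng_maf, rng_gamma, rng_pleio, rng_x, rng_y, rng_allele = (
        np.random.default_rng(child) for child in ss.spawn(6)
    )

    maf = rng_maf.uniform(config.maf_range[0], config.maf_range[1], size=m)
    gamma = np.zeros(m)
    gamma[: config.n_causal] = rng_gamma.normal(0.0, config.gamma_sd, size=config.n_causal)

    alpha = np.zeros(m)
    if config.pleiotropy_mode != "none" and config.n_causal > 0:
        n_pleio = int(round(config.pleio_fraction * config.n_causal))
        chosen = rng_pleio.choice(config.n_causal, size=n_pleio, replace=False)
        eps = rng_pleio.normal(0.0, 1.0, size=n_pleio)
        rho = config.corr_pleio_gamma
        if rho != 0.0 and config.gamma_sd > 0:
            std_gamma = gamma[chosen] / config.gamma_sd
            raw = rho * std_gamma + np.sqrt(1.0 - rho * rho) * eps
        else:
            raw = eps
        alpha[chosen] = config.pleio_mean + config.pleio_sd * raw

    se_x = 1.0 / np.sqrt(2.0 * config.n_exp * maf * (1.0 - maf))
    se_y = 1.0 / np.sqrt(2.0 * config.n_out * maf * (1.0 - maf))
    beta_x = gamma + se_x * rng_x.normal(size=m)
    beta_y = config.true_beta * gamma + alpha + se_y * rng_y.normal(size=m)
    p_x = 2.0 * stats.norm.sf(np.abs(beta_x / se_x))
    p_y = 2.0 * stats.norm.sf(np.abs(beta_y / se_y))

    n_palin = int(round(config.palindromic_fraction * m))
    palin_idx = set(rng_allele.choice(m, size=n_palin, replace=False).tolist())
    alleles = []
    for i in range(m):
        if i in palin_idx:
            alleles.append(_PALINDROMIC_PAIRS[i % len(_PALINDROMIC_PAIRS)])
        else:
            alleles.append(_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)])

    snp = [f"rs{i + 1:06d}" for i in range(m)]
    pos = _positions(m, config.ld_blocks)
    base = {
        "SNP": snp,
        "CHR": ["1"] * m,
        "POS": pos,
        "EA": [a for a, _ in alleles],
        "OA": [b for _, b in alleles],
        "EAF": maf,
    }
    exposure = pd.DataFrame(
        {**base, "BETA": beta_x, "SE": se_x,
         "P": np.clip(p_x, np.nextafter(0, 1), 1.0), "N": config.n_exp}
    )
    outcome = pd.DataFrame(
        {**base, "BETA": beta_y, "SE": se_y,
         "P": np.clip(p_y, np.nextafter(0, 1), 1.0), "N": config.n_out}
    )
    truth = SimTruth(
        true_beta=config.true_beta,
        table=pd.DataFrame({"SNP": snp, "gamma": gamma, "alpha": alpha}),
    )
    return exposure, outcome, truth


def simulate_ld_matrix(
    snp_table: pd.DataFrame,
    ld_blocks: Sequence[tuple[int, float]],
    seed: Optional[int] = None,
) -> LDMatrix:
    """Block-diagonal LD matrix matching a simulated SNP table.

    Blocks consume SNPs from the start of the table in order; within a
    block every off-diagonal entry equals the block's r-squared, across
    blocks it is 0.  The construction is deterministic; ``seed`` is accepted
    for interface symmetry.
    """
    ids = [str(s) for s in snp_table["SNP"]]
    m = len(ids)
    if sum(s for s, _ in ld_blocks) > m:
        raise ConfigurationError("LD block sizes exceed the SNP count")
    r2 = np.eye(m)
    start = 0
    for size, block_r2 in ld_blocks:
        if not (0.0 <= block_r2 <= 1.0):
            raise ConfigurationError(f"block r2 {block_r2} outside [0, 1]")
        stop = start + size
        r2[start:stop, start:stop] = block_r2
        np.fill_diagonal(r2[start:stop, start:stop], 1.0)
        start = stop
    return LDMatrix(snp_ids=tuple(ids), r2=r2)


def write_simulation(
    config: SimConfig, outdir: str | Path
) -> tuple[Path, Path, Path, Path]:
    """Run a simulation and write exposure/outcome/truth TSVs plus a manifest.

    Also writes ``ld.tsv`` covering the full panel.  Returns the four table
    paths (exposure, outcome, truth, ld).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exposure, outcome, truth = simulate_gwas_pair(config)
    exp_path = outdir / "exposure.tsv"
    out_path = outdir / "outcome.tsv"
    truth_path = outdir / "truth.tsv"
    ld_path = outdir / "ld.tsv"
    exposure.to_csv(exp_path, sep="\t", index=False)
    outcome.to_csv(out_path, sep="\t", index=False)
    truth.table.assign(true_beta=truth.true_beta).to_csv(truth_path, sep="\t", index=False)
    simulate_ld_matrix(exposure, config.ld_blocks).to_tsv(ld_path)
    manifest = dataclasses.asdict(config)
    manifest["ld_blocks"] = [list(b) for b in config.ld_blocks]
    manifest["maf_range"] = list(config.maf_range)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return exp_path, out_path, truth_path, ld_path
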