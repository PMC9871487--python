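import numpy as np
import pytest

from mrkit.gwas_io import HarmonizedVariant, VariantAssociation


def variant(
    snp="rs1",
    chrom="1",
    pos=1_000_000,
    ea="A",
    oa="G",
    beta=0.1,
    se=0.01,
    p=1e-8,
    n=10_000,
    eaf=0.3,
):
    return VariantAssociation(
        snp_id=snp,
        chrom=chrom,
        pos=pos,
        effect_allele=ea,
        other_allele=oa,
        beta=beta,
        se=se,
        pval=p,
        n=n,
        eaf=eaf,
    )


def make_pairs(bx, sx, by, sy, n_exp=100_000, n_out=100_000, eaf=None):
    """Build harmonized variants directly from effect arrays."""
    bx, sx, by, sy = map(np.asarray, (bx, sx, by, sy))
    return [
        HarmonizedVariant(
            snp_id=f"rs{i:06d}",
            effect_allele="A",
            other_allele="G",
            beta_exp=float(bx[i]),
            se_exp=float(sx[i]),
            beta_out=float(by[i]),
            se_out=float(sy[i]),
            n_exp=n_exp,
            n_out=n_out,
            eaf_exp=None if eaf is None else float(eaf[i]),
            eaf_out=None if eaf is None else float(eaf[i]),
        )
        for i in range(len(bx))
    ]


def draw_harmonized(
    rng,
    J,
    true_beta,
    gamma_sd=0.05,
    n_exp=100_000,
    n_out=100_000,
    maf=(0.05, 0.5),
    alpha=None,
    orient_gamma=False,
):
    """Sample harmonized pairs straight from the two-sample generative model:
    strong-ish instruments with allele-frequency-scaled sampling noise and an
    optional per-SNP direct (pleiotropic) effect ``alpha``.

    ``orient_gamma=True`` codes every SNP by its exposure-increasing allele
    (half-normal gamma), the frame in which a nonzero-mean direct effect is
    genuinely directional."""
    f = rng.uniform(*maf, J)
    sx = 1.0 / np.sqrt(2 * n_exp * f * (1 - f))
    sy = 1.0 / np.sqrt(2 * n_out * f * (1 - f))
    gamma = rng.normal(0.0, gamma_sd, J)
    if orient_gamma:
        gamma = np.abs(gamma)
    bx = gamma + rng.normal(size=J) * sx
    mean_y = true_beta * gamma + (0.0 if alpha is None else np.asarray(alpha))
    by = mean_y + rng.normal(size=J) * sy
    return make_pairs(bx, sx, by, sy, n_exp, n_out, eaf=f)


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)
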