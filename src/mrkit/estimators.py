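"""Causal-effect estimators for two-sample Mendelian randomization.

All estimators consume harmonized per-SNP association pairs
(beta_exp, se_exp, beta_out, se_out) and return a log-scale causal effect
with its standard error, 95% confidence interval, p-value and odds-ratio
transform.  Implemented methods:

- Wald ratio (single SNP): beta_out / beta_exp.
- Inverse-variance weighted (IVW): inverse-variance average of Wald ratios,
  equivalent to weighted regression of beta_out on beta_exp through the
  origin with weights 1/se_out^2; multiplicative-random-effects mode scales
  the SE by max(1, sqrt(Q/(J-1))).
- MR-Egger: the same weighted regression with a free intercept; the
  intercept estimates directional pleiotropy, the slope stays consistent
  under the InSIDE assumption.
- Weighted median: consistent when instruments carrying at least half the
  weight are valid; SE by parametric bootstrap.
- Maximum likelihood: joint-normal model beta_exp_j ~ N(gamma_j, se_exp_j^2),
  beta_out_j ~ N(beta * gamma_j, se_out_j^2), profiled over the gamma_j.
- MR-RAPS: robust adjusted profile score with optional Huber loss and
  overdispersion parameter, tolerant of weak instruments and systematic
  pleiotropy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import (
    CollinearityError,
    ConvergenceError,
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
)
from .gwas_io import HarmonizedVariant

Z95 = 1.959963984540054  # normal 97.5% quantile


@dataclass(frozen=True)
class MREstimate:
    """A causal estimate on the log(OR) scale with its OR presentation."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    or_: float
    or_low: float
    or_high: float
    extra: dict = field(default_factory=dict)


def _finalize(
    method: str,
    beta: float,
    se: float,
    n_snps: int,
    df: Optional[int] = None,
    extra: Optional[dict] = None,
) -> MREstimate:
    """Attach CI, p-value (normal, or t with ``df``) and OR transform."""
    ci_low = beta - Z95 * se
    ci_high = beta + Z95 * se
    if se > 0:
        t = beta / se
        if df is not None:
            pval = float(2.0 * stats.t.sf(abs(t), df))
        else:
            pval = float(2.0 * stats.norm.sf(abs(t)))
    else:
        pval = 1.0 if beta == 0 else 0.0
    pval = min(max(pval, np.nextafter(0.0, 1.0)), 1.0)
    return MREstimate(
        method=method,
        beta=beta,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        pval=pval,
        n_snps=n_snps,
        or_=math.exp(beta),
        or_low=math.exp(ci_low),
        or_high=math.exp(ci_high),
        extra=dict(extra or {}),
    )


def to_odds_ratio(est: MREstimate) -> MREstimate:
    """Recompute the 95% CI (beta +/- 1.96 se) and OR fields from beta and se.

    Values are stored at full precision; rounding (2 decimals for ORs) is a
    presentation concern left to report writers.
    """
    ci_low = est.beta - Z95 * est.se
    ci_high = est.beta + Z95 * est.se
    return replace(
        est,
        ci_low=ci_low,
        ci_high=ci_high,
        or_=math.exp(est.beta),
        or_low=math.exp(ci_low),
        or_high=math.exp(ci_high),
    )


def _arrays(pairs: Sequence[HarmonizedVariant]):
    bx = np.array([p.beta_exp for p in pairs], float)
    sx = np.array([p.se_exp for p in pairs], float)
    by = np.array([p.beta_out for p in pairs], float)
    sy = np.array([p.se_out for p in pairs], float)
    return bx, sx, by, sy


def _check_nonzero_exposure(pairs: Sequence[HarmonizedVariant]) -> None:
    for p in pairs:
        if p.beta_exp == 0:
            raise DegenerateInstrumentError(
                f"{p.snp_id}: zero SNP-exposure effect makes the Wald ratio undefined"
            )


def wald_ratio(pair: HarmonizedVariant, second_order_se: bool = False) -> MREstimate:
    """Single-SNP causal estimate beta_out / beta_exp.

    The default SE is first-order, se_out / |beta_exp|; ``second_order_se``
    adds the delta-method term for uncertainty in the exposure effect:
    sqrt(se_out^2 / beta_exp^2 + beta_out^2 se_exp^2 / beta_exp^4).
    """
    _check_nonzero_exposure([pair])
    beta = pair.beta_out / pair.beta_exp
    if second_order_se:
        se = math.sqrt(
            pair.se_out**2 / pair.beta_exp**2
            + pair.beta_out**2 * pair.se_exp**2 / pair.beta_exp**4
        )
    else:
        se = pair.se_out / abs(pair.beta_exp)
    return _finalize("wald_ratio", beta, se, 1)


def _ivw_core(bx, sy, by):
    """Inverse-variance weighted mean of ratios and Cochran's Q.

    Weights w_j = beta_exp_j^2 / se_out_j^2 are the inverse first-order
    ratio variances; the weighted mean equals the WLS slope through the
    origin of beta_out on beta_exp with weights 1/se_out^2.
    """
    w = bx**2 / sy**2
    ratios = by / bx
    beta = float(np.sum(w * ratios) / np.sum(w))
    se_fixed = float(1.0 / math.sqrt(np.sum(w)))
    q = float(np.sum(w * (ratios - beta) ** 2))
    return beta, se_fixed, q, w


def ivw(pairs: Sequence[HarmonizedVariant], mode: str = "mre") -> MREstimate:
    """Inverse-variance-weighted estimate over >= 2 SNPs.

    ``mode="fixed"`` uses the fixed-effect SE 1/sqrt(sum w); ``mode="mre"``
    (default, multiplicative random effects) inflates it by
    max(1, sqrt(Q/(J-1))), reverting to fixed-effect behaviour on
    under-dispersed data.  A single pair delegates to :func:`wald_ratio`.
    """
    if mode not in ("fixed", "mre"):
        raise ValueError(f"unknown IVW mode {mode!r}")
    if len(pairs) == 0:
        raise InsufficientInstrumentsError("IVW needs at least one SNP")
    if len(pairs) == 1:
        return wald_ratio(pairs[0])
    _check_nonzero_exposure(pairs)
    bx, _, by, sy = _arrays(pairs)
    beta, se, q, _ = _ivw_core(bx, sy, by)
    extra = {"Q": q, "mode": mode}
    if mode == "mre":
        se *= max(1.0, math.sqrt(q / (len(pairs) - 1)))
    return _finalize("ivw", beta, se, len(pairs), extra=extra)


def mr_egger(pairs: Sequence[HarmonizedVariant]) -> MREstimate:
    """MR-Egger regression: weighted fit of beta_out on beta_exp with intercept.

    Every SNP is first oriented so beta_exp >= 0 (both betas negated where
    needed), which makes the intercept interpretable as the average
    directional pleiotropic effect.  Weights are 1/se_out^2; coefficient SEs
    use a residual variance inflation factor floored at 1, and p-values come
    from a t distribution with J - 2 degrees of freedom.  The intercept
    estimate, SE and p-value are reported in ``extra``.
    """
    J = len(pairs)
    if J < 3:
        raise InsufficientInstrumentsError(f"MR-Egger needs >= 3 SNPs, got {J}")
    _check_nonzero_exposure(pairs)
    bx, _, by, sy = _arrays(pairs)
    flip = np.sign(bx)
    bx, by = bx * flip, by * flip
    if np.allclose(bx, bx[0]):
        raise CollinearityError("no spread in SNP-exposure effects after orientation")
    w = 1.0 / sy**2
    # closed-form weighted least squares with design [1, bx]
    X = np.column_stack([np.ones(J), bx])
    XtW = X.T * w
    xtwx = XtW @ X
    coef = np.linalg.solve(xtwx, XtW @ by)
    resid = by - X @ coef
    sigma2 = float(np.sum(w * resid**2) / (J - 2))
    inflation = max(1.0, sigma2)
    cov = inflation * np.linalg.inv(xtwx)
    intercept, slope = float(coef[0]), float(coef[1])
    se_int, se_slope = float(math.sqrt(cov[0, 0])), float(math.sqrt(cov[1, 1]))
    df = J - 2
    p_int = float(2.0 * stats.t.sf(abs(intercept / se_int), df)) if se_int > 0 else (
        1.0 if intercept == 0 else 0.0
    )
    extra = {
        "intercept": intercept,
        "intercept_se": se_int,
        "intercept_pval": p_int,
        "sigma2": sigma2,
        "df": df,
    }
    return _finalize("egger", slope, se_slope, J, df=df, extra=extra)


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median: cumulative midpoint weights vs 0.5."""
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / np.sum(weights)
    s = np.cumsum(w) - 0.5 * w  # midpoint of each weight block
    return float(np.interp(0.5, s, r))


def weighted_median(
    pairs: Sequence[HarmonizedVariant],
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Weighted-median estimate with parametric-bootstrap SE.

    Ratio estimates are sorted, their normalized inverse-variance weights
    accumulated, and the estimate is the linear interpolation of the sorted
    ratios at cumulative midpoint weight 0.5.  The estimator is consistent
    when valid instruments carry at least 50% of the weight.  The SE is the
    standard deviation of the estimate over ``n_boot`` parametric resamples
    of (beta_exp, beta_out) from normals centred on the observations.
    """
    J = len(pairs)
    if J < 3:
        raise InsufficientInstrumentsError(f"weighted median needs >= 3 SNPs, got {J}")
    if n_boot < 100:
        raise ValueError(f"n_boot must be >= 100, got {n_boot}")
    _check_nonzero_exposure(pairs)
    bx, sx, by, sy = _arrays(pairs)
    weights = bx**2 / sy**2
    beta = _weighted_median_point(by / bx, weights)

    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_boot, J))
    by_star = rng.normal(by, sy, size=(n_boot, J))
    boot = np.empty(n_boot)
    for i in range(n_boot):
        bxi = bx_star[i]
        bxi = np.where(bxi == 0, np.finfo(float).tiny, bxi)
        boot[i] = _weighted_median_point(by_star[i] / bxi, bxi**2 / sy**2)
    se = float(np.std(boot, ddof=1))
    return _finalize("weighted_median", beta, se, J, extra={"n_boot": n_boot})


def _profile_nll(beta: float, bx, sx, by, sy) -> float:
    """-2 log-likelihood of the joint-normal model profiled over gamma."""
    v = sy**2 + beta * beta * sx**2
    return float(np.sum((by - beta * bx) ** 2 / v))


def max_likelihood(
    pairs: Sequence[HarmonizedVariant],
    bracket_halfwidth: float = 10.0,
    tol: float = 1e-10,
) -> MREstimate:
    """Maximum-likelihood causal estimate under the joint-normal model.

    For fixed beta the per-SNP true exposure effects gamma_j have a
    closed-form optimum, reducing the fit to a one-dimensional profile
    minimization of sum_j (beta_out_j - beta * beta_exp_j)^2 /
    (se_out_j^2 + beta^2 se_exp_j^2).  The SE comes from the observed
    information (numeric second derivative of the profile log-likelihood).
    In the se_exp -> 0 limit the estimate equals fixed-effect IVW.
    """
    J = len(pairs)
    if J < 2:
        raise InsufficientInstrumentsError(f"MLE needs >= 2 SNPs, got {J}")
    _check_nonzero_exposure(pairs)
    bx, sx, by, sy = _arrays(pairs)
    center, _, _, _ = _ivw_core(bx, sy, by)
    lo = center - bracket_halfwidth
    hi = center + bracket_halfwidth
    res = optimize.minimize_scalar(
        _profile_nll,
        bounds=(lo, hi),
        args=(bx, sx, by, sy),
        method="bounded",
        options={"xatol": tol, "maxiter": 500},
    )
    if not res.success:
        raise ConvergenceError(f"profile likelihood did not converge in [{lo}, {hi}]")
    beta = float(res.x)
    # observed information: second derivative of (1/2) * profile -2logL
    h = 1e-5 * max(1.0, abs(beta))
    d2 = (
        _profile_nll(beta + h, bx, sx, by, sy)
        - 2.0 * _profile_nll(beta, bx, sx, by, sy)
        + _profile_nll(beta - h, bx, sx, by, sy)
    ) / (h * h)
    if d2 <= 0:
        raise ConvergenceError("non-positive curvature at the profile optimum")
    se = math.sqrt(2.0 / d2)
    return _finalize("mle", beta, se, J)


_HUBER_C = 1.345
# moments of the Huber psi under a standard normal score
_HUBER_DELTA = 2.0 * stats.norm.cdf(_HUBER_C) - 1.0  # E[psi(Z) Z]
_HUBER_PSI2 = (
    (2.0 * stats.norm.cdf(_HUBER_C) - 1.0)
    - 2.0 * _HUBER_C * stats.norm.pdf(_HUBER_C)
    + 2.0 * _HUBER_C**2 * stats.norm.sf(_HUBER_C)
)  # E[psi(Z)^2]
_HUBER_DPSI = 2.0 * stats.norm.cdf(_HUBER_C) - 1.0  # E[psi'(Z)]


def _psi(t: np.ndarray, loss: str) -> np.ndarray:
    if loss == "l2":
        return t
    return np.clip(t, -_HUBER_C, _HUBER_C)


def _rho(t: np.ndarray, loss: str) -> np.ndarray:
    if loss == "l2":
        return 0.5 * t * t
    a = np.abs(t)
    return np.where(a <= _HUBER_C, 0.5 * t * t, _HUBER_C * a - 0.5 * _HUBER_C**2)


def _raps_score(beta: float, tau2: float, bx, sx, by, sy, loss: str) -> float:
    v = sy**2 + beta * beta * sx**2 + tau2
    t = (by - beta * bx) / np.sqrt(v)
    # minus the derivative of t w.r.t. beta
    m = (bx * (sy**2 + tau2) + beta * by * sx**2) / v**1.5
    return float(np.sum(_psi(t, loss) * m))


def _raps_tau2_moment(beta: float, tau2: float, bx, sx, by, sy, loss: str) -> float:
    v = sy**2 + beta * beta * sx**2 + tau2
    t = (by - beta * bx) / np.sqrt(v)
    delta = 1.0 if loss == "l2" else _HUBER_DELTA
    return float(np.sum((_psi(t, loss) * t - delta) / v))


def _solve_raps_beta(
    tau2: float, bx, sx, by, sy, loss: str, center: float, halfwidth: float = 10.0
) -> float:
    """Minimize the robustified profile loss sum_j rho(t_j); its stationarity
    condition is the adjusted profile-score equation."""

    def objective(b: float) -> float:
        v = sy**2 + b * b * sx**2 + tau2
        return float(np.sum(_rho((by - b * bx) / np.sqrt(v), loss)))

    res = optimize.minimize_scalar(
        objective,
        bounds=(center - halfwidth, center + halfwidth),
        method="bounded",
        options={"xatol": 1e-10, "maxiter": 500},
    )
    if not res.success:
        raise ConvergenceError(
            f"profile-score minimization failed in "
            f"[{center - halfwidth}, {center + halfwidth}]"
        )
    return float(res.x)


def mr_raps(
    pairs: Sequence[HarmonizedVariant],
    loss: str = "huber",
    overdispersion: bool = True,
) -> MREstimate:
    """Robust adjusted profile score estimator.

    Solves the profile-score estimating equation in beta built from the
    standardized residuals t_j = (beta_out_j - beta * beta_exp_j) /
    sqrt(se_out_j^2 + beta^2 se_exp_j^2 + tau^2).  The ``l2`` loss without
    overdispersion reproduces the maximum-likelihood profile estimate; the
    ``huber`` loss (tuning constant 1.345) bounds the influence of outlying
    instruments.  With ``overdispersion`` on, a systematic-pleiotropy
    variance tau^2 >= 0 is estimated from the moment condition
    E[psi(t) t] = E[psi(Z) Z].  The SE is a sandwich estimate.
    """
    J = len(pairs)
    if J < 3:
        raise InsufficientInstrumentsError(f"MR-RAPS needs >= 3 SNPs, got {J}")
    if loss not in ("l2", "huber"):
        raise ValueError(f"unknown loss {loss!r}")
    _check_nonzero_exposure(pairs)
    bx, sx, by, sy = _arrays(pairs)
    center, _, _, _ = _ivw_core(bx, sy, by)

    tau2 = 0.0
    if overdispersion:
        def moment(t2: float) -> float:
            b = _solve_raps_beta(t2, bx, sx, by, sy, loss, center)
            return _raps_tau2_moment(b, t2, bx, sx, by, sy, loss)

        if moment(0.0) > 0:  # residuals overdispersed at tau2 = 0
            hi = float(np.var(by - center * bx)) + np.mean(sy**2)
            for _ in range(60):
                if moment(hi) < 0:
                    break
                hi *= 2.0
            else:
                raise ConvergenceError("overdispersion bracket not found")
            tau2 = float(optimize.brentq(moment, 0.0, hi, xtol=1e-14))

    beta = _solve_raps_beta(tau2, bx, sx, by, sy, loss, center)

    # sandwich SE: A = dg/dbeta at the root (numeric), B = E[psi^2] sum m_j^2
    h = 1e-6 * max(1.0, abs(beta))
    A = (
        _raps_score(beta + h, tau2, bx, sx, by, sy, loss)
        - _raps_score(beta - h, tau2, bx, sx, by, sy, loss)
    ) / (2.0 * h)
    v = sy**2 + beta * beta * sx**2 + tau2
    m = (bx * (sy**2 + tau2) + beta * by * sx**2) / v**1.5
    c2 = 1.0 if loss == "l2" else _HUBER_PSI2
    B = c2 * float(np.sum(m * m))
    if A == 0:
        raise ConvergenceError("flat profile score at the root")
    se = math.sqrt(B) / abs(A)
    return _finalize(
        "raps", beta, se, J, extra={"tau2": tau2, "loss": loss, "overdispersion": overdispersion}
    )
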