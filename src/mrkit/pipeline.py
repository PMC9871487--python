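"""Study orchestration: discovery/replication MR over exposure-outcome grids.

``run_study`` executes, for every exposure x outcome pair, the chain
read -> p-value filter -> LD clumping -> harmonization (palindromes
dropped) -> Steiger directionality filter -> instrument-strength F
statistics -> the configured causal estimators -> the sensitivity battery
-> odds-ratio presentation, and writes a report shaped like the familiar
per-exposure results tables: one row per exposure x outcome x stage with
per-method p-values, heterogeneity and pleiotropy p-values, a leave-one-out
robustness flag and a suggestive flag (IVW p below alpha).

A replicated-stage row is marked ``replicated`` when the same exposure was
suggestive in the discovery stage with a concordant effect sign.  No
multiple-testing correction is applied to the suggestive flag; a Bonferroni
column over the exposure x outcome grid is emitted for transparency only.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import estimators as est
from . import sensitivity as sens
from .errors import ConfigurationError, MRKitError
from .gwas_io import HarmonizedVariant, VariantAssociation, harmonize_pair, read_summary_stats
from .instruments import (
    LDMatrix,
    f_statistic,
    filter_by_pvalue,
    ld_clump,
    read_clumps_file,
    snp_r2,
    steiger_filter,
)

DEFAULT_METHODS = ("ivw", "egger", "weighted_median", "mle", "raps")

_METHOD_P_COLUMNS = {
    "ivw": "P_ivw",
    "egger": "P_egger",
    "weighted_median": "P_wm",
    "mle": "P_mle",
    "raps": "P_raps",
}


@dataclass(frozen=True)
class Thresholds:
    """Selection thresholds; the defaults are the conventional locus-wide
    instrument p-value, clumping parameters, and suggestive alpha."""

    p_iv: float = 1e-5
    clump_r2: float = 0.001
    clump_kb: int = 10_000
    alpha: float = 0.05


@dataclass
class StudyConfig:
    """Full study specification: cohorts, LD source, thresholds, methods."""

    exposures: list[tuple[str, Path]]
    outcomes: list[tuple[str, Path, str]]  # (name, path, stage)
    ld_matrix: Optional[Path] = None
    clumps: Optional[Path] = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    methods: tuple[str, ...] = DEFAULT_METHODS
    seed: int = 0
    sensitivity: bool = True
    n_boot: int = 1000
    presso_n_sim: int = 1000
    column_map: Optional[dict] = None

    def __post_init__(self) -> None:
        for _, _, stage in self.outcomes:
            if stage not in ("discovery", "replicated"):
                raise ConfigurationError(f"unknown stage {stage!r}")
        for m in self.methods:
            if m not in _METHOD_P_COLUMNS:
                raise ConfigurationError(f"unknown method {m!r}")
        if self.ld_matrix is None and self.clumps is None:
            raise ConfigurationError("either an LD matrix or a clumps file is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        base = path.parent

        def resolve(p):
            return (base / p) if not Path(p).is_absolute() else Path(p)

        thresholds = Thresholds(**raw.get("thresholds", {}))
        return cls(
            exposures=[(e["name"], resolve(e["path"])) for e in raw["exposures"]],
            outcomes=[
                (o["name"], resolve(o["path"]), o.get("stage", "discovery"))
                for o in raw["outcomes"]
            ],
            ld_matrix=resolve(raw["ld_matrix"]) if raw.get("ld_matrix") else None,
            clumps=resolve(raw["clumps"]) if raw.get("clumps") else None,
            thresholds=thresholds,
            methods=tuple(raw.get("methods", DEFAULT_METHODS)),
            seed=int(raw.get("seed", 0)),
            sensitivity=bool(raw.get("sensitivity", True)),
            n_boot=int(raw.get("n_boot", 1000)),
            presso_n_sim=int(raw.get("presso_n_sim", 1000)),
            column_map=raw.get("column_map"),
        )


@dataclass
class PairAnalysis:
    """Everything computed for one exposure x outcome pair."""

    exposure: str
    outcome: str
    stage: str
    counts: dict
    f_min: Optional[float]
    f_max: Optional[float]
    estimates: dict  # method -> MREstimate
    errors: dict  # method -> reason string
    het_ivw: Optional[sens.HeterogeneityResult] = None
    het_egger: Optional[sens.HeterogeneityResult] = None
    egger_intercept: Optional[sens.EggerInterceptResult] = None
    presso: Optional[sens.PressoResult] = None
    loo: Optional[list] = None
    steiger: Optional[list] = None
    note: str = ""

    @property
    def primary(self) -> Optional[est.MREstimate]:
        """The headline estimate: IVW (which is the Wald ratio at J = 1)."""
        return self.estimates.get("ivw")


def _pair_seed(base_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([base_seed, index]).generate_state(1)[0] % (2**31))


def _f_range(pairs: Sequence[HarmonizedVariant]) -> tuple[Optional[float], Optional[float]]:
    """Per-instrument F statistics (k = 1) from the exposure associations."""
    fs = []
    for h in pairs:
        r2 = snp_r2(h.beta_exp, h.se_exp, h.n_exp, h.eaf_exp)
        fs.append(f_statistic(r2, h.n_exp, k=1).F)
    if not fs:
        return None, None
    return float(min(fs)), float(max(fs))


def analyze_pair(
    exposure_records: Sequence[VariantAssociation],
    outcome_records: Sequence[VariantAssociation],
    *,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
    stage: str = "discovery",
    ld: Optional[LDMatrix] = None,
    clump_ids: Optional[Sequence[str]] = None,
    thresholds: Thresholds = Thresholds(),
    methods: Sequence[str] = DEFAULT_METHODS,
    seed: int = 0,
    run_sensitivity: bool = True,
    n_boot: int = 1000,
    presso_n_sim: int = 1000,
) -> PairAnalysis:
    """Run the full selection/estimation/sensitivity chain on one pair.

    ``ld`` triggers internal greedy clumping; ``clump_ids`` instead restricts
    to a precomputed index-SNP list (bypass mode).  Estimator-level errors
    are recorded per method, never raised.
    """
    counts = {"input": len(exposure_records)}
    selected = filter_by_pvalue(exposure_records, thresholds.p_iv)
    counts["p_filter"] = len(selected)
    if ld is not None:
        selected = ld_clump(selected, ld, thresholds.clump_r2, thresholds.clump_kb)
    elif clump_ids is not None:
        keep = set(clump_ids)
        selected = [r for r in selected if r.snp_id in keep]
    counts["clump"] = len(selected)

    harmonized = harmonize_pair(selected, outcome_records)
    counts["harmonized"] = len(harmonized)
    retained, steiger_records = steiger_filter(harmonized)
    counts["steiger"] = len(retained)

    analysis = PairAnalysis(
        exposure=exposure_name,
        outcome=outcome_name,
        stage=stage,
        counts=counts,
        f_min=None,
        f_max=None,
        estimates={},
        errors={},
        steiger=steiger_records,
    )
    J = len(retained)
    if J < 1:
        analysis.note = "no instruments"
        return analysis
    analysis.f_min, analysis.f_max = _f_range(retained)

    for method in methods:
        try:
            if method == "ivw":
                analysis.estimates[method] = est.ivw(retained)
            elif method == "egger":
                analysis.estimates[method] = est.mr_egger(retained)
            elif method == "weighted_median":
                analysis.estimates[method] = est.weighted_median(
                    retained, n_boot=n_boot, seed=seed
                )
            elif method == "mle":
                analysis.estimates[method] = est.max_likelihood(retained)
            elif method == "raps":
                analysis.estimates[method] = est.mr_raps(retained)
        except MRKitError as err:
            analysis.errors[method] = f"{type(err).__name__}: {err}"

    if run_sensitivity:
        for attr, fn in (
            ("het_ivw", lambda: sens.cochran_q(retained, "ivw")),
            ("het_egger", lambda: sens.cochran_q(retained, "egger")),
            ("egger_intercept", lambda: sens.egger_intercept_test(retained)),
            (
                "presso",
                lambda: sens.mr_presso(
                    retained, n_sim=presso_n_sim, seed=seed
                ),
            ),
            ("loo", lambda: sens.leave_one_out(retained)),
        ):
            try:
                setattr(analysis, attr, fn())
            except MRKitError as err:
                analysis.errors[attr] = f"{type(err).__name__}: {err}"
    return analysis


def _loo_robust(analysis: PairAnalysis) -> Optional[bool]:
    """True when no single omission moves the IVW beta by 3 full-set SEs
    or flips its sign."""
    if analysis.loo is None or analysis.primary is None:
        return None
    full = analysis.primary
    spread = max(abs(e.beta - full.beta) for e in analysis.loo)
    signs_ok = all(e.beta * full.beta >= 0 for e in analysis.loo)
    return bool(spread < 3.0 * full.se and signs_ok)


def _report_rows(analyses: Sequence[PairAnalysis], alpha: float) -> pd.DataFrame:
    n_tests = sum(1 for a in analyses if a.primary is not None)
    rows = []
    for a in analyses:
        c = a.counts
        if not (
            c["input"] >= c["p_filter"] >= c["clump"] >= c["harmonized"] >= c["steiger"]
        ):
            raise AssertionError(f"filter counts not monotone for {a.exposure}/{a.outcome}")
        primary = a.primary
        row: dict = {
            "exposure": a.exposure,
            "outcome": a.outcome,
            "stage": a.stage,
            "n_input": c["input"],
            "n_pfilter": c["p_filter"],
            "n_clump": c["clump"],
            "n_harmonized": c["harmonized"],
            "n_instruments": c["steiger"],
            "F_min": a.f_min,
            "F_max": a.f_max,
        }
        for method, col in _METHOD_P_COLUMNS.items():
            e = a.estimates.get(method)
            row[col] = e.pval if e is not None else None
        if primary is not None:
            row.update(
                b_ivw=primary.beta,
                or_ivw=primary.or_,
                or_lci95=primary.or_low,
                or_uci95=primary.or_high,
            )
        else:
            row.update(b_ivw=None, or_ivw=None, or_lci95=None, or_uci95=None)
        row["P_Q_ivw"] = a.het_ivw.pval if a.het_ivw else None
        row["P_Q_egger"] = a.het_egger.pval if a.het_egger else None
        row["P_egger_intercept"] = a.egger_intercept.pval if a.egger_intercept else None
        row["P_presso_global"] = a.presso.global_p if a.presso else None
        if a.egger_intercept is not None and a.presso is not None:
            row["pleiotropy_disagreement"] = (
                a.egger_intercept.pleiotropy != (a.presso.global_p < alpha)
            )
        else:
            row["pleiotropy_disagreement"] = None
        row["loo_robust"] = _loo_robust(a)
        row["suggestive"] = bool(primary is not None and primary.pval < alpha)
        row["P_bonferroni"] = (
            min(1.0, primary.pval * n_tests) if primary is not None else None
        )
        row["note"] = a.note or (
            "; ".join(f"{k}: {v}" for k, v in sorted(a.errors.items())) or ""
        )
        rows.append(row)
    df = pd.DataFrame(rows)

    # replication marking: replicated-stage rows whose exposure was
    # discovery-suggestive with a concordant sign and is suggestive again
    replicated = []
    for _, row in df.iterrows():
        flag = False
        if row["stage"] == "replicated" and row["suggestive"] and row["b_ivw"] is not None:
            disc = df[
                (df["exposure"] == row["exposure"])
                & (df["stage"] == "discovery")
                & df["suggestive"]
            ]
            flag = any(
                b is not None and b * row["b_ivw"] > 0 for b in disc["b_ivw"]
            )
        replicated.append(flag)
    df["replicated"] = replicated
    return df


def run_study(config: StudyConfig, outdir: str | Path) -> pd.DataFrame:
    """Execute every exposure x outcome analysis and write report files.

    Outputs under ``outdir``: ``report.tsv`` (one row per pair, the per-
    method and sensitivity p-value layout), ``estimates.tsv`` (tidy
    per-method estimates), ``loo.tsv`` (leave-one-out series) and
    ``study.log`` (per-filter SNP counts).  Reruns with an identical config
    are byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    ld = LDMatrix.from_tsv(config.ld_matrix) if config.ld_matrix else None
    clump_ids = read_clumps_file(config.clumps) if config.clumps else None

    analyses: list[PairAnalysis] = []
    log_lines: list[str] = []
    pair_index = 0
    for exp_name, exp_path in config.exposures:
        exp_records = read_summary_stats(exp_path, column_map=config.column_map)
        for out_name, out_path, stage in config.outcomes:
            out_records = read_summary_stats(out_path, column_map=config.column_map)
            analysis = analyze_pair(
                exp_records,
                out_records,
                exposure_name=exp_name,
                outcome_name=out_name,
                stage=stage,
                ld=ld,
                clump_ids=clump_ids,
                thresholds=config.thresholds,
                methods=config.methods,
                seed=_pair_seed(config.seed, pair_index),
                run_sensitivity=config.sensitivity,
                n_boot=config.n_boot,
                presso_n_sim=config.presso_n_sim,
            )
            analyses.append(analysis)
            c = analysis.counts
            log_lines.append(
                f"exposure={exp_name} outcome={out_name} stage={stage} "
                f"input={c['input']} p_filter={c['p_filter']} clump={c['clump']} "
                f"harmonized={c['harmonized']} steiger={c['steiger']}"
                + (f" note={analysis.note}" if analysis.note else "")
            )
            pair_index += 1

    report = _report_rows(analyses, config.thresholds.alpha)
    report.to_csv(outdir / "report.tsv", sep="\t", index=False)

    est_rows = []
    loo_rows = []
    for a in analyses:
        for method, e in a.estimates.items():
            est_rows.append(
                {
                    "exposure": a.exposure,
                    "outcome": a.outcome,
                    "stage": a.stage,
                    "method": e.method,
                    "nsnp": e.n_snps,
                    "b": e.beta,
                    "se": e.se,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                    "pval": e.pval,
                    "or": e.or_,
                    "or_lci95": e.or_low,
                    "or_uci95": e.or_high,
                }
            )
        for entry in a.loo or []:
            loo_rows.append(
                {
                    "exposure": a.exposure,
                    "outcome": a.outcome,
                    "stage": a.stage,
                    "snp": entry.snp_id,
                    "b": entry.beta,
                    "se": entry.se,
                    "pval": entry.pval,
                }
            )
    pd.DataFrame(est_rows).to_csv(outdir / "estimates.tsv", sep="\t", index=False)
    pd.DataFrame(
        loo_rows, columns=["exposure", "outcome", "stage", "snp", "b", "se", "pval"]
    ).to_csv(outdir / "loo.tsv", sep="\t", index=False)
    (outdir / "study.log").write_text("\n".join(log_lines) + "\n")
    return report
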