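# Methods note

## Model and assumptions

For each candidate instrument (SNP) *j* we observe, from two non-overlapping
GWAS, the exposure association β̂<sub>Xj</sub> ± σ<sub>Xj</sub> and the
outcome association β̂<sub>Yj</sub> ± σ<sub>Yj</sub>. The working model is

β̂<sub>Xj</sub> ~ N(γ<sub>j</sub>, σ<sub>Xj</sub>²),
β̂<sub>Yj</sub> ~ N(β·γ<sub>j</sub> + α<sub>j</sub>, σ<sub>Yj</sub>²),

independently across SNPs, where γ<sub>j</sub> is the SNP's true effect on the
exposure, β is the causal effect of interest, and α<sub>j</sub> is a direct
(pleiotropic) path to the outcome. A valid instrument requires (i) relevance
(γ<sub>j</sub> ≠ 0), (ii) independence from confounders, and (iii) no direct
effect (α<sub>j</sub> = 0). The estimators below differ in how much of (iii)
they relax; only (i) is empirically checkable (F statistics), so results are
always read across the whole battery rather than from one method.

Standard errors are treated as known. Two-sample independence means the
exposure and outcome sampling errors are uncorrelated, which the estimators
assume throughout.

## Instrument selection

Defaults are the package's study conditions and are deliberately conventional
for summary-data MR with modest numbers of genome-wide hits:

| parameter | default | rationale |
|---|---|---|
| `p_iv` | 1e-5 | locus-wide threshold; strict `<`, keeps enough instruments for exposures with few genome-wide-significant hits while bounding weak-instrument contamination |
| `clump_r2` | 0.001 | near-independence; the estimators assume uncorrelated instruments |
| `clump_kb` | 10,000 | generous window so long-range LD cannot leak correlated instruments through |
| F threshold | 10 | conventional weak-instrument rule of thumb; F = R²(n−k−1)/(k(1−R²)) with k = 1 per SNP |

Clumping is greedy: SNPs are processed in order of ascending p-value (ties
broken lexicographically by SNP id for determinism) and any same-chromosome
SNP within the window with r² ≥ threshold against a kept SNP is removed. Per
SNP, R² is 2β²f(1−f) when the effect-allele frequency f is available, else
z²/(z² + n − 2).

MR-Steiger filtering keeps a SNP only if it explains strictly more variance in
the exposure than in the outcome; the directionality p-value compares the two
correlations via Fisher's z transform.

## Harmonization

Variants are matched by SNP id. If the outcome study lists the same alleles
swapped, the outcome effect is negated and its frequency reflected; strand
complements are resolved before matching. Palindromic variants (A/T, C/G) are
always dropped, because strand cannot be resolved from alleles alone and
frequency-based rescue is unreliable near f = 0.5. Irreconcilable allele pairs
and duplicates are dropped (duplicates within one study are an input error).
Output is sorted by SNP id so downstream results are order-independent.

## Estimators

All estimators operate on the harmonized (β̂<sub>Xj</sub>, β̂<sub>Yj</sub>)
pairs. CIs are ±1.96·SE on the log-odds scale; `to_odds_ratio` exponentiates
point and interval.

- **Wald ratio** (single SNP): β̂<sub>Y</sub>/β̂<sub>X</sub> with a first-order
  delta-method SE (second-order available).
- **IVW**: weighted least squares of β̂<sub>Y</sub> on β̂<sub>X</sub> through
  the origin with weights β̂<sub>Xj</sub>²/σ<sub>Yj</sub>² — equivalently an
  inverse-variance meta-analysis of Wald ratios. Default mode is
  multiplicative random effects: the fixed-effect SE is inflated by
  max(1, √(Q/(J−1))), so the SE never shrinks below the fixed-effect SE.
  With one SNP, IVW reduces to the Wald ratio.
- **MR-Egger**: the same WLS with a free intercept, after orienting every SNP
  so β̂<sub>X</sub> ≥ 0 (the intercept is only meaningful in the
  exposure-increasing-allele frame). The residual-variance inflation is
  floored at 1 (no shrinking below the fixed-effect SE); p-values use
  t(J−2). The intercept estimates the mean directional pleiotropy
  (InSIDE assumption required for the slope to be consistent).
- **Weighted median**: ratio estimates sorted, cumulative midpoint weights
  s<sub>j</sub> = Σ<sub>i<j</sub>w<sub>i</sub> + w<sub>j</sub>/2 (normalized),
  linear interpolation at 0.5. Consistent when ≥ 50% of the weight comes from
  valid instruments. SE by parametric bootstrap (default 1000 draws,
  resampling both β̂<sub>X</sub> and β̂<sub>Y</sub>; a floor of 100 draws is
  enforced, and the draw count and seed are explicit arguments so results are
  reproducible).
- **Profile maximum likelihood**: minimizes
  f(β) = Σ(β̂<sub>Yj</sub> − ββ̂<sub>Xj</sub>)²/(σ<sub>Yj</sub>² + β²σ<sub>Xj</sub>²),
  which accounts for sampling error in the exposure effects (IVW ignores it,
  giving its well-known weak-instrument attenuation). Minimized by bounded
  scalar search on an interval of ±10 around the IVW estimate (xatol 1e-10);
  SE from the observed information, √(2/f″), with f″ by central differences
  (h = 1e-5·max(1, |β|)).
- **MR-RAPS**: standardized residuals
  t<sub>j</sub>(β) = (β̂<sub>Yj</sub> − ββ̂<sub>Xj</sub>)/√(σ<sub>Yj</sub>² + β²σ<sub>Xj</sub>² + τ²)
  run through a Huber loss (c = 1.345). β is found by *minimizing the
  robustified profile loss* Σρ(t<sub>j</sub>) rather than root-finding the
  score equation: the score is not monotone in β when exposure effects have
  mixed signs, and bracketing can fail outright in contaminated data, while
  stationarity of the loss is the same equation. With the squared-error loss
  this reproduces the profile MLE. Overdispersion τ² is profiled from the
  moment condition E[ψ(t)t] = δ = 2Φ(c)−1 (Gaussian reference), with τ² = 0
  when the data are underdispersed; the SE is a sandwich estimator with the
  β-derivative of the score computed numerically.

Orientation convention: a "directional" pleiotropy signal means
E[α<sub>j</sub>] ≠ 0 *in the exposure-increasing-allele frame*. Since the
Egger estimator internally orients SNPs that way, a nonzero-mean direct
effect attached to symmetrically coded SNPs cancels under orientation and is
indistinguishable from balanced pleiotropy — the validation scenarios
therefore generate directional effects in the oriented frame.

## Sensitivity battery

- **Cochran's Q** on the IVW basis (df J−1) and Rücker's Q′ on the Egger
  basis (df J−2), χ² p-values.
- **Egger intercept test**: intercept ≠ 0 at α = 0.05 flags directional
  pleiotropy.
- **MR-PRESSO**: the global test compares the observed sum of leave-one-out
  weighted squared residuals with its parametric null distribution (both
  β̂<sub>X</sub> and β̂<sub>Y</sub> resimulated; default 1000 simulations,
  floor 500, all seeded). Empirical p-values use (1 + #exceedances)/(1 + n_sim)
  smoothing so zero can never be reported. The per-SNP outlier test runs only
  when the global test is significant (two-stage design, matching the method's
  usual staging) and is Bonferroni-corrected across SNPs. When outliers are
  found, an outlier-corrected IVW estimate and a distortion test (random
  same-size subset removals) are reported. Requires ≥ 4 SNPs.
- **Leave-one-out**: IVW re-estimated dropping each SNP in turn; the pipeline
  calls the series "robust" when all J estimates share the full-sample sign
  and their spread is below 3 full-sample SEs.

## Synthetic GWAS generator

`simulate_gwas_pair(SimConfig)` emulates a pair of independent summary-stat
studies under the working model above: MAFs uniform on `maf_range`, per-SNP
standard errors σ = 1/√(2nf(1−f)), true exposure effects
γ<sub>j</sub> ~ N(0, `gamma_sd`²) for causal SNPs and 0 for null SNPs, outcome
means `true_beta`·γ<sub>j</sub> + α<sub>j</sub>. Pleiotropy modes: `none`;
`balanced` (α ~ N(0, sd²)); `directional` (α ~ N(mean, sd²)), applied to a
configurable fraction of causal SNPs, with an optional γ-correlated component.
Optional block-diagonal LD (blocks of SNPs 5 kb apart, 20,000 kb between
blocks, so clumping windows behave realistically) and a configurable fraction
of palindromic variants to exercise harmonization. All randomness flows
through `numpy.random.SeedSequence(seed).spawn(...)` sub-streams, so output is
bit-identical for a given config.

What it does **not** emulate: real LD from a reference panel (r² values are
asserted, not derived from haplotypes), sample overlap between the two
studies, binary-trait liability-scale effects (outcome effects are plain
Gaussians on the log-odds scale), population stratification, winner's curse
in instrument discovery, and allele-frequency differences between studies.

Default problem sizes in the validation suite (50 instruments, n = 100,000
per study, gamma_sd = 0.05, true β = 0.1) were chosen so instruments are
strong (F well above 10) but finite-sample effects are visible; they are the
package's own choices.

## Reported quantities

The pipeline reports, per exposure–outcome pair: instrument counts through
each selection stage (monotonically non-increasing by construction), the F
range, all five estimators (β, SE, CI, p, OR scale), the sensitivity battery,
a "suggestive" flag (IVW p < α, default 0.05), Bonferroni-adjusted p across
the report, a pleiotropy-disagreement flag (diagnostics disagree with the
primary estimate), and replication marking when a replication-stage result is
suggestive with the same sign as its discovery-stage counterpart. Runs are
byte-identical for a given config and seed (no timestamps in any output).

## Limitations

Estimates are as good as the instruments: undetected correlated pleiotropy
(violating InSIDE), selection on the exposure p-value (winner's curse), or
sample overlap will bias all methods in this package to varying degrees.
MR-PRESSO's two-stage design has no power against many small violations that
shift no single SNP far from the bulk. The weighted-median bootstrap SE is a
parametric approximation. All operating characteristics quoted anywhere in
this repository are the ones computed by the test suite and
`scripts/acceptance.py`.
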