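# Methods

`clockmr` implements a complete two-sample Mendelian randomization (MR)
analysis of epigenetic age acceleration on cancer risk, operating purely on
GWAS summary statistics. This note records the statistical model, the
numerical and design choices that were genuinely open, what the synthetic
data generator does and does not emulate, and the package's known
limitations.

## The model

Two-sample MR treats genetic variants as instrumental variables. For
instrument j we observe the SNP–exposure association γ̂_j (standard error
σ_xj) from a GWAS of an epigenetic clock's age acceleration (a continuous
trait measured in years), and the SNP–outcome association Γ̂_j (standard
error σ_yj) from an independent cancer case–control GWAS on the log-odds
scale. Under the instrumental-variable assumptions (relevance,
independence, exclusion restriction), Γ_j = θ γ_j, and each Wald ratio
θ̂_j = Γ̂_j / γ̂_j estimates the causal log odds ratio per year of clock
acceleration.

### Estimators

* **IVW** — weighted regression of Γ̂ on γ̂ through the origin with weights
  1/σ_yj²; algebraically the inverse-variance-weighted mean of the Wald
  ratios with first-order delta-method weights. The *multiplicative
  random-effects* variant (the package default, matching common tooling)
  multiplies the fixed-effect standard error by the residual standard
  deviation φ = √(Q/(k−1)) with **no flooring at 1**; the flooring variant
  is a flag. Heterogeneity is summarised by Cochran's Q = Σ w_j(θ̂_j −
  θ̂_IVW)² with k−1 degrees of freedom.
* **MR-Egger** — the same regression with a free intercept after orienting
  all instruments to γ̂_j ≥ 0. The intercept estimates average directional
  pleiotropy; the slope is consistent under the InSIDE assumption. Here the
  residual dispersion **is** floored at 1 (per the method's original
  description) and inference uses the t distribution with k−2 df.
* **Weighted median** — the inverse-variance-weighted 50th percentile of the
  ordered Wald ratios (cumulative percentile p_j = Σ_{i≤j} w_i − w_j/2,
  linear interpolation at 0.5); consistent when at least half the weight
  comes from valid instruments. Standard errors by parametric bootstrap:
  (γ̂_j, Γ̂_j) resampled from their normal sampling distributions, 1,000
  draws by default, seed required for reproducibility.
* **Weighted mode** — the maximiser of a Gaussian-kernel weighted density of
  the Wald ratios, evaluated on a 2,048-point grid spanning the ratios
  ± 3 bandwidths. The bandwidth is φ_bw · 0.9 · min(sd, IQR/1.349) ·
  k^(−1/5) with φ_bw = 1 by default; consistent under the zero-modal-
  pleiotropy assumption. Bootstrap as for the median.
* **Wald ratio** — used alone when only one instrument survives; variance by
  the first-order delta method σ_yj²/γ̂_j² (the convention of the standard
  MR tooling); a second-order correction adding the γ̂ contribution is an
  option.

Single-SNP and leave-one-out tables re-run the Wald ratio and IVW on the
obvious subsets. Confidence intervals are normal-theory (±1.96 se) except
MR-Egger's t-based intervals. ORs are exp(θ̂) with exponentiated CIs;
internal arithmetic stays on the log scale throughout.

### Steiger directionality

The per-SNP variance explained in the exposure uses
r² = 2p(1−p)β²/(2p(1−p)β² + 2Np(1−p)se²) with p the minor-allele
frequency. For binary outcomes the observed-scale pseudo-r² is
2p(1−p)Γ²K(1−K) (K the case fraction), from the first-order
logistic-to-linear slope approximation; a liability-scale transformation
(multiplying by K(1−K)/φ(Φ⁻¹(K))²) is provided as an option since the
appropriate scale is a modelling choice. The aggregate direction is
exposure → outcome iff Σr²_exposure > Σr²_outcome; the p-value compares
the two aggregate correlations with a two-sample z test on the Fisher
atanh scale. Steiger filtering retains SNPs with r²_exposure >
r²_outcome (strict).

### Harmonisation

Outcome effect alleles are aligned to the exposure's per shared rsid:
direct match, swapped labels (negate, 1−eaf), or strand complement for
non-palindromic SNPs. Palindromic SNPs (A/T, C/G) carry no strand
information in their labels, so orientation is inferred from allele
frequency and only when the minor-allele frequency is strictly below 0.3
in *both* datasets (the threshold is a parameter); at MAF ≥ 0.3 in either
dataset the variant is excluded (`palindromic_high_maf`). A palindromic
variant with missing eaf on either side has indeterminate orientation and
is excluded with reason `strand_mismatch` — the conservative choice.
Indels pass through with palindromy undefined and complement matching
disabled. Exclusion reasons partition the excluded set.

### Instrument selection

Genome-wide significance is strict (p < 5×10⁻⁸). LD clumping is the pure
greedy r² rule (accept by ascending p-value iff r² < 0.001 with everything
already accepted); p-value ties break by larger |β/se| then rsid, making
the output invariant to row order. Distance windows are not applied by
default because the LD reference is explicit; absent LD pairs are treated
as independent with a warning. Proxy substitution requires r² > 0.8
(strict) and takes the maximal-r² candidate, ties broken by smaller
outcome p then rsid; a proxy is only usable if present in both datasets,
which is how proxy extraction works in practice. F ≤ 10 instruments are
flagged, not dropped.

### Meta-analysis and multiplicity

Study-level pooling is inverse-variance fixed-effect. I² = max(0,
(Q−df)/Q)·100 with a test-based CI on the ln(H) scale (Higgins–Thompson);
for k = 2 the se of ln(H) is undefined and the CI is reported as
unavailable, which is also what the original analysis prints. The
colorectal meta-group excludes UK Biobank (its participants are inside
the GECCO meta-analysis); group membership lives in configuration, not
code. Per-SNP GWAS meta-analysis harmonises each dataset against the
first, pools per-rsid, and emits an ordinary summary dataset so
single-SNP MR can consume it; rsids with irreconcilable alleles in any
dataset are dropped and logged. Benjamini–Hochberg q-values use the
configured family size m (20 = 4 clocks × 5 cancers) rather than the
count of p-values present, so partial runs stay comparable to the full
design.

## Power

For a binary outcome with instruments explaining R² of exposure variance,
the IVW estimator's asymptotic variance under the logistic-score standard
error model is 1/(N·R²·K(1−K)). The two-sided Wald test of a probed OR
therefore has non-centrality λ = √(N·R²·K(1−K))·|ln OR| and power
Φ(λ−z_{1−α/2}) + Φ(−λ−z_{1−α/2}), which reduces exactly to α at OR = 1.
This log-odds-scale formulation is the package default because it is
self-consistent with the rest of the pipeline (all binary-outcome effects
live on the log-odds scale) and because it reproduces the published
detectable-OR endpoints of the study design (1.04–1.39) exactly; an
alternative that attenuates the probed effect onto the observed 0/1 scale
before forming the non-centrality is available as
`approximation="attenuated"` (it yields slightly smaller detectable ORs
at the weak end of the design, max 1.33 on the same grid). The
detectable-OR inversion bisects on the log-OR scale to 10⁻⁴ on the OR
scale.

## The synthetic data generator

The generator emulates the statistical structure of the real inputs, not
their genomic detail:

* exposure: continuous, unit variance, measured in years, N = 34,710;
  instrument counts and total R² per clock follow the published design
  (9/1.48%, 24/4.41%, 11/1.86%, 4/0.47%);
* instruments emulate *post-selection* genome-wide-significant SNPs:
  per-SNP variance shares are Dirichlet-distributed with concentration 30
  by default, so no instrument has a near-zero effect and F statistics
  cluster tightly above 10, as selected instruments do in practice; the
  concentration is a parameter (smaller values spread instrument strength,
  which MR-Egger identification benefits from);
* true effects are scaled so Σ2p(1−p)γ² equals the target R² exactly;
  observed effects add normal noise with se = 1/√(2p(1−p)N) for the
  continuous exposure and se = 1/√(2p(1−p)·N·K(1−K)) for the binary
  outcome — the standard logistic-score approximation, chosen because the
  study's GWAS provide no generative detail;
* pleiotropy models: none; balanced (mean-zero); directional (mean μ_p,
  optionally on a fraction of instruments); correlated (α_j = q_c·u_j with
  u_j also contributing to γ_j — a shared heritable confounder). Under the
  correlated model with θ = 0, naive IVW is biased away from zero while
  the truth record's θ is 0: the fixture that motivates
  correlated-pleiotropy caveats for this design;
* optional LD blocks append satellite SNPs with effect r·γ_lead
  (r = √r²) and emit the matching pairwise LD reference, exercising
  clumping and proxy lookup; satellite noise is drawn independently;
* optional reverse-causal SNPs explain more outcome than exposure
  variance and are flagged in the truth record, exercising Steiger
  filtering;
* one seed governs everything through spawned substreams (effects,
  pleiotropy, exposure noise, outcome noise, reverse SNPs), so sub-draws
  are independently reproducible.

What it does **not** emulate: genome-wide LD maps, allele-frequency
spectra, selection and winner's-curse effects on the instrument effect
sizes, sample overlap between exposure and outcome GWAS, or population
stratification. Passing recovery tests on this generator therefore shows
the estimators are implemented and calibrated correctly under the stated
model — not that the real-data conclusions are immune to those
unmodelled features.

## Calibration checks and problem sizes

The test suite verifies, among others: mean IVW recovery of a planted
θ = ln(1.12) and 95% CI coverage over 2,000 replicates at the full study
scale (grimage-like design, colorectal-sized outcome); type-I error of
the IVW Wald test within [0.04, 0.06] over 2,000 null replicates; exact
(1e-10) agreement of IVW/Egger/weighted-median/Q with normal-equation and
definitional oracles on 100 random fixtures; BH-FDR against the step-up
definition on 1,000 random p-vectors; harmonisation orientation
invariance on 500 random fixtures; and Steiger direction calls on 300
mediation-chain replicates. Calibration-style checks (coverage, type-I
error) use the fixed-effect IVW variant: under the generator's
no-heterogeneity null its theoretical weights are exact and the test is
the correctly calibrated one. The multiplicative random-effects variant
estimates its dispersion from k−1 degrees of freedom, so with very few
instruments (k = 4) its normal-quantile p-values are anti-conservative —
a known property of the method, inherited by any faithful implementation,
and the reason it is not the subject of the level-calibration checks.

## Known limitations

* Weighted-mode estimates are unstable with very few SNPs (the
  4-instrument design is at the edge of what the method supports).
* The Egger intercept test has low power at small k; its Q statistic uses
  k−2 df.
* No CAUSE-style modelling of correlated pleiotropy, no MR-PRESSO,
  contamination mixture, or multivariable MR; no LD-score regression.
  The correlated-pleiotropy simulation exists precisely to show what the
  included estimators cannot detect.
* Proxy lookup requires a local LD reference; no remote services are
  queried.
* GWAS-by-proxy (parental history) outcomes are analysed identically to
  direct outcomes; their effect scale differs and no correction is
  applied.
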