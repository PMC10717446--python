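# Methods

## Model and assumptions

The package implements two-sample Mendelian randomization for a binary
exposure (ever-use of cannabis) and binary outcomes (coronary artery
disease, ischemic stroke) using only GWAS summary statistics. Each SNP
*j* is treated as an instrument with exposure association γⱼ and outcome
association Γⱼ, both additive per-allele effects on the log-odds scale,
estimated in two non-overlapping samples. Under the three instrumental
assumptions (relevance, independence from confounders, exclusion
restriction), Γⱼ = θ·γⱼ and the Wald ratio Γ̂ⱼ/γ̂ⱼ estimates the causal
effect θ — a log-OR of the outcome per 1-log-odds-unit increase in
genetically indexed liability to the exposure. Instruments are assumed
pre-clumped: linkage disequilibrium is an input-level annotation and is
never computed.

## Estimators and numerical choices

**Wald ratio SE.** The default is the first-order delta approximation
σ_Γ/|γ̂| (the exposure effect treated as known). This is the standard
weighting convention: inverse-variance pooling of ratios then coincides
algebraically with the weighted regression of Γ̂ on γ̂ through the origin,
and it avoids the extra weak-instrument bias that γ̂-dependent weights
introduce (the full delta SE puts γ̂ in the weights twice, and the
correlation between weight and ratio error biases the pooled estimate
measurably at realistic instrument strength). The two-term delta SE
√(σ_Γ²/γ̂² + Γ̂²σ_γ²/γ̂⁴) is available via `wald_ratio(...,
second_order=True)` for per-SNP reporting.

**Pooling.** Fixed-effects IVW and DerSimonian–Laird random effects are
implemented directly from the moment formulas (they are the object under
study); `statsmodels.stats.meta_analysis.combine_effects` serves as an
independent oracle in the tests, never as the implementation. Confidence
intervals and p-values use the normal reference distribution throughout,
consistent with standard two-sample MR practice; ratio-scale results are
`exp`-transformed on output.

**MR-Egger.** Instruments are re-oriented so every γ̂ⱼ ≥ 0 (the fit is
otherwise not invariant to allele labelling; re-orientation flips Γ̂ⱼ with
γ̂ⱼ, leaving ratios unchanged). Weights are 1/σ_Γⱼ². SEs come from
resampling SNPs with replacement, 10,000 draws by default; `n_boot=0`
falls back to analytic WLS SEs with a multiplicative overdispersion factor
floored at 1. I²_GX is computed on the oriented effects with weights
1/σ_γⱼ². SIMEX uses the grid λ ∈ {0, 0.5, 1, 1.5, 2}, 1,000 simulations
per λ, a quadratic extrapolant to λ = −1 (standard SIMEX practice; the
grid and simulation count balance desk-scale runtime against extrapolation
stability), and a 200-draw SNP bootstrap for its SE by default.

**Weighted median.** Ratios are sorted; each carries normalized
inverse-variance weight wⱼ′ at cumulative-midpoint percentile
pⱼ = Σᵢ≤ⱼwᵢ′ − wⱼ′/2, and the estimate interpolates linearly at p = 0.5
(clamped to the extreme ratios outside [p₁, p_k]). The SE is a parametric
bootstrap drawing θ̂ⱼ* ~ N(θ̂ⱼ, σⱼ²), 10,000 draws by default.

**Steiger.** Per-SNP variance explained is recovered from the Wald z as
r² = z²/(z² + n − 2) on the observed log-odds scale for both traits
(liability-scale conversion is out of scope; this is a documented choice,
not an inference about how any particular analysis derived it). The
per-SNP test compares Fisher-transformed correlations from the two
independent samples; the overall test applies the same comparison to the
aggregate correlation √(Σr²) per side, valid under instrument
independence.

**Multivariable MR.** Weighted least squares of Γ̂ on (γ̂_cannabis,
γ̂_tobacco) with weights 1/σ_Γ² and no intercept; instruments missing
from the covariate dataset are dropped and counted, never imputed. A
rank-deficient (collinear) design raises an explicit estimation error;
the degenerate all-zero covariate column reduces, by construction, to the
regression-form IVW fit. SEs from a 10,000-draw SNP bootstrap.

**Observational arm.** Study ORs/HRs/RRs are pooled on a common log scale
without conversion. SEs are recovered from 95% CIs as
(ln U − ln L)/(2·1.96); intervals whose log-asymmetry exceeds 15% of the
half-width are rejected — they cannot come from a symmetric Wald interval.
The funnel test regresses effects on their SEs with inverse-variance
weights and an intercept, reporting the SE-coefficient with t-based
inference (study counts are small); the algebraically equivalent
precision-regression form is available behind a flag. The between-group
test is the two-group inverse-variance Q against χ²(1).

**Population-scale transform.** The MR estimate is per 1-log-odds-unit of
exposure liability, not per ever- vs never-user. The module applies a
monotone linear rescaling of the log-OR (point, SE and CI bounds all
multiplied by a contrast factor c, leaving z and p invariant — hence
null-preserving, order-preserving, and CI-width-consistent). c is either
supplied directly (`exposure_contrast`, for analyses whose calibration is
known) or derived from the exposure prevalence P as 1/(P(1−P)), the
probability-scale calibration of a binary exposure instrumented on the
log-odds scale. The outcome-risk parameters (population risk K, never-user
risk K₀) are validated for internal consistency via the implied ever-user
risk K₁ = (K − (1−P)K₀)/P ∈ (0,1). All three are configuration inputs;
nothing is hard-coded.

**Power.** The binary-outcome power approximation
Φ(|ln OR|·√(N·R²·K(1−K)) − z₁₋α/₂) is adopted as the standard
non-centrality form; it is symmetric in cases/controls and returns α at
OR = 1 (with a warning).

## Harmonization rules

rsID is the sole join key. When the outcome's effect allele equals the
exposure's other allele — directly or after strand complement — the
outcome beta is sign-flipped and its frequency complemented; strand
complement is always attempted before declaring a mismatch, because
outcome consortia strand conventions are generally unverifiable.
Irreconcilable SNPs are excluded with an explicit reason, never silently
kept. Palindromic (A/T, C/G) SNPs are flagged; the optional ambiguity
filter removes them when |EAF − 0.5| < 0.08 (a conventional window) or
when their frequency is missing (conservative). Instrument selection
removes listed discordant rsIDs, applies the exposure p-value threshold
(5×10⁻⁵ lenient default; 5×10⁻⁸ flags the genome-wide-significant
subset), and reports counts at every step rather than hard-coding any
instrument number.

## What the synthetic generator emulates — and what it does not

`simulate_two_sample` draws allele frequencies uniformly on (0.05, 0.5),
half-normal exposure-effect magnitudes rescaled so the instruments jointly
explain exactly `total_r2` (default 1%) with random signs, and emits
estimates around the truth with the analytic SEs 1/√(2np(1−p)) and
√((1/n_cases + 1/n_controls)/(2p(1−p))). Default sample sizes mirror the
cannabis/CAD design (184,765; 60,801/123,504; tobacco 1,232,091).
Directional pleiotropy is drawn N(μ_α, σ_α²) *per exposure-increasing
allele* — with random instrument signs an unoriented constant mean would
cancel out of IVW and be invisible to the Egger intercept — optionally
correlated with instrument strength (InSIDE violation) and restricted to
a fraction of SNPs. A correlated secondary exposure supports the
multivariable tests. Seeds are mandatory; there is no hidden global
randomness.

Not emulated: linkage disequilibrium between instruments, sample overlap,
winner's-curse inflation of the discovery effects, liability-scale
subtleties of binary traits, and population stratification. Passing
calibration tests therefore show that the estimators behave correctly
under the stated sampling model, not that any real-data analysis is free
of those additional complications.

## Calibration test design

The Monte-Carlo acceptance checks run the workflow as an analyst would:
harmonization followed by p < 5×10⁻⁵ instrument selection. This matters
for the Egger intercept: an unselected half-normal effect panel contains
near-zero instruments whose estimated orientation flips sign with high
probability, attenuating the measured mean pleiotropy — a real phenomenon,
but one a p-value-selected panel (the only kind this analysis ever feeds
to Egger) does not exhibit. Monte-Carlo sizes are 500 replicates for the
calibration properties and 60 for the SIMEX attenuation-ordering check;
problem sizes throughout the suite are chosen to keep a desk-scale run
comfortable while leaving Monte-Carlo error well below the asserted
margins.

## Known limitations

- Weak-instrument bias of ratio-based IVW is mitigated but not removed by
  the first-order weighting; at the default design (cumulative F ≈ 29)
  the residual attenuation is under 5% of the effect.
- The ever- vs never-user rescaling is a linear log-scale calibration;
  analyses with a published non-linear recipe should supply their own
  contrast factor.
- The Steiger r² approximation is on the observed scale; for rare binary
  outcomes the liability-scale r² can order differently.
- The funnel-asymmetry test has low power with few studies; a
  non-significant coefficient is weak evidence against publication bias.
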