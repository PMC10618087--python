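# Methods

## Model

Two-sample MR treats each instrument SNP *j* as a natural experiment. With
γ_j the SNP→exposure effect (SE σ_γj) from one GWAS and α_j the SNP→outcome
effect (σ_αj) from an independent, non-overlapping GWAS, a valid instrument
(relevant, exchangeable, acting on the outcome only through the exposure)
satisfies α_j = β γ_j, so β is estimable as the Wald ratio α_j/γ_j. With
several instruments the package combines ratios by inverse-variance
weighting, which is identical to the zero-intercept weighted regression of
α on γ with weights w_j = 1/σ_αj²:

    b_IVW = Σ w_j γ_j α_j / Σ w_j γ_j²,   se²_fixed = 1 / Σ w_j γ_j².

Horizontal pleiotropy (a direct SNP→outcome path a_j) breaks the exclusion
restriction; the sensitivity battery targets different violation patterns:
MR-Egger estimates the mean directional pleiotropy as a free intercept
(valid under InSIDE: a_j independent of γ_j), the weighted median is
consistent while valid instruments hold >50% of the weight, the weighted
mode while the largest cluster of similar ratios is valid, MR-PRESSO
detects and removes outlying SNPs, MR-RAPS tolerates weak instruments, and
the Steiger test checks that instruments explain more variance in the
exposure than the outcome.

## Estimation conventions

- **Random-effects IVW** uses multiplicative overdispersion: the SE is
  inflated by max(1, √(Q/(J−1))) with Q Cochran's statistic — never
  deflated. This is the common default of two-sample MR tooling; the
  underdispersed case is treated as sampling noise.
- **Wald ratio SE** is the first-order delta method σ_α/|γ|; the
  second-order term is negligible for instruments that cleared genome-wide
  selection (F ≳ 30) and is omitted.
- **MR-Egger** first orients all SNPs to γ_j ≥ 0 (flipping γ and α jointly),
  then fits the free-intercept weighted regression; its residual scale is
  floored at 1 like the IVW inflation. P-values for all closed-form
  estimators use the normal reference with the exact z quantile
  (1.959964…, not 1.96); report files round to 3 decimals only at output.
- **Weighted median**: the per-SNP ratio at cumulative normalised weight
  0.5, linearly interpolated between adjacent order statistics
  (midpoint-of-mass convention). SE by parametric bootstrap: γ_j, α_j
  redrawn from normals around their observed values, 1,000 replicates by
  default, seeded and bit-reproducible.
- **Weighted mode**: normal-kernel density over ratios with bandwidth
  1.4826·MAD·bandwidth_factor (default factor 1.0), argmax on a
  10,000-point grid spanning the ratios ± 3 bandwidths; zero spread returns
  the common ratio. SE by the same bootstrap.
- **MR-RAPS** solves d/db Σ ρ(t_j) = 0 with
  t_j = (α_j − bγ_j)/s_j, s_j² = σ_αj² + b²σ_γj² + τ², ρ squared or Huber
  (k = 1.345). The score Σ ψ(t_j)(γ_j/s_j + bσ_γj² t_j/s_j²) contains the
  weak-instrument correction term that removes the regression-dilution bias
  of IVW weighting; with σ_γ → 0, squared loss and τ² = 0 it reduces
  exactly to IVW. Overdispersion τ² ≥ 0 solves the moment condition
  mean(ψ(t_j)t_j) = E[ψ(Z)Z] (1 for squared loss, 2Φ(k)−1 for Huber),
  alternating with b; initialisation at IVW, iteration cap 100, tolerance
  1e-10, SE from the sandwich of the estimating equation. An exact fit
  (all residuals zero) falls back to the model-based score variance.
- **MR-PRESSO** compares the observed weighted RSS about leave-one-out IVW
  predictions with parametric simulations under the no-pleiotropy model
  (default n_sim = 1,000); weights are 1/σ_αj², consistent with IVW.
  Outliers are flagged at per-SNP simulation p < 0.05/J (Bonferroni); the
  distortion null resamples 500 random subsets of the flagged size.
  Requires ≥ 4 SNPs and n_sim ≥ 100.
- **Steiger** sums per-SNP variance explained r²_j = t_j²/(t_j² + n − 2)
  over the (pre-clumped, hence approximately independent) instruments and
  compares Fisher-transformed |r| values:
  z = (atanh|r_exp| − atanh|r_out|)/√(1/(n_exp−3) + 1/(n_out−3)). The
  filter drops SNPs with r²_exposure ≤ r²_outcome; both the instrument-set
  and per-SNP granularities are exposed, with the per-SNP comparison
  defining removal.
- **BH-FDR** is the step-up procedure with an explicit family size m ≥ the
  number of computed p-values, so grid cells skipped for lack of
  instruments still count. The default family is one direction of the grid
  at one threshold tier (the 5 × 11 = 55-cell design); an overall family is
  configurable. Re-adjusting adjusted values is intentionally not the
  identity — each step-up term gains a factor m/j ≥ 1 — so reports always
  carry raw and adjusted values side by side.

## Harmonisation and instruments

Outcome effects are aligned to the exposure's effect allele: identical
allele pair taken as is, swapped pair sign-flipped, strand-complement pairs
complemented first. Palindromic SNPs (A/T, C/G) cannot be strand-resolved
from labels; they are kept only when both EAFs are known, on the same side
of 0.5 and outside [0.42, 0.58] (the `palindrome_eaf_limit=0.42` default),
else dropped. Proxies (r² > 0.8, best-r² with lexicographic tie-break) are
accepted only when their allele labels reconcile exactly, since the LD
reference stores no allele phase. Clumping is greedy and p-value-ordered at
r² > 0.001; no genomic-distance window is used because the data model
carries no positions (a deliberate divergence from position-aware clumpers,
documented here). Thresholding is strict (p < threshold).

## Simulation presets

Summary statistics are simulated directly on the effect scale — two-sample
MR never touches individual-level data, so nothing is lost at desk scale.
For SNP j with frequency f_j ~ U(0.1, 0.9): γ_j = γ_min + |N(0, γ_sd²)|
(effect alleles coded as the exposure-increasing allele, as instruments are
reported after selection), α_j = βγ_j + a_j, observed values add
independent noise with σ_γj = (2f_j(1−f_j)n_exp)^(−1/2) and the outcome
analogue; binary outcomes use the effective size n·φ(1−φ)/0.25 for case
fraction φ (a log-odds approximation adequate for estimator testing, not a
liability model). Exposure and outcome noise come from separate substreams
of the seeded generator (non-overlapping samples). Reverse mode routes the
SNP effects through the outcome trait instead.

Presets (J = SNPs, n = 100k per GWAS, γ_sd = 0.04, mean F ≈ 65 unless
noted): `null` (β = 0), `causal` (β = 0.1, J = 50), `balanced`
(a ~ N(0, 0.02²) on all SNPs), `directional` (a ~ N(0.02, 0.005²), all
SNPs, γ_min = 0.03 so no instrument is sign-ambiguous — orientation on
noisy observed signs would otherwise shrink the recoverable intercept),
`inside_violation` (half the SNPs gain a confounder path δ ~ N(0, γ_sd²)
entering both γ and a with loading 2.0; γ_min = 0.05 because the Egger
intercept displacement under correlated pleiotropy is −bias(slope)·mean(γ)
and vanishes for small mean γ), `forty_pct_invalid` (directional a with
mean 0.05 on 40% of SNPs), `outlier_spike` (J = 8, γ = 0.06 + |N(0, 0.01²)|,
one SNP's α inflated by 10σ_α: with homogeneous instrument-grade effects the
spike shifts IVW by ≈ 10/√J ≈ 3.5 SEs, so outlier removal demonstrably
improves the estimate; heterogeneous or larger panels dilute the shift
below sampling noise), `weak_instruments` (J = 200, γ_sd = 0.01, mean
F ≈ 5), `reverse` (β = 0.3 from outcome to exposure).

What the generator does **not** emulate: real LD beyond block-constant r²,
allele-frequency–dependent architectures, sample overlap, population
stratification, winner's curse in instrument discovery, or liability-scale
case-control effects. Passing tests therefore certify the estimators and
pipeline mechanics, not robustness to those real-data complications.

## Numerical and reporting choices

Confidence intervals are normal-theory at the exact quantile; odds ratios
exponentiate b and its bounds; standardised betas for continuous outcomes
are plain SD rescaling with user-supplied scales and flagged
"unstandardised" otherwise (no published conversion formula is assumed).
Q p-values use the asymptotic chi-square reference without small-sample
correction. All stochastic components (bootstrap, PRESSO, simulation) take
explicit seeds and are bit-reproducible; the study pipeline derives one
seed per grid cell from the run seed.

The test suite and `scripts/acceptance.py` use scaled study conditions
chosen as desk-scale defaults: 2,000 replicates for type-I-error
calibration, 500 for causal recovery and Egger-intercept recovery, 300 for
robustness-bias comparisons, 200 for outlier flagging (PRESSO n_sim = 400
there; the library default stays 1,000), 100 for direction reversal.

## Limitations

Single-SNP analyses inherit all Wald-ratio caveats; no multivariable MR,
correlated-instrument IVW, CAUSE or contamination-mixture estimators; no
LD computation from genotypes, liftover, or remote proxy services
(variant-id equality is the join key); heritability metadata is accepted,
never estimated. The Huber variant of RAPS uses the standard influence
truncation without the exact simultaneous overdispersion theory of the
full published estimator family.
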