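# Methods

## Model and assumptions

`mrpipe` performs two-sample summary-data Mendelian randomization. The
structural assumption is the standard instrumental-variable triad: each SNP
used as an instrument is (i) associated with the exposure, (ii) independent
of exposure–outcome confounders, and (iii) affects the outcome only through
the exposure. Analysis operates entirely on per-SNP (beta, SE) pairs from
two non-overlapping GWAS; individual-level genotypes are never touched.
Binary outcomes are handled on the log-odds scale — estimates exponentiate
to odds ratios per unit of (standardized) exposure.

The per-SNP Wald ratio uses the first-order delta-method SE,
se(Γ̂/γ̂) = σ_Γ/|γ̂|, which ignores the exposure-side noise term
β²σ_γ²/γ̂². This matches common practice and keeps every estimator a
function of the same weights; its consequences are measured rather than
hidden (see *Known limitations*).

## Estimators

* **IVW.** Weighted mean of Wald ratios with weights (γ̂/σ_Γ)². The `auto`
  model computes Cochran's Q first: Q p ≥ 0.05 keeps the fixed-effects SE,
  otherwise the multiplicative random-effects SE se_FE·√(Q/(J−1)), floored
  at se_FE. A single instrument degrades to the Wald ratio with a logged
  note.
* **MR-Egger.** Pairs are oriented so γ̂ ≥ 0 (joint negation of a SNP's two
  effects is an allele re-coding and changes nothing). WLS of Γ̂ on γ̂ with
  intercept and weights 1/σ_Γ²; the residual scale is floored at 1 so SEs
  are never deflated on under-dispersed data; inference uses t with J−2 df.
  The intercept estimates average directional pleiotropy under InSIDE.
* **Weighted median.** Ratios sorted ascending with normalized weights wⱼ;
  the estimate interpolates the curve Sⱼ = Σ_{k≤j} w_k − wⱼ/2 at S = 0.5.
  SE from 1000 (default) parametric bootstrap draws βⱼ* ~ N(βⱼ, seⱼ).
* **Mode-based.** Normal-kernel density over the ratios with bandwidth
  h = φ·0.9·min(sd, IQR/1.34)·J^{−1/5} (φ = 1 by default, exposed in
  config), evaluated on a 512-point grid spanning the ratio range ± 3h;
  the weighted variant weights kernels by normalized (γ̂/σ_Γ)². If all
  ratios coincide the common ratio is returned with the IVW fixed SE.
  SE by the same bootstrap as the weighted median.

All bootstrap operations take an explicit seed (package default 20250721);
the pipeline derives per-pair seeds from the config seed and the trait-pair
labels via CRC32, so re-running a configuration is byte-identical.

## Instrument selection and harmonization

Stage order: p-value threshold → exclusion-list removal → palindromic-SNP
removal → greedy LD clumping → R²/F computation → F > 10 filter. Counts
removed per stage are recorded; selection failing at any stage raises an
error naming that stage. Confounder screening is a static one-rsID-per-line
exclusion list (a reproducible stand-in for interactive trait-lookup
services), and clumping runs against a user-supplied square r² matrix; with
no matrix the input is assumed pre-clumped and a warning is logged. Ties on
p during clumping break by lexicographic rsID, making the output invariant
to input row order.

Per-SNP variance explained defaults to the t-statistic form
r² = t²/(t²+n−2), which needs no allele frequency and makes F = (n−2)r²/(1−r²)
exactly the squared Wald t; the allele-frequency form 2β²·eaf·(1−eaf)
(standardized continuous traits) is available by config. The same t-statistic
r² feeds the Steiger test for both trait types; for binary traits this is an
approximation (no liability-scale correction) and is logged as such.

Harmonization matches SNPs by rsID only. Outcome alleles equal to the
exposure's are kept; swapped alleles negate the outcome beta and complement
its frequency; opposite-strand alleles are complemented and re-tested.
Palindromic (A/T, C/G) SNPs are dropped unconditionally — no
frequency-based rescue — trading power for unambiguous strand alignment.

## Sensitivity battery

Cochran's Q uses the first-order weights (γ̂/σ_Γ)² and a χ²_{J−1} reference.
MR-PRESSO computes the observed residual sum of squares around
leave-one-out IVW fits and calibrates it against parametric simulations
drawn from the fitted model; empirical p-values use add-one smoothing
(global p ≥ 1/(n_sim+1), default n_sim = 1000, exposed as `--presso-nsim`);
per-SNP outlier p-values are Bonferroni-scaled; the distortion test compares
the outlier-removed IVW shift against removals of equally many random SNPs.
Steiger compares summed instrument r² on the two traits with a two-sample
Fisher-z test. Result tables drop pairs whose direction flag is false and
flag IVW/Egger sign disagreement, Egger-intercept p < 0.05 and Q p < 0.05.

FDR correction is Benjamini–Hochberg per family, one family per exposure
panel × outcome. `bh_fdr` accepts an explicit family size m larger than the
number of testable p-values (extra tests treated as non-significant) because
published analyses are ambiguous about whether screened-out traits count
toward the family; the pipeline default is m = rows actually tested.

## Synthetic data generator

The generator emulates standardized-trait GWAS: maf ~ Uniform(0.05, 0.5)
(common variants), per-allele SEs 1/√(2n·maf(1−maf)), true instrument
effects γⱼ ~ N(0, 0.05²) rejection-sampled so the expected per-SNP F exceeds
10 (about 1–5% of exposure variance explained by 50 instruments — typical
for molecular-trait panels), observed effects with Gaussian estimation
noise, and default sample sizes of 50,000. Mediation triads default to path
effects matching the worked mediation example (total −0.333, paths 0.191 and
−0.124, true mediated proportion 7.11%); the direct path is set so the total
is exact, and an independent, equally sized instrument set drives the
mediator.

Directional pleiotropy is planted relative to the exposure-increasing
allele: Γⱼ = βγⱼ + sign(γⱼ)·αⱼ. Allele coding is arbitrary (γ is symmetric
around zero), so a coding-invariant definition is the only one under which
"mean pleiotropy μ" biases IVW in a fixed direction and is recoverable by
MR-Egger's oriented regression. In robustness studies α ~ N(μ, μ²)
(coefficient of variation 1): invalid instruments in real data differ in
their pleiotropic effects, and with degenerate constant pleiotropy the
weighted median provably sits at a fixed quantile of the valid-ratio
distribution and loses most of its advantage over IVW.

What the generator does **not** emulate: LD between instruments beyond the
synthetic block matrices, winner's curse from discovery-based selection,
sample overlap between the two GWAS, liability-scale effects for binary
traits, or allele-frequency differences between studies. Passing tests
therefore validate the estimators and the pipeline logic under the stated
generative model, not robustness to those real-data complications.

## Simulation study sizes and measured behaviour

The calibration studies (`mrpipe.calibration`) use 200 replicates for
estimator recovery, robustness and Steiger accuracy, 50 replicates at
n_sim = 500 for MR-PRESSO, and 40 triads for full-pipeline mediation
recovery — sizes at which Monte-Carlo error on a mean is ≈ 0.004 and on a
rate ≈ 1.5–4 percentage points. Bootstrap draws are reduced to 8 inside
these studies since only point estimates are averaged.

Two behaviours of the first-order machinery are worth knowing and are
reproduced deliberately by the test suite:

* Under the clean reference scenario (true β = 0.3, n_exp = n_out), each
  Wald ratio's true variance exceeds the first-order weight by the factor
  1 + β²(σ_γ/σ_Γ)² ≈ 1.09, independent of instrument strength. Cochran's Q
  therefore rejects a true homogeneity null at ≈ 11% instead of 5% whenever
  the causal effect is non-zero and the two GWAS are of similar size; at
  β = 0 the rate is nominal. IVW coverage shows the same mild effect
  (≈ 94%).
* MR-Egger's slope attenuates by ≈ 5–7% of the true effect in the same
  scenario: the γ̂ ≥ 0 orientation folds the instrument-effect distribution,
  leaving little spread in |γ̂| relative to its estimation noise
  (I²_GX ≈ 0.93–0.95), the classic NOME regression-dilution of MR-Egger.

## Known limitations

No multivariable MR (mediation is univariable two-step; mediated
proportions outside [0, 100]% are reported with a warning, without SE or
CI). No proxy-SNP substitution or reference-panel LD estimation. No
GWAS-VCF parsing, liftover, or remote download of the accession IDs that
real analyses would use. The direction-consistency exclusion between IVW
and MR-Egger is a sign comparison only.
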