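# mrpipe

Two-sample bidirectional Mendelian randomization (MR) and two-step mediation
analysis on GWAS summary statistics.

`mrpipe` is for epidemiologists and statistical geneticists who want to test
whether a circulating biomarker (e.g. an inflammatory protein) causally
affects a disease, whether the disease feeds back on the biomarker, and
whether a third trait (e.g. an immune-cell phenotype) mediates the pathway —
using nothing but published per-SNP association tables. It implements the
whole workflow as a tested library plus a thin `mr` command line, and ships a
synthetic GWAS generator with known ground truth so every stage can be
validated without downloading any real GWAS.

## The method

For SNP *j*, let γ̂ⱼ (SE σ_{γj}) be its effect on the exposure and Γ̂ⱼ
(SE σ_{Γj}) its effect on the outcome, harmonized to a common effect allele.
Each SNP gives a Wald ratio β̂ⱼ = Γ̂ⱼ/γ̂ⱼ. The primary estimator is
inverse-variance weighted (IVW) meta-analysis with first-order weights
wⱼ = (γ̂ⱼ/σ_{Γj})²:

    β_IVW = Σ wⱼ β̂ⱼ / Σ wⱼ ,   se_FE = (Σ wⱼ)^{-1/2}

with a multiplicative random-effects SE, se_FE·√(Q/(J−1)), when Cochran's
Q = Σ wⱼ(β̂ⱼ − β_IVW)² flags heterogeneity (p < 0.05). Supplementary
estimators with different identifying assumptions: MR-Egger (WLS of Γ̂ on γ̂
with a free intercept estimating directional pleiotropy), the weighted
median (consistent if ≥50% of weight is valid), and simple/weighted
mode-based estimators (kernel-density mode of the ratios).

Instrument selection applies, in order: significance threshold (5×10⁻⁶ for
molecular exposure panels, 1×10⁻⁵ for immune-cell panels, 5×10⁻⁸ for
diseases as exposures) → confounder exclusion list → palindromic-SNP removal
→ greedy LD clumping (10,000 kb window, r² < 0.001, against a user-supplied
LD matrix) → per-SNP F-statistic filter, F = (n−2)r²/(1−r²) > 10 with
r² = t²/(t²+n−2).

The sensitivity battery per pair: Cochran's Q, the MR-Egger intercept test,
MR-PRESSO (simulation-based global/outlier/distortion residual tests),
leave-one-out IVW, and the MR-Steiger directionality test (instruments must
explain more variance in the exposure than in the outcome). IVW p-values are
Benjamini–Hochberg adjusted per exposure panel × outcome family; pairs
failing Steiger or with IVW/Egger sign disagreement are excluded.

Mediation uses two-step MR and the product of coefficients: with total
effect β, exposure→mediator effect β₁ and mediator→outcome effect β₂, the
indirect effect is β₁β₂ and the mediated proportion β₁β₂/β.

## Worked example

```python
import mrpipe as mp

scenario = mp.SimScenario(seed=7, n_snps=40, true_beta=0.3)
exposure, outcome, truth = mp.simulate_sumstats_pair(scenario)
pairs = mp.harmonize(exposure, outcome)

for fn in (lambda p: mp.ivw(p), mp.egger, lambda p: mp.weighted_median(p, seed=1)):
    e = fn(pairs)
    print(f"{e.method:>16}: beta={e.beta:.3f}  se={e.se:.3f}  OR={e.or_value:.2f} "
          f"[{e.ci_low:.3f}, {e.ci_high:.3f}]  p={e.pval:.2e}")
q, df, qp = mp.cochran_q(pairs)
st = mp.steiger_direction(pairs)
print(f"Cochran Q={q:.1f} (df={df}, p={qp:.2f}); "
      f"Steiger r2_exp={st.r2_exp:.4f} r2_out={st.r2_out:.4f} correct={st.correct_causal_direction}")
med = mp.mediation_effects(-0.333, 0.191, -0.124)
print(f"indirect={med.indirect:.4f}  mediated proportion={med.proportion_pct:.2f}%")
```

prints

```
          ivw_fe: beta=0.258  se=0.021  OR=1.29 [0.217, 0.299]  p=3.04e-35
           egger: beta=0.275  se=0.051  OR=1.32 [0.171, 0.379]  p=4.31e-06
 weighted_median: beta=0.248  se=0.031  OR=1.28 [0.187, 0.308]  p=1.07e-15
Cochran Q=40.9 (df=39, p=0.39); Steiger r2_exp=0.0460 r2_out=0.0039 correct=True
indirect=-0.0237  mediated proportion=7.11%
```

All three estimators recover the planted causal effect 0.3 within sampling
error; Q finds no heterogeneity (none was planted); Steiger confirms the
simulated causal direction. The last line is the product-of-coefficients
decomposition for a total effect of −0.333 with path effects 0.191 and
−0.124: the mediator carries −0.0237 of the effect, i.e. 7.11% of the total.

The same analyses run from the shell:

```bash
mr simulate --kind triad --seed 11 --out sim
mkdir -p exp med && cp sim/exposure.tsv exp/ && cp sim/mediator.tsv med/
mr mediate --exposures exp --mediators med --outcome sim/outcome.tsv --out results --seed 5
mr pair --exposure sim/exposure.tsv --outcome sim/outcome.tsv --out pair_results --plot
```

`results/mediation.tsv` holds one row per surviving triad with columns
`exposure mediator outcome beta_total beta1 beta2 indirect proportion_pct`;
`estimates.tsv`, `sensitivity.tsv`, `audit.tsv` and `run.log` carry the full
per-pair results and the stage-by-stage audit trail. Real GWAS tables in any
column dialect are read via `--column-map map.yaml`.

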