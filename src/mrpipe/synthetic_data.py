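"""Synthetic GWAS summary statistics with known ground truth.

Generates the (beta, se, p, n, eaf) tables that two-sample MR consumes,
under a linear structural model on standardized traits:

* per-SNP allele frequency maf_j ~ Uniform(maf_range);
* true instrument effects gamma_j ~ N(0, gamma_sd^2), rejection-sampled so
  the true per-SNP F-statistic passes the weak-instrument bound in
  expectation;
* standard errors follow the standardized-trait form
  se = 1/sqrt(2 n maf (1-maf));
* observed effects are the true effects plus Gaussian estimation noise;
* outcome effects are true_beta*gamma_j plus optional pleiotropy and
  heterogeneity.

Directional pleiotropy is planted relative to the exposure-increasing
allele, i.e. Gamma_j gains sign(gamma_j)*alpha_j: allele coding is arbitrary
here (gamma is symmetric around zero), so a coding-invariant definition is
the only one under which "mean pleiotropy mu" is recoverable by MR-Egger's
oriented regression and biases IVW in a fixed direction.

Mediation triads share one rsID namespace across exposure, mediator and
outcome tables: exposure instruments propagate as beta1*gamma_j to the
mediator and true_beta*gamma_j to the outcome (direct path chosen so the
total is exactly true_beta), while an independent set of mediator
instruments carries delta_k to the mediator and beta2*delta_k to the
outcome, with null exposure effects.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import LdMatrix
from .sumstats_io import SumStats

#: non-palindromic ordered allele pairs assigned cyclically to simulated SNPs
_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
                 ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G")]

_P_FLOOR = 1e-300


@dataclass
class SimScenario:
    """Generative conditions for one simulated study.

    Defaults mirror the study conditions the pipeline is meant for: GWAS of
    tens of thousands of samples, ~50 independent instruments, common
    variants, and mediation path effects at the magnitudes of the worked
    mediation example (total -0.333, exposure->mediator 0.191,
    mediator->outcome -0.124).  ``seed`` is mandatory.
    """

    seed: int
    n_snps: int = 50
    n_exp: int = 50_000
    n_med: int = 50_000
    n_out: int = 50_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    true_beta: float = -0.333
    true_beta1: float = 0.191
    true_beta2: float = -0.124
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    invalid_fraction: float = 0.0
    heterogeneity_sd: float = 0.0
    gamma_sd: float = 0.05
    min_f: float = 10.0

    def __post_init__(self) -> None:
        if not (0 <= self.invalid_fraction <= 1):
            raise ValueError("invalid_fraction must lie in [0, 1]")
        if min(self.n_exp, self.n_med, self.n_out) <= 3:
            raise ValueError("all sample sizes must exceed 3")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be a sub-interval of (0, 0.5]")
        if self.n_snps < 1:
            raise ValueError("n_snps must be positive")


def _se_standardized(n: float, maf: np.ndarray) -> np.ndarray:
    """SE of a per-allele effect on a standardized trait: 1/sqrt(2 n maf(1-maf))."""
    return 1.0 / np.sqrt(2.0 * n * maf * (1.0 - maf))


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return np.clip(2.0 * stats.norm.sf(np.abs(beta) / se), _P_FLOOR, 1.0)


def _draw_instruments(rng, J, n, maf_range, gamma_sd, min_f):
    """maf, se and true effects, rejection-sampled for expected F > min_f."""
    maf = rng.uniform(maf_range[0], maf_range[1], size=J)
    se = _se_standardized(n, maf)
    thr = np.sqrt(min_f) * se
    gamma = rng.normal(0.0, gamma_sd, size=J)
    bad = np.abs(gamma) < thr
    while bad.any():
        gamma[bad] = rng.normal(0.0, gamma_sd, size=int(bad.sum()))
        bad = np.abs(gamma) < thr
    return maf, se, gamma


def _table(trait_id, trait_type, rsids, chrom, pos, ea, oa, maf, beta, se, n) -> SumStats:
    df = pd.DataFrame(
        dict(rsid=rsids, chrom=chrom, pos=pos, ea=ea, oa=oa, eaf=maf,
             beta=beta, se=se, pval=_two_sided_p(beta, se), n=float(n))
    )
    return SumStats(trait_id=trait_id, trait_type=trait_type, df=df)


def _snp_annotations(J: int, prefix: str = "rs", offset: int = 0):
    rsids = [f"{prefix}{i + 1:05d}" for i in range(J)]
    chrom = ["1"] * J
    pos = [(offset + i + 1) * 50_000 for i in range(J)]
    ea = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)][0] for i in range(J)]
    oa = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)][1] for i in range(J)]
    return rsids, chrom, pos, ea, oa


def simulate_sumstats_pair(s: SimScenario) -> tuple[SumStats, SumStats, dict]:
    """One exposure GWAS, one outcome GWAS, and the latent truth record."""
    rng = np.random.default_rng(s.seed)
    J = s.n_snps
    maf, se_g, gamma = _draw_instruments(rng, J, s.n_exp, s.maf_range, s.gamma_sd, s.min_f)
    se_G = _se_standardized(s.n_out, maf)

    n_invalid = int(round(s.invalid_fraction * J))
    invalid = np.zeros(J, dtype=bool)
    invalid[rng.choice(J, size=n_invalid, replace=False)] = True
    alpha = np.where(invalid, rng.normal(s.pleiotropy_mean, s.pleiotropy_sd, size=J), 0.0)

    Gamma_true = s.true_beta * gamma + np.sign(gamma) * alpha
    if s.heterogeneity_sd > 0:
        Gamma_true = Gamma_true + rng.normal(0.0, s.heterogeneity_sd, size=J)

    gamma_hat = gamma + se_g * rng.standard_normal(J)
    Gamma_hat = Gamma_true + se_G * rng.standard_normal(J)

    rsids, chrom, pos, ea, oa = _snp_annotations(J)
    exposure = _table("sim_exposure", "continuous", rsids, chrom, pos, ea, oa, maf, gamma_hat, se_g, s.n_exp)
    outcome = _table("sim_outcome", "binary", rsids, chrom, pos, ea, oa, maf, Gamma_hat, se_G, s.n_out)
    truth = dict(
        scenario=asdict(s), rsid=rsids, maf=maf, gamma=gamma, alpha=alpha,
        invalid=invalid, Gamma_true=Gamma_true, se_gamma=se_g, se_Gamma=se_G,
    )
    return exposure, outcome, truth


def simulate_mediation_triple(s: SimScenario) -> tuple[SumStats, SumStats, SumStats, dict]:
    """Exposure, mediator and outcome GWAS tables for a mediation triad.

    The direct exposure->outcome path is true_beta - true_beta1*true_beta2,
    so the total effect is exactly ``true_beta`` and the true mediated
    proportion is true_beta1*true_beta2/true_beta.
    """
    rng = np.random.default_rng(s.seed)
    J = s.n_snps
    # exposure instruments
    maf_e, se_ge, gamma = _draw_instruments(rng, J, s.n_exp, s.maf_range, s.gamma_sd, s.min_f)
    # independent mediator instruments
    maf_m, se_dm, delta = _draw_instruments(rng, J, s.n_med, s.maf_range, s.gamma_sd, s.min_f)

    rs_e, chrom_e, pos_e, ea_e, oa_e = _snp_annotations(J, prefix="rse")
    rs_m, chrom_m, pos_m, ea_m, oa_m = _snp_annotations(J, prefix="rsm", offset=J)
    rsids = rs_e + rs_m
    chrom = chrom_e + chrom_m
    pos = pos_e + pos_m
    ea, oa = ea_e + ea_m, oa_e + oa_m
    maf = np.concatenate([maf_e, maf_m])

    # true per-SNP effects on each trait, exposure instruments first
    eff_exp = np.concatenate([gamma, np.zeros(J)])
    eff_med = np.concatenate([s.true_beta1 * gamma, delta])
    eff_out = np.concatenate([s.true_beta * gamma, s.true_beta2 * delta])

    se_exp = _se_standardized(s.n_exp, maf)
    se_med = _se_standardized(s.n_med, maf)
    se_out = _se_standardized(s.n_out, maf)

    obs_exp = eff_exp + se_exp * rng.standard_normal(2 * J)
    obs_med = eff_med + se_med * rng.standard_normal(2 * J)
    obs_out = eff_out + se_out * rng.standard_normal(2 * J)

    exposure = _table("sim_exposure", "continuous", rsids, chrom, pos, ea, oa, maf, obs_exp, se_exp, s.n_exp)
    mediator = _table("sim_mediator", "continuous", rsids, chrom, pos, ea, oa, maf, obs_med, se_med, s.n_med)
    outcome = _table("sim_outcome", "binary", rsids, chrom, pos, ea, oa, maf, obs_out, se_out, s.n_out)
    truth = dict(
        scenario=asdict(s), rsid=rsids, maf=maf, gamma=gamma, delta=delta,
        eff_exp=eff_exp, eff_med=eff_med, eff_out=eff_out,
        indirect=s.true_beta1 * s.true_beta2,
        proportion=s.true_beta1 * s.true_beta2 / s.true_beta,
    )
    return exposure, mediator, outcome, truth


def simulate_ld_blocks(
    n_snps: int,
    block_size: int,
    within_r2: float,
    seed: int | None = None,
    rsids: Sequence[str] | None = None,
) -> LdMatrix:
    """Block-diagonal LD matrix: ``within_r2`` inside blocks, 0 between.

    rsIDs default to the naming used by :func:`simulate_sumstats_pair`, so
    the matrix lines up with a simulated pair of the same size.  ``seed`` is
    accepted for interface symmetry; the structure is deterministic.
    """
    if n_snps % block_size:
        raise ValueError("block_size must divide n_snps")
    if not (0 <= within_r2 <= 1):
        raise ValueError("within_r2 must lie in [0, 1]")
    blocks = n_snps // block_size
    r2 = np.kron(np.eye(blocks), np.full((block_size, block_size), within_r2))
    np.fill_diagonal(r2, 1.0)
    if rsids is None:
        rsids = [f"rs{i + 1:05d}" for i in range(n_snps)]
    return LdMatrix(rsids=list(rsids), r2=r2)


def truth_frames(truth: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten a truth record into per-SNP and scalar-parameter tables."""
    per_snp = {k: v for k, v in truth.items()
               if isinstance(v, (list, np.ndarray)) and len(v) == len(truth["rsid"])}
    scalars = {k: v for k, v in truth.items() if np.isscalar(v)}
    scalars.update({f"scenario_{k}": v for k, v in truth["scenario"].items() if np.isscalar(v)})
    snp_df = pd.DataFrame(per_snp)
    par_df = pd.DataFrame([scalars])
    return snp_df, par_df
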