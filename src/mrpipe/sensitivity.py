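"""Sensitivity diagnostics for one exposure–outcome MR pair.

Heterogeneity (Cochran's Q), horizontal pleiotropy (MR-Egger intercept),
pleiotropic outliers (MR-PRESSO global/outlier/distortion tests), influence
(leave-one-out IVW) and directionality (MR-Steiger) — the battery run after
the point estimators to decide whether a nominal causal pair is trustworthy.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import estimators as est
from .harmonize import HarmonizedPairs
from .instruments import snp_r2

logger = logging.getLogger(__name__)


def cochran_q(pairs: HarmonizedPairs) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity test on the per-SNP Wald ratios.

    Q = sum_j w_j (beta_j - beta_IVW)^2 with beta_j = Gamma_j/gamma_j and
    first-order weights w_j = (gamma_j/se_Gamma_j)^2; p is the upper tail of
    chi-square with J-1 df.  Q p < 0.05 is read as heterogeneity.
    """
    if pairs.nsnp < 2:
        raise ValueError("Cochran's Q requires at least 2 SNPs")
    g, G, sG = pairs.gamma, pairs.Gamma, pairs.se_Gamma
    w = (g / sG) ** 2
    ratios = G / g
    beta = float(np.sum(w * ratios) / np.sum(w))
    Q = float(np.sum(w * (ratios - beta) ** 2))
    df = pairs.nsnp - 1
    return Q, df, float(stats.chi2.sf(Q, df))


def egger_intercept_test(pairs: HarmonizedPairs) -> tuple[float, float, float]:
    """MR-Egger intercept as a horizontal-pleiotropy test.

    Delegates to the MR-Egger estimator; an intercept p > 0.05 is evidence
    against directional pleiotropy.
    """
    e = est.egger(pairs)
    return e.intercept, e.intercept_se, e.intercept_p


@dataclass
class PressoResult:
    global_p: float
    outliers: list[str]
    distortion_p: float
    outlier_p: Optional[np.ndarray] = None
    skipped: bool = False


def mr_presso(
    pairs: HarmonizedPairs,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int = est.DEFAULT_SEED,
) -> PressoResult:
    """MR-PRESSO residual test for pleiotropic outliers.

    The observed statistic is RSS = sum_j w_j (Gamma_j - beta_(-j) gamma_j)^2
    with w_j = 1/se_Gamma_j^2 and beta_(-j) the IVW estimate leaving SNP j
    out.  The null distribution comes from ``n_sim`` parametric simulations
    drawing gamma* ~ N(gamma, se_gamma) and Gamma* ~ N(beta_(-j) gamma,
    se_Gamma) and recomputing RSS the same way.  Empirical p-values use
    add-one smoothing, so global_p >= 1/(n_sim+1).  Per-SNP outlier p-values
    are Bonferroni-scaled by J.  The distortion test compares the
    outlier-removed IVW estimate against estimates after removing equally
    many random SNPs.  Fewer than 4 SNPs: skipped with a logged note.
    """
    if pairs.nsnp < 4:
        logger.info("mr_presso: skipped (%d < 4 SNPs)", pairs.nsnp)
        return PressoResult(np.nan, [], np.nan, skipped=True)
    rng = np.random.default_rng(seed)
    g, sg, G, sG = pairs.gamma, pairs.se_gamma, pairs.Gamma, pairs.se_Gamma
    J = pairs.nsnp
    sG2 = sG**2
    w = 1.0 / sG2

    num, den = g * G / sG2, g * g / sG2
    beta_loo = (num.sum() - num) / (den.sum() - den)
    r_obs = w * (G - beta_loo * g) ** 2
    rss_obs = r_obs.sum()

    gs = g + sg * rng.standard_normal((n_sim, J))
    Gs = beta_loo * g + sG * rng.standard_normal((n_sim, J))
    nums, dens = gs * Gs / sG2, gs * gs / sG2
    bloo = (nums.sum(axis=1, keepdims=True) - nums) / (dens.sum(axis=1, keepdims=True) - dens)
    r_sim = w * (Gs - bloo * gs) ** 2
    rss_sim = r_sim.sum(axis=1)

    global_p = (1.0 + float((rss_sim >= rss_obs).sum())) / (n_sim + 1.0)
    outlier_p = np.minimum(1.0, (1.0 + (r_sim >= r_obs).sum(axis=0)) / (n_sim + 1.0) * J)
    out_mask = outlier_p < outlier_alpha
    outliers = list(pairs.df["rsid"][out_mask])

    distortion_p = np.nan
    k = int(out_mask.sum())
    if 0 < k < J - 1:
        beta_full, _ = est._ivw_fixed(g, G, sG)
        beta_no, _ = est._ivw_fixed(g[~out_mask], G[~out_mask], sG[~out_mask])
        d_obs = abs(beta_no - beta_full)
        keep_idx = np.argsort(rng.random((n_sim, J)), axis=1)[:, : J - k]
        d_rand = np.empty(n_sim)
        for s in range(n_sim):
            b, _ = est._ivw_fixed(g[keep_idx[s]], G[keep_idx[s]], sG[keep_idx[s]])
            d_rand[s] = abs(b - beta_full)
        distortion_p = (1.0 + float((d_rand >= d_obs).sum())) / (n_sim + 1.0)
    return PressoResult(global_p, outliers, distortion_p, outlier_p=outlier_p)


def leave_one_out(pairs: HarmonizedPairs) -> pd.DataFrame:
    """IVW (auto model) on J-1 SNPs, once per left-out SNP.

    Flags rows whose estimate changes sign versus the full IVW, or whose CI
    gains/loses overlap with zero.
    """
    full = est.ivw(pairs, model="auto")
    full_spans_zero = full.ci_low <= 0 <= full.ci_high
    rows = []
    for i in range(pairs.nsnp):
        sub = est.ivw(pairs.drop_snp(i), model="auto")
        spans_zero = sub.ci_low <= 0 <= sub.ci_high
        rows.append(
            dict(
                rsid_left_out=pairs.df["rsid"].iloc[i],
                nsnp=sub.nsnp, beta=sub.beta, se=sub.se,
                ci_low=sub.ci_low, ci_high=sub.ci_high, pval=sub.pval,
                sign_change=bool(np.sign(sub.beta) != np.sign(full.beta)),
                zero_overlap_change=bool(spans_zero != full_spans_zero),
            )
        )
    return pd.DataFrame(rows)


@dataclass
class SteigerResult:
    r2_exp: float
    r2_out: float
    correct_causal_direction: bool
    pval: float


def steiger_direction(
    pairs: HarmonizedPairs,
    n_exp: float | None = None,
    n_out: float | None = None,
) -> SteigerResult:
    """MR-Steiger directionality test.

    Sums the per-SNP variance explained (t-statistic form) across instruments
    for the exposure and for the outcome; the presumed direction is correct
    when the instruments explain more exposure than outcome variance.  The
    p-value is a two-sample Fisher z comparison of the two correlations.
    """
    if pairs.nsnp < 1:
        raise ValueError("Steiger test requires at least 1 SNP")
    n_exp = float(n_exp) if n_exp is not None else pairs.n_exp
    n_out = float(n_out) if n_out is not None else pairs.n_out
    if n_exp <= 3 or n_out <= 3:
        raise ValueError("Steiger test requires sample sizes > 3")
    r2e = float(np.sum(snp_r2(pairs.gamma, se=pairs.se_gamma, n=pairs.df["n_exp"], method="tstat")))
    r2o = float(np.sum(snp_r2(pairs.Gamma, se=pairs.se_Gamma, n=pairs.df["n_out"], method="tstat")))
    r2e_c = min(r2e, np.nextafter(1.0, 0.0))
    r2o_c = min(r2o, np.nextafter(1.0, 0.0))
    z = (np.arctanh(np.sqrt(r2e_c)) - np.arctanh(np.sqrt(r2o_c))) / np.sqrt(
        1.0 / (n_exp - 3.0) + 1.0 / (n_out - 3.0)
    )
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return SteigerResult(r2_exp=r2e, r2_out=r2o, correct_causal_direction=bool(r2e > r2o), pval=p)


@dataclass
class SensitivityReport:
    """Full diagnostic battery for one exposure–outcome pair."""

    exposure: str
    outcome: str
    nsnp: int
    q_stat: float
    q_df: int
    q_p: float
    egger_intercept: float
    egger_intercept_se: float
    egger_intercept_p: float
    presso_global_p: float
    presso_outliers: list[str]
    presso_distortion_p: float
    steiger_r2_exp: float
    steiger_r2_out: float
    correct_causal_direction: bool
    steiger_p: float
    loo: pd.DataFrame = field(repr=False, default=None)

    def to_row(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "loo"}
        d["presso_outliers"] = ";".join(self.presso_outliers)
        return d


def sensitivity_battery(
    pairs: HarmonizedPairs,
    presso_nsim: int = 1000,
    presso_alpha: float = 0.05,
    seed: int = est.DEFAULT_SEED,
) -> SensitivityReport:
    """Run every diagnostic that the instrument count permits.

    Q needs >= 2 SNPs, Egger >= 3, PRESSO >= 4, leave-one-out >= 3; anything
    below its minimum is reported as NaN rather than failing the pair.
    """
    nan3 = (np.nan, np.nan, np.nan)
    q, q_df, q_p = cochran_q(pairs) if pairs.nsnp >= 2 else (np.nan, 0, np.nan)
    icpt, icpt_se, icpt_p = egger_intercept_test(pairs) if pairs.nsnp >= 3 else nan3
    presso = mr_presso(pairs, n_sim=presso_nsim, outlier_alpha=presso_alpha, seed=seed)
    loo = leave_one_out(pairs) if pairs.nsnp >= 3 else pd.DataFrame()
    steiger = steiger_direction(pairs)
    return SensitivityReport(
        exposure=pairs.exposure_id, outcome=pairs.outcome_id, nsnp=pairs.nsnp,
        q_stat=q, q_df=q_df, q_p=q_p,
        egger_intercept=icpt, egger_intercept_se=icpt_se, egger_intercept_p=icpt_p,
        presso_global_p=presso.global_p, presso_outliers=presso.outliers,
        presso_distortion_p=presso.distortion_p,
        steiger_r2_exp=steiger.r2_exp, steiger_r2_out=steiger.r2_out,
        correct_causal_direction=steiger.correct_causal_direction,
        steiger_p=steiger.pval, loo=loo,
    )
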