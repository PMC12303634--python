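"""Causal-effect estimators for two-sample MR on harmonized pairs.

Five estimators, each with a different robustness profile:

* Wald ratio — single-SNP estimate Gamma/gamma, first-order delta-method SE.
* IVW — inverse-variance weighted mean of the per-SNP ratios; fixed-effects
  by default, switching to a multiplicative random-effects SE when Cochran's
  Q flags heterogeneity (the ``auto`` model).
* MR-Egger — weighted regression of Gamma on gamma with a free intercept;
  the slope is the causal estimate and the intercept the average directional
  pleiotropy (requires the InSIDE assumption).
* Weighted median — consistent when at least half of the weight comes from
  valid instruments; SE by parametric bootstrap.
* Mode-based (simple / weighted) — kernel-density mode of the ratio
  estimates; consistent when the largest group of instruments is valid.

All estimators are equivariant under a joint sign flip of (gamma, Gamma).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .harmonize import HarmonizedPairs

logger = logging.getLogger(__name__)

#: default seed for every bootstrap operation
DEFAULT_SEED = 20250721

_Z95 = float(stats.norm.ppf(0.975))


class InsufficientInstrumentsError(ValueError):
    """Too few SNPs for the requested estimator."""


class DegenerateInstrumentError(ValueError):
    """Wald ratio undefined: the exposure effect is zero."""


@dataclass
class MrEstimate:
    """One method's causal estimate with SE, 95% CI, p and odds ratio."""

    method: str
    nsnp: int
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    or_value: float
    intercept: Optional[float] = None
    intercept_se: Optional[float] = None
    intercept_p: Optional[float] = None

    @classmethod
    def from_beta_se(
        cls, method: str, nsnp: int, beta: float, se: float, t_df: int | None = None, **kw
    ) -> "MrEstimate":
        """Build the full estimate from (beta, se).

        CI is beta +/- 1.96*se with the normal quantile, or the t quantile
        with ``t_df`` degrees of freedom (MR-Egger).  p is two-sided.
        """
        if t_df is None:
            crit = _Z95
            p = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else (1.0 if beta == 0 else 0.0)
        else:
            crit = float(stats.t.ppf(0.975, t_df))
            p = 2.0 * stats.t.sf(abs(beta) / se, t_df) if se > 0 else (1.0 if beta == 0 else 0.0)
        return cls(
            method=method, nsnp=nsnp, beta=float(beta), se=float(se),
            ci_low=float(beta - crit * se), ci_high=float(beta + crit * se),
            pval=float(p), or_value=float(np.exp(beta)), **kw,
        )

    def to_row(self) -> dict:
        return asdict(self)


def _arrays(pairs: HarmonizedPairs):
    return pairs.gamma, pairs.se_gamma, pairs.Gamma, pairs.se_Gamma


def _ivw_fixed(g: np.ndarray, G: np.ndarray, sG: np.ndarray) -> tuple[float, float]:
    w = g**2 / sG**2
    beta = float(np.sum(g * G / sG**2) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    return beta, se


def wald_ratio(pairs: HarmonizedPairs) -> MrEstimate:
    """Single-SNP causal estimate: beta = Gamma/gamma, se = se_Gamma/|gamma|."""
    if pairs.nsnp != 1:
        raise ValueError("wald_ratio expects exactly one harmonized SNP")
    g, _, G, sG = (a[0] for a in _arrays(pairs))
    if g == 0:
        raise DegenerateInstrumentError("wald ratio undefined for gamma = 0")
    return MrEstimate.from_beta_se("wald", 1, G / g, sG / abs(g))


def ivw(pairs: HarmonizedPairs, model: str = "auto") -> MrEstimate:
    """Inverse-variance weighted estimate.

    beta = sum(gamma*Gamma/se_Gamma^2) / sum(gamma^2/se_Gamma^2); the
    fixed-effects SE is sqrt(1/sum(gamma^2/se_Gamma^2)).  With
    ``model="auto"`` Cochran's Q decides: Q p >= 0.05 keeps the fixed-effects
    SE, otherwise the multiplicative random-effects SE
    se_fixed*sqrt(Q/(J-1)) (floored at se_fixed) is used.  A single SNP falls
    back to the Wald ratio with a logged note.
    """
    if model not in ("fixed", "random", "auto"):
        raise ValueError(f"unknown IVW model {model!r}")
    if pairs.nsnp < 2:
        logger.info("ivw: single instrument, falling back to Wald ratio")
        return wald_ratio(pairs)
    g, _, G, sG = _arrays(pairs)
    beta, se_fixed = _ivw_fixed(g, G, sG)
    w = g**2 / sG**2
    ratios = G / g
    J = pairs.nsnp
    Q = float(np.sum(w * (ratios - beta) ** 2))
    q_p = float(stats.chi2.sf(Q, J - 1))
    if model == "fixed" or (model == "auto" and q_p >= 0.05):
        return MrEstimate.from_beta_se("ivw_fe", J, beta, se_fixed)
    se = se_fixed * max(1.0, np.sqrt(Q / (J - 1)))
    return MrEstimate.from_beta_se("ivw_re", J, beta, se)


def egger(pairs: HarmonizedPairs) -> MrEstimate:
    """MR-Egger regression: WLS of Gamma on gamma with a free intercept.

    Pairs are first oriented so every gamma >= 0 (joint negation leaves the
    model invariant).  Weights are 1/se_Gamma^2; coefficient SEs use the
    estimated residual scale floored at 1, and p-values come from the t
    distribution with J-2 df.  The intercept estimates average directional
    pleiotropy.
    """
    if pairs.nsnp < 3:
        raise InsufficientInstrumentsError("MR-Egger requires at least 3 SNPs")
    g, _, G, sG = _arrays(pairs)
    flip = np.sign(g)
    flip[flip == 0] = 1.0
    g, G = g * flip, G * flip
    X = sm.add_constant(g)
    fit = sm.WLS(G, X, weights=1.0 / sG**2).fit()
    sigma = float(np.sqrt(fit.scale))
    # residual scale floored at 1: do not deflate SEs on under-dispersed data
    bse = fit.bse / min(1.0, sigma) if sigma > 0 else fit.bse
    J = pairs.nsnp
    icpt, slope = float(fit.params[0]), float(fit.params[1])
    icpt_se, slope_se = float(bse[0]), float(bse[1])
    icpt_p = 2.0 * float(stats.t.sf(abs(icpt) / icpt_se, J - 2)) if icpt_se > 0 else 1.0
    return MrEstimate.from_beta_se(
        "egger", J, slope, slope_se, t_df=J - 2,
        intercept=icpt, intercept_se=icpt_se, intercept_p=icpt_p,
    )


def _weighted_median(b: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(b, kind="mergesort")
    b, w = b[order], w[order]
    w = w / w.sum()
    s = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, s, b))


def weighted_median(
    pairs: HarmonizedPairs, n_boot: int = 1000, seed: int = DEFAULT_SEED
) -> MrEstimate:
    """Weighted-median estimator over per-SNP Wald ratios.

    Ratios beta_j = Gamma_j/gamma_j carry weights w_j = (gamma_j/se_Gamma_j)^2
    normalized to sum to one; the estimate interpolates the weighted ratio
    distribution at cumulative weight 0.5.  The SE is the SD of ``n_boot``
    parametric-bootstrap replicates drawing beta_j* ~ N(beta_j, se_j) with
    se_j the first-order Wald SE; p is two-sided normal.
    """
    if pairs.nsnp < 3:
        raise InsufficientInstrumentsError("weighted median requires at least 3 SNPs")
    g, _, G, sG = _arrays(pairs)
    ratios = G / g
    se_ratio = sG / np.abs(g)
    w = (g / sG) ** 2
    est = _weighted_median(ratios, w)
    rng = np.random.default_rng(seed)
    draws = ratios + se_ratio * rng.standard_normal((n_boot, len(ratios)))
    boot = np.array([_weighted_median(row, w) for row in draws])
    se = float(np.std(boot, ddof=1))
    return MrEstimate.from_beta_se("weighted_median", pairs.nsnp, est, se)


def _kde_mode(b: np.ndarray, w: np.ndarray, phi: float) -> float | None:
    """Argmax of the weighted normal-kernel density over a 512-point grid.

    Returns None when the bandwidth degenerates (all ratios identical)."""
    J = len(b)
    sd = float(np.std(b, ddof=1)) if J > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(b, [75, 25]))) if J > 1 else 0.0
    scales = [x for x in (sd, abs(iqr) / 1.34) if x > 0]
    if not scales:
        return None
    h = phi * 0.9 * min(scales) * J ** (-1.0 / 5.0)
    grid = np.linspace(b.min() - 3 * h, b.max() + 3 * h, 512)
    z = (grid[:, None] - b[None, :]) / h
    dens = (w[None, :] * np.exp(-0.5 * z**2)).sum(axis=1)
    return float(grid[int(np.argmax(dens))])


def mode_based(
    pairs: HarmonizedPairs,
    weighted: bool = True,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int = DEFAULT_SEED,
) -> MrEstimate:
    """Mode-based estimator (simple or weighted).

    The estimate is the mode of a normal-kernel density over the per-SNP
    ratios with bandwidth h = phi * 0.9 * min(sd, IQR/1.34) * J^(-1/5); the
    weighted variant weights each kernel by normalized (gamma/se_Gamma)^2.
    SE via the same parametric bootstrap as the weighted median.  When all
    ratios coincide the common ratio is returned with the IVW fixed-effects
    SE.
    """
    if pairs.nsnp < 3:
        raise InsufficientInstrumentsError("mode-based estimator requires at least 3 SNPs")
    g, _, G, sG = _arrays(pairs)
    ratios = G / g
    se_ratio = sG / np.abs(g)
    J = pairs.nsnp
    if weighted:
        w = (g / sG) ** 2
        w = w / w.sum()
    else:
        w = np.full(J, 1.0 / J)
    method = "weighted_mode" if weighted else "simple_mode"
    est = _kde_mode(ratios, w, phi)
    if est is None:
        _, se_fixed = _ivw_fixed(g, G, sG)
        return MrEstimate.from_beta_se(method, J, float(ratios[0]), se_fixed)
    rng = np.random.default_rng(seed)
    draws = ratios + se_ratio * rng.standard_normal((n_boot, J))
    boot = []
    for row in draws:
        m = _kde_mode(row, w, phi)
        boot.append(m if m is not None else float(row[0]))
    se = float(np.std(np.asarray(boot), ddof=1))
    return MrEstimate.from_beta_se(method, J, est, se)


def estimates_to_frame(estimates, exposure: str | None = None, outcome: str | None = None) -> pd.DataFrame:
    """Tabulate MrEstimate rows in the documented TSV column order."""
    rows = [e.to_row() for e in estimates]
    df = pd.DataFrame(rows)
    df = df.rename(columns={"or_value": "or"})
    cols = ["method", "nsnp", "beta", "se", "ci_low", "ci_high", "or", "pval",
            "intercept", "intercept_se", "intercept_p"]
    df = df[cols]
    if exposure is not None:
        df.insert(0, "exposure", exposure)
    if outcome is not None:
        df.insert(1, "outcome", outcome)
    return df
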