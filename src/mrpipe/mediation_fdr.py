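"""Multiple-testing correction and the two-step mediation calculus.

Exposure panels are screened family-wise with Benjamini–Hochberg FDR (one
family per panel x outcome).  For a surviving exposure–mediator–outcome triad
the indirect effect follows the product-of-coefficients rule: with beta the
total exposure->outcome effect, beta1 the exposure->mediator effect and beta2
the mediator->outcome effect, the indirect effect is beta1*beta2 and the
mediated proportion is beta1*beta2/beta.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def bh_fdr(pvals, m: int | None = None) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    ``m`` optionally fixes the family size to a value larger than the number
    of p-values supplied (e.g. a full trait panel of which only a subset was
    testable); the extra hypothetical tests are treated as non-significant.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("bh_fdr requires at least one p-value")
    if np.any(~np.isfinite(p)) or np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if m is not None and m > p.size:
        padded = np.concatenate([p, np.ones(m - p.size)])
        return multipletests(padded, method="fdr_bh")[1][: p.size]
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class MediationResult:
    """Product-of-coefficients decomposition for one triad."""

    exposure: str
    mediator: str
    outcome: str
    beta_total: float
    beta1: float
    beta2: float
    indirect: float
    proportion: float  # fraction of the total effect; report as percent

    @property
    def proportion_pct(self) -> float:
        return 100.0 * self.proportion

    def to_row(self) -> dict:
        d = asdict(self)
        d.pop("proportion")
        d["proportion_pct"] = self.proportion_pct
        return d


def mediation_effects(
    beta_total: float,
    beta1: float,
    beta2: float,
    exposure: str = "exposure",
    mediator: str = "mediator",
    outcome: str = "outcome",
) -> MediationResult:
    """Indirect effect beta1*beta2 and mediated proportion beta1*beta2/beta.

    A zero total effect leaves the proportion undefined and raises.  Negative
    or >100% proportions are possible in univariable two-step MR and are
    returned as-is with a warning.
    """
    if beta_total == 0:
        raise ValueError("mediated proportion undefined for beta_total = 0")
    indirect = beta1 * beta2
    proportion = indirect / beta_total
    if proportion < 0 or proportion > 1:
        logger.warning(
            "mediated proportion %.1f%% outside [0, 100]%% for %s->%s->%s",
            100 * proportion, exposure, mediator, outcome,
        )
    return MediationResult(
        exposure=exposure, mediator=mediator, outcome=outcome,
        beta_total=float(beta_total), beta1=float(beta1), beta2=float(beta2),
        indirect=float(indirect), proportion=float(proportion),
    )


def build_result_table(
    estimates: pd.DataFrame,
    sensitivity: pd.DataFrame,
    alpha: float = 0.05,
    family_col: str = "family",
    family_m: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annotate per-pair IVW results with FDR, significance and audit flags.

    ``estimates`` carries one row per method per (exposure, outcome) pair with
    at least columns exposure, outcome, method, beta, pval and a family label
    (all exposures of one panel against one outcome form a family).
    ``sensitivity`` carries one row per pair with correct_causal_direction and
    the Egger intercept p.

    Per family, BH-FDR is applied to the primary (IVW, or single-SNP Wald
    fallback) p-values; rows are flagged significant (pFDR < alpha) and
    nominal (p < alpha); Egger/IVW sign disagreement and pleiotropy (Egger
    intercept p < alpha) are flagged.  Pairs whose presumed direction fails
    the Steiger test are dropped from the main table and returned separately
    as the audit.  ``family_m`` optionally maps a family label to a fixed
    family size for the FDR.
    """
    primary = estimates[estimates["method"].str.startswith(("ivw", "wald"))].copy()
    primary = primary.drop_duplicates(subset=["exposure", "outcome"], keep="first")
    eg = estimates[estimates["method"] == "egger"][["exposure", "outcome", "beta"]]
    eg = eg.rename(columns={"beta": "egger_beta"})
    tab = primary.merge(eg, on=["exposure", "outcome"], how="left")
    sens_cols = ["exposure", "outcome", "correct_causal_direction", "egger_intercept_p", "q_p"]
    tab = tab.merge(sensitivity[[c for c in sens_cols if c in sensitivity.columns]],
                    on=["exposure", "outcome"], how="left")

    if family_col not in tab.columns:
        tab[family_col] = "all"
    tab["p_fdr"] = np.nan
    for fam, idx in tab.groupby(family_col).groups.items():
        m = family_m.get(fam) if family_m else None
        tab.loc[idx, "p_fdr"] = bh_fdr(tab.loc[idx, "pval"].to_numpy(), m=m)
    tab["nominal"] = tab["pval"] < alpha
    tab["significant"] = tab["p_fdr"] < alpha
    tab["egger_sign_agree"] = ~(np.sign(tab["egger_beta"]) * np.sign(tab["beta"]) < 0)
    if "egger_intercept_p" in tab.columns:
        tab["pleiotropy_warning"] = tab["egger_intercept_p"] < alpha
    if "q_p" in tab.columns:
        tab["heterogeneity_warning"] = tab["q_p"] < alpha

    direction_ok = tab["correct_causal_direction"].fillna(True).astype(bool)
    audit = tab[~direction_ok].reset_index(drop=True)
    table = tab[direction_ok].reset_index(drop=True)
    if len(audit):
        logger.info("build_result_table: dropped %d pairs failing Steiger direction", len(audit))
    return table, audit
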