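"""Allele harmonization between exposure and outcome summary statistics.

Two-sample MR needs every SNP's exposure effect (gamma) and outcome effect
(Gamma) expressed per copy of the *same* effect allele.  SNPs are matched by
rsID; when the outcome table reports the swapped allele pair the outcome beta
is negated and its frequency complemented; when it reports the opposite
strand, both outcome alleles are complemented first and the match re-tested.
Palindromic (A/T, C/G) SNPs are dropped unconditionally — their strand cannot
be resolved from alleles alone — and irreconcilable allele sets are dropped
as mismatches.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd

from .instruments import InstrumentSet
from .sumstats_io import SumStats, validate_alleles

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

ACTIONS = ("kept", "sign_flipped", "strand_flipped", "dropped_palindromic", "dropped_mismatch", "dropped_missing")


class HarmonizationError(ValueError):
    """No SNP pair survived harmonization."""


def _comp(allele: str) -> str:
    return allele.translate(_COMPLEMENT)


@dataclass
class HarmonizedPairs:
    """Per-SNP exposure/outcome effects aligned to a shared effect allele.

    ``df`` columns: rsid, ea, oa, gamma, se_gamma, Gamma, se_Gamma, n_exp,
    n_out.  ``audit`` records the harmonization action taken for every
    exposure instrument, kept or not.
    """

    exposure_id: str
    outcome_id: str
    df: pd.DataFrame
    audit: pd.DataFrame

    @property
    def nsnp(self) -> int:
        return len(self.df)

    @property
    def gamma(self) -> np.ndarray:
        return self.df["gamma"].to_numpy(dtype=float)

    @property
    def se_gamma(self) -> np.ndarray:
        return self.df["se_gamma"].to_numpy(dtype=float)

    @property
    def Gamma(self) -> np.ndarray:
        return self.df["Gamma"].to_numpy(dtype=float)

    @property
    def se_Gamma(self) -> np.ndarray:
        return self.df["se_Gamma"].to_numpy(dtype=float)

    @property
    def n_exp(self) -> float:
        return float(np.median(self.df["n_exp"]))

    @property
    def n_out(self) -> float:
        return float(np.median(self.df["n_out"]))

    def subset(self, mask) -> "HarmonizedPairs":
        """Pairs restricted to a boolean mask or integer index array."""
        sub = self.df.iloc[np.arange(self.nsnp)[mask]] if np.asarray(mask).dtype != bool else self.df[mask]
        return HarmonizedPairs(self.exposure_id, self.outcome_id, sub.reset_index(drop=True), self.audit)

    def drop_snp(self, i: int) -> "HarmonizedPairs":
        """Pairs with the i-th SNP left out (for leave-one-out analyses)."""
        keep = np.ones(self.nsnp, dtype=bool)
        keep[i] = False
        return self.subset(keep)


def harmonize(exposure: Union[InstrumentSet, SumStats], outcome: SumStats) -> HarmonizedPairs:
    """Align exposure instruments with outcome statistics SNP by SNP.

    ``exposure`` may be an :class:`InstrumentSet` (the usual pipeline path) or
    a raw :class:`SumStats` table (useful on simulated data where every SNP is
    a known instrument).  Raises :class:`HarmonizationError` if nothing is
    kept.
    """
    exp_df = exposure.df
    exposure_id = exposure.trait_id
    out_df = outcome.df.set_index("rsid")

    rows = []
    actions = []
    for e in exp_df.itertuples(index=False):
        action = None
        if e.rsid not in out_df.index:
            action = "dropped_missing"
        elif validate_alleles(e.ea, e.oa) == "palindromic":
            action = "dropped_palindromic"
        else:
            o = out_df.loc[e.rsid]
            oea, ooa = str(o["ea"]).upper(), str(o["oa"]).upper()
            obeta, oeaf = float(o["beta"]), float(o["eaf"]) if pd.notna(o["eaf"]) else np.nan
            if validate_alleles(oea, ooa) == "palindromic":
                action = "dropped_palindromic"
            elif (oea, ooa) == (e.ea, e.oa):
                action = "kept"
            elif (oea, ooa) == (e.oa, e.ea):
                action = "sign_flipped"
                obeta, oeaf = -obeta, 1.0 - oeaf
            elif (_comp(oea), _comp(ooa)) == (e.ea, e.oa):
                action = "strand_flipped"
            elif (_comp(oea), _comp(ooa)) == (e.oa, e.ea):
                # opposite strand and swapped alleles: complement, then flip
                action = "strand_flipped"
                obeta, oeaf = -obeta, 1.0 - oeaf
            else:
                action = "dropped_mismatch"
        actions.append((e.rsid, action))
        if action in ("kept", "sign_flipped", "strand_flipped"):
            rows.append(
                dict(
                    rsid=e.rsid, ea=e.ea, oa=e.oa,
                    gamma=float(e.beta), se_gamma=float(e.se),
                    Gamma=obeta, se_Gamma=float(o["se"]),
                    n_exp=float(e.n), n_out=float(o["n"]),
                )
            )

    audit = pd.DataFrame(actions, columns=["rsid", "action"])
    counts = audit["action"].value_counts().to_dict()
    logger.info("harmonize %s -> %s: %s", exposure_id, outcome.trait_id, counts)
    if not rows:
        raise HarmonizationError(
            f"no SNP pairs kept harmonizing {exposure_id} against {outcome.trait_id}: {counts}"
        )
    df = pd.DataFrame(rows)
    return HarmonizedPairs(exposure_id=exposure_id, outcome_id=outcome.trait_id, df=df, audit=audit)


def swap_roles(pairs: HarmonizedPairs) -> HarmonizedPairs:
    """Exchange exposure and outcome columns (used for directionality checks)."""
    df = pairs.df.rename(
        columns={
            "gamma": "Gamma", "Gamma": "gamma",
            "se_gamma": "se_Gamma", "se_Gamma": "se_gamma",
            "n_exp": "n_out", "n_out": "n_exp",
        }
    )[pairs.df.columns]
    return HarmonizedPairs(pairs.outcome_id, pairs.exposure_id, df, pairs.audit)
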