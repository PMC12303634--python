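"""Instrumental-variable selection for two-sample MR.

Candidate instruments for an exposure are its genome-wide significant SNPs,
thinned to approximate linkage equilibrium by greedy p-value-ordered clumping
(default window 10,000 kb, r^2 < 0.001), screened against a user-supplied
confounder exclusion list, stripped of palindromic variants, and finally
required to be strong instruments (per-SNP F-statistic > 10).

Variance explained per SNP defaults to the t-statistic form
``r2 = t^2 / (t^2 + n - 2)`` with ``t = beta/se``, which needs no allele
frequency; the frequency-based form ``2 beta^2 eaf (1-eaf)`` (standardized
continuous traits) is available when eaf is present.  The F-statistic
``F = (n-2) r2 / (1-r2)`` then equals the squared Wald t under the default.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .sumstats_io import SumStats, validate_alleles

logger = logging.getLogger(__name__)


class EmptyInstrumentsError(ValueError):
    """Instrument selection exhausted the candidate set at some stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(message)
        self.stage = stage


@dataclass
class LdMatrix:
    """Symmetric matrix of squared LD correlations with unit diagonal."""

    rsids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.rsids)
        if self.r2.shape != (k, k):
            raise ValueError("LD matrix shape does not match rsid count")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-8):
            raise ValueError("LD matrix diagonal must be 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise ValueError("LD r2 values must lie in [0, 1]")
        self._index = {r: i for i, r in enumerate(self.rsids)}

    def get(self, a: str, b: str) -> float | None:
        """r^2 between two rsIDs, or None when either is not covered."""
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return None
        return float(self.r2[ia, ib])

    @classmethod
    def read_tsv(cls, path: str | Path) -> "LdMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(rsids=[str(c) for c in df.columns], r2=df.to_numpy(dtype=float))

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.r2, index=self.rsids, columns=self.rsids).to_csv(path, sep="\t")


@dataclass
class InstrumentSet:
    """Selected instruments for one exposure, with per-SNP R^2 and F."""

    trait_id: str
    df: pd.DataFrame  # canonical columns + r2 + f_stat
    provenance: dict[str, int] = field(default_factory=dict)

    @property
    def n_snps(self) -> int:
        return len(self.df)


def snp_r2(beta, se=None, n=None, eaf=None, method: str = "tstat"):
    """Per-SNP proportion of trait variance explained by the instrument.

    ``tstat``: r2 = t^2/(t^2 + n - 2) with t = beta/se (requires se and n).
    ``eaf``:   r2 = 2 beta^2 eaf (1-eaf), for standardized continuous traits.
    Results are clipped to [0, 1).  Vectorized over array inputs.
    """
    beta = np.asarray(beta, dtype=float)
    if method == "tstat":
        if se is None or n is None:
            raise ValueError("tstat method requires se and n")
        se = np.asarray(se, dtype=float)
        n = np.asarray(n, dtype=float)
        if np.any(n <= 2):
            raise ValueError("tstat method requires n > 2")
        t2 = (beta / se) ** 2
        r2 = t2 / (t2 + n - 2)
    elif method == "eaf":
        if eaf is None or np.any(pd.isna(eaf)):
            raise ValueError("eaf method requires effect-allele frequencies")
        eaf = np.asarray(eaf, dtype=float)
        r2 = 2.0 * beta**2 * eaf * (1.0 - eaf)
    else:
        raise ValueError(f"unknown r2 method {method!r}")
    return np.clip(r2, 0.0, np.nextafter(1.0, 0.0))


def f_statistic(r2, n):
    """Per-SNP F-statistic, F = (n - 2) r2 / (1 - r2).

    Equals the squared Wald t when r2 comes from the ``tstat`` method.
    Strictly increasing in both r2 and n.
    """
    r2 = np.asarray(r2, dtype=float)
    n = np.asarray(n, dtype=float)
    return (n - 2.0) * r2 / (1.0 - r2)


def clump(
    candidates: pd.DataFrame,
    ld: LdMatrix,
    window_kb: int = 10_000,
    r2_max: float = 0.001,
) -> pd.DataFrame:
    """Greedy LD clumping by ascending p-value.

    A SNP is accepted iff its LD r^2 with every already-accepted SNP on the
    same chromosome within ``window_kb`` is below ``r2_max``.  Ties on p are
    broken by lexicographic rsID, so the result does not depend on input row
    order.  SNP pairs missing from the LD matrix are treated as independent
    (logged once).
    """
    df = candidates.sort_values(["pval", "rsid"], kind="mergesort").reset_index(drop=True)
    accepted: list[int] = []
    n_uncovered = 0
    for i, row in enumerate(df.itertuples(index=False)):
        keep = True
        for j in accepted:
            other = df.iloc[j]
            if other["chrom"] != row.chrom:
                continue
            if abs(int(other["pos"]) - int(row.pos)) > window_kb * 1000:
                continue
            r2 = ld.get(row.rsid, other["rsid"])
            if r2 is None:
                n_uncovered += 1
                continue
            if r2 >= r2_max:
                keep = False
                break
        if keep:
            accepted.append(i)
    if n_uncovered:
        logger.info("clump: %d SNP pairs absent from LD matrix treated as independent", n_uncovered)
    return df.iloc[accepted].reset_index(drop=True)


def select_instruments(
    stats: SumStats,
    p_threshold: float,
    exclusion: Sequence[str] = (),
    ld: LdMatrix | None = None,
    window_kb: int = 10_000,
    r2_max: float = 0.001,
    f_min: float = 10.0,
    r2_method: str = "tstat",
) -> InstrumentSet:
    """Run the full instrument-selection pipeline for one exposure.

    Stage order: p-value filter -> exclusion-list removal -> palindrome
    removal -> LD clumping -> R^2/F computation -> F > ``f_min`` filter.
    Provenance records the count removed at each stage; an empty set at any
    stage raises :class:`EmptyInstrumentsError` naming that stage.
    """
    if not (0 < p_threshold < 1):
        raise ValueError("p_threshold must lie in (0, 1)")
    df = stats.df
    prov: dict[str, int] = {"input": len(df)}

    def _check(stage: str, frame: pd.DataFrame) -> None:
        if frame.empty:
            raise EmptyInstrumentsError(stage, f"{stats.trait_id}: no instruments left after stage {stage!r}")

    kept = df[df["pval"] <= p_threshold]
    prov["removed_pval"] = len(df) - len(kept)
    _check("p_filter", kept)

    excl = set(exclusion)
    kept2 = kept[~kept["rsid"].isin(excl)]
    prov["removed_exclusion"] = len(kept) - len(kept2)
    _check("exclusion_list", kept2)

    classes = np.array([validate_alleles(e, o) for e, o in zip(kept2["ea"], kept2["oa"])])
    kept3 = kept2[classes == "valid"]
    prov["removed_palindromic"] = len(kept2) - len(kept3)
    _check("palindrome_filter", kept3)

    if ld is None:
        logger.warning("%s: no LD matrix supplied; assuming candidates are pre-clumped", stats.trait_id)
        kept4 = kept3.reset_index(drop=True)
        prov["removed_clump"] = 0
    else:
        kept4 = clump(kept3, ld, window_kb=window_kb, r2_max=r2_max)
        prov["removed_clump"] = len(kept3) - len(kept4)
        _check("clump", kept4)

    kept4 = kept4.copy()
    kept4["r2"] = snp_r2(
        kept4["beta"], se=kept4["se"], n=kept4["n"],
        eaf=kept4["eaf"] if r2_method == "eaf" else None, method=r2_method,
    )
    kept4["f_stat"] = f_statistic(kept4["r2"], kept4["n"])
    kept5 = kept4[kept4["f_stat"] > f_min].reset_index(drop=True)
    prov["removed_weak"] = len(kept4) - len(kept5)
    _check("f_filter", kept5)
    prov["retained"] = len(kept5)
    logger.info("%s: instrument selection %s", stats.trait_id, prov)
    return InstrumentSet(trait_id=stats.trait_id, df=kept5, provenance=prov)
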