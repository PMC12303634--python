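"""Reading, validating and writing GWAS summary-statistics tables.

Summary statistics arrive as flat TSV tables, one row per SNP, carrying the
per-allele association of that SNP with a single trait: effect allele, other
allele, effect-allele frequency, effect size (log-odds for binary traits, SD
units for continuous ones), its standard error, p-value and the GWAS sample
size.  Source repositories use different column dialects, so the reader takes
an explicit column map instead of guessing headers.

Rows that violate the per-SNP invariants (non-positive SE, p outside (0, 1],
malformed alleles, duplicate rsIDs, ...) are dropped with a logged count
rather than failing the whole table: public GWAS exports routinely contain a
handful of degenerate rows.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

#: canonical column order used everywhere downstream; ``eaf`` is optional.
CANONICAL_COLUMNS = ["rsid", "chrom", "pos", "ea", "oa", "eaf", "beta", "se", "pval", "n"]
MANDATORY_COLUMNS = [c for c in CANONICAL_COLUMNS if c != "eaf"]

TRAIT_TYPES = ("binary", "continuous")


class ColumnMapError(ValueError):
    """A mandatory summary-statistics column is missing from the input."""


class EmptyInputError(ValueError):
    """No valid SNP rows survived validation."""


def validate_alleles(ea: str, oa: str) -> str:
    """Classify an allele pair as ``valid``, ``palindromic`` or ``invalid``.

    Palindromic (ambiguous-strand) pairs are A/T and C/G: their strand cannot
    be resolved from the alleles alone, so harmonization discards them.
    Anything that is not a single A/C/G/T base, or has identical alleles, is
    ``invalid``.
    """
    ea, oa = str(ea).upper(), str(oa).upper()
    if ea not in VALID_BASES or oa not in VALID_BASES or ea == oa:
        return "invalid"
    if {ea, oa} in ({"A", "T"}, {"C", "G"}):
        return "palindromic"
    return "valid"


@dataclass(frozen=True)
class SnpRecord:
    """One SNP's association with one trait."""

    rsid: str
    chrom: str
    pos: int
    ea: str
    oa: str
    beta: float
    se: float
    pval: float
    n: float
    eaf: float | None = None

    def __post_init__(self) -> None:
        if self.se <= 0 or not np.isfinite(self.se):
            raise ValueError(f"{self.rsid}: se must be > 0")
        if not np.isfinite(self.beta):
            raise ValueError(f"{self.rsid}: beta must be finite")
        if not (0 < self.pval <= 1):
            raise ValueError(f"{self.rsid}: pval must lie in (0, 1]")
        if self.n <= 0:
            raise ValueError(f"{self.rsid}: n must be > 0")
        if validate_alleles(self.ea, self.oa) == "invalid":
            raise ValueError(f"{self.rsid}: invalid allele pair {self.ea}/{self.oa}")
        if self.eaf is not None and not np.isnan(self.eaf) and not (0 < self.eaf < 1):
            raise ValueError(f"{self.rsid}: eaf must lie in (0, 1)")


@dataclass
class SumStats:
    """A full summary-statistics table for one trait.

    ``df`` holds the canonical columns of :data:`CANONICAL_COLUMNS`; rsIDs are
    unique and the trait type is fixed for the whole table.
    """

    trait_id: str
    trait_type: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.trait_type not in TRAIT_TYPES:
            raise ValueError(f"trait_type must be one of {TRAIT_TYPES}")
        if self.df["rsid"].duplicated().any():
            raise ValueError("duplicate rsid in SumStats")

    @property
    def n_snps(self) -> int:
        return len(self.df)

    def records(self) -> list[SnpRecord]:
        out = []
        for row in self.df.itertuples(index=False):
            eaf = None if pd.isna(row.eaf) else float(row.eaf)
            out.append(
                SnpRecord(
                    rsid=row.rsid, chrom=str(row.chrom), pos=int(row.pos),
                    ea=row.ea, oa=row.oa, beta=float(row.beta), se=float(row.se),
                    pval=float(row.pval), n=float(row.n), eaf=eaf,
                )
            )
        return out


def _validity_mask(df: pd.DataFrame) -> pd.Series:
    allele_class = [validate_alleles(e, o) for e, o in zip(df["ea"], df["oa"])]
    ok = pd.Series(allele_class, index=df.index) != "invalid"
    ok &= np.isfinite(df["beta"]) & np.isfinite(df["se"]) & (df["se"] > 0)
    ok &= (df["pval"] > 0) & (df["pval"] <= 1)
    ok &= df["n"] > 0
    ok &= df["pos"] > 0
    # eaf is optional: NaN passes, out-of-range values fail.
    ok &= df["eaf"].isna() | ((df["eaf"] > 0) & (df["eaf"] < 1))
    return ok


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_type: str = "continuous",
    trait_id: str | None = None,
) -> SumStats:
    """Read one GWAS summary-statistics TSV into a validated :class:`SumStats`.

    Parameters
    ----------
    path
        TSV file with one header row.
    column_map
        Mapping from canonical names (:data:`CANONICAL_COLUMNS`) to the source
        file's headers, e.g. ``{"rsid": "SNP", "beta": "b"}``.  Unmapped
        canonical names are assumed to appear verbatim in the header.
    trait_type
        ``"binary"`` or ``"continuous"``; metadata only, fixed per table.
    trait_id
        Defaults to the file stem.

    Invalid rows are dropped with a logged count; duplicated rsIDs keep the
    first occurrence.  Raises :class:`ColumnMapError` if a mandatory column is
    absent and :class:`EmptyInputError` if no valid rows remain.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype={"rsid": str, "chrom": str})
    rename = {}
    column_map = dict(column_map or {})
    for canon in CANONICAL_COLUMNS:
        src = column_map.get(canon, canon)
        if src in raw.columns:
            rename[src] = canon
        elif canon in MANDATORY_COLUMNS:
            raise ColumnMapError(f"{path.name}: missing mandatory column {canon!r} (source name {src!r})")
    df = raw.rename(columns=rename)
    if "eaf" not in df.columns:
        df["eaf"] = np.nan
    df = df[CANONICAL_COLUMNS].copy()
    df["rsid"] = df["rsid"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    for col in ("pos", "eaf", "beta", "se", "pval", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["ea"] = df["ea"].astype(str).str.upper()
    df["oa"] = df["oa"].astype(str).str.upper()
    df = df.dropna(subset=[c for c in MANDATORY_COLUMNS if c not in ("rsid", "chrom", "ea", "oa")])

    n_in = len(raw)
    ok = _validity_mask(df)
    n_invalid = int((~ok).sum()) + (n_in - len(df))
    df = df[ok]
    dup = df["rsid"].duplicated(keep="first")
    n_dup = int(dup.sum())
    df = df[~dup].reset_index(drop=True)
    if n_invalid:
        logger.info("%s: dropped %d invalid rows", path.name, n_invalid)
    if n_dup:
        logger.info("%s: dropped %d duplicate rsid rows", path.name, n_dup)
    if df.empty:
        raise EmptyInputError(f"{path.name}: no valid SNP rows after validation")
    df["pos"] = df["pos"].astype(np.int64)
    return SumStats(trait_id=trait_id or path.stem, trait_type=trait_type, df=df)


def write_sumstats(stats: SumStats, path: str | Path) -> None:
    """Write a :class:`SumStats` table in the canonical TSV dialect."""
    write_results(stats.df, path)


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write any pipeline result table as TSV.

    Column order is the DataFrame's order (fixed by each producer); floats are
    rendered with 10 significant digits so tables round-trip through
    :func:`read_results` to rendered precision.  Empty tables are an error.
    """
    if table is None or len(table) == 0:
        raise ValueError("refusing to write an empty result table")
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t")


def read_rsid_list(path: str | Path) -> list[str]:
    """Read a plain-text exclusion list, one rsID per line; '#' starts a comment."""
    out: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.append(line)
    return out
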