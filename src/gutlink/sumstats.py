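"""Summary-statistics and LD-matrix containers, I/O, and harmonization.

Per-SNP GWAS/QTL summary statistics for one trait at one locus are held in a
:class:`LocusTable` (a validated :class:`pandas.DataFrame` plus a trait id).
Pairs of tables from two non-overlapping cohorts are allele-aligned with
:func:`harmonize_pair` before two-sample MR: outcome effects at SNPs whose
alleles are swapped relative to the exposure are sign-flipped, mismatched
SNPs are dropped, and strand-ambiguous palindromic SNPs (A/T, C/G) near 50%
frequency are removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical column order for summary-statistics tables.
COLUMNS = [
    "snp", "chr", "pos", "effect_allele", "other_allele",
    "beta", "se", "pval", "eaf", "n",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class FormatError(ValueError):
    """A mandatory column is missing or the file layout is unusable."""


class ValidationError(ValueError):
    """Table content violates a structural invariant (e.g. duplicate SNP ids)."""


def _normalize_chrom(c) -> str:
    s = str(c)
    return s[3:] if s.lower().startswith("chr") else s


def validate_records(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split rows into valid records and a per-row rejection report.

    Checks: se > 0, pval in (0, 1], pos >= 1, alleles distinct single
    nucleotides, eaf (when present) in (0, 1), n > 0.
    Returns ``(valid, report)`` where *report* has columns ``snp`` and
    ``reason``.
    """
    reasons = pd.Series("", index=df.index, dtype=object)

    def _flag(mask, why):
        nonlocal reasons
        mask = mask.fillna(False) if hasattr(mask, "fillna") else mask
        reasons = reasons.mask((reasons == "") & mask, why)

    alle = df["effect_allele"].astype(str).str.upper()
    allo = df["other_allele"].astype(str).str.upper()
    _flag(~(df["se"] > 0), "se must be > 0")
    _flag(~((df["pval"] > 0) & (df["pval"] <= 1)), "pval must be in (0, 1]")
    _flag(~(df["pos"] >= 1), "pos must be >= 1")
    _flag(alle == allo, "effect and other allele identical")
    _flag(~alle.isin(list(_COMPLEMENT)) | ~allo.isin(list(_COMPLEMENT)),
          "allele not a single nucleotide")
    eaf_bad = df["eaf"].notna() & ~((df["eaf"] > 0) & (df["eaf"] < 1))
    _flag(eaf_bad, "eaf must be in (0, 1) or missing")
    _flag(~(df["n"] > 0), "n must be > 0")

    bad = reasons != ""
    report = pd.DataFrame({"snp": df.loc[bad, "snp"], "reason": reasons[bad]})
    return df.loc[~bad].copy(), report


@dataclass
class LocusTable:
    """Per-SNP summary statistics for one trait at one locus."""

    trait_id: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"missing mandatory columns: {missing}")
        self.df = self.df[COLUMNS].reset_index(drop=True)
        if self.df["snp"].duplicated().any():
            dups = self.df.loc[self.df["snp"].duplicated(), "snp"].tolist()
            raise ValidationError(f"duplicate snp ids: {dups}")
        self.df["chr"] = self.df["chr"].map(_normalize_chrom)
        if self.df["chr"].nunique() > 1:
            raise ValidationError("records span multiple chromosomes")
        for c in ("effect_allele", "other_allele"):
            self.df[c] = self.df[c].astype(str).str.upper()

    @property
    def snp_ids(self) -> list[str]:
        return self.df["snp"].tolist()

    def __len__(self) -> int:
        return len(self.df)

    def zscores(self) -> pd.Series:
        return self.df["beta"] / self.df["se"]

    def subset(self, snp_ids) -> "LocusTable":
        keep = self.df[self.df["snp"].isin(set(snp_ids))]
        return LocusTable(self.trait_id, keep.copy())


def read_sumstats(path, dialect: Mapping[str, str] | None = None,
                  trait_id: str | None = None) -> LocusTable:
    """Read a tab-separated summary-statistics table into a LocusTable.

    ``dialect`` maps canonical column names to the file's column names
    (e.g. ``{"snp": "rsid"}``). Rows violating record invariants are
    rejected with a logged per-row report; structural problems raise.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if dialect:
        rename = {v: k for k, v in dialect.items()}
        df = df.rename(columns=rename)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory columns {missing}")
    df["chr"] = df["chr"].astype(str)
    df["snp"] = df["snp"].astype(str)
    valid, report = validate_records(df)
    for _, row in report.iterrows():
        logger.warning("%s: rejected SNP %s: %s", path.name, row["snp"], row["reason"])
    return LocusTable(trait_id or path.stem, valid)


def write_sumstats(table: LocusTable, path) -> None:
    """Write a LocusTable as canonical TSV; round-trips bit-exactly."""
    table.df.to_csv(path, sep="\t", index=False)


@dataclass
class LDMatrix:
    """Symmetric SNP x SNP correlation matrix (r, not r^2) with a SNP index."""

    snp_ids: list[str]
    r: np.ndarray
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        m = len(self.snp_ids)
        if self.r.shape != (m, m):
            raise ValidationError("LD matrix shape does not match snp_ids")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValidationError("LD matrix not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-6):
            raise ValidationError("LD matrix diagonal must be 1")
        if np.any(np.abs(self.r) > 1 + 1e-8):
            raise ValidationError("|r| must be <= 1")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def r_between(self, a: str, b: str) -> float:
        return float(self.r[self._index[a], self._index[b]])

    def r2_between(self, a: str, b: str) -> float:
        return self.r_between(a, b) ** 2

    def submatrix(self, snp_ids) -> "LDMatrix":
        idx = [self._index[s] for s in snp_ids]
        return LDMatrix(list(snp_ids), self.r[np.ix_(idx, idx)])


def read_ld(path) -> LDMatrix:
    """Read an LD panel: square matrix TSV with SNP-id header, or long
    triplets (snp_a, snp_b, r)."""
    df = pd.read_csv(path, sep="\t")
    cols = [c.lower() for c in df.columns]
    if cols[:3] == ["snp_a", "snp_b", "r"]:
        snps = sorted(set(df.iloc[:, 0]) | set(df.iloc[:, 1]))
        idx = {s: i for i, s in enumerate(snps)}
        r = np.eye(len(snps))
        for a, b, v in df.itertuples(index=False):
            r[idx[a], idx[b]] = v
            r[idx[b], idx[a]] = v
        return LDMatrix(snps, r)
    return LDMatrix(list(df.columns), df.to_numpy(dtype=float))


def write_ld(ld: LDMatrix, path) -> None:
    pd.DataFrame(ld.r, columns=ld.snp_ids).to_csv(path, sep="\t", index=False)


def is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


@dataclass
class HarmonizedInstrumentTable:
    """Allele-aligned exposure/outcome effect pairs, oriented to the
    exposure's effect allele."""

    exposure_id: str
    outcome_id: str
    df: pd.DataFrame  # snp, chr, pos, effect_allele, other_allele,
    #                   beta_exp, se_exp, pval_exp, eaf_exp, n_exp,
    #                   beta_out, se_out, pval_out, eaf_out, n_out

    def __len__(self) -> int:
        return len(self.df)

    @property
    def empty(self) -> bool:
        return len(self.df) == 0

    def subset(self, snp_ids) -> "HarmonizedInstrumentTable":
        keep = self.df[self.df["snp"].isin(set(snp_ids))]
        return HarmonizedInstrumentTable(self.exposure_id, self.outcome_id,
                                         keep.reset_index(drop=True))


def harmonize_pair(exposure: LocusTable, outcome: LocusTable,
                   palindrome_band: float = 0.08) -> HarmonizedInstrumentTable:
    """Align outcome effects to the exposure's effect allele.

    Shared SNPs with identical allele pairs are kept as-is; swapped pairs
    have the outcome beta negated and eaf reflected; anything else is a
    mismatch and is dropped. Palindromic SNPs whose eaf lies within
    ``palindrome_band`` of 0.5 in either study — or whose eaf is missing —
    are dropped as strand-ambiguous. An empty intersection yields an empty
    table, not an exception.
    """
    e = exposure.df.set_index("snp")
    o = outcome.df.set_index("snp")
    shared = e.index.intersection(o.index)

    rows = []
    for snp in shared:
        er, orow = e.loc[snp], o.loc[snp]
        ea, eo = er["effect_allele"], er["other_allele"]
        oa, oo = orow["effect_allele"], orow["other_allele"]
        if (oa, oo) == (ea, eo):
            b_out, eaf_out = orow["beta"], orow["eaf"]
        elif (oa, oo) == (eo, ea):
            b_out = -orow["beta"]
            eaf_out = 1.0 - orow["eaf"] if pd.notna(orow["eaf"]) else np.nan
        else:
            logger.debug("SNP %s dropped: allele mismatch", snp)
            continue
        if is_palindromic(ea, eo):
            eafs = [er["eaf"], eaf_out]
            if any(pd.isna(f) for f in eafs) or any(
                    abs(f - 0.5) <= palindrome_band for f in eafs):
                logger.debug("SNP %s dropped: ambiguous palindrome", snp)
                continue
        rows.append({
            "snp": snp, "chr": er["chr"], "pos": er["pos"],
            "effect_allele": ea, "other_allele": eo,
            "beta_exp": er["beta"], "se_exp": er["se"],
            "pval_exp": er["pval"], "eaf_exp": er["eaf"], "n_exp": er["n"],
            "beta_out": b_out, "se_out": orow["se"],
            "pval_out": orow["pval"], "eaf_out": eaf_out, "n_out": orow["n"],
        })
    cols = ["snp", "chr", "pos", "effect_allele", "other_allele",
            "beta_exp", "se_exp", "pval_exp", "eaf_exp", "n_exp",
            "beta_out", "se_out", "pval_out", "eaf_out", "n_out"]
    df = pd.DataFrame(rows, columns=cols)
    return HarmonizedInstrumentTable(exposure.trait_id, outcome.trait_id, df)


def weighted_case_control_maf(maf_cases: float, maf_controls: float,
                              n_cases: float, n_controls: float) -> float:
    """Sample-size-weighted MAF for a case-control GWAS."""
    if n_cases < 0 or n_controls < 0:
        raise ValueError("counts must be non-negative")
    if n_cases + n_controls == 0:
        raise ValueError("at least one of n_cases, n_controls must be > 0")
    for f in (maf_cases, maf_controls):
        if not 0 <= f <= 1:
            raise ValueError("frequencies must be in [0, 1]")
    return (maf_cases * n_cases + maf_controls * n_controls) / (n_cases + n_controls)
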