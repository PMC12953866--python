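"""Instrument selection and greedy LD clumping.

Instruments are SNPs passing a genome-wide significance threshold on the
exposure (5e-8 for expression QTL exposures, 1e-5 for microbiome QTL
exposures), pruned to approximate independence by greedy clumping:
repeatedly take the lowest-p remaining candidate as index and drop every
remaining candidate with r^2 >= ``r2_max`` within ``window_kb`` of it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .sumstats import LDMatrix, LocusTable

logger = logging.getLogger(__name__)


@dataclass
class InstrumentSet:
    exposure_id: str
    snp_ids: list[str]
    selection_pthresh: float
    clump_r2: float
    clump_window_kb: float

    def __len__(self) -> int:
        return len(self.snp_ids)


def select_ivs(exposure: LocusTable, pthresh: float) -> list[str]:
    """SNPs with pval < pthresh, sorted by (pval, pos, snp)."""
    df = exposure.df
    hits = df[df["pval"] < pthresh]
    hits = hits.sort_values(["pval", "pos", "snp"], kind="mergesort")
    return hits["snp"].tolist()


def ld_clump(candidates: LocusTable, ld: LDMatrix, r2_max: float = 0.01,
             window_kb: float = 100.0, pthresh: float = 1.0,
             exposure_id: str | None = None) -> InstrumentSet:
    """Greedy p-value-ordered clumping of candidate instruments.

    ``candidates`` is a LocusTable restricted (or not) to pre-selected
    SNPs; rows failing ``pthresh`` are ignored.  Ties in p are broken by
    smaller position, then lexicographic snp id, making the result
    deterministic.  Candidates absent from the LD panel are dropped with a
    warning.
    """
    df = candidates.df
    df = df[df["pval"] < pthresh]
    missing = [s for s in df["snp"] if s not in ld]
    if missing:
        logger.warning("clump: %d candidate(s) absent from LD panel dropped: %s",
                       len(missing), missing[:5])
        df = df[~df["snp"].isin(set(missing))]
    df = df.sort_values(["pval", "pos", "snp"], kind="mergesort")

    window_bp = window_kb * 1000.0
    remaining = list(df[["snp", "pos"]].itertuples(index=False, name=None))
    kept: list[str] = []
    while remaining:
        index_snp, index_pos = remaining.pop(0)
        kept.append(index_snp)
        remaining = [
            (s, p) for s, p in remaining
            if abs(p - index_pos) > window_bp or ld.r2_between(index_snp, s) < r2_max
        ]
    return InstrumentSet(
        exposure_id=exposure_id or candidates.trait_id,
        snp_ids=kept, selection_pthresh=pthresh,
        clump_r2=r2_max, clump_window_kb=window_kb,
    )
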