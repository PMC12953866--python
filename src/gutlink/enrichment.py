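"""Taxon-enrichment odds ratio and generic gene-set over-representation.

The taxon enrichment of a genus within one tissue-sharing category uses

    OR = [n / (n_s - n)] / [(N - n) / (N_s - N - (n_s - n))]

where n = loci regulating the focal genus inside the category, n_s = all
loci in the category, N = loci regulating the focal genus across all
categories, and N_s = all loci across all categories; this is algebraically
the cross-product ratio of the 2x2 table
[[n, n_s - n], [N - n, (N_s - n_s) - (N - n)]].  Significance is the
right tail of the hypergeometric distribution (one-sided Fisher test).

The gene-set engine applies the same right-sided Fisher test per set of a
GMT collection against a user-supplied background (all genes tested in the
MR analysis), with Benjamini-Hochberg adjustment across the collection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .mr import bh_fdr

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    n: int
    n_s: int
    N: int
    N_s: int
    odds_ratio: float       # may be 0.0 or inf at zero cells
    odds_ratio_haldane: float  # +0.5 continuity-corrected, for plotting
    p_right: float
    p_left: float           # depletion tail, reported separately

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.n, self.n_s - self.n],
                         [self.N - self.n,
                          self.N_s - self.N - (self.n_s - self.n)]])


def microbiome_enrichment(n: int, n_s: int, N: int, N_s: int) -> EnrichmentResult:
    """Enrichment of one genus in one regulatory category (see module doc)."""
    if not (0 <= n <= min(n_s, N) and N <= N_s and n_s <= N_s):
        raise ValueError(f"invalid contingency counts n={n}, n_s={n_s}, "
                         f"N={N}, N_s={N_s}")
    a, b = n, n_s - n
    c, d = N - n, N_s - N - (n_s - n)
    if min(a, b, c, d) < 0:
        raise ValueError("contingency cells must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        if b == 0 or c == 0:
            odds = np.inf if a * d > 0 else (0.0 if a == 0 else np.inf)
        elif a == 0 or d == 0:
            odds = 0.0
        else:
            odds = (a / b) / (c / d)
    haldane = ((a + 0.5) / (b + 0.5)) / ((c + 0.5) / (d + 0.5))
    # hypergeometric: population N_s, N successes, draws n_s, observed n
    p_right = float(stats.hypergeom.sf(n - 1, N_s, N, n_s))
    p_left = float(stats.hypergeom.cdf(n, N_s, N, n_s))
    return EnrichmentResult(n, n_s, N, N_s, float(odds), float(haldane),
                            min(p_right, 1.0), min(p_left, 1.0))


def read_gmt(path) -> dict[str, set]:
    """Read a GMT gene-set collection (name, description, members...).
    Duplicate set names are rejected."""
    sets: dict[str, set] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        name = fields[0]
        if name in sets:
            raise ValueError(f"duplicate gene-set name {name!r}")
        sets[name] = {g for g in fields[2:] if g}
    return sets


def gene_set_enrichment(query_genes, collection: dict[str, set],
                        background, alpha: float = 0.05) -> pd.DataFrame:
    """Right-sided Fisher over-representation of ``query_genes`` in each
    set, against ``background``, BH-adjusted across the collection."""
    query = set(query_genes)
    bg = set(background)
    if not bg:
        raise ValueError("background must be non-empty")
    if not query <= bg:
        raise ValueError("query genes must be a subset of the background")

    rows = []
    for name, members in collection.items():
        inset = members & bg
        if not inset:
            warnings.warn(f"gene set {name!r} disjoint from background; skipped")
            continue
        hits = len(query & inset)
        res = microbiome_enrichment(hits, len(query), len(inset), len(bg))
        rows.append({"set": name, "set_size": len(inset), "hits": hits,
                     "odds_ratio": res.odds_ratio, "pval": res.p_right})
    df = pd.DataFrame(rows, columns=["set", "set_size", "hits",
                                     "odds_ratio", "pval"])
    if len(df):
        df["qval"] = bh_fdr(df["pval"].to_numpy())
        df["significant"] = df["pval"] < alpha
    return df
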