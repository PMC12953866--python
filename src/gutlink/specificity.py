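"""Tissue-sharing, tissue-specificity and regulatory-breadth analytics.

Operates on a flat table of regulatory pairs — one row per
(gene, genus, tissue) with the MR effect, its SE and a ``significant``
flag — produced by the MR pipeline.  Significant pairs across the three
intestinal tissues are partitioned into the seven non-empty tissue subsets
(three tissue-specific, three pairwise-shared, one all-shared); for
tissue-specific pairs, specificity is attributed either to the eQTL layer
(the gene is an eGene only in that tissue) or to the gene-to-microbiome
regulation itself.  Genes are further classed as broadly regulating
(more than 10 distinct genera) or specifically regulating.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

DEFAULT_TISSUES = ("ileum", "sigmoid", "transverse")
BREADTH_THRESHOLD = 10


def enumerate_sharing_categories(tissues=DEFAULT_TISSUES) -> list[tuple[str, ...]]:
    """The non-empty subsets of the tissue set (seven for three tissues)."""
    cats = []
    for k in range(1, len(tissues) + 1):
        cats.extend(combinations(sorted(tissues), k))
    return cats


def _category_label(tissues) -> str:
    return "+".join(sorted(tissues))


def sharing_categories(pairs: pd.DataFrame,
                       tissues=DEFAULT_TISSUES) -> tuple[pd.DataFrame, pd.Series]:
    """Label every significant (gene, genus) key by its tissue subset.

    Returns ``(labels, counts)``: labels has one row per significant
    (gene, genus) key with its category; counts indexes every possible
    category (zero-filled), so the seven-way Venn summary is direct.
    """
    sig = pairs[pairs["significant"]]
    grouped = (sig.groupby(["gene", "genus"])["tissue"]
               .agg(lambda ts: _category_label(set(ts))).rename("category"))
    labels = grouped.reset_index()
    all_cats = [_category_label(c) for c in enumerate_sharing_categories(tissues)]
    counts = labels["category"].value_counts().reindex(all_cats, fill_value=0)
    counts.name = "n_pairs"
    return labels, counts


def specificity_source(labels: pd.DataFrame,
                       egene_sets: dict[str, set],
                       tissues=DEFAULT_TISSUES) -> pd.DataFrame:
    """Attribute tissue-specific pairs to eQTL vs regulation specificity.

    ``labels`` is the output of :func:`sharing_categories`.  A pair
    specific to tissue t is ``eqtl_specific`` when its gene is an eGene in
    t only, ``regulation_specific`` when the gene is an eGene in t and at
    least one other tissue, and ``unclassifiable`` when the gene is absent
    from every eGene set.
    """
    rows = []
    for t in sorted(tissues):
        spec = labels[labels["category"] == t]
        n_eqtl = n_reg = n_un = 0
        for gene in spec["gene"]:
            in_tissues = {tt for tt, genes in egene_sets.items() if gene in genes}
            if not in_tissues:
                n_un += 1
            elif in_tissues == {t}:
                n_eqtl += 1
            else:
                n_reg += 1
        total = len(spec)
        rows.append({
            "tissue": t, "n_specific": total, "eqtl_specific": n_eqtl,
            "regulation_specific": n_reg, "unclassifiable": n_un,
            "prop_eqtl_specific": n_eqtl / total if total else np.nan,
            "prop_regulation_specific": n_reg / total if total else np.nan,
        })
    return pd.DataFrame(rows)


def directionality_consistency(pairs: pd.DataFrame,
                               tissues=DEFAULT_TISSUES) -> pd.DataFrame:
    """Per tissue pairing, the fraction of shared (gene, genus) keys whose
    MR effects agree in sign."""
    sig = pairs[pairs["significant"]]
    rows = []
    for t1, t2 in combinations(sorted(tissues), 2):
        a = sig[sig["tissue"] == t1].set_index(["gene", "genus"])["beta"]
        b = sig[sig["tissue"] == t2].set_index(["gene", "genus"])["beta"]
        shared = a.index.intersection(b.index)
        frac = (float(np.mean(np.sign(a.loc[shared]) == np.sign(b.loc[shared])))
                if len(shared) else np.nan)
        rows.append({"tissue_1": t1, "tissue_2": t2,
                     "n_shared": len(shared), "consistency": frac})
    return pd.DataFrame(rows)


def weighted_effect_correlation(b1, b2, se1, se2):
    """Weighted Pearson correlation and WLS slope between two tissues'
    effects, weights 1 / (se1^2 + se2^2).  Returns (r, slope, p); missing
    below 3 points."""
    b1, b2 = np.asarray(b1, float), np.asarray(b2, float)
    se1, se2 = np.asarray(se1, float), np.asarray(se2, float)
    n = len(b1)
    if n < 3:
        return np.nan, np.nan, np.nan
    w = 1.0 / (se1 ** 2 + se2 ** 2)
    w = w / w.sum()
    mx, my = np.sum(w * b1), np.sum(w * b2)
    cov = np.sum(w * (b1 - mx) * (b2 - my))
    vx = np.sum(w * (b1 - mx) ** 2)
    vy = np.sum(w * (b2 - my) ** 2)
    r = cov / np.sqrt(vx * vy)
    slope = cov / vx
    r_cl = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_cl * np.sqrt((n - 2) / (1 - r_cl ** 2))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return float(r), float(slope), float(p)


def regulatory_breadth(pairs: pd.DataFrame,
                       threshold: int = BREADTH_THRESHOLD) -> pd.DataFrame:
    """Per gene per tissue, count distinct significantly regulated genera;
    class ``broadly`` when strictly more than ``threshold`` (a count of
    exactly 10 is ``specifically``)."""
    sig = pairs[pairs["significant"]]
    counts = (sig.groupby(["gene", "tissue"])["genus"].nunique()
              .rename("n_genera").reset_index())
    counts["class"] = np.where(counts["n_genera"] > threshold,
                               "broadly", "specifically")
    return counts


def gene_set_clustering(indicator: pd.DataFrame, k: int) -> pd.Series:
    """Agglomerative (average-linkage) clustering of genes on Jaccard
    distances between their genus-regulation profiles.

    Rows are put in canonical (sorted gene-id) order before linkage, so
    memberships are invariant to input row order; clusters are relabelled
    1..k by first appearance in that order.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(indicator):
        raise ValueError("k exceeds the number of genes")
    canon = indicator.sort_index()
    dist = pdist(canon.to_numpy(dtype=bool), metric="jaccard")
    z = linkage(dist, method="average")
    raw = fcluster(z, t=k, criterion="maxclust")
    relabel, out = {}, []
    for lab in raw:
        relabel.setdefault(lab, len(relabel) + 1)
        out.append(relabel[lab])
    return pd.Series(out, index=canon.index, name="cluster").reindex(indicator.index)


def jaccard_index(set_a, set_b) -> float:
    """|A ∩ B| / |A ∪ B|; defined as 0 when both sets are empty."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def genus_summary(n_pairs: int, n_genera: int) -> int:
    """Mean significant pairs per genus, rounded half away from zero."""
    if n_genera <= 0:
        raise ValueError("n_genera must be positive")
    x = n_pairs / n_genera
    return int(np.floor(x + 0.5)) if x >= 0 else int(np.ceil(x - 0.5))
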