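#!/usr/bin/env python
"""Tissue-sharing and specificity analytics over the forward MR results:
seven-way sharing categories, eQTL- vs regulation-specificity, effect-size
consistency between tissues, regulatory breadth and gene clustering.

Reads results/mr_forward.tsv and the simulation manifest; writes the
classification tables under results/ and prints the headline proportions.
"""

import json
from pathlib import Path

import pandas as pd

from gutlink import (directionality_consistency, gene_set_clustering,
                     jaccard_index, regulatory_breadth, sharing_categories,
                     specificity_source, weighted_effect_correlation)

ROOT = Path(__file__).resolve().parents[1] / "results"
TISSUES = ("ileum", "sigmoid", "transverse")


def main() -> None:
    df = pd.read_csv(ROOT / "mr_forward.tsv", sep="\t")
    manifest = json.loads((ROOT / "simulated" / "manifest.json").read_text())
    egenes = {t: set(v) for t, v in manifest["egenes"].items()}

    labels, counts = sharing_categories(df, TISSUES)
    counts.to_csv(ROOT / "sharing_counts.tsv", sep="\t")
    print("tissue-sharing categories (significant (gene, genus) keys):")
    for cat, n in counts.items():
        print(f"  {cat:28s} {n}")
    shared2plus = counts[[c for c in counts.index if "+" in c]].sum()
    print(f"  shared by >=2 tissues: {shared2plus} of {counts.sum()} "
          f"({shared2plus / max(counts.sum(), 1):.0%})")

    source = specificity_source(labels, egenes, TISSUES)
    source.to_csv(ROOT / "specificity_source.tsv", sep="\t", index=False)
    for _, row in source.iterrows():
        if row["n_specific"]:
            print(f"  {row['tissue']}-specific pairs: {row['n_specific']} "
                  f"({row['prop_eqtl_specific']:.0%} eQTL-specific, "
                  f"{row['prop_regulation_specific']:.0%} regulation-specific)")

    cons = directionality_consistency(df, TISSUES)
    cons.to_csv(ROOT / "consistency.tsv", sep="\t", index=False)
    print("cross-tissue effect consistency:")
    for _, row in cons.iterrows():
        sig = df[df["significant"]]
        a = sig[sig["tissue"] == row["tissue_1"]].set_index(["gene", "genus"])
        b = sig[sig["tissue"] == row["tissue_2"]].set_index(["gene", "genus"])
        shared = a.index.intersection(b.index)
        if len(shared) >= 3:
            r, slope, p = weighted_effect_correlation(
                a.loc[shared, "beta"], b.loc[shared, "beta"],
                a.loc[shared, "se"], b.loc[shared, "se"])
            extra = f"weighted r={r:.2f} (slope {slope:.2f}, p={p:.2g})"
        else:
            extra = "too few shared pairs for correlation"
        print(f"  {row['tissue_1']} vs {row['tissue_2']}: "
              f"direction consistency {row['consistency']:.2f} "
              f"({row['n_shared']} shared pairs); {extra}")

    breadth = regulatory_breadth(df)
    breadth.to_csv(ROOT / "breadth.tsv", sep="\t", index=False)
    print("regulatory breadth:",
          dict(breadth["class"].value_counts()))

    # gene similarity by regulated-genus profiles, per tissue
    sig = df[df["significant"]]
    for tissue in TISSUES:
        sub = sig[sig["tissue"] == tissue]
        if sub["gene"].nunique() < 4:
            continue
        ind = (sub.assign(one=1)
               .pivot_table(index="gene", columns="genus", values="one",
                            fill_value=0))
        clusters = gene_set_clustering(ind, k=2)
        clusters.rename("cluster").to_csv(
            ROOT / f"clusters_{tissue}.tsv", sep="\t")
        genes = ind.index.tolist()
        jac = [jaccard_index(set(ind.columns[ind.loc[g1] > 0]),
                             set(ind.columns[ind.loc[g2] > 0]))
               for i, g1 in enumerate(genes) for g2 in genes[i + 1:]]
        if jac:
            print(f"  {tissue}: {len(genes)} genes in 2 clusters; "
                  f"pairwise Jaccard {min(jac):.2f}-{max(jac):.2f}")


if __name__ == "__main__":
    main()
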