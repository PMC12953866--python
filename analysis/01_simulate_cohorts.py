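#!/usr/bin/env python
"""Simulate the synthetic study panel: three intestinal tissues, a handful
of gene loci and microbial genera.

Cohort sizes mirror the real designs this package targets: eQTL cohorts of
368 (transverse colon), 318 (sigmoid colon) and 174 (ileum), and a
genus-abundance GWAS cohort of 18,340.  Each (gene, genus, tissue) unit is
an independently simulated locus; the design matrix below injects a known
tissue-sharing structure (some pairs regulated in all tissues, some in two,
some tissue-specific, some null) and a known eGene structure (a few genes
carry eQTLs in one tissue only), so downstream classification can be
checked against truth.

Writes per-unit summary-stats TSVs, LD panels and a truth manifest under
results/simulated/.
"""

import json
import sys
from pathlib import Path

from gutlink import make_scenario, simulate_locus_study

OUT = Path(__file__).resolve().parents[1] / "results" / "simulated"

TISSUE_N = {"transverse": 368, "sigmoid": 318, "ileum": 174}
GENERA = ["Allisonella", "Parasutterella", "Holdemanella"]
N_OUTCOME = 18_340

# which tissues truly carry the gene->genus regulation, per gene index mod 6
SHARING_DESIGN = [
    ("transverse", "sigmoid", "ileum"),
    ("transverse", "sigmoid"),
    ("transverse",),
    ("ileum",),
    (),                       # null gene
    ("sigmoid", "ileum"),
]
# genes 0-9; genes 8, 9 are eGenes in a single tissue only
EGENE_ONLY = {8: "transverse", 9: "ileum"}
N_GENES = 10


def main() -> None:
    seed0 = int(sys.argv[1]) if len(sys.argv) > 1 else 20240917
    manifest = {"egenes": {t: [] for t in TISSUE_N}, "units": [],
                "true_regulation": []}
    n_units = 0
    for gi in range(N_GENES):
        gene = f"GENE{gi:02d}"
        regulated_tissues = (EGENE_ONLY.get(gi) and (EGENE_ONLY[gi],)
                             or SHARING_DESIGN[gi % len(SHARING_DESIGN)])
        for ti, (tissue, n_exp) in enumerate(TISSUE_N.items()):
            is_egene = gi not in EGENE_ONLY or EGENE_ONLY[gi] == tissue
            if is_egene:
                manifest["egenes"][tissue].append(gene)
            for mi, genus in enumerate(GENERA):
                regulated = is_egene and tissue in regulated_tissues
                scenario = "causal" if regulated else "null"
                ov = {"m_snps": 48, "ld_rho": 0.4, "min_gap": 4,
                      "n_instruments": 6, "instrument_beta": 1.0,
                      "n_exposure": n_exp, "n_outcome": N_OUTCOME,
                      "rint_outcome": True}
                if not is_egene:  # no cis signal at all in this tissue
                    ov.update(n_instruments=1, instrument_beta=0.0)
                seed = seed0 + gi * 997 + ti * 101 + mi * 11
                study = simulate_locus_study(
                    make_scenario(scenario, ov, seed=seed))
                unit_dir = OUT / tissue / f"{gene}__{genus}"
                study.write(unit_dir)
                manifest["units"].append({"gene": gene, "tissue": tissue,
                                          "genus": genus,
                                          "scenario": scenario,
                                          "seed": seed})
                if regulated:
                    manifest["true_regulation"].append(
                        [gene, genus, tissue])
                n_units += 1
    OUT.mkdir(parents=True, exist_ok=True)
    with open(OUT / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    n_true = len(manifest["true_regulation"])
    print(f"simulated {n_units} (gene, genus, tissue) units "
          f"({n_true} with true regulation) -> {OUT}")


if __name__ == "__main__":
    main()
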