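#!/usr/bin/env python
"""Disease integration: three-trait colocalization plus two-step MR over
simulated (gene eQTL, genus mbQTL, disease GWAS) triads.

Half the triads carry a genuine causal chain (gene -> genus -> trait
through shared causal variants); the other half have a null disease trait.
A triad is flagged when PP_abc > 0.1 and the two-step chain is supported.
Writes results/disease_triads.tsv.
"""

import sys
from pathlib import Path

from gutlink import TriadInput, make_scenario, simulate_locus_study
from gutlink.pipeline import RunConfig, run_disease

ROOT = Path(__file__).resolve().parents[1] / "results"

DISEASES = ["depression", "allergic_rhinitis", "asthma", "insomnia"]
GENERA = ["Allisonella", "Parasutterella"]


def main() -> None:
    seed0 = int(sys.argv[1]) if len(sys.argv) > 1 else 7
    triads = []
    for i, disease in enumerate(DISEASES):
        for j, genus in enumerate(GENERA):
            chain = (i + j) % 2 == 0
            ov = {"m_snps": 60, "min_gap": 5, "n_exposure": 10_000,
                  "n_outcome": 18_340, "n_third": 20_000}
            if not chain:
                ov["alpha"] = (0.4, 0.0)   # genus does not affect the trait
            spec = make_scenario("shared3", ov,
                                 seed=seed0 + 31 * i + 7 * j)
            st = simulate_locus_study(spec)
            triads.append(TriadInput(f"GENE{i}{j}", genus, disease,
                                     st.tables["exposure"],
                                     st.tables["outcome"],
                                     st.tables["third"], st.ld,
                                     tissue="transverse"))
    df = run_disease(triads, RunConfig(direction="disease"), out_dir=ROOT)
    df.to_csv(ROOT / "disease_triads.tsv", sep="\t", index=False)
    print(df[["gene", "genus", "trait", "pp_abc", "moloc_colocalized",
              "two_step_supported", "triad_flagged"]].to_string(index=False))
    n_chain = sum((i + j) % 2 == 0 for i in range(len(DISEASES))
                  for j in range(len(GENERA)))
    print(f"\nflagged {int(df['triad_flagged'].sum())} of {len(df)} triads "
          f"({n_chain} carry a true gene->genus->disease chain)")


if __name__ == "__main__":
    main()
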