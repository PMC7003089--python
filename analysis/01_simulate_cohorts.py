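#!/usr/bin/env python
"""Generate the four synthetic study cohorts and summarize their truth.

Writes results/cohort_truth_summary.tsv: per genotype, the number of
offspring and implanted truth events by kind. The SC-null cohorts
carry fewer DSB-derived events (20-40% of the wild-type DSB dose, no
crossovers) but more TE insertions and segregation errors, mirroring
the experimental contrast the downstream scripts quantify.
"""
import pandas as pd

from cohorts import build_cohort, config, results_path
from scfate import simgen

rows = []
panel = simgen.generate_parents(config())
for genotype in ("wildtype", "c3g_het", "c3g_hom", "corolla_hom"):
    panel, cohort = build_cohort(genotype, components=(), panel=panel)
    counts: dict[str, int] = {}
    for ds in cohort:
        for e in ds.truth:
            counts[e.kind] = counts.get(e.kind, 0) + 1
    rows.append({"genotype": genotype, "n_offspring": len(cohort), **counts})

df = pd.DataFrame(rows).fillna(0)
kind_cols = [c for c in df.columns if c not in ("genotype", "n_offspring")]
df[kind_cols] = df[kind_cols].astype(int)
out = results_path("cohort_truth_summary.tsv")
df.to_csv(out, sep="\t", index=False)
print(df.to_string(index=False))
print(f"\nCrossovers are confined to the SC-proficient genotypes and TE "
      f"insertions are enriched in the SC-null cohort, as designed.\n-> {out}")
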