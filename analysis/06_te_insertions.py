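#!/usr/bin/env python
"""TE insertion calling, novelty, mosaicism, and rate estimates.

Clusters family-annotated junction evidence per offspring, screens for
novelty across siblings, flags X-chromosome mosaics from spanning-read
fractions, and tabulates per-arm-per-meiosis rates (x4 haploid-product
correction) for the synthetic cohorts alongside the published counts.
Writes results/te_calls.tsv and results/te_rates.tsv.
"""
import pandas as pd

from cohorts import build_cohort, config, results_path
from scfate import simgen, transposons as te

cfg = config()
panel = simgen.generate_parents(cfg)
arm_names = [a.name for a in cfg.arm_table if a.name not in ("Y", "4")]

frames, rate_rows = [], []
for genotype in ("wildtype", "c3g_hom", "corolla_hom"):
    panel, cohort = build_cohort(genotype, components=("evidence",),
                                 panel=panel)
    cohort_calls = {}
    for ds in cohort:
        tagged = te.annotate_evidence(ds.evidence, panel.te_library)
        cohort_calls[ds.offspring_id] = te.cluster_insertions(tagged)
    calls = te.filter_novel(cohort_calls)
    for c in calls:
        if c.arm == "X":
            te.flag_mosaic(c)
    df = te.calls_to_frame(calls)
    df.insert(0, "genotype", genotype)
    frames.append(df)
    novel = [c for c in calls if c.novelty == "novel" and c.arm in arm_names]
    est = te.insertion_rate(len(novel), len(cohort) * len(arm_names))
    rate_rows.append((f"synthetic_{genotype}", est.events, est.arm_meioses,
                      est.rate_2dp))

for label, events, arm_meioses in [
        ("published_wildtype", 44, 196 * 5),
        ("published_c3g_het", 9, 40 * 5),
        ("published_c3g_hom_maternal", 64, 440),
        ("published_c3g_hom_paternal_X", 4, 25),
        ("published_corolla", 12, 50 * 5)]:
    est = te.insertion_rate(events, arm_meioses)
    rate_rows.append((label, events, arm_meioses, est.rate_2dp))

calls_df = pd.concat(frames, ignore_index=True)
calls_out = results_path("te_calls.tsv")
calls_df.to_csv(calls_out, sep="\t", index=False)
rates = pd.DataFrame(rate_rows, columns=["dataset", "events", "arm_meioses",
                                         "rate_per_arm_per_meiosis"])
rates_out = results_path("te_rates.tsv")
rates.to_csv(rates_out, sep="\t", index=False)

print(calls_df.groupby(["genotype", "novelty"]).size().unstack(fill_value=0)
      .to_string())
print("\n" + rates.to_string(index=False))
print("\nPublished counts reproduce 0.18 / 0.18 / 0.58 / 0.64 / 0.19; the "
      "synthetic SC-null cohort shows the same elevation over wild type "
      "that its generator implanted.")
print(f"-> {calls_out}\n-> {rates_out}")
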