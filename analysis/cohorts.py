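"""Shared study cohorts for the analysis scripts.

Each script regenerates the same deterministic synthetic cohorts from
one master seed, so the scripts can run independently and in any
order. Cohort sizes are desk-scale stand-ins for the study design
(196 wild-type, 40 heterozygous-control, 93 SC-null, 50 corolla
offspring) chosen so every script finishes in seconds.
"""
from __future__ import annotations

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), os.pardir, "src"))

from scfate import simgen  # noqa: E402

MASTER_SEED = 20190827

COHORT_SIZES = {
    "wildtype": 16,
    "c3g_het": 8,
    "c3g_hom": 24,
    "corolla_hom": 12,
}

RESULTS_DIR = os.path.join(os.path.dirname(__file__), os.pardir, "results")


def results_path(name: str) -> str:
    os.makedirs(RESULTS_DIR, exist_ok=True)
    return os.path.join(RESULTS_DIR, name)


def config(seed_offset: int = 0, **overrides) -> simgen.SimConfig:
    return simgen.SimConfig(seed=MASTER_SEED + seed_offset, **overrides)


def build_cohort(genotype: str, components=("markers", "indels", "depth",
                                            "evidence"), n=None,
                 panel=None, cfg=None):
    cfg = cfg or config()
    if panel is None:
        panel = simgen.generate_parents(cfg)
    n = n or COHORT_SIZES[genotype]
    return panel, simgen.simulate_cohort(
        cfg, genotype, n, components=components, panel=panel)[1]


def panel_frame(panel):
    return panel.markers.rename(
        columns={"ref": "allele_A", "alt": "allele_B"})[
        ["arm", "pos", "allele_A", "allele_B", "span"]]
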