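"""Panel construction and haplotype assignment, including the VCF
round trip through files and the masking monotonicity property."""
import numpy as np
import pandas as pd
import pytest

from scfate import io as sio
from scfate import markers, simgen


def _parent_frames(panel):
    m = panel.markers
    n = len(m)
    a = pd.DataFrame({"arm": m["arm"], "pos": m["pos"], "ref": m["ref"],
                      "alt": m["alt"], "qual": 999.0, "gt": ["0/0"] * n,
                      "depth": 30, "ad_alt": 0, "gq": 99})
    b = a.copy()
    b["gt"] = "1/1"
    b["ad_alt"] = 30
    return a, b


def test_build_marker_panel_roundtrip(panel):
    """Noise-free parental VCFs recover every truth marker site."""
    a, b = _parent_frames(panel)
    built = markers.build_marker_panel(a, b).sort_values(
        ["arm", "pos"]).reset_index(drop=True)
    truth = panel.markers.sort_values(["arm", "pos"]).reset_index(drop=True)
    assert len(built) == panel.n_markers()
    assert (built["allele_A"].to_numpy() == truth["ref"].to_numpy()).all()
    assert (built["allele_B"].to_numpy() == truth["alt"].to_numpy()).all()
    # indel markers carry their reference footprint
    assert (built["span"].to_numpy() == truth["span"].to_numpy()).all()


def test_panel_drops_het_and_concordant_sites():
    base = dict(ref="A", alt="T", qual=99.0, depth=30, ad_alt=15, gq=99)
    a = pd.DataFrame([
        {"arm": "2L", "pos": 100, "gt": "0/0", **base},
        {"arm": "2L", "pos": 200, "gt": "0/1", **base},   # het in A
        {"arm": "2L", "pos": 300, "gt": "1/1", **base},   # same in both
    ])
    b = a.copy()
    b["gt"] = ["1/1", "1/1", "1/1"]
    built = markers.build_marker_panel(a, b)
    assert list(built["pos"]) == [100]


def test_mismatched_contigs_raise():
    base = dict(pos=1, ref="A", alt="T", qual=9.0, gt="0/0", depth=30,
                ad_alt=0, gq=99)
    a = pd.DataFrame([{"arm": "chr2L", **base}])
    b = pd.DataFrame([{"arm": "2L", **base}])
    with pytest.raises(ValueError, match="contig"):
        markers.build_marker_panel(a, b)


def test_assignment_through_vcf_files(panel, panel_df, sim_config, tmp_path):
    """Synthetic male X written to VCF and read back reproduces the
    truth haplotype mosaic at every unmasked informative site."""
    m = simgen.simulate_meiosis(panel, sim_config, "wildtype", 4)
    ds = simgen.synthesize_offspring(panel, m, sim_config, "o4", 4,
                                     components=("markers",))
    contigs = {a.name: a.length for a in sim_config.arm_table}
    path = tmp_path / "o4.vcf"
    sio.write_vcf(ds.markers, path, "o4", contigs)
    table = markers.assign_haplotypes(path, panel_df,
                                      repeat_mask=panel.repeat_mask())
    arm_x = next(a for a in sim_config.arm_table if a.name == "X")
    inf = table.informative("X")
    truth = simgen.hap_along_arm(m.events, arm_x, m.recovered["X"],
                                 inf["pos"].to_numpy())
    assert (inf["call"].to_numpy() == truth).all()
    assert len(inf) > 3000


def test_masked_sites_are_missing(panel_df):
    n = len(panel_df)
    off = pd.DataFrame({
        "arm": panel_df["arm"], "pos": panel_df["pos"],
        "ref": panel_df["allele_A"], "alt": panel_df["allele_B"],
        "qual": 99.0, "gt": "1/1", "depth": 20, "ad_alt": 20, "gq": 99})
    mask = pd.DataFrame([("2L", 0, 10_000_000)], columns=["arm", "start", "end"])
    table = markers.assign_haplotypes(off, panel_df, repeat_mask=mask)
    assert (table.arm("2L")["call"] == "MISSING").all()
    assert (table.arm("2R")["call"] == "B").all()


def test_masking_monotonicity(panel_df):
    """Enlarging the repeat mask never increases informative calls."""
    off = pd.DataFrame({
        "arm": panel_df["arm"], "pos": panel_df["pos"],
        "ref": panel_df["allele_A"], "alt": panel_df["allele_B"],
        "qual": 99.0, "gt": "1/1", "depth": 20, "ad_alt": 20, "gq": 99})
    counts = []
    for end in (0, 200_000, 800_000, 2_000_000):
        mask = pd.DataFrame([(a, 0, end) for a in ("X", "2L", "2R")],
                            columns=["arm", "start", "end"])
        t = markers.assign_haplotypes(off, panel_df, repeat_mask=mask)
        counts.append(len(t.informative()))
    assert counts == sorted(counts, reverse=True)
    assert counts[0] == len(panel_df)   # empty mask keeps every call


def test_depth_and_quality_filters(panel_df):
    sub = panel_df[panel_df["arm"] == "X"].head(4).reset_index(drop=True)
    off = pd.DataFrame({
        "arm": sub["arm"], "pos": sub["pos"], "ref": sub["allele_A"],
        "alt": sub["allele_B"], "qual": 99.0, "gt": "1/1",
        "depth": [2, 20, 20, 20], "ad_alt": [2, 20, 20, 20],
        "gq": [99, 10, 99, 99]})
    t = markers.assign_haplotypes(off, sub, min_depth=3, min_qual=30)
    assert list(t.df["call"]) == ["MISSING", "MISSING", "B", "B"]


def test_autosomal_maternal_haplotype_logic(panel_df):
    """With a B father, a het site reports maternal A and a hom-B site
    maternal B."""
    sub = panel_df[panel_df["arm"] == "2L"].head(2).reset_index(drop=True)
    off = pd.DataFrame({
        "arm": sub["arm"], "pos": sub["pos"], "ref": sub["allele_A"],
        "alt": sub["allele_B"], "qual": 99.0, "gt": ["0/1", "1/1"],
        "depth": 20, "ad_alt": [10, 20], "gq": 99})
    t = markers.assign_haplotypes(off, sub)
    assert list(t.df["call"]) == ["A", "B"]


def test_empty_panel_rejected():
    empty = pd.DataFrame(columns=["arm", "pos", "allele_A", "allele_B", "span"])
    off = pd.DataFrame(columns=sio.VCF_COLUMNS)
    with pytest.raises(ValueError):
        markers.assign_haplotypes(off, empty)
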