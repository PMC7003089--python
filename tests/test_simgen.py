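"""Generator invariants: marker placement, determinism, depth law,
conversion-tract marker flips, and the deletion benchmark design."""
import numpy as np
import pandas as pd
import pytest

from scfate import simgen
from scfate.arms import Arm


def test_marker_count_matches_poisson_rate():
    """1 Mb at 1/500 bp yields ~2000 markers (within 3 Poisson SDs)."""
    cfg = simgen.SimConfig(
        seed=11, arm_table=[Arm("X", 1_000_000, 1, 1_000_000)],
        background_indel_count=0)
    panel = simgen.generate_parents(cfg)
    n = panel.n_markers()
    assert abs(n - 2000) <= 3 * np.sqrt(2000)
    pos = panel.markers["pos"].to_numpy()
    assert (np.diff(pos) > 0).all()
    assert (panel.markers["ref"] != panel.markers["alt"]).all()


def test_zero_snp_rate_gives_empty_panel():
    cfg = simgen.SimConfig(seed=1, snp_rate=0.0, background_indel_count=0)
    panel = simgen.generate_parents(cfg)
    assert panel.n_markers() == 0


def test_generator_is_deterministic(sim_config):
    p1 = simgen.generate_parents(sim_config)
    p2 = simgen.generate_parents(sim_config)
    pd.testing.assert_frame_equal(p1.markers, p2.markers)
    m1 = simgen.simulate_meiosis(p1, sim_config, "wildtype", 3)
    m2 = simgen.simulate_meiosis(p2, sim_config, "wildtype", 3)
    assert [e.to_dict() for e in m1.events] == [e.to_dict() for e in m2.events]
    d1 = simgen.synthesize_offspring(p1, m1, sim_config, "o", 3)
    d2 = simgen.synthesize_offspring(p2, m2, sim_config, "o", 3)
    pd.testing.assert_frame_equal(d1.markers, d2.markers)
    pd.testing.assert_frame_equal(d1.depth, d2.depth)
    pd.testing.assert_frame_equal(d1.evidence, d2.evidence)


def test_invalid_configs_rejected():
    with pytest.raises(simgen.ConfigurationError):
        simgen.SimConfig(dsb_fraction=1.5)
    with pytest.raises(simgen.ConfigurationError):
        simgen.SimConfig(tract_len_range=(1000, 250))
    with pytest.raises(simgen.ConfigurationError):
        simgen.SimConfig(deletion_size_class="5-50")
    with pytest.raises(ValueError):
        Arm("X", 0, 1, 1)


def test_sc_null_genotype_refuses_forced_crossover(panel, sim_config):
    forced = [simgen.TruthEvent("CO", "2L", 500_000, 500_000, 1,
                                {"partner_chromatid": 3})]
    with pytest.raises(simgen.PolicyError):
        simgen.simulate_meiosis(panel, sim_config, "c3g_hom",
                                forced_events=forced)


def test_zero_dsbs_yields_no_break_events(panel):
    cfg = simgen.SimConfig(seed=5, dsb_per_meiosis=(0, 0))
    m = simgen.simulate_meiosis(panel, cfg, "c3g_hom", 0)
    assert not any(e.kind in ("CO", "NCOGC", "DSB_DELETION") for e in m.events)


def test_forced_co_switches_recovered_haplotype_once(panel, sim_config):
    """A single crossover at a known position flips the product's
    haplotype exactly there and nowhere else."""
    co_pos = 1_000_000
    forced = [simgen.TruthEvent("CO", "X", co_pos, co_pos, 1,
                                {"partner_chromatid": 3})]
    cfg = simgen.SimConfig(seed=9, dsb_per_meiosis=(0, 0))
    m = simgen.simulate_meiosis(panel, cfg, "wildtype", 0,
                                forced_events=forced)
    m.recovered["X"] = 1
    pos = panel.arm_markers("X")["pos"].to_numpy()
    hap = simgen.hap_along_arm(m.events, panel.arm_table[0], 1, pos)
    switches = np.flatnonzero(hap[1:] != hap[:-1])
    assert len(switches) == 1
    assert pos[switches[0]] <= co_pos <= pos[switches[0] + 1]


def test_ncogc_tract_flips_exactly_covered_markers(panel, sim_config):
    """Marker flip property: a conversion tract flips every covered
    marker call and no other."""
    arm = next(a for a in sim_config.arm_table if a.name == "2L")
    tract = simgen.TruthEvent("NCOGC", "2L", 600_000, 600_999, 1,
                              {"tract_len": 1000})
    cfg = simgen.SimConfig(seed=13, dsb_per_meiosis=(0, 0))
    m = simgen.simulate_meiosis(panel, cfg, "wildtype", 0)
    m.recovered["2"] = 1
    m.events.append(tract)
    pos = panel.arm_markers("2L")["pos"].to_numpy()
    hap = simgen.hap_along_arm(m.events, arm, 1, pos)
    inside = (pos >= tract.start) & (pos <= tract.end)
    assert (hap[inside] == "B").all()     # chromatid 1 background is A
    assert (hap[~inside] == "A").all()


def test_depth_law_diploid(panel, sim_config):
    """Genome-wide mean depth over diploid arms ~ configured combined
    depth within 3 SE."""
    m = simgen.simulate_meiosis(panel, sim_config, "wildtype", 1)
    ds = simgen.synthesize_offspring(panel, m, sim_config, "o", 1,
                                     components=("depth",))
    auto = ds.depth[ds.depth["arm"].isin(["2L", "2R", "3L", "3R"])]
    mean = auto["value"].mean()
    se = auto["value"].std() / np.sqrt(len(auto))
    assert abs(mean - sim_config.combined_depth) <= 3 * se


def test_truth_log_conserves_events(panel, sim_config, tmp_path):
    m = simgen.simulate_meiosis(panel, sim_config, "wildtype", 2)
    ds = simgen.synthesize_offspring(panel, m, sim_config, "o2", 2)
    contigs = {a.name: a.length for a in sim_config.arm_table}
    paths = ds.write(tmp_path, contigs)
    import json
    with open(paths["truth"]) as fh:
        log = json.load(fh)
    assert len(log["events"]) == len(ds.truth)


def test_benchmark_design():
    """100 genomes per class, 2-6 deletions each, sizes within class."""
    cfg = simgen.SimConfig(seed=3)
    bm = simgen.make_deletion_benchmark(cfg, "1-10", n_genomes=20)
    per = bm.truth.groupby("offspring_id").size()
    assert len(per) == 20
    assert per.between(2, 6).all()
    assert bm.truth["size"].between(1, 10).all()
    bm2 = simgen.make_deletion_benchmark(cfg, "1-1000", n_genomes=5)
    assert bm2.truth["size"].between(1, 1000).all()
    # expectation of uniform{2..6} is 4 deletions per genome
    assert 2 <= per.mean() <= 6


def test_benchmark_empty_is_valid():
    cfg = simgen.SimConfig(seed=3)
    bm = simgen.make_deletion_benchmark(cfg, "1-10", n_genomes=0)
    assert len(bm.individuals) == 0 and len(bm.truth) == 0


def test_event_outside_euchromatin_skipped_and_logged(panel, sim_config):
    bad = simgen.TruthEvent("NCOGC", "2L", 10, 400, 1, {"tract_len": 391})
    m = simgen.simulate_meiosis(
        panel, simgen.SimConfig(seed=4, dsb_per_meiosis=(0, 0)),
        "wildtype", 0)
    ds = simgen.synthesize_offspring(panel, m, sim_config, "o", 0,
                                     extra_events=[bad],
                                     components=("depth",))
    skipped = [e for e in ds.truth
               if e.payload.get("skipped") == "outside_euchromatin"]
    assert len(skipped) == 1


def test_parent_fasta_export_encodes_both_haplotypes(tmp_path):
    from scfate.arms import Arm
    from scfate import io as sio
    cfg = simgen.SimConfig(seed=17, arm_table=[Arm("X", 2000, 1, 2000)],
                           background_indel_count=0,
                           indel_marker_fraction=0.0)
    panel = simgen.generate_parents(cfg)
    path = tmp_path / "parents.fasta"
    simgen.write_parent_fasta(panel, cfg, path)
    seqs = sio.read_fasta(path)
    assert set(seqs) == {"X_hapA", "X_hapB"}
    for r in panel.arm_markers("X").itertuples():
        assert seqs["X_hapA"][r.pos - 1] == r.ref
        assert seqs["X_hapB"][r.pos - 1] == r.alt
    diffs = sum(a != b for a, b in zip(seqs["X_hapA"], seqs["X_hapB"]))
    assert diffs == panel.n_markers()
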