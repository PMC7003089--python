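"""TE evidence annotation, clustering thresholds, novelty verdicts,
mosaic flagging, and the rate arithmetic with its x4 correction."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from scfate import io as sio
from scfate import simgen, transposons as te


@pytest.fixture(scope="module")
def library():
    return simgen.make_te_library(seed=7)


def evidence_rows(arm, pos, fam, n, library, ev_type="split",
                  offspring="o1", read_len=150):
    cons = library[fam]
    rows = []
    for i in range(n):
        s0 = (37 * i) % (len(cons) - read_len)
        rows.append((offspring, arm, pos + i, ev_type, fam, f"r{fam}{i}",
                     cons[s0:s0 + read_len]))
    return pd.DataFrame(rows, columns=sio.EVIDENCE_COLUMNS)


def test_kmer_annotation_assigns_true_family(library):
    ev = evidence_rows("X", 1000, "roo", 8, library)
    tagged = te.annotate_evidence(ev, library)
    assert (tagged["family"] == "roo").all()


def test_unmatchable_sequence_dropped(library):
    ev = evidence_rows("X", 1000, "roo", 2, library)
    ev.loc[0, "sequence"] = "A" * 150        # matches nothing
    tagged = te.annotate_evidence(ev, library)
    assert len(tagged) == 1


def test_empty_library_rejected(library):
    with pytest.raises(ValueError):
        te.annotate_evidence(evidence_rows("X", 1, "roo", 1, library), {})


def test_cluster_threshold_is_more_than_five(library):
    """Five supporting reads: no call; six: one call."""
    five = te.annotate_evidence(evidence_rows("X", 1000, "roo", 5, library),
                                library)
    assert te.cluster_insertions(five, min_reads=5) == []
    six = te.annotate_evidence(evidence_rows("X", 1000, "roo", 6, library),
                               library)
    calls = te.cluster_insertions(six, min_reads=5)
    assert len(calls) == 1
    assert calls[0].family == "roo"
    assert abs(calls[0].position - 1002) <= 10


@settings(max_examples=25, deadline=None, derandomize=True)
@given(n=st.integers(0, 30), thresh=st.integers(0, 10))
def test_raising_min_reads_never_increases_calls(n, thresh):
    lib = simgen.make_te_library(seed=7)
    ev = te.annotate_evidence(evidence_rows("X", 1000, "doc", n, lib), lib)
    lo = len(te.cluster_insertions(ev, min_reads=thresh))
    hi = len(te.cluster_insertions(ev, min_reads=thresh + 3))
    assert hi <= lo


def test_novelty_verdicts_partition(library):
    def call(oid, arm, pos, fam):
        return te.TEInsertionCall(oid, arm, pos, fam, 5, 3)

    cohort = {
        "o1": [call("o1", "X", 1000, "roo"),       # inherited (stock)
               call("o1", "2L", 9000, "doc")],     # novel
        "o2": [call("o2", "3R", 4000, "hobo")],    # shared with o3
        "o3": [call("o3", "3R", 4060, "hobo")],
    }
    stock = [call("stock", "X", 980, "roo")]
    out = te.filter_novel(cohort, stock, position_tolerance=100)
    v = {(c.offspring_id, c.position): c.novelty for c in out}
    assert v[("o1", 1000)] == "inherited"
    assert v[("o1", 9000)] == "novel"
    assert v[("o2", 4000)] == "shared" and v[("o3", 4060)] == "shared"
    assert len(out) == 4 and all(c.novelty for c in out)


def test_novelty_respects_haplotype_background(library):
    """A call matching a sibling on the other parental haplotype does
    not count as shared."""
    def call(oid, pos):
        return te.TEInsertionCall(oid, "X", pos, "roo", 5, 3)

    cohort = {"o1": [call("o1", 1000)], "o2": [call("o2", 1010)]}
    haps = {"o1": {"X": "A"}, "o2": {"X": "B"}}
    out = te.filter_novel(cohort, haplotypes=haps)
    assert all(c.novelty == "novel" for c in out)
    out2 = te.filter_novel(cohort)
    assert all(c.novelty == "shared" for c in out2)


def test_mosaic_flagging():
    even = te.TEInsertionCall("o", "X", 1, "doc", 6, 4, n_spanning=10)
    assert te.flag_mosaic(even) == "mosaic"
    const = te.TEInsertionCall("o", "X", 1, "doc", 12, 8, n_spanning=0)
    assert te.flag_mosaic(const) == "constitutive"
    thin = te.TEInsertionCall("o", "X", 1, "doc", 2, 1, n_spanning=0)
    assert te.flag_mosaic(thin) == "indeterminate"
    skew = te.TEInsertionCall("o", "X", 1, "doc", 28, 12, n_spanning=2)
    assert te.flag_mosaic(skew) in ("constitutive", "ambiguous")


def test_spanning_fraction_definition():
    c = te.TEInsertionCall("o", "X", 1, "doc", 6, 4, n_spanning=10)
    assert c.spanning_fraction == pytest.approx(0.5)
    assert 0.0 <= c.spanning_fraction <= 1.0


def test_insertion_rate_formula():
    est = te.insertion_rate(44, 196 * 5)
    assert est.rate == pytest.approx(44 * 4 / 980)
    assert est.rate_2dp == 0.18
    assert te.insertion_rate(0, 100).rate == 0.0
    with pytest.raises(ValueError):
        te.insertion_rate(1, 0)


def test_rate_matches_brute_force_on_synthetic_truth(panel, sim_config):
    """Rate from recovered truth events equals count x 4 / arm-meioses."""
    arms = [a.name for a in sim_config.arm_table if a.name not in ("Y", "4")]
    n_meioses = 20
    n_recovered = 0
    for i in range(n_meioses):
        m = simgen.simulate_meiosis(panel, sim_config, "c3g_hom", i)
        for e in m.events:
            if (e.kind == "TE_INSERTION" and e.arm in arms
                    and e.chromatid == m.recovered[
                        simgen.arms_by_name(sim_config.arm_table)[e.arm].chromosome]):
                n_recovered += 1
    est = te.insertion_rate(n_recovered, n_meioses * len(arms))
    assert est.rate == n_recovered * 4 / (n_meioses * len(arms))
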