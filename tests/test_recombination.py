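"""Event calling: segmentation, NCOGC/CO classification, tract bounds
(against a brute-force oracle), CO-associated conversions, landscapes,
and orientation symmetry."""
import numpy as np
import pandas as pd
import pytest

from scfate import recombination as rec
from scfate.markers import MarkerTable

from conftest import make_marker_table


def test_single_haplotype_is_one_block_no_events():
    t = make_marker_table(list(range(100, 1100, 100)), ["A"] * 10)
    blocks = rec.segment_haplotypes(t, "2L")
    assert len(blocks) == 1 and blocks[0].n_markers == 10
    assert rec.call_events(blocks, t) == []


def test_two_blocks_give_one_crossover():
    t = make_marker_table(list(range(100, 2100, 100)),
                          ["A"] * 10 + ["B"] * 10)
    blocks = rec.segment_haplotypes(t, "2L")
    assert [b.hap for b in blocks] == ["A", "B"]
    events = rec.call_events(blocks, t)
    assert [e.kind for e in events] == ["CO"]
    assert (events[0].min_start, events[0].min_end) == (1000, 1100)


def test_interior_tract_is_ncogc():
    """A,B(2 markers spanning 300 bp),A -> one NCOGC."""
    pos = [100, 600, 1100, 1400, 1900, 2400]
    t = make_marker_table(pos, ["A", "A", "B", "B", "A", "A"])
    events = rec.call_events(rec.segment_haplotypes(t, "2L"), t)
    assert [e.kind for e in events] == ["NCOGC"]
    e = events[0]
    assert e.min_bp == 301
    assert e.max_bp == 1900 - 600 - 1


def test_long_interior_block_policy():
    pos = [1000, 2000, 30_000, 60_000, 90_000, 91_000]
    calls = ["A", "A", "B", "B", "A", "A"]
    t = make_marker_table(pos, calls)
    amb = rec.call_events(rec.segment_haplotypes(t, "2L"), t,
                          ncogc_max_span=25_000)
    assert [e.kind for e in amb] == ["AMBIGUOUS"]
    dco = rec.call_events(rec.segment_haplotypes(t, "2L"), t,
                          ncogc_max_span=25_000, long_interior="dco")
    assert [e.kind for e in dco] == ["CO", "CO"]


def test_min_tract_with_indel_marker_footprint():
    """A conversion bounded by a 4-bp deletion and a SNP 180 bp apart
    has a 180-bp minimum tract: the indel counts its full reference
    footprint from its 5'-most base."""
    pos = [23_350_000, 23_350_969, 23_351_148, 23_353_655]
    spans = [1, 4, 1, 1]
    t = make_marker_table(pos, ["A", "B", "B", "A"], arm="2R", spans=spans)
    events = rec.call_events(rec.segment_haplotypes(t, "2R"), t)
    assert len(events) == 1 and events[0].kind == "NCOGC"
    min_bp, max_bp = rec.tract_bounds(events[0], t)
    assert min_bp == 180
    assert max_bp == 23_353_655 - 23_350_000 - 1


def test_max_bound_matches_brute_force_enumeration():
    """The reported maximum tract equals the longest interval that
    covers all converted markers and no flanking discordant marker,
    found by exhaustive enumeration."""
    pos = [50, 210, 390, 455, 700, 901]
    calls = ["A", "B", "B", "B", "A", "A"]
    t = make_marker_table(pos, calls)
    events = rec.call_events(rec.segment_haplotypes(t, "2L"), t)
    (event,) = events
    _, max_bp = rec.tract_bounds(event, t)
    converted = [p for p, c in zip(pos, calls) if c == "B"]
    best = 0
    for s in range(1, 1000):
        for e in range(s, 1001):
            covers_all = all(s <= p <= e for p in converted)
            covers_bad = any(s <= p <= e
                             for p, c in zip(pos, calls) if c == "A")
            if covers_all and not covers_bad:
                best = max(best, e - s + 1)
    assert max_bp == best


def test_single_marker_tract_min_is_footprint():
    t = make_marker_table([100, 500, 900], ["A", "B", "A"])
    events = rec.call_events(rec.segment_haplotypes(t, "2L"), t)
    assert rec.tract_bounds(events[0], t)[0] == 1
    t2 = make_marker_table([100, 500, 900], ["A", "B", "A"],
                           spans=[1, 5, 1])
    events2 = rec.call_events(rec.segment_haplotypes(t2, "2L"), t2)
    assert rec.tract_bounds(events2[0], t2)[0] == 5


def test_edge_event_has_open_max_bound():
    t = make_marker_table([100, 500, 900], ["B", "A", "A"])
    events = rec.call_events(rec.segment_haplotypes(t, "2L"), t)
    # terminal block change -> CO, not NCOGC; force the tract at the edge
    assert [e.kind for e in events] == ["CO"]


def test_co_gc_reports_two_placements():
    """Pattern A..A b a a B..B near a switch: the conversion plus CO
    admits two crossover placements."""
    pos = [100, 600, 1100, 1250, 1400, 1900, 2400, 2900]
    calls = ["A", "A", "B", "A", "A", "B", "B", "B"]
    t = make_marker_table(pos, calls)
    events = rec.call_arm(t, "2L", co_gc_window=5000)
    kinds = sorted(e.kind for e in events)
    assert kinds == ["CO", "CO_GC"]
    co_gc = next(e for e in events if e.kind == "CO_GC")
    assert len(co_gc.alternatives) == 2
    assert co_gc.alternatives[0] != co_gc.alternatives[1]


def test_co_with_clean_flanks_has_no_co_gc():
    t = make_marker_table(list(range(100, 2100, 100)),
                          ["A"] * 10 + ["B"] * 10)
    events = rec.call_arm(t, "2L")
    assert [e.kind for e in events] == ["CO"]


def test_noise_tolerance_absorbs_low_quality_singleton():
    pos = list(range(100, 1100, 100))
    calls = ["A"] * 4 + ["B"] + ["A"] * 5
    quals = [99.0] * 4 + [20.0] + [99.0] * 5
    t = make_marker_table(pos, calls, quals=quals)
    strict = rec.segment_haplotypes(t, "2L")
    assert len(strict) == 3
    tolerant = rec.segment_haplotypes(t, "2L", noise_tolerance=1)
    assert len(tolerant) == 1


def test_event_calls_symmetric_under_arm_reversal():
    pos = [100, 600, 1100, 1400, 1900, 2400, 3000, 3600]
    calls = ["A", "A", "B", "B", "A", "A", "B", "B"]
    t = make_marker_table(pos, calls)
    fwd = rec.call_events(rec.segment_haplotypes(t, "2L"), t)
    arm_len = 4000
    rpos = [arm_len - p for p in reversed(pos)]
    rcalls = list(reversed(calls))
    tr = make_marker_table(rpos, rcalls)
    bwd = rec.call_events(rec.segment_haplotypes(tr, "2L"), tr)
    assert sorted(e.kind for e in fwd) == sorted(e.kind for e in bwd)


def test_exchange_landscape_sums_and_uniformity():
    events = pd.DataFrame({
        "arm": "2L", "min_start": [100, 5100, 10_100], "min_end":
        [200, 5200, 10_200]})
    lands = rec.exchange_landscape(events, n_meioses=10, binsize_bp=5000,
                                   arm_length=15_000)
    assert lands["frequency"].sum() == pytest.approx(3 / 10)
    assert list(lands["n_events"]) == [1, 1, 1]
    with pytest.raises(ValueError):
        rec.exchange_landscape(events, 0, 5000, 15_000)


def test_all_missing_arm_yields_no_blocks():
    t = make_marker_table([100, 200], ["MISSING", "MISSING"])
    assert rec.segment_haplotypes(t, "2L") == []
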