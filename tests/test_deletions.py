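"""Novelty screening, large-deletion calling, per-DSB rates, and the
sensitivity benchmark."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from scfate import deletions as dele
from scfate import io as sio


def indel_frame(rows):
    """rows: (arm, anchor_pos, del_size, qual)."""
    out = []
    for arm, pos, size, qual in rows:
        out.append((arm, pos, "A" * (size + 1), "A", qual, "0/1", 20, 10, 99))
    return pd.DataFrame(out, columns=sio.VCF_COLUMNS)


def test_verdict_partition_and_rules():
    mask = pd.DataFrame([("2L", 0, 1000)], columns=["arm", "start", "end"])
    cohort = {
        "o1": indel_frame([("2L", 500, 5, 900),      # masked
                           ("2L", 5000, 5, 150),     # low quality
                           ("2L", 9000, 5, 900),     # shared with o2
                           ("2R", 40_000, 8, 900)]),  # novel
        "o2": indel_frame([("2L", 9050, 3, 900)]),   # shared with o1
    }
    calls = dele.screen_small(cohort, repeat_mask=mask)
    verdicts = {(c.offspring_id, c.start): c.verdict for c in calls}
    assert verdicts[("o1", 501)] == "masked"
    assert verdicts[("o1", 5001)] == "low_quality"
    assert verdicts[("o1", 9001)] == "shared"
    assert verdicts[("o2", 9051)] == "shared"
    assert verdicts[("o1", 40_001)] == "novel"
    # partition: every call gets exactly one verdict
    assert sum(c.verdict in dele.VERDICTS for c in calls) == len(calls)


def test_two_offspring_deletions_50bp_apart_are_shared():
    cohort = {"o1": indel_frame([("3L", 1000, 5, 900)]),
              "o2": indel_frame([("3L", 1055, 5, 900)])}
    calls = dele.screen_small(cohort)
    assert all(c.verdict == "shared" for c in calls)


def test_far_apart_deletions_are_novel():
    cohort = {"o1": indel_frame([("3L", 1000, 5, 900)]),
              "o2": indel_frame([("3L", 2000, 5, 900)])}
    calls = dele.screen_small(cohort)
    assert all(c.verdict == "novel" for c in calls)


def test_single_offspring_cohort_undeterminable():
    calls = dele.screen_small({"o1": indel_frame([("3L", 1000, 5, 900)])})
    assert calls[0].verdict == "shared_undeterminable"


@settings(max_examples=40, deadline=None, derandomize=True)
@given(quals=st.lists(st.floats(0, 2000, allow_nan=False), min_size=2,
                      max_size=20),
       threshold=st.floats(0, 2000))
def test_raising_qual_threshold_never_increases_novel_count(quals, threshold):
    cohort = {
        f"o{i}": indel_frame([("2L", 1000 + 500 * i, 4, q)])
        for i, q in enumerate(quals)
    }
    low = dele.screen_small(cohort, qual_min=threshold)
    high = dele.screen_small(cohort, qual_min=min(threshold * 2 + 1, 2001))
    n_low = sum(c.verdict == "novel" for c in low)
    n_high = sum(c.verdict == "novel" for c in high)
    assert n_high <= n_low


def split_evidence(arm, left, right, n, offspring="o1"):
    rows = [(offspring, arm, left, "split", f"{arm}:{right}", f"r{i}", ".")
            for i in range(n)]
    return pd.DataFrame(rows, columns=sio.EVIDENCE_COLUMNS)


def test_call_large_threshold_boundary():
    ev = split_evidence("2L", 99_999, 100_500, 2)
    assert dele.call_large(ev, min_support=3) == []
    ev = split_evidence("2L", 99_999, 100_500, 3)
    calls = dele.call_large(ev, min_support=3)
    assert len(calls) == 1
    assert (calls[0].start, calls[0].end) == (100_000, 100_499)


def test_call_large_requires_depth_drop_for_big_deletions():
    ev = split_evidence("2L", 99_999, 110_000, 6)
    flat = pd.DataFrame({"arm": "2L",
                         "start": np.arange(0, 200_000, 100),
                         "end": np.arange(100, 200_100, 100),
                         "value": 20.0})
    assert dele.call_large(ev, flat, min_support=3) == []
    dropped = flat.copy()
    inside = (dropped["start"] >= 100_000) & (dropped["end"] <= 110_000)
    dropped.loc[inside, "value"] = 10.0
    assert len(dele.call_large(ev, dropped, min_support=3)) == 1


def test_no_split_reads_no_calls():
    ev = pd.DataFrame(columns=sio.EVIDENCE_COLUMNS)
    assert dele.call_large(ev) == []


def test_deletions_per_dsb_reproduces_printed_rates():
    """11 deletions / (196 x 19 x 0.25) ~ 1%; 9 / (93 x 4 x 0.25) ~ 10%."""
    wt = dele.deletions_per_dsb(11, 196, 19, 0.25)
    assert wt == pytest.approx(0.0118, abs=0.0002)
    mut = dele.deletions_per_dsb(9, 93, 4, 0.25)
    assert mut == pytest.approx(0.097, abs=0.001)
    assert dele.deletions_per_dsb(0, 100, 19) == 0.0
    with pytest.raises(ValueError):
        dele.deletions_per_dsb(1, 0, 19)


def test_benchmark_sensitivity_extremes():
    truth = pd.DataFrame({
        "offspring_id": ["o1", "o1"], "arm": ["2L", "2R"],
        "start": [1000, 5000], "end": [1099, 5099],
        "size": [100, 100], "size_class": ["1-1000"] * 2})
    perfect = [dele.DeletionCall("o1", "2L", 1000, 1099, 900, "split_read"),
               dele.DeletionCall("o1", "2R", 5000, 5099, 900, "split_read")]
    rep = dele.benchmark_sensitivity(truth, perfect)
    assert rep.loc[rep["size_class"] == "overall", "recall"].iloc[0] == 1.0
    rep0 = dele.benchmark_sensitivity(truth, [])
    assert rep0.loc[rep0["size_class"] == "overall", "recall"].iloc[0] == 0.0
    with pytest.raises(ValueError):
        dele.benchmark_sensitivity(truth.iloc[:0], perfect)


def test_benchmark_requires_reciprocal_overlap():
    truth = pd.DataFrame({
        "offspring_id": ["o1"], "arm": ["2L"], "start": [1000],
        "end": [1999], "size": [1000], "size_class": ["1-1000"]})
    # call covers truth but is 10x larger: reciprocal overlap fails
    huge = [dele.DeletionCall("o1", "2L", 500, 10_500, 900, "split_read")]
    rep = dele.benchmark_sensitivity(truth, huge)
    assert rep["recall"].iloc[0] == 0.0
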