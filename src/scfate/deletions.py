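"""De novo deletion screening and sensitivity benchmarking.

Small deletions come from per-offspring indel VCFs and are screened for
novelty: masked (repeat overlap), low-quality (score <= 200), shared
(within 100 bp of a deletion in a different offspring), or novel.
Large deletions are called from split-read junction clusters backed by
a depth drop. Rates are expressed per DSB per meiosis assuming one in
four meiotic products is recovered.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from . import io as sio

log = logging.getLogger(__name__)

VERDICTS = ("novel", "shared", "masked", "low_quality", "shared_undeterminable")


@dataclass
class DeletionCall:
    offspring_id: str
    arm: str
    start: int          # 1-based inclusive, first deleted base
    end: int
    quality: float
    source: str         # small_indel | split_read
    verdict: str = ""

    @property
    def size(self) -> int:
        return self.end - self.start + 1


def _deletions_from_vcf(vcf, offspring_id: str) -> list[DeletionCall]:
    df = vcf if isinstance(vcf, pd.DataFrame) else sio.read_vcf(vcf)
    calls = []
    for r in df.itertuples():
        if len(r.ref) <= len(r.alt):
            continue  # not a deletion
        size = len(r.ref) - len(r.alt)
        start = int(r.pos) + len(r.alt)      # first deleted base
        calls.append(DeletionCall(offspring_id, str(r.arm), start,
                                  start + size - 1, float(r.qual),
                                  "small_indel"))
    return calls


def screen_small(cohort_vcfs: dict[str, object],
                 repeat_mask: pd.DataFrame | None = None,
                 qual_min: float = 200.0,
                 proximity_bp: int = 100) -> list[DeletionCall]:
    """Partition every cohort deletion into exactly one novelty verdict.

    Verdict precedence: masked, then low_quality (score <= qual_min),
    then shared (closest breakpoints within ``proximity_bp`` of any
    deletion in a *different* offspring, regardless of that deletion's
    quality), else novel. A single-offspring cohort cannot establish
    novelty; every unmasked call is then 'shared_undeterminable'.
    """
    single = len(cohort_vcfs) < 2
    if single:
        log.warning("novelty screen on a single-offspring cohort: "
                    "verdicts are undeterminable")
    all_calls: list[DeletionCall] = []
    for oid, vcf in cohort_vcfs.items():
        all_calls.extend(_deletions_from_vcf(vcf, oid))

    mask_trees: dict[str, IntervalTree] = {}
    if repeat_mask is not None:
        for r in repeat_mask.itertuples():
            mask_trees.setdefault(str(r.arm), IntervalTree()).addi(
                int(r.start), int(r.end))

    # interval trees of every unmasked deletion, padded by proximity
    prox_trees: dict[str, IntervalTree] = {}
    masked_flags = []
    for c in all_calls:
        t = mask_trees.get(c.arm)
        is_masked = t is not None and t.overlaps(c.start - 1, c.end)
        masked_flags.append(is_masked)
        if not is_masked:
            prox_trees.setdefault(c.arm, IntervalTree()).addi(
                c.start - 1 - proximity_bp, c.end + proximity_bp,
                c.offspring_id)

    for c, is_masked in zip(all_calls, masked_flags):
        if is_masked:
            c.verdict = "masked"
        elif single:
            c.verdict = "shared_undeterminable"
        elif c.quality <= qual_min:
            c.verdict = "low_quality"
        else:
            hits = prox_trees.get(c.arm, IntervalTree()).overlap(c.start - 1, c.end)
            if any(h.data != c.offspring_id for h in hits):
                c.verdict = "shared"
            else:
                c.verdict = "novel"
    return all_calls


def _parse_locus(target: str) -> tuple[str, int] | None:
    if ":" not in str(target):
        return None
    arm, _, pos = str(target).partition(":")
    try:
        return arm, int(pos)
    except ValueError:
        return None


def call_large(evidence: pd.DataFrame,
               depth_track: pd.DataFrame | None = None,
               min_support: int = 3,
               cluster_window: int = 20,
               depth_check_min_size: int = 300,
               depth_drop_ratio: float = 0.8,
               offspring_id: str = "") -> list[DeletionCall]:
    """Cluster deletion-type split reads into large-deletion calls.

    Split records whose mate locus lies downstream on the same arm are
    clustered by breakpoint pair within ``cluster_window``; clusters
    with at least ``min_support`` reads emit a call. Calls longer than
    ``depth_check_min_size`` additionally require the interval's mean
    depth to drop below ``depth_drop_ratio`` of the flanking mean.
    """
    splits = evidence[evidence["evidence_type"] == "split"]
    cands: dict[str, list[tuple[int, int]]] = {}
    for r in splits.itertuples():
        locus = _parse_locus(r.mate_target)
        if locus is None or locus[0] != r.arm:
            continue
        left, right = int(r.position), locus[1]
        if right <= left:
            continue
        cands.setdefault(str(r.arm), []).append((left, right))

    calls: list[DeletionCall] = []
    for arm, pairs in cands.items():
        pairs.sort()
        cluster: list[tuple[int, int]] = []
        for pair in pairs + [(None, None)]:
            if (cluster and pair[0] is not None
                    and abs(pair[0] - cluster[-1][0]) <= cluster_window
                    and abs(pair[1] - cluster[-1][1]) <= cluster_window):
                cluster.append(pair)
                continue
            if len(cluster) >= min_support:
                left = int(np.median([p[0] for p in cluster]))
                right = int(np.median([p[1] for p in cluster]))
                start, end = left + 1, right - 1
                if end >= start and _depth_concordant(
                        depth_track, arm, start, end,
                        depth_check_min_size, depth_drop_ratio):
                    calls.append(DeletionCall(
                        offspring_id, arm, start, end,
                        quality=float(len(cluster)), source="split_read"))
            cluster = [pair] if pair[0] is not None else []
    return calls


def _depth_concordant(depth_track, arm, start, end, min_size, drop_ratio) -> bool:
    if depth_track is None or end - start + 1 < min_size:
        return True
    d = depth_track[depth_track["arm"] == arm]
    inside = d[(d["start"] >= start - 1) & (d["end"] <= end)]
    flank_size = max(end - start + 1, 2000)
    flank = d[((d["end"] <= start - 1) & (d["start"] >= start - 1 - flank_size))
              | ((d["start"] >= end) & (d["end"] <= end + flank_size))]
    if len(inside) == 0 or len(flank) == 0:
        return True
    fm = flank["value"].mean()
    return fm > 0 and inside["value"].mean() / fm < drop_ratio


def deletions_per_dsb(n_deletions: int, n_offspring: int,
                      dsb_per_meiosis: float,
                      recovery_fraction: float = 0.25) -> float:
    """Deletions per DSB per meiosis.

    Only ``recovery_fraction`` of the DSBs made in a meiosis can show up
    in the single recovered product (one chromatid of four), so the
    denominator is offspring x DSBs x recovery fraction.
    """
    if n_offspring <= 0:
        raise ValueError("n_offspring must be positive")
    if dsb_per_meiosis <= 0 or recovery_fraction <= 0:
        raise ValueError("dsb_per_meiosis and recovery_fraction must be positive")
    if n_deletions < 0:
        raise ValueError("n_deletions must be nonnegative")
    return n_deletions / (n_offspring * dsb_per_meiosis * recovery_fraction)


def benchmark_sensitivity(truth: pd.DataFrame,
                          calls: list[DeletionCall],
                          reciprocal_overlap: float = 0.5) -> pd.DataFrame:
    """Recall of a truth deletion set, overall and per size class and arm.

    A truth deletion is recovered if any call in the same individual
    overlaps it reciprocally by at least ``reciprocal_overlap``.
    Returns a tidy frame with rows for 'overall', each size class, and
    each (class, arm) stratum.
    """
    if len(truth) == 0:
        raise ValueError("empty truth set")
    call_trees: dict[tuple[str, str], IntervalTree] = {}
    for c in calls:
        call_trees.setdefault((c.offspring_id, c.arm), IntervalTree()).addi(
            c.start - 1, c.end)

    recovered = []
    for t in truth.itertuples():
        tree = call_trees.get((t.offspring_id, t.arm))
        hit = False
        if tree is not None:
            t_len = t.end - t.start + 1
            for iv in tree.overlap(t.start - 1, t.end):
                ov = min(iv.end, t.end) - max(iv.begin, t.start - 1)
                c_len = iv.end - iv.begin
                if ov / t_len >= reciprocal_overlap and ov / c_len >= reciprocal_overlap:
                    hit = True
                    break
        recovered.append(hit)
    truth = truth.assign(recovered=recovered)

    rows = [("overall", "all", len(truth), int(truth["recovered"].sum()))]
    for cls, g in truth.groupby("size_class"):
        rows.append((str(cls), "all", len(g), int(g["recovered"].sum())))
        for arm, ga in g.groupby("arm"):
            rows.append((str(cls), str(arm), len(ga), int(ga["recovered"].sum())))
    out = pd.DataFrame(rows, columns=["size_class", "arm", "n_truth", "n_recovered"])
    out["recall"] = out["n_recovered"] / out["n_truth"]
    return out


def calls_to_frame(calls: list[DeletionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.offspring_id, c.arm, c.start, c.end, c.size, c.quality, c.source,
          c.verdict) for c in calls],
        columns=["offspring_id", "arm", "start", "end", "size", "quality",
                 "source", "verdict"])
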