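"""Crossover and gene-conversion calling from marker haplotype mosaics.

A crossover (CO) appears as a haplotype switch that persists to the arm
end; a noncrossover gene conversion (NCOGC) as a short interior tract of
the opposite haplotype returning to the flanking haplotype; a
CO-associated gene conversion (CO-GC) as a short heterogeneous tract
next to a switch, which makes two crossover placements equally
consistent. Every event carries both a minimum tract (span of the
outermost converted markers, counting an indel marker's full reference
footprint) and a maximum tract (distance between the nearest flanking
markers of the opposite haplotype, exclusive).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markers import MarkerTable

log = logging.getLogger(__name__)

DEFAULT_NCOGC_MAX_SPAN = 25_000   # interior tracts above this are AMBIGUOUS


@dataclass
class HaplotypeBlock:
    arm: str
    first_pos: int
    last_pos: int
    hap: str
    n_markers: int
    first_idx: int                 # indices into the informative marker list
    last_idx: int

    @property
    def span(self) -> int:
        return self.last_pos - self.first_pos + 1


@dataclass
class RecombinationEvent:
    kind: str                      # CO | NCOGC | CO_GC | AMBIGUOUS
    arm: str
    min_start: int
    min_end: int
    max_start: int | None          # None = unbounded at the arm edge
    max_end: int | None
    n_markers: int
    hap: str = ""                  # converted-tract haplotype (NCOGC/CO_GC)
    alternatives: list[dict] = field(default_factory=list)

    @property
    def min_bp(self) -> int:
        return self.min_end - self.min_start + 1

    @property
    def max_bp(self) -> int | None:
        if self.max_start is None or self.max_end is None:
            return None
        return self.max_end - self.max_start - 1


def segment_haplotypes(table: MarkerTable, arm: str,
                       noise_tolerance: int = 0,
                       strict_qual: float = 60.0) -> list[HaplotypeBlock]:
    """Maximal runs of identical haplotype over the informative markers.

    HET/MISSING markers are skipped. With ``noise_tolerance`` > 0, runs
    of up to that many discordant markers whose quality is below
    ``strict_qual`` are treated as miscalls and absorbed into the
    surrounding block (default 0: no absorption).
    """
    inf = table.informative(arm).reset_index(drop=True)
    if len(inf) == 0:
        log.warning("no informative markers on arm %s for %s", arm,
                    table.offspring_id)
        return []
    calls = inf["call"].to_numpy()
    quals = inf["qual"].to_numpy()
    if noise_tolerance > 0:
        calls = calls.copy()
        i = 0
        n = len(calls)
        while i < n:
            j = i
            while j < n and calls[j] == calls[i]:
                j += 1
            run_len = j - i
            if (0 < i and j < n and run_len <= noise_tolerance
                    and calls[i - 1] == calls[j]
                    and (quals[i:j] < strict_qual).all()):
                calls[i:j] = calls[i - 1]
            i = j
    blocks: list[HaplotypeBlock] = []
    start = 0
    for i in range(1, len(calls) + 1):
        if i == len(calls) or calls[i] != calls[start]:
            blocks.append(HaplotypeBlock(
                arm=arm, first_pos=int(inf["pos"].iloc[start]),
                last_pos=int(inf["pos"].iloc[i - 1]), hap=str(calls[start]),
                n_markers=i - start, first_idx=start, last_idx=i - 1))
            start = i
    return blocks


def _tract_bounds_from_blocks(inf: pd.DataFrame, first_idx: int,
                              last_idx: int) -> tuple[int, int, int | None, int | None]:
    """(min_start, min_end, max_start, max_end) for a converted marker run.

    min span is inclusive of the outermost converted markers (an indel
    marker contributes its reference footprint from its 5'-most base);
    the max bound runs between the nearest informative flanking markers,
    exclusive, and is open at an arm edge.
    """
    min_start = int(inf["pos"].iloc[first_idx])
    min_end = int(inf["pos"].iloc[last_idx] + inf["span"].iloc[last_idx] - 1)
    max_start = None
    max_end = None
    if first_idx > 0:
        prev = first_idx - 1
        max_start = int(inf["pos"].iloc[prev] + inf["span"].iloc[prev] - 1)
    if last_idx < len(inf) - 1:
        max_end = int(inf["pos"].iloc[last_idx + 1])
    return min_start, min_end, max_start, max_end


def tract_bounds(event: RecombinationEvent,
                 table: MarkerTable) -> tuple[int, int | None]:
    """(min_bp, max_bp) of a conversion tract; max is None at an open edge."""
    inf = table.informative(event.arm).reset_index(drop=True)
    sel = (inf["pos"] >= event.min_start) & (inf["pos"] <= event.min_end)
    idx = np.flatnonzero(sel)
    if len(idx) == 0:
        raise ValueError("event has no converted marker in the table")
    ms, me, xs, xe = _tract_bounds_from_blocks(inf, int(idx[0]), int(idx[-1]))
    max_bp = None if (xs is None or xe is None) else xe - xs - 1
    return me - ms + 1, max_bp


def call_events(blocks: list[HaplotypeBlock], table: MarkerTable,
                ncogc_max_span: int = DEFAULT_NCOGC_MAX_SPAN,
                ncogc_min_markers: int = 1,
                long_interior: str = "ambiguous") -> list[RecombinationEvent]:
    """Classify block structure into NCOGC tracts and crossovers.

    Interior blocks whose marker span is at most ``ncogc_max_span``
    (and carry at least ``ncogc_min_markers`` markers) are NCOGCs.
    Longer interior blocks are, by default, flagged AMBIGUOUS (a long
    conversion tract and a double crossover are both consistent) rather
    than silently classified; ``long_interior="dco"`` instead treats
    them as persisting haplotype, appropriate when tract lengths are
    known to be far below the cutoff (e.g. noise-free synthetic data).
    Boundaries between the persisting blocks that remain are COs; two
    on one arm constitute a double CO (two CO records).
    """
    if not blocks:
        return []
    if long_interior not in ("ambiguous", "dco"):
        raise ValueError("long_interior must be 'ambiguous' or 'dco'")
    arm = blocks[0].arm
    inf = table.informative(arm).reset_index(drop=True)
    events: list[RecombinationEvent] = []
    persisting: list[HaplotypeBlock] = [blocks[0]]
    for b in blocks[1:-1]:
        if b.span <= ncogc_max_span:
            ms, me, xs, xe = _tract_bounds_from_blocks(inf, b.first_idx, b.last_idx)
            kind = "NCOGC" if b.n_markers >= ncogc_min_markers else "AMBIGUOUS"
            events.append(RecombinationEvent(
                kind, arm, ms, me, xs, xe, b.n_markers, hap=b.hap))
        elif long_interior == "dco":
            persisting.append(b)
        else:
            ms, me, xs, xe = _tract_bounds_from_blocks(inf, b.first_idx, b.last_idx)
            events.append(RecombinationEvent(
                "AMBIGUOUS", arm, ms, me, xs, xe, b.n_markers, hap=b.hap))
    if len(blocks) >= 2:
        persisting.append(blocks[-1])
    for left, right in zip(persisting[:-1], persisting[1:]):
        if left.hap == right.hap:
            continue
        events.append(RecombinationEvent(
            "CO", arm, left.last_pos, right.first_pos,
            left.last_pos, right.first_pos, 0))
    events.sort(key=lambda e: e.min_start)
    return events


def detect_co_gc(events: list[RecombinationEvent], table: MarkerTable,
                 window_bp: int = 10_000) -> list[RecombinationEvent]:
    """Resolve short conversion tracts inside a CO interval into CO-GC.

    Alternating short tracts between a crossover's flanking blocks
    (marker pattern ``A..A b a a B..B``) admit two equally parsimonious
    interpretations: the crossover before the first tract with the
    second as its associated conversion, or after the second with the
    first as the conversion. Such tract pairs are replaced by a single
    CO_GC event listing both placements (the CO keeps the full
    flank-to-flank interval); isolated conversions away from any CO are
    untouched. ``window_bp`` bounds how far from the CO interval a
    tract may sit and still be considered associated.
    """
    cos = [e for e in events if e.kind == "CO"]
    inside_of: dict[int, RecombinationEvent] = {}
    for i, e in enumerate(events):
        if e.kind != "NCOGC":
            continue
        for co in cos:
            if (co.min_start - window_bp <= e.min_start
                    and e.min_end <= co.min_end + window_bp
                    and co.min_start < e.min_start
                    and e.min_end < co.min_end):
                inside_of[i] = co
                break
    out: list[RecombinationEvent] = []
    for co in cos:
        tracts = sorted((events[i] for i, c in inside_of.items() if c is co),
                        key=lambda t: t.min_start)
        out.append(co)
        if not tracts:
            continue
        first, last = tracts[0], tracts[-1]
        alternatives = [
            {"co_interval": (co.min_start, first.min_start),
             "gc_interval": (last.min_start, last.min_end), "gc_hap": last.hap},
            {"co_interval": (last.min_end, co.min_end),
             "gc_interval": (first.min_start, first.min_end),
             "gc_hap": first.hap},
        ]
        out.append(RecombinationEvent(
            "CO_GC", co.arm, first.min_start, last.min_end,
            co.min_start, co.min_end,
            sum(t.n_markers for t in tracts), hap=first.hap,
            alternatives=alternatives))
    for i, e in enumerate(events):
        if e.kind != "CO" and i not in inside_of:
            out.append(e)
    return sorted(out, key=lambda e: e.min_start)


def call_arm(table: MarkerTable, arm: str,
             ncogc_max_span: int = DEFAULT_NCOGC_MAX_SPAN,
             ncogc_min_markers: int = 1,
             co_gc_window: int = 10_000,
             noise_tolerance: int = 0,
             long_interior: str = "ambiguous") -> list[RecombinationEvent]:
    """Segment one arm and call all recombination events on it."""
    blocks = segment_haplotypes(table, arm, noise_tolerance=noise_tolerance)
    events = call_events(blocks, table, ncogc_max_span, ncogc_min_markers,
                         long_interior=long_interior)
    return detect_co_gc(events, table, co_gc_window)


def events_to_frame(offspring_id: str,
                    events: list[RecombinationEvent]) -> pd.DataFrame:
    rows = [(offspring_id, e.arm, e.kind, e.min_start, e.min_end,
             e.max_start, e.max_end, e.n_markers, e.min_bp, e.max_bp)
            for e in events]
    return pd.DataFrame(rows, columns=[
        "offspring_id", "arm", "kind", "min_start", "min_end",
        "max_start", "max_end", "n_markers", "min_bp", "max_bp"])


def exchange_landscape(events: pd.DataFrame | list, n_meioses: int,
                       binsize_bp: int, arm_length: int,
                       arm: str | None = None) -> pd.DataFrame:
    """Per-bin event frequency (events per meiosis) along an arm.

    An event is binned at the midpoint of its minimal interval. Bin
    frequencies sum to total events / n_meioses.
    """
    if n_meioses <= 0:
        raise ValueError("n_meioses must be positive")
    if binsize_bp <= 0:
        raise ValueError("binsize_bp must be positive")
    if isinstance(events, list):
        events = events_to_frame("", events)
    if arm is not None:
        events = events[events["arm"] == arm]
    nb = int(np.ceil(arm_length / binsize_bp))
    edges = np.arange(nb + 1) * binsize_bp
    mid = ((events["min_start"] + events["min_end"]) / 2).to_numpy()
    counts, _ = np.histogram(mid, bins=edges)
    return pd.DataFrame({
        "bin_start": edges[:-1].astype(int),
        "bin_end": np.minimum(edges[1:], arm_length).astype(int),
        "n_events": counts,
        "frequency": counts / n_meioses,
    })
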