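"""Windowed copy-number analysis: segmentation, mosaic fractions, recurrence.

Depth is averaged in 5-kb nonoverlapping windows and normalized to the
major-autosome diploid baseline, giving a linear copy ratio (1.0 = two
copies; 1.5 = a constitutive heterozygous duplication; 1.25 = the same
duplication in half the cells); log2 of the ratio is carried alongside
for plotting. Runs of extreme windows become CNV calls, a mosaic cell
fraction is read off the mean ratio, and recurrent events are matched
across individuals by breakpoint agreement.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arms import AUTOSOME_BASELINE_ARMS

DEFAULT_WINDOW = 5_000


@dataclass
class CNVCall:
    offspring_id: str
    arm: str
    start: int            # 1-based inclusive
    end: int
    type: str             # duplication | deletion
    mean_ratio: float
    n_windows: int
    mosaic_fraction_est: float | None = None
    flank_te: tuple[str | None, str | None] = (None, None)
    te_mediated: bool = False
    tandem: bool | None = None

    @property
    def size(self) -> int:
        return self.end - self.start + 1


def window_depth(depth_track: pd.DataFrame, window: int = DEFAULT_WINDOW,
                 baseline_arms=AUTOSOME_BASELINE_ARMS,
                 baseline: float | None = None) -> pd.DataFrame:
    """Re-bin a depth track into fixed windows with copy ratios.

    Returns a frame with arm, start (0-based), end, depth, copy_ratio,
    log2_ratio. The diploid baseline defaults to the mean window depth
    over the major autosome arms.
    """
    frames = []
    for arm, grp in depth_track.groupby("arm", sort=False):
        g = grp.sort_values("start")
        arm_len = int(g["end"].max())
        edges = np.arange(0, arm_len + window, window)
        mids = (g["start"] + g["end"]) / 2.0
        idx = np.clip(np.searchsorted(edges, mids, side="right") - 1,
                      0, len(edges) - 2)
        w = (g["end"] - g["start"]).to_numpy(dtype=float)
        sums = np.bincount(idx, weights=g["value"].to_numpy() * w,
                           minlength=len(edges) - 1)
        ws = np.bincount(idx, weights=w, minlength=len(edges) - 1)
        with np.errstate(invalid="ignore"):
            mean = np.where(ws > 0, sums / np.maximum(ws, 1), np.nan)
        frames.append(pd.DataFrame({
            "arm": arm, "start": edges[:-1].astype(int),
            "end": np.minimum(edges[1:], arm_len).astype(int),
            "depth": mean}))
    win = pd.concat(frames, ignore_index=True).dropna(subset=["depth"])
    if baseline is None:
        base = win[win["arm"].isin(baseline_arms)]["depth"]
        if len(base) == 0 or base.median() == 0:
            raise ValueError("no usable baseline windows")
        baseline = float(base.median())   # robust to CNVs in the baseline arms
    win["copy_ratio"] = win["depth"] / baseline
    with np.errstate(divide="ignore"):
        win["log2_ratio"] = np.log2(win["copy_ratio"].where(win["copy_ratio"] > 0))
    return win


def segment(windows: pd.DataFrame, up_thresh: float = 1.2,
            down_thresh: float = 0.8, min_windows: int = 3,
            offspring_id: str = "",
            split_evidence: pd.DataFrame | None = None,
            expected_ratio: dict[str, float] | None = None,
            smooth_windows: int = 3) -> list[CNVCall]:
    """Seed-and-extend runs of extreme windows become CNV calls.

    Window states are assigned on a rolling-median-smoothed ratio
    (width ``smooth_windows``); runs seeded at the main thresholds are
    merged across gap windows that still clear the halfway extension
    threshold, so a mosaic event whose true ratio sits near a threshold
    is not shattered by Poisson noise.
    ``expected_ratio`` supplies each arm's baseline copy ratio (e.g.
    0.5 for a male X) so hemizygous arms are not wholesale flagged;
    thresholds apply to ratio / expected. Breakpoints sit at window
    resolution, refined by same-arm deletion split reads within one
    window when ``split_evidence`` is given.
    """
    calls: list[CNVCall] = []
    for arm, grp in windows.groupby("arm", sort=False):
        g = grp.sort_values("start").reset_index(drop=True)
        exp = (expected_ratio or {}).get(arm, 1.0)
        if exp <= 0:
            continue
        rel = g["copy_ratio"].to_numpy() / exp
        if smooth_windows > 1:
            rel = pd.Series(rel).rolling(
                smooth_windows, center=True, min_periods=1).median().to_numpy()
        state = np.where(rel >= up_thresh, 1,
                         np.where(rel <= down_thresh, -1, 0))
        runs = []      # (state, i, j) half-open over window indices
        i = 0
        while i < len(state):
            j = i
            while j < len(state) and state[j] == state[i]:
                j += 1
            if state[i] != 0:
                runs.append([int(state[i]), i, j])
            i = j
        ext_up = 1.0 + (up_thresh - 1.0) / 2.0
        ext_down = 1.0 - (1.0 - down_thresh) / 2.0
        merged = []
        for run in runs:
            if merged and merged[-1][0] == run[0]:
                gap = rel[merged[-1][2]:run[1]]
                bridge = ((gap >= ext_up).all() if run[0] == 1
                          else (gap <= ext_down).all())
                if bridge:
                    merged[-1][2] = run[2]
                    continue
            merged.append(run)
        for st, i, j in merged:
            if j - i < min_windows:
                continue
            seg = g.iloc[i:j]
            start = int(seg["start"].iloc[0]) + 1
            end = int(seg["end"].iloc[-1])
            ratio = float(seg["copy_ratio"].mean())
            typ = "duplication" if st == 1 else "deletion"
            start, end = _refine_breakpoints(
                split_evidence, arm, start, end,
                int(g["end"].iloc[0] - g["start"].iloc[0]))
            call = CNVCall(offspring_id, str(arm), start, end, typ,
                           ratio, j - i)
            try:
                call.mosaic_fraction_est = mosaic_fraction(ratio / exp, typ)
            except ValueError:
                call.mosaic_fraction_est = None
            calls.append(call)
    return calls


def _refine_breakpoints(split_evidence, arm, start, end, window) -> tuple[int, int]:
    if split_evidence is None or len(split_evidence) == 0:
        return start, end
    s = split_evidence[(split_evidence["arm"] == arm)
                       & (split_evidence["evidence_type"] == "split")]
    if len(s) == 0:
        return start, end
    near_start = s[abs(s["position"] - (start - 1)) <= window]
    if len(near_start):
        start = int(near_start["position"].median()) + 1
    mates = s["mate_target"].astype(str).str.extract(rf"^{arm}:(\d+)$")[0]
    mates = pd.to_numeric(mates, errors="coerce").dropna()
    near_end = mates[abs(mates - (end + 1)) <= window]
    if len(near_end):
        end = int(near_end.median()) - 1
    return start, end


def mosaic_fraction(mean_ratio: float, type: str) -> float:
    """Cell fraction carrying a heterozygous CNV from its mean copy ratio.

    A duplication in a fraction f of cells raises the ratio to
    1 + f/2, so f = 2(ratio - 1); a deletion lowers it to 1 - f/2, so
    f = 2(1 - ratio). Clipped to (0, 1]: 1.5 (or 0.5) is constitutive.
    """
    if type == "duplication":
        if mean_ratio <= 1.0:
            raise ValueError("duplication requires mean ratio > 1")
        f = 2.0 * (mean_ratio - 1.0)
    elif type == "deletion":
        if mean_ratio >= 1.0:
            raise ValueError("deletion requires mean ratio < 1")
        f = 2.0 * (1.0 - mean_ratio)
    else:
        raise ValueError(f"unknown CNV type {type!r}")
    return float(np.clip(f, 1e-9, 1.0))


def match_recurrent(call_sets: dict[str, list[CNVCall]],
                    breakpoint_tol: int = 5_000) -> list[dict]:
    """Group CNVs whose both breakpoints agree within ``breakpoint_tol``.

    ``call_sets`` maps a cohort/individual label to its calls. Groups
    spanning at least two labels are flagged recurrent.
    """
    flat = [(label, c) for label, calls in call_sets.items() for c in calls]
    groups: list[list[tuple[str, CNVCall]]] = []
    for label, c in flat:
        placed = False
        for grp in groups:
            ref = grp[0][1]
            if (ref.arm == c.arm
                    and abs(ref.start - c.start) <= breakpoint_tol
                    and abs(ref.end - c.end) <= breakpoint_tol):
                grp.append((label, c))
                placed = True
                break
        if not placed:
            groups.append([(label, c)])
    out = []
    for grp in groups:
        labels = sorted({lab for lab, _ in grp})
        out.append({
            "arm": grp[0][1].arm,
            "start": int(np.median([c.start for _, c in grp])),
            "end": int(np.median([c.end for _, c in grp])),
            "members": [(lab, c.offspring_id, c.type) for lab, c in grp],
            "recurrent": len(labels) >= 2,
        })
    return out


def annotate_flanks(call: CNVCall, te_annotation: pd.DataFrame,
                    flank_bp: int = 10_000) -> CNVCall:
    """TE families near each breakpoint; TE-mediated iff same family both sides.

    ``te_annotation`` is BED-schema: arm, start (0-based), end, name
    (family). Works equally from an annotation track or from TE
    insertion calls converted to intervals.
    """
    d = te_annotation[te_annotation["arm"] == call.arm]
    left = d[(d["end"] >= call.start - 1 - flank_bp) & (d["start"] <= call.start)]
    right = d[(d["end"] >= call.end - 1) & (d["start"] <= call.end + flank_bp)]
    fam_left = str(left["name"].iloc[0]) if len(left) else None
    fam_right = str(right["name"].iloc[0]) if len(right) else None
    call.flank_te = (fam_left, fam_right)
    call.te_mediated = fam_left is not None and fam_left == fam_right
    return call


def infer_tandem(call: CNVCall, evidence: pd.DataFrame,
                 tol: int = 2_000) -> CNVCall:
    """Tandem orientation from discordant pairs linking the dup's two ends."""
    if call.type != "duplication":
        call.tandem = None
        return call
    d = evidence[(evidence["arm"] == call.arm)
                 & (evidence["evidence_type"] == "discordant")]
    n_link = 0
    for r in d.itertuples():
        locus = str(r.mate_target)
        if ":" not in locus:
            continue
        arm2, _, pos2 = locus.partition(":")
        try:
            pos2 = int(pos2)
        except ValueError:
            continue
        if (arm2 == call.arm and abs(r.position - call.end) <= tol + call.size // 10
                and abs(pos2 - call.start) <= tol):
            n_link += 1
    call.tandem = n_link >= 3
    return call


def calls_to_frame(calls: list[CNVCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.offspring_id, c.arm, c.start, c.end, c.size, c.type,
          round(c.mean_ratio, 4), c.n_windows, c.mosaic_fraction_est,
          c.flank_te[0], c.flank_te[1], c.te_mediated, c.tandem)
         for c in calls],
        columns=["offspring_id", "arm", "start", "end", "size", "type",
                 "mean_ratio", "n_windows", "mosaic_fraction", "flank_left",
                 "flank_right", "te_mediated", "tandem"])
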