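"""Chromosome-dose classification and nondisjunction rates.

Arm-level mean depth normalized to the major-autosome baseline gives a
dose ratio per arm (1.0 = two copies on a diploid background). The Y is
assessed only over a mappable interval because of its repeat content.
Triploidy is confirmed by B-allele balance: heterozygous sites on a
trisomic AAB/ABB arm sit at 1/3 and 2/3 rather than 1/2.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .arms import AUTOSOME_BASELINE_ARMS, DEFAULT_Y_REGION
from .markers import MarkerTable

KARYOTYPE_CLASSES = (
    "XY", "X0", "XXY", "XX", "triplo4", "haplo4", "XX_AAA", "XXY_AAA",
    "mosaic", "ambiguous",
)

DOSE_HALF_WIDTH = 0.15   # copy state k accepted in [k/2 - w, k/2 + w]


@dataclass
class ArmDepthSummary:
    offspring_id: str
    arm_means: dict[str, float]
    baseline: float
    dose: dict[str, float]
    y_region: tuple[int, int]

    def ratio(self, arm: str) -> float:
        return self.dose.get(arm, np.nan)


@dataclass
class AlleleBalanceSummary:
    modes: dict[str, list[float]]        # arm -> KDE modes of B-allele fraction
    n_sites: dict[str, int]
    low_confidence: dict[str, bool]

    def is_triploid_like(self, arm: str) -> bool:
        m = self.modes.get(arm, [])
        if self.low_confidence.get(arm, True):
            return False
        has_third = any(abs(x - 1 / 3) < 0.09 for x in m)
        has_two_thirds = any(abs(x - 2 / 3) < 0.09 for x in m)
        has_half = any(abs(x - 0.5) < 0.06 for x in m)
        return (has_third or has_two_thirds) and not has_half


@dataclass
class KaryotypeCall:
    offspring_id: str
    label: str
    dose: dict[str, float]
    mosaic: bool = False
    mosaic_arms: dict[str, float] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)


def arm_depth(depth_track: pd.DataFrame, arm_table, offspring_id: str = "",
              y_region: tuple[int, int] = DEFAULT_Y_REGION,
              baseline_arms=AUTOSOME_BASELINE_ARMS) -> ArmDepthSummary:
    """Per-arm mean depth and dose ratios from a bedGraph-schema track.

    The mean is length-weighted over bins; the Y contributes only the
    bins inside ``y_region`` (1-based, inclusive). Dose = arm mean /
    mean of the baseline autosome arms.
    """
    if len(depth_track) == 0:
        raise ValueError("empty depth track")
    arm_names = {a.name for a in arm_table}
    means: dict[str, float] = {}
    for arm, grp in depth_track.groupby("arm"):
        if arm not in arm_names:
            continue
        if arm == "Y":
            lo, hi = y_region
            grp = grp[(grp["end"] > lo - 1) & (grp["start"] < hi)]
            if len(grp) == 0:
                means[arm] = 0.0
                continue
        w = (grp["end"] - grp["start"]).to_numpy(dtype=float)
        means[arm] = float(np.average(grp["value"], weights=w))
    missing = arm_names - set(means)
    for arm in missing:
        means[arm] = 0.0
    base = [means[a] for a in baseline_arms if a in means]
    if not base or np.mean(base) == 0:
        raise ValueError("no usable baseline autosome coverage")
    baseline = float(np.mean(base))
    dose = {a: means[a] / baseline for a in means}
    return ArmDepthSummary(offspring_id, means, baseline, dose, y_region)


def allele_balance(table: MarkerTable, min_sites: int = 10,
                   het_band: tuple[float, float] = (0.12, 0.88)
                   ) -> AlleleBalanceSummary:
    """Modes of the per-arm B-allele read-fraction distribution.

    Only intermediate fractions (within ``het_band``) inform the modes:
    a diploid heterozygous arm shows one mode near 0.5, a trisomic arm
    modes near 1/3 and/or 2/3, a hemizygous arm has no intermediate
    sites at all.
    """
    modes: dict[str, list[float]] = {}
    n_sites: dict[str, int] = {}
    lowconf: dict[str, bool] = {}
    for arm in table.df["arm"].unique():
        d = table.arm(arm)
        frac = d["b_frac"].dropna().to_numpy()
        het = frac[(frac > het_band[0]) & (frac < het_band[1])]
        n_sites[arm] = len(het)
        if len(het) < min_sites:
            modes[arm] = []
            lowconf[arm] = True
            continue
        lowconf[arm] = False
        grid = np.linspace(0.05, 0.95, 181)
        dens = gaussian_kde(het, bw_method=0.25)(grid)
        peak_idx = [i for i in range(1, len(grid) - 1)
                    if dens[i] >= dens[i - 1] and dens[i] >= dens[i + 1]
                    and dens[i] > 0.25 * dens.max()]
        modes[arm] = [float(grid[i]) for i in peak_idx]
    return AlleleBalanceSummary(modes=modes, n_sites=n_sites,
                                low_confidence=lowconf)


def _copy_state(ratio: float) -> int | None:
    """Nearest integer copy state if the ratio is inside its window."""
    for k in range(0, 5):
        if abs(ratio - k / 2) <= DOSE_HALF_WIDTH:
            return k
    return None


def classify(summary: ArmDepthSummary,
             balance: AlleleBalanceSummary | None = None) -> KaryotypeCall:
    """Map dose ratios (plus allele balance) to a karyotype class.

    Triploidy requires both an X dose near 2/3 of the autosomes and
    triploid allele-balance modes on the autosomes; a 4th-chromosome
    dose between integer states is flagged mosaic with the implied cell
    fraction. Doses in no-man's bands yield "ambiguous" with both
    neighboring states noted.
    """
    dose = summary.dose
    notes: list[str] = []
    x, y = dose.get("X", np.nan), dose.get("Y", 0.0)
    d4 = dose.get("4", np.nan)

    triploid_balance = False
    if balance is not None:
        auto_arms = [a for a in ("2L", "2R", "3L", "3R") if a in balance.modes]
        trip_votes = sum(balance.is_triploid_like(a) for a in auto_arms)
        triploid_balance = trip_votes >= max(1, len(auto_arms) // 2)

    # X dose ~2/3 on a triploid background (autosome baseline = 3 copies)
    if 0.58 <= x <= 0.76 and triploid_balance:
        label = "XXY_AAA" if y >= 0.25 else "XX_AAA"
        call = KaryotypeCall(summary.offspring_id, label, dose, notes=notes)
        _flag_mosaic_4(call, d4, triploid=True)
        return call

    kx, ky = _copy_state(x), _copy_state(y)
    k4 = _copy_state(d4)
    if kx is None:
        notes.append(f"X dose {x:.2f} between states")
        return KaryotypeCall(summary.offspring_id, "ambiguous", dose, notes=notes)
    if kx == 1 and ky == 1:
        label = "XY"
    elif kx == 1 and ky == 0:
        label = "X0"
    elif kx == 2 and ky == 1:
        label = "XXY"
    elif kx == 2 and ky == 0:
        label = "XX"
    else:
        notes.append(f"unrecognized sex-chromosome dose X={x:.2f} Y={y:.2f}")
        return KaryotypeCall(summary.offspring_id, "ambiguous", dose, notes=notes)

    call = KaryotypeCall(summary.offspring_id, label, dose, notes=notes)
    if k4 == 3:
        call.label = "triplo4" if label == "XY" else call.label
        call.notes.append("triplo4")
    elif k4 == 1:
        call.label = "haplo4" if label == "XY" else call.label
        call.notes.append("haplo4")
    elif k4 is None:
        _flag_mosaic_4(call, d4, triploid=False)
    return call


def _flag_mosaic_4(call: KaryotypeCall, d4: float, triploid: bool) -> None:
    if np.isnan(d4):
        return
    base_copies = 3.0 if triploid else 2.0
    expected = base_copies / 2.0 if not triploid else 1.0
    # dose is relative to the autosome baseline (2 or 3 copies): full dose = 1.0
    if abs(d4 - 1.0) <= DOSE_HALF_WIDTH:
        return
    # intermediate dose: fraction of cells having lost (or gained) one copy
    frac_loss = (1.0 - d4) * base_copies
    if 0.1 < frac_loss < 0.95:
        call.mosaic = True
        call.mosaic_arms["4"] = float(np.clip(frac_loss, 0.0, 1.0))
        call.notes.append(f"mosaic 4th loss, cell fraction ~{frac_loss:.2f}")
    elif -0.95 < frac_loss < -0.1:
        call.mosaic = True
        call.mosaic_arms["4"] = float(np.clip(-frac_loss, 0.0, 1.0))
        call.notes.append(f"mosaic 4th gain, cell fraction ~{-frac_loss:.2f}")


def ndj_rate(n_exceptional: int, n_normal: int) -> float:
    """Viability-corrected nondisjunction percentage, 100*2E/(N+2E).

    Exceptional zygote classes are recovered at half the frequency of
    normal ones (their reciprocal products die), so each surviving
    exceptional offspring stands for two nondisjunctional meioses.
    """
    if n_exceptional < 0 or n_normal < 0:
        raise ValueError("counts must be nonnegative")
    if n_exceptional == 0 and n_normal == 0:
        raise ValueError("at least one offspring required")
    return 100.0 * 2 * n_exceptional / (n_normal + 2 * n_exceptional)
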