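"""Monte Carlo model of recoverable noncrossover gene conversions.

Under a reduced-DSB genotype, how many NCOGCs should a sequenced cohort
have recovered if every DSB were repaired as one? Per trial, each
surveyed arm-meiosis draws a DSB count (default uniform over {0,1,2});
every DSB lands on one of four chromatids, converts a tract of uniform
length 250-1000 bp, and is recovered only when the single recovered
chromatid is the converted one (probability 1/4) and the tract covers
at least one informative marker. The observed count is then compared
against the simulated distribution and with Fisher's exact test.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact


@dataclass
class ArmSpec:
    name: str
    length: int
    n_meioses: int
    marker_positions: np.ndarray | None = None   # 1-based, sorted


@dataclass
class ExpectationConfig:
    """Defaults follow the reduced-DSB survey: 68 X plus 93 of each
    second-chromosome arm, 0-2 DSBs per arm per meiosis, 250-1000 bp
    tracts, ~1 informative marker per 500 bp, 100,000 trials."""

    arms: list[ArmSpec] = field(default_factory=lambda: [
        ArmSpec("X", 23_542_271, 68),
        ArmSpec("2L", 23_513_712, 93),
        ArmSpec("2R", 25_286_936, 93),
    ])
    dsb_values: tuple[int, ...] = (0, 1, 2)      # uniform per-arm draw
    tract_len_range: tuple[int, int] = (250, 1000)
    marker_density: float | None = 1.0 / 500.0   # used when no positions given
    chromatid_count: int = 4
    trials: int = 100_000
    seed: int = 0
    dsb_mode: str = "per_arm"                    # per_arm | genome_total
    genome_total_dsbs: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6)

    def validate(self) -> None:
        if self.trials < 1:
            raise ValueError("trials must be >= 1")
        if not self.arms:
            raise ValueError("at least one surveyed arm required")
        if self.tract_len_range[0] <= 0 or \
                self.tract_len_range[0] > self.tract_len_range[1]:
            raise ValueError("invalid tract length range")
        for a in self.arms:
            if a.n_meioses < 1:
                raise ValueError(f"arm {a.name}: surveyed meioses must be >= 1")
            if a.marker_positions is None and self.marker_density is None:
                raise ValueError(f"arm {a.name}: need marker positions or density")


@dataclass
class ExpectationResult:
    counts: np.ndarray          # recoverable NCOGCs per trial
    config: ExpectationConfig

    @property
    def mean(self) -> float:
        return float(self.counts.mean())

    def central_interval(self, level: float = 0.95) -> tuple[float, float]:
        lo = (1 - level) / 2 * 100
        return (float(np.percentile(self.counts, lo)),
                float(np.percentile(self.counts, 100 - lo)))

    def tail_probability(self, observed: int) -> float:
        """Two-sided empirical p for the observed count."""
        lo = float((self.counts <= observed).mean())
        hi = float((self.counts >= observed).mean())
        return min(1.0, 2 * min(lo, hi))

    def summary(self) -> dict:
        lo, hi = self.central_interval()
        return {"mean": self.mean, "p2.5": lo, "p97.5": hi,
                "trials": len(self.counts)}


def _coverage_probability_fn(arm: ArmSpec, density: float | None):
    """P(tract of length L covers >= 1 marker), vectorized over L.

    With explicit positions the probability is computed from a uniform
    tract start; with a density the marker process is Poisson and the
    exact marginal is 1 - exp(-rho*L).
    """
    if arm.marker_positions is not None:
        pos = np.asarray(arm.marker_positions)

        def from_positions(starts: np.ndarray, lengths: np.ndarray,
                           rng: np.random.Generator) -> np.ndarray:
            ends = np.minimum(starts + lengths - 1, arm.length)
            i0 = np.searchsorted(pos, starts, side="left")
            i1 = np.searchsorted(pos, ends, side="right")
            return i1 > i0

        return from_positions

    rho = float(density)

    def from_density(starts: np.ndarray, lengths: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
        p = 1.0 - np.exp(-rho * lengths)
        return rng.random(len(lengths)) < p

    return from_density


def simulate_expected_ncogc(config: ExpectationConfig) -> ExpectationResult:
    """Distribution of recoverable NCOGC counts over Monte Carlo trials."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo_t, hi_t = config.tract_len_range
    counts = np.zeros(config.trials, dtype=np.int64)
    cover_fns = {a.name: _coverage_probability_fn(a, config.marker_density)
                 for a in config.arms}

    if config.dsb_mode == "per_arm":
        per_arm = [(a, a.n_meioses) for a in config.arms]
        dsb_vals = np.asarray(config.dsb_values)
        for a, n_mei in per_arm:
            cover = cover_fns[a.name]
            total_units = n_mei * config.trials
            dsbs = rng.choice(dsb_vals, size=total_units)
            n_dsb_total = int(dsbs.sum())
            # recovered iff the recovered chromatid equals the converted one
            recovered = rng.integers(0, config.chromatid_count,
                                     size=n_dsb_total) == 0
            lengths = rng.integers(lo_t, hi_t + 1, size=n_dsb_total)
            starts = rng.integers(1, a.length + 1, size=n_dsb_total)
            covered = cover(starts, lengths, rng)
            ok = (recovered & covered).astype(np.int64)
            # map each DSB back to its trial
            trial_of_unit = np.repeat(np.arange(config.trials), n_mei)
            trial_of_dsb = np.repeat(trial_of_unit, dsbs)
            counts += np.bincount(trial_of_dsb, weights=ok,
                                  minlength=config.trials).astype(np.int64)
    elif config.dsb_mode == "genome_total":
        lens = np.array([a.length for a in config.arms], dtype=float)
        p_arm = lens / lens.sum()
        mei_weights = np.array([a.n_meioses for a in config.arms], dtype=float)
        n_mei = int(mei_weights.max())
        for t in range(config.trials):
            c = 0
            for m in range(n_mei):
                active = [i for i, a in enumerate(config.arms)
                          if m < a.n_meioses]
                k = int(rng.choice(config.genome_total_dsbs))
                for _ in range(k):
                    i = int(rng.choice(active, p=p_arm[active] / p_arm[active].sum()))
                    a = config.arms[i]
                    if rng.integers(0, config.chromatid_count) != 0:
                        continue
                    L = int(rng.integers(lo_t, hi_t + 1))
                    s = int(rng.integers(1, a.length + 1))
                    if cover_fns[a.name](np.array([s]), np.array([L]), rng)[0]:
                        c += 1
            counts[t] = c
    else:
        raise ValueError(f"unknown dsb_mode {config.dsb_mode!r}")
    return ExpectationResult(counts=counts, config=config)


def expected_from_rate(per_arm_rate: float, n_arms: int) -> dict:
    """Closed-form expected count: per-arm event rate x arms surveyed."""
    if per_arm_rate < 0 or n_arms < 0:
        raise ValueError("inputs must be nonnegative")
    value = per_arm_rate * n_arms
    return {"expected": value, "rounded": round(value)}


def compare_counts(observed: int,
                   expected: float | ExpectationResult,
                   opportunities: int | None = None) -> dict:
    """Observed vs expected recoverable counts.

    Builds a 2x2 table of recovered vs non-recovered opportunities
    (total DSB opportunities default to the simulation's surveyed
    arm-meioses x mean DSB count, or must be given for a scalar
    expectation) for Fisher's exact test; with a simulated distribution
    an empirical two-sided tail probability is added.
    """
    if observed < 0:
        raise ValueError("observed must be nonnegative")
    out: dict = {"observed": observed}
    if isinstance(expected, ExpectationResult):
        exp_val = expected.mean
        if opportunities is None:
            cfg = expected.config
            mean_dsb = float(np.mean(cfg.dsb_values))
            opportunities = int(round(
                sum(a.n_meioses for a in cfg.arms) * mean_dsb))
        out["empirical_p"] = expected.tail_probability(observed)
    else:
        exp_val = float(expected)
        if opportunities is None:
            raise ValueError("opportunities required with a scalar expectation")
    exp_int = int(round(exp_val))
    table = [[observed, max(opportunities - observed, 0)],
             [exp_int, max(opportunities - exp_int, 0)]]
    try:
        out["fisher_p"] = float(fisher_exact(table)[1])
    except ValueError as err:
        raise ValueError(f"malformed contingency table {table}") from err
    out["expected"] = exp_val
    out["opportunities"] = opportunities
    return out
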