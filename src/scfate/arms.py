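"""Chromosome-arm definitions.

Coordinates are 1-based inclusive throughout the library; emitted files
follow each format's own convention (VCF 1-based, BED/bedGraph 0-based
half-open).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd


@dataclass(frozen=True)
class Arm:
    """One chromosome arm with its euchromatic interval.

    Telomeric/centromeric heterochromatin (everything outside
    ``eu_start..eu_end``) is excluded from DSB placement and masked
    during marker calling.
    """

    name: str
    length: int
    eu_start: int
    eu_end: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"arm {self.name}: length must be positive")
        if not (1 <= self.eu_start <= self.eu_end <= self.length):
            raise ValueError(f"arm {self.name}: invalid euchromatin interval")

    @property
    def eu_length(self) -> int:
        return self.eu_end - self.eu_start + 1

    @property
    def chromosome(self) -> str:
        """Chromosome this arm belongs to (2L and 2R are one chromosome)."""
        if self.name in ("X", "Y", "4"):
            return self.name
        return self.name[0]


# Major autosome arms used as the diploid depth baseline.
AUTOSOME_BASELINE_ARMS = ("2L", "2R", "3L", "3R")

# Repeat-rich interval of the Y that is usable for dose estimation in dm6.
DEFAULT_Y_REGION = (332_000, 510_000)


def default_arm_table() -> list[Arm]:
    """Desk-scale synthetic genome: five major arms plus 4 and Y.

    Lengths are ~1/15 of D. melanogaster arms so whole-cohort simulation
    runs in seconds; 5% of each end (10% for the small heterochromatic 4
    and Y) is treated as heterochromatin.
    """
    def arm(name: str, length: int, frac: float = 0.05) -> Arm:
        pad = int(length * frac)
        return Arm(name, length, pad + 1, length - pad)

    return [
        arm("X", 2_000_000),
        arm("2L", 1_500_000),
        arm("2R", 1_500_000),
        arm("3L", 1_500_000),
        arm("3R", 1_500_000),
        arm("4", 400_000, frac=0.10),
        arm("Y", 600_000, frac=0.10),
    ]


def arms_by_name(arm_table: Iterable[Arm]) -> dict[str, Arm]:
    return {a.name: a for a in arm_table}


def write_arm_table(arm_table: Iterable[Arm], path) -> None:
    pd.DataFrame(
        [(a.name, a.length, a.eu_start, a.eu_end) for a in arm_table],
        columns=["arm", "length", "eu_start", "eu_end"],
    ).to_csv(path, sep="\t", index=False)


def read_arm_table(path) -> list[Arm]:
    df = pd.read_csv(path, sep="\t")
    return [
        Arm(str(r.arm), int(r.length), int(r.eu_start), int(r.eu_end))
        for r in df.itertuples()
    ]
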