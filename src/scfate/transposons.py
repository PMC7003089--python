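"""TE insertion detection from junction evidence, novelty and mosaicism.

Split and discordant reads are annotated to a TE family by shared
k-mers with the family consensus, clustered per family within a
position window, and emitted as candidate insertions when supported by
more than five reads (configurable). Novelty is established against
sibling and parental-stock call sets; mosaicism on a hemizygous arm
from the fraction of junction-spanning reads lacking TE sequence.
Rates are reported per arm per meiosis with the x4 haploid-product
correction: only one of four meiotic products is recovered.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest

log = logging.getLogger(__name__)


@dataclass
class TEInsertionCall:
    offspring_id: str
    arm: str
    position: int
    family: str
    n_split: int
    n_discordant: int
    n_spanning: int = 0
    novelty: str = ""            # novel | inherited | shared
    mosaic_status: str = ""      # constitutive | mosaic | indeterminate | ambiguous
    parental_origin: str = "unknown"

    @property
    def support(self) -> int:
        return self.n_split + self.n_discordant

    @property
    def spanning_fraction(self) -> float:
        tot = self.n_spanning + self.support
        return self.n_spanning / tot if tot else float("nan")


@dataclass
class RateEstimate:
    """Events per arm per meiosis with the x4 haploid-product correction."""

    events: int
    arm_meioses: int
    correction: int = 4

    @property
    def rate(self) -> float:
        return self.events * self.correction / self.arm_meioses

    @property
    def rate_2dp(self) -> float:
        return round(self.rate, 2)


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def annotate_evidence(evidence: pd.DataFrame, te_library: dict[str, str],
                      k: int = 21, min_match_fraction: float = 0.5
                      ) -> pd.DataFrame:
    """Assign each junction read a TE family by shared k-mer fraction.

    Reads carrying a sequence are matched against every library
    consensus; the family sharing the largest fraction of the read's
    k-mers wins if it clears ``min_match_fraction``. Reads without
    sequence keep their ``mate_target`` tag when it names a library
    family. Unassignable reads are dropped (count logged). Spanning
    records pass through untouched.
    """
    if not te_library:
        raise ValueError("empty TE library")
    lib_kmers = {fam: _kmers(seq, k) for fam, seq in te_library.items()}
    spanning = evidence[evidence["evidence_type"] == "spanning"]
    junc = evidence[evidence["evidence_type"] != "spanning"].copy()

    families = []
    for r in junc.itertuples():
        seq = getattr(r, "sequence", ".")
        fam_out = None
        if isinstance(seq, str) and len(seq) >= k and set(seq) <= set("ACGTN"):
            km = _kmers(seq, k)
            best, best_frac = None, 0.0
            for fam, lk in lib_kmers.items():
                frac = len(km & lk) / len(km) if km else 0.0
                if frac > best_frac:
                    best, best_frac = fam, frac
            if best is not None and best_frac >= min_match_fraction:
                fam_out = best
        elif str(r.mate_target) in te_library:
            fam_out = str(r.mate_target)
        families.append(fam_out)
    junc["family"] = families
    n_dropped = sum(f is None for f in families)
    if n_dropped:
        log.info("annotate_evidence: dropped %d unassignable reads", n_dropped)
    junc = junc[junc["family"].notna()]
    spanning = spanning.assign(family=None)
    return pd.concat([junc, spanning], ignore_index=True)


def cluster_insertions(tagged: pd.DataFrame, min_reads: int = 5,
                       window_bp: int = 500,
                       offspring_id: str | None = None
                       ) -> list[TEInsertionCall]:
    """Single-linkage position clusters per (arm, family) -> calls.

    A cluster is emitted iff its split+discordant support exceeds
    ``min_reads`` (the default 5 means at least 6 reads). Spanning
    reads within the cluster window are attached for mosaicism work.
    """
    junc = tagged[tagged["evidence_type"].isin(("split", "discordant"))]
    spanning = tagged[tagged["evidence_type"] == "spanning"]
    calls: list[TEInsertionCall] = []
    for (oid, arm, fam), grp in junc.groupby(["offspring_id", "arm", "family"]):
        if offspring_id is not None and oid != offspring_id:
            continue
        pos = np.sort(grp["position"].to_numpy())
        types = grp.sort_values("position")["evidence_type"].to_numpy()
        start = 0
        for i in range(1, len(pos) + 1):
            if i == len(pos) or pos[i] - pos[i - 1] > window_bp:
                members = types[start:i]
                if len(members) > min_reads:
                    n_split = int((members == "split").sum())
                    center = int(np.median(pos[start:i][members == "split"])
                                 if n_split else np.median(pos[start:i]))
                    span_near = spanning[
                        (spanning["offspring_id"] == oid)
                        & (spanning["arm"] == arm)
                        & (abs(spanning["position"] - center) <= window_bp)]
                    calls.append(TEInsertionCall(
                        offspring_id=str(oid), arm=str(arm), position=center,
                        family=str(fam), n_split=n_split,
                        n_discordant=len(members) - n_split,
                        n_spanning=len(span_near)))
                start = i
    calls.sort(key=lambda c: (c.offspring_id, c.arm, c.position))
    return calls


def filter_novel(cohort_calls: dict[str, list[TEInsertionCall]],
                 stock_calls: list[TEInsertionCall] | None = None,
                 position_tolerance: int = 100,
                 haplotypes: dict[str, dict[str, str]] | None = None
                 ) -> list[TEInsertionCall]:
    """Assign novelty verdicts across a sibling cohort.

    A call matching a parental-stock call (same arm and family within
    ``position_tolerance``) is inherited; matching a call in another
    sibling — on the same haplotype background where ``haplotypes``
    (offspring -> arm -> hap) are supplied — is shared; otherwise novel.
    """
    stock_idx = [(c.arm, c.family, c.position) for c in (stock_calls or [])]
    out: list[TEInsertionCall] = []
    for oid, calls in cohort_calls.items():
        for c in calls:
            if any(a == c.arm and f == c.family
                   and abs(p - c.position) <= position_tolerance
                   for a, f, p in stock_idx):
                c.novelty = "inherited"
                out.append(c)
                continue
            shared = False
            for o2, calls2 in cohort_calls.items():
                if o2 == oid:
                    continue
                if haplotypes is not None:
                    h1 = haplotypes.get(oid, {}).get(c.arm)
                    h2 = haplotypes.get(o2, {}).get(c.arm)
                    if h1 is not None and h2 is not None and h1 != h2:
                        continue
                if any(c2.arm == c.arm and c2.family == c.family
                       and abs(c2.position - c.position) <= position_tolerance
                       for c2 in calls2):
                    shared = True
                    break
            c.novelty = "shared" if shared else "novel"
            out.append(c)
    return out


def flag_mosaic(call: TEInsertionCall, min_total_reads: int = 8,
                mosaic_band: tuple[float, float] = (0.25, 0.75),
                alpha: float = 0.05) -> str:
    """Mosaic status from junction vs junction-spanning read support.

    On a hemizygous arm a constitutive insertion leaves no spanning
    reads; an insertion present in ~half the cells (arising between the
    first and second mitotic division) leaves about equal junction and
    spanning reads. The insertion-support fraction is tested against
    0.5 with an exact binomial test inside ``mosaic_band``.
    """
    total = call.support + call.n_spanning
    if total < min_total_reads:
        call.mosaic_status = "indeterminate"
        return call.mosaic_status
    frac = call.support / total
    if frac >= 0.9:
        call.mosaic_status = "constitutive"
    elif (mosaic_band[0] <= frac <= mosaic_band[1]
          and binomtest(call.support, total, 0.5).pvalue >= alpha):
        call.mosaic_status = "mosaic"
    else:
        call.mosaic_status = "ambiguous"
    return call.mosaic_status


def insertion_rate(n_events: int, arm_meioses: int) -> RateEstimate:
    """De novo insertion rate per arm per meiosis.

    rate = events x 4 / arm-meioses; the factor 4 corrects for the
    single recovered product of each meiosis.
    """
    if arm_meioses <= 0:
        raise ValueError("arm_meioses must be positive")
    if n_events < 0:
        raise ValueError("n_events must be nonnegative")
    return RateEstimate(events=n_events, arm_meioses=arm_meioses)


def calls_to_frame(calls: list[TEInsertionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.offspring_id, c.arm, c.position, c.family, c.n_split,
          c.n_discordant, c.n_spanning, c.novelty, c.mosaic_status,
          c.parental_origin) for c in calls],
        columns=["offspring_id", "arm", "position", "family", "n_split",
                 "n_discordant", "n_spanning", "novelty", "mosaic_status",
                 "parental_origin"])
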