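"""Parental-haplotype marker panels and per-offspring haplotype assignment.

The experimental design has a mother heterozygous for two strain
haplotypes (A and B) crossed to a father isogenic for one of them.
Along each arm of an offspring, every informative marker is assigned
the maternal haplotype it reports: directly on the hemizygous male X,
and by presence/absence of the non-paternal allele on autosomes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from . import io as sio

log = logging.getLogger(__name__)

CALLS = ("A", "B", "HET", "MISSING")


@dataclass(frozen=True)
class MarkerSite:
    arm: str
    pos: int
    allele_A: str
    allele_B: str
    span: int = 1   # reference footprint in bp (1 for a SNP)

    def __post_init__(self) -> None:
        if self.allele_A == self.allele_B:
            raise ValueError(f"marker {self.arm}:{self.pos} is not biallelic")


@dataclass
class MarkerTable:
    """Ordered per-arm haplotype assignments for one offspring.

    ``df`` columns: arm, pos, allele_A, allele_B, span, call, depth,
    qual, b_frac (fraction of reads supporting the B allele; NaN when
    missing).
    """

    offspring_id: str
    df: pd.DataFrame

    def arm(self, arm: str) -> pd.DataFrame:
        return self.df[self.df["arm"] == arm]

    def informative(self, arm: str | None = None) -> pd.DataFrame:
        d = self.df if arm is None else self.arm(arm)
        return d[d["call"].isin(("A", "B"))]

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path, offspring_id: str = "") -> "MarkerTable":
        return cls(offspring_id, pd.read_csv(path, sep="\t", dtype={"arm": str}))


def _as_frame(vcf) -> pd.DataFrame:
    if isinstance(vcf, pd.DataFrame):
        return vcf
    return sio.read_vcf(vcf)


def build_marker_panel(parentA_vcf, parentB_vcf) -> pd.DataFrame:
    """Sites homozygous in both parents for different alleles.

    Heterozygous, missing, multi-allelic and allele-conflicting sites
    are dropped; counts of each are logged. Returns a frame with
    columns arm, pos, allele_A, allele_B, span.
    """
    a = _as_frame(parentA_vcf)
    b = _as_frame(parentB_vcf)
    contigs_a, contigs_b = set(a["arm"]), set(b["arm"])
    if contigs_a and contigs_b and not (contigs_a & contigs_b):
        raise ValueError(
            f"parental VCFs share no contigs: {sorted(contigs_a)[:3]} vs "
            f"{sorted(contigs_b)[:3]} — mismatched reference builds?")

    def hom_allele(row):
        if row.gt == "0/0":
            return row.ref
        if row.gt == "1/1":
            return row.alt
        return None

    merged = a.merge(b, on=["arm", "pos"], suffixes=("_a", "_b"), how="inner")
    n_in = len(merged)
    allele_a = []
    allele_b = []
    keep = []
    for row in merged.itertuples():
        aa = row.ref_a if row.gt_a == "0/0" else (row.alt_a if row.gt_a == "1/1" else None)
        ab = row.ref_b if row.gt_b == "0/0" else (row.alt_b if row.gt_b == "1/1" else None)
        ok = (aa is not None and ab is not None and aa != ab
              and row.ref_a == row.ref_b and "." not in (aa, ab))
        keep.append(ok)
        allele_a.append(aa)
        allele_b.append(ab)
    merged["allele_A"] = allele_a
    merged["allele_B"] = allele_b
    panel = merged.loc[keep, ["arm", "pos", "allele_A", "allele_B", "ref_a"]].copy()
    panel["span"] = panel["ref_a"].str.len()
    panel = panel.drop(columns=["ref_a"]).sort_values(["arm", "pos"]).reset_index(drop=True)
    log.info("marker panel: %d/%d joint sites informative (%d dropped)",
             len(panel), n_in, n_in - len(panel))
    return panel


def _mask_trees(mask: pd.DataFrame | None) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    if mask is None or len(mask) == 0:
        return trees
    for r in mask.itertuples():
        if int(r.end) > int(r.start):
            trees.setdefault(str(r.arm), IntervalTree()).addi(
                int(r.start), int(r.end))
    return trees


def assign_haplotypes(
    offspring_vcf,
    panel: pd.DataFrame,
    min_depth: int = 3,
    min_qual: float = 30.0,
    repeat_mask: pd.DataFrame | None = None,
    hemizygous_arms: tuple[str, ...] = ("X",),
    paternal_hap: str = "B",
) -> MarkerTable:
    """Assign A/B/HET/MISSING at every panel site for one offspring.

    Sites inside the repeat mask or failing the depth/quality filters
    are MISSING. On hemizygous arms the call is the observed allele; on
    autosomes the maternal haplotype is read from presence of the
    non-paternal allele (a heterozygous call reports the non-paternal
    maternal allele, a homozygous-paternal call reports the paternal
    one). A genuinely heterozygous non-paternal pattern is HET.
    """
    if len(panel) == 0:
        raise ValueError("marker panel is empty")
    if paternal_hap not in ("A", "B"):
        raise ValueError("paternal_hap must be 'A' or 'B'")
    off = _as_frame(offspring_vcf)
    if isinstance(offspring_vcf, str) or hasattr(offspring_vcf, "__fspath__"):
        oid = str(offspring_vcf)
    else:
        oid = ""
    missing_contigs = set(panel["arm"]) - set(off["arm"])
    if missing_contigs:
        log.warning("offspring VCF lacks contigs %s; sites there are MISSING",
                    sorted(missing_contigs))
    trees = _mask_trees(repeat_mask)

    merged = panel.merge(
        off[["arm", "pos", "ref", "alt", "gt", "depth", "ad_alt", "gq"]],
        on=["arm", "pos"], how="left")
    calls = np.full(len(merged), "MISSING", dtype=object)
    b_frac = np.full(len(merged), np.nan)
    depth = merged["depth"].fillna(0).to_numpy()
    qual = merged["gq"].fillna(-1).to_numpy(dtype=float)

    for i, row in enumerate(merged.itertuples()):
        tree = trees.get(row.arm)
        if tree is not None and tree.overlaps(row.pos - 1, row.pos - 1 + row.span):
            continue  # masked -> MISSING
        gt = row.gt
        if not isinstance(gt, str) or gt in (".", "./."):
            continue
        if row.depth < min_depth or row.gq < min_qual:
            continue
        # which of A/B does the ALT allele correspond to at this site?
        alt_is_b = (row.alt == row.allele_B)
        if not alt_is_b and row.alt != row.allele_A:
            continue  # third allele: uninterpretable
        if row.depth > 0 and row.ad_alt >= 0:
            f_alt = row.ad_alt / row.depth
            b_frac[i] = f_alt if alt_is_b else 1.0 - f_alt
        has_ref = "0" in gt.split("/")
        has_alt = "1" in gt.split("/")
        obs = set()
        if has_ref:
            obs.add("A" if row.ref == row.allele_A else "B")
        if has_alt:
            obs.add("B" if alt_is_b else "A")
        if row.arm in hemizygous_arms:
            calls[i] = obs.pop() if len(obs) == 1 else "HET"
        else:
            maternal = "A" if paternal_hap == "B" else "B"
            if obs == {"A", "B"}:
                calls[i] = maternal
            elif obs == {paternal_hap}:
                calls[i] = paternal_hap
            elif obs == {maternal}:
                # non-paternal homozygote: unexpected under the cross; flag HET
                calls[i] = "HET"
    out = merged[["arm", "pos", "allele_A", "allele_B", "span"]].copy()
    out["call"] = calls
    out["depth"] = depth.astype(int)
    out["qual"] = qual
    out["b_frac"] = b_frac
    return MarkerTable(offspring_id=oid, df=out)
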