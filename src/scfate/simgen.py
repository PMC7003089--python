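"""Synthetic meiosis and sequencing-feature generator.

Emulates the experimental design of whole-genome sequencing of single
meiotic products from a female heterozygous for two strain haplotypes
(A and B) crossed to a male isogenic for haplotype B: parental marker
panels (~1 SNP per 500 bp), meioses with configurable DSB counts
(18-20 in wild type, 20-40% of that in SC-null mutants), DSB fates
(crossover, noncrossover gene-conversion tract of 250-1000 bp, or a
deletion starting at the break), de novo TE insertions, segregation
errors (X and 4th nondisjunction, triploidy), and copy-number variants
(including 50%-mosaic events).

Rather than simulating reads and realigning, the generator synthesizes
the alignment-level features the pipeline consumes directly: per-site
genotype calls with allelic depths, binned depth tracks with Poisson
noise, and split/discordant/spanning junction-evidence records.
"""
from __future__ import annotations

import copy
import json
import os
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import io as sio
from .arms import Arm, arms_by_name, default_arm_table, write_arm_table

BASES = np.array(list("ACGT"))

DELETION_CLASSES = {"1-10": (1, 10), "1-1000": (1, 1000)}

EVENT_KINDS = {
    "CO", "NCOGC", "DSB_DELETION", "TE_INSERTION", "CNV_DUP", "CNV_DEL",
    "NDJ_X", "NDJ_4", "TRIPLOID", "MOSAIC",
}

TE_FAMILIES = ("roo", "doc", "hobo", "copia", "blood", "jockey")


class ConfigurationError(ValueError):
    pass


class PolicyError(ValueError):
    """A truth event was requested that the genotype's policy forbids."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults follow the source study's design: parental haplotypes
    differing about once per 500 bp, 18-20 DSBs per wild-type meiosis,
    conversion tracts of 250-1000 bp, DSB-site deletions in a 1-10 bp or
    1-1000 bp class, 2-6 DSBs per benchmark genome, ~10x depth per
    haploid genome (20x combined), 200-bp insert libraries.
    """

    arm_table: list[Arm] = field(default_factory=default_arm_table)
    snp_rate: float = 1.0 / 500.0
    dsb_per_meiosis: tuple[int, int] = (18, 20)
    dsb_fraction: float = 1.0
    tract_len_range: tuple[int, int] = (250, 1000)
    deletion_size_class: str = "1-10"
    dsb_per_genome_benchmark: tuple[int, int] = (2, 6)
    mean_depth: float = 10.0          # per haploid genome; combined = 2x this
    insert_size: int = 200
    read_len: int = 150
    seed: int = 0
    # implementation parameters
    depth_bin: int = 100
    indel_vcf_max: int = 20           # deletions above this emit split reads
    capture_prob: float = 0.8         # P(a junction-overlapping read is captured)
    paternal_hap: str = "B"
    marker_error_rate: float = 0.0
    indel_marker_fraction: float = 0.02
    background_indel_count: int = 30  # inherited indel polymorphisms per cohort
    noise_low_qual_prob: float = 0.1  # fraction of indel calls drawn low-quality

    def __post_init__(self) -> None:
        if self.snp_rate < 0:
            raise ConfigurationError("snp_rate must be >= 0")
        if not 0.0 <= self.dsb_fraction <= 1.0:
            raise ConfigurationError("dsb_fraction must lie in [0, 1]")
        if self.tract_len_range[0] > self.tract_len_range[1]:
            raise ConfigurationError("tract_len_range min must be <= max")
        if self.tract_len_range[0] <= 0:
            raise ConfigurationError("tract lengths must be positive")
        if self.deletion_size_class not in DELETION_CLASSES:
            raise ConfigurationError(
                f"deletion_size_class must be one of {sorted(DELETION_CLASSES)}")
        if self.mean_depth <= 0 or self.insert_size <= 0 or self.read_len <= 0:
            raise ConfigurationError("depth, insert size and read length must be positive")
        for a in self.arm_table:
            if a.length <= 0:
                raise ConfigurationError(f"arm {a.name} has non-positive length")

    @property
    def combined_depth(self) -> float:
        return 2.0 * self.mean_depth


@dataclass(frozen=True)
class GenotypePolicy:
    """Maternal genotype: DSB dose, allowed fates, and event rates.

    ``te_rate`` is the de novo TE insertion rate per arm per meiosis
    (before the 1/4 recovery thinning); nondisjunction rates are true
    per-meiosis rates, applied with the standard half-viability of
    exceptional zygotes.
    """

    name: str
    dsb_fraction: float
    co_allowed: bool
    co_prob: float
    del_prob: float
    te_rate: float = 0.18
    ndj_x_rate: float = 0.0
    ndj_4_rate: float = 0.0
    triploid_rate: float = 0.0


POLICIES = {
    "wildtype": GenotypePolicy("wildtype", 1.0, True, 0.30, 0.01, te_rate=0.18),
    "c3g_het": GenotypePolicy("c3g_het", 1.0, True, 0.30, 0.01, te_rate=0.18),
    "c3g_hom": GenotypePolicy(
        "c3g_hom", 0.2, False, 0.0, 0.10, te_rate=0.58,
        ndj_x_rate=0.42, ndj_4_rate=0.12, triploid_rate=0.03),
    "corolla_hom": GenotypePolicy(
        "corolla_hom", 0.4, False, 0.0, 0.03, te_rate=0.19,
        ndj_x_rate=0.20, ndj_4_rate=0.20),
}


@dataclass
class TruthEvent:
    kind: str
    arm: str
    start: int
    end: int
    chromatid: int = 0      # 1-4 for chromatid-borne events, 0 otherwise
    payload: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.start > self.end:
            raise ValueError("event start must be <= end")
        if self.chromatid not in (0, 1, 2, 3, 4):
            raise ValueError("chromatid index must be in 1..4 (0 = not chromatid-borne)")
        frac = self.payload.get("cell_fraction")
        if frac is not None and not 0.0 < frac < 1.0001:
            raise ValueError("mosaic cell fraction must lie in (0, 1]")

    def to_dict(self) -> dict:
        return {"kind": self.kind, "arm": self.arm, "start": self.start,
                "end": self.end, "chromatid": self.chromatid,
                "payload": self.payload}


@dataclass
class ParentalPanel:
    """Marker sites distinguishing haplotypes A (reference) and B."""

    markers: pd.DataFrame          # arm, pos, ref, alt, span
    arm_table: list[Arm]
    te_library: dict[str, str]
    background_indels: pd.DataFrame | None = None

    def arm_markers(self, arm: str) -> pd.DataFrame:
        return self.markers[self.markers["arm"] == arm]

    def n_markers(self) -> int:
        return len(self.markers)

    def repeat_mask(self) -> pd.DataFrame:
        """Heterochromatic complement of the euchromatin (BED, 0-based half-open)."""
        rows = []
        for a in self.arm_table:
            if a.eu_start > 1:
                rows.append((a.name, 0, a.eu_start - 1))
            if a.eu_end < a.length:
                rows.append((a.name, a.eu_end, a.length))
        return pd.DataFrame(rows, columns=["arm", "start", "end"])

    def write(self, outdir) -> None:
        os.makedirs(outdir, exist_ok=True)
        contigs = {a.name: a.length for a in self.arm_table}
        m = self.markers
        n = len(m)
        recs_a = pd.DataFrame({
            "arm": m["arm"], "pos": m["pos"], "ref": m["ref"], "alt": m["alt"],
            "qual": 999.0, "gt": ["0/0"] * n, "depth": 30, "ad_alt": 0, "gq": 99})
        recs_b = recs_a.copy()
        recs_b["gt"] = "1/1"
        recs_b["ad_alt"] = 30
        sio.write_vcf(recs_a, os.path.join(outdir, "parentA.vcf"), "parentA", contigs)
        sio.write_vcf(recs_b, os.path.join(outdir, "parentB.vcf"), "parentB", contigs)
        sio.write_bed(self.repeat_mask(), os.path.join(outdir, "repeat_mask.bed"))
        write_arm_table(self.arm_table, os.path.join(outdir, "arms.tsv"))
        sio.write_fasta(self.te_library, os.path.join(outdir, "te_library.fasta"))


@dataclass
class MeiosisResult:
    """All truth events of one meiosis plus the recovered product."""

    events: list[TruthEvent]
    recovered: dict[str, int]        # chromosome -> recovered chromatid (1-4)
    karyotype: dict                  # per-arm copy numbers + class label
    genotype: str


@dataclass
class OffspringDataset:
    offspring_id: str
    genotype: str
    markers: pd.DataFrame | None     # VCF-schema frame
    indels: pd.DataFrame | None
    depth: pd.DataFrame | None       # bedGraph-schema frame
    evidence: pd.DataFrame | None
    truth: list[TruthEvent]
    karyotype: dict

    def write(self, outdir, contigs: dict[str, int]) -> dict[str, str]:
        os.makedirs(outdir, exist_ok=True)
        oid = self.offspring_id
        paths = {}
        if self.markers is not None:
            paths["markers"] = os.path.join(outdir, f"{oid}.markers.vcf")
            sio.write_vcf(self.markers, paths["markers"], oid, contigs)
        if self.indels is not None:
            paths["indels"] = os.path.join(outdir, f"{oid}.indels.vcf")
            sio.write_vcf(self.indels, paths["indels"], oid, contigs)
        if self.depth is not None:
            paths["depth"] = os.path.join(outdir, f"{oid}.depth.bedgraph")
            sio.write_bedgraph(self.depth, paths["depth"])
        if self.evidence is not None:
            paths["evidence"] = os.path.join(outdir, f"{oid}.evidence.tsv")
            sio.write_evidence(self.evidence, paths["evidence"])
        paths["truth"] = os.path.join(outdir, f"{oid}.truth.json")
        with open(paths["truth"], "w") as fh:
            json.dump({"offspring_id": oid, "genotype": self.genotype,
                       "karyotype": self.karyotype,
                       "events": [e.to_dict() for e in self.truth]}, fh, indent=1)
        return paths


def _rng(config: SimConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, *key]))


def make_te_library(seed: int = 7, families: Sequence[str] = TE_FAMILIES,
                    length: int = 3000) -> dict[str, str]:
    """Synthetic stand-in for a canonical TE consensus library.

    Random sequences are mutually dissimilar enough that 21-mer matching
    assigns reads unambiguously.
    """
    rng = np.random.default_rng(seed)
    return {f: "".join(rng.choice(BASES, size=length)) for f in families}


def generate_parents(config: SimConfig) -> ParentalPanel:
    """Place biallelic markers along each arm at ``snp_rate``.

    Haplotype A is the reference; each marker's B allele is a different
    random base (or, for a small fraction, a 1-10 bp deletion relative
    to A, giving the panel indel markers with a multi-base reference
    footprint).
    """
    rng = _rng(config, 0)
    rows = []
    for arm in config.arm_table:
        if arm.name == "Y":
            continue  # maternal panel: the mother carries no Y
        n = rng.poisson(config.snp_rate * arm.length)
        if n == 0:
            continue
        pos = np.sort(rng.choice(np.arange(1, arm.length + 1), size=n, replace=False))
        refs = rng.choice(BASES, size=n)
        alts = rng.choice(BASES, size=n)
        same = alts == refs
        while same.any():
            alts[same] = rng.choice(BASES, size=int(same.sum()))
            same = alts == refs
        spans = np.ones(n, dtype=int)
        is_indel = rng.random(n) < config.indel_marker_fraction
        for i in np.flatnonzero(is_indel):
            dlen = int(rng.integers(1, 11))
            refs_i = refs[i] + "".join(rng.choice(BASES, size=dlen))
            refs = refs.astype(object)
            refs[i] = refs_i
            alts[i] = refs_i[0]
            spans[i] = dlen + 1
        rows.append(pd.DataFrame({
            "arm": arm.name, "pos": pos, "ref": refs.astype(str),
            "alt": alts.astype(str), "span": spans}))
    markers = (pd.concat(rows, ignore_index=True) if rows
               else pd.DataFrame(columns=["arm", "pos", "ref", "alt", "span"]))
    bg = _background_indels(config, rng)
    return ParentalPanel(markers=markers, arm_table=list(config.arm_table),
                         te_library=make_te_library(), background_indels=bg)


def write_parent_fasta(panel: ParentalPanel, config: SimConfig, path) -> None:
    """Sequence-level export of the two parental haplotypes.

    Haplotype A is a seeded random reference; haplotype B substitutes
    the B allele at every SNP marker (indel markers substitute their
    first base only, keeping coordinates aligned across haplotypes).
    Intended for users who want to run a sequence-level tool; the
    pipeline itself never reads these.
    """
    rng = _rng(config, 9)
    seqs: dict[str, str] = {}
    for arm in config.arm_table:
        ref = rng.choice(BASES, size=arm.length)
        m = panel.arm_markers(arm.name)
        alt = ref.copy()
        for r in m.itertuples():
            ref[r.pos - 1] = r.ref[0]
            alt[r.pos - 1] = r.alt[0]
        seqs[f"{arm.name}_hapA"] = "".join(ref)
        seqs[f"{arm.name}_hapB"] = "".join(alt)
    sio.write_fasta(seqs, path)


def _background_indels(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Inherited deletion polymorphisms segregating in the cohort."""
    n = config.background_indel_count
    if n == 0:
        return pd.DataFrame(columns=["arm", "pos", "size", "freq"])
    arms = config.arm_table
    lens = np.array([a.length for a in arms], dtype=float)
    idx = rng.choice(len(arms), size=n, p=lens / lens.sum())
    rows = []
    for i in idx:
        a = arms[i]
        rows.append((a.name, int(rng.integers(1, a.length + 1)),
                     int(rng.integers(1, 15)), 0.5))
    return pd.DataFrame(rows, columns=["arm", "pos", "size", "freq"])


def _chromatid_hap(chromatid: int) -> str:
    return "A" if chromatid <= 2 else "B"


def simulate_meiosis(
    panel: ParentalPanel,
    config: SimConfig,
    genotype: str = "wildtype",
    meiosis_index: int = 0,
    forced_events: Sequence[TruthEvent] | None = None,
) -> MeiosisResult:
    """Simulate one meiosis and pick one of the four products.

    DSB count is drawn uniformly from ``dsb_per_meiosis`` then thinned by
    the genotype's DSB fraction. Each DSB lands uniformly in euchromatin
    on a uniformly chosen chromatid (1-2 = haplotype A, 3-4 = B) and is
    resolved as a CO (if the genotype permits), an NCOGC tract, or a
    DSB-site deletion. One chromatid per chromosome is recovered.
    """
    policy = POLICIES[genotype] if isinstance(genotype, str) else genotype
    rng = _rng(config, 1, meiosis_index)
    arms = [a for a in config.arm_table if a.name != "Y"]
    eu_lens = np.array([a.eu_length for a in arms], dtype=float)
    p_arm = eu_lens / eu_lens.sum()

    events: list[TruthEvent] = []
    if forced_events:
        for ev in forced_events:
            if ev.kind == "CO" and not policy.co_allowed:
                raise PolicyError(
                    f"crossover requested for SC-null genotype {policy.name}")
            events.append(copy.deepcopy(ev))

    n_total = int(rng.integers(config.dsb_per_meiosis[0],
                               config.dsb_per_meiosis[1] + 1))
    n_dsb = int(rng.binomial(n_total, policy.dsb_fraction * config.dsb_fraction))
    lo_del, hi_del = DELETION_CLASSES[config.deletion_size_class]
    lo_t, hi_t = config.tract_len_range
    for _ in range(n_dsb):
        ai = int(rng.choice(len(arms), p=p_arm))
        arm = arms[ai]
        pos = int(rng.integers(arm.eu_start, arm.eu_end + 1))
        chromatid = int(rng.integers(1, 5))
        u = rng.random()
        if policy.co_allowed and u < policy.co_prob:
            partner = int(rng.integers(1, 3))
            partner = partner if chromatid > 2 else partner + 2
            events.append(TruthEvent("CO", arm.name, pos, pos, chromatid,
                                     {"partner_chromatid": partner}))
        elif u < policy.co_prob + policy.del_prob:
            size = int(rng.integers(lo_del, hi_del + 1))
            end = min(pos + size - 1, arm.eu_end)
            events.append(TruthEvent("DSB_DELETION", arm.name, pos, end,
                                     chromatid, {"size": end - pos + 1}))
        else:
            tract = int(rng.integers(lo_t, hi_t + 1))
            end = min(pos + tract - 1, arm.eu_end)
            events.append(TruthEvent("NCOGC", arm.name, pos, end, chromatid,
                                     {"tract_len": end - pos + 1}))

    # De novo TE insertions: policy.te_rate per arm per meiosis, uniform
    # over the four chromatids (only 1/4 are recovered downstream).
    fam_names = list(panel.te_library)
    for arm in arms:
        k = rng.poisson(policy.te_rate)
        for _ in range(k):
            pos = int(rng.integers(arm.eu_start, arm.eu_end + 1))
            events.append(TruthEvent(
                "TE_INSERTION", arm.name, pos, pos, int(rng.integers(1, 5)),
                {"family": str(rng.choice(fam_names)), "cell_fraction": 1.0}))

    recovered = {a.chromosome: 0 for a in arms}
    for chrom in recovered:
        recovered[chrom] = int(rng.integers(1, 5))

    karyotype = _draw_karyotype(policy, rng, config, events)
    return MeiosisResult(events=events, recovered=recovered,
                         karyotype=karyotype, genotype=policy.name)


def _draw_karyotype(policy: GenotypePolicy, rng: np.random.Generator,
                    config: SimConfig, events: list[TruthEvent]) -> dict:
    """Segregation outcome for a (by default male) offspring.

    Exceptional zygote classes from nondisjunction survive at half the
    rate of normal ones; the draw reflects the recovered frequencies.
    """
    copies = {a.name: 2 for a in config.arm_table}
    copies["X"], copies["Y"] = 1, 1
    label, mosaic = "XY", {}
    r = policy.ndj_x_rate
    p_exceptional = (r / 2) / ((1 - r) + r / 2) if r > 0 else 0.0
    if rng.random() < p_exceptional:
        if rng.random() < 0.5:
            copies["X"], copies["Y"], label = 1, 0, "X0"
            events.append(TruthEvent("NDJ_X", "X", 1, 1, 0, {"class": "X0"}))
        else:
            copies["X"], copies["Y"], label = 2, 1, "XXY"
            events.append(TruthEvent("NDJ_X", "X", 1, 1, 0, {"class": "XXY"}))
    r4 = policy.ndj_4_rate
    p4 = (r4 / 2) / ((1 - r4) + r4 / 2) if r4 > 0 else 0.0
    label4 = None
    if rng.random() < p4:
        if rng.random() < 0.5:
            copies["4"], label4 = 3, "triplo4"
        else:
            copies["4"], label4 = 1, "haplo4"
        events.append(TruthEvent("NDJ_4", "4", 1, 1, 0, {"class": label4}))
    if rng.random() < policy.triploid_rate:
        for a in config.arm_table:
            if a.name not in ("X", "Y"):
                copies[a.name] = 3
        copies["X"] = 2
        label = "XXY_AAA" if copies["Y"] == 1 else "XX_AAA"
        events.append(TruthEvent("TRIPLOID", "X", 1, 1, 0, {"class": label}))
    kary = {"copies": copies, "label": label, "mosaic": mosaic}
    if label4 and label == "XY":
        kary["label"] = label4
    elif label4:
        kary["label4"] = label4
    return kary


def product_switches(events: Iterable[TruthEvent], arm: str,
                     chromatid: int) -> list[int]:
    """Haplotype switch points on one chromatid from the COs involving it."""
    return sorted(
        e.start for e in events
        if e.kind == "CO" and e.arm == arm
        and chromatid in (e.chromatid, e.payload.get("partner_chromatid"))
    )


def hap_along_arm(events: Iterable[TruthEvent], arm: Arm, chromatid: int,
                  positions: np.ndarray) -> np.ndarray:
    """Maternal haplotype ('A'/'B') at each position on the recovered chromatid.

    Starts from the chromatid's parental haplotype, toggles at each CO
    switch point, then overwrites NCOGC tracts with the donor haplotype.
    """
    start_hap = _chromatid_hap(chromatid)
    switches = product_switches(events, arm.name, chromatid)
    n_sw = np.searchsorted(np.asarray(switches), positions, side="right")
    hap_is_a = (start_hap == "A") ^ (n_sw % 2 == 1)
    for e in events:
        if e.kind == "NCOGC" and e.arm == arm.name and e.chromatid == chromatid:
            inside = (positions >= e.start) & (positions <= e.end)
            # the tract copies the homolog present at the tract location
            local_a = hap_is_a[inside]
            hap_is_a[inside] = ~local_a
    return np.where(hap_is_a, "A", "B")


def synthesize_offspring(
    panel: ParentalPanel,
    meiosis: MeiosisResult,
    config: SimConfig,
    offspring_id: str = "off_0",
    offspring_index: int = 0,
    extra_events: Sequence[TruthEvent] | None = None,
    components: Sequence[str] = ("markers", "indels", "depth", "evidence"),
) -> OffspringDataset:
    """Render the recovered product as pipeline input files.

    ``extra_events`` lets callers implant CNVs, mosaic TEs or other
    non-meiotic truth directly on the recovered product. Events outside
    euchromatin are skipped with a log entry in the truth payload.
    """
    rng = _rng(config, 2, offspring_index)
    arm_map = arms_by_name(config.arm_table)
    copies = dict(meiosis.karyotype["copies"])
    events = list(meiosis.events)
    if extra_events:
        events = events + [copy.deepcopy(e) for e in extra_events]

    skipped: list[TruthEvent] = []
    kept: list[TruthEvent] = []
    for e in events:
        a = arm_map.get(e.arm)
        if a is None:
            raise ConfigurationError(f"event on unknown arm {e.arm}")
        if e.kind in ("DSB_DELETION", "NCOGC", "TE_INSERTION", "CNV_DUP",
                      "CNV_DEL") and not (a.eu_start <= e.start and
                                          e.end <= a.eu_end):
            skipped.append(e)
        else:
            kept.append(e)
    events = kept

    def on_product(e: TruthEvent) -> bool:
        if e.chromatid == 0:
            return True
        rec = meiosis.recovered.get(arm_map[e.arm].chromosome, 0)
        if e.kind == "CO":
            return rec in (e.chromatid, e.payload.get("partner_chromatid"))
        return e.chromatid == rec

    recovered_events = [e for e in events if on_product(e)]

    markers_df = (_marker_calls(panel, meiosis, events, config, rng)
                  if "markers" in components else None)
    indels_df = (_indel_calls(panel, meiosis, recovered_events, config, rng)
                 if "indels" in components else None)
    depth_df = (_depth_track(meiosis, recovered_events, config, rng)
                if "depth" in components else None)
    evidence_df = (_junction_evidence(panel, meiosis, recovered_events, config,
                                      rng, offspring_id)
                   if "evidence" in components else None)

    truth = recovered_events + [
        TruthEvent(e.kind, e.arm, e.start, e.end, e.chromatid,
                   {**e.payload, "skipped": "outside_euchromatin"})
        for e in skipped
    ]
    return OffspringDataset(
        offspring_id=offspring_id, genotype=meiosis.genotype,
        markers=markers_df, indels=indels_df, depth=depth_df,
        evidence=evidence_df, truth=truth, karyotype=meiosis.karyotype)


def _site_depth(rng, mean: float, n: int) -> np.ndarray:
    return np.maximum(rng.poisson(mean, size=n), 1)


def _marker_calls(panel, meiosis, events, config, rng) -> pd.DataFrame:
    """Genotype calls with allelic depths at every panel site."""
    out = []
    copies = meiosis.karyotype["copies"]
    pat_b = config.paternal_hap == "B"
    for arm in config.arm_table:
        m = panel.arm_markers(arm.name)
        if len(m) == 0:
            continue
        pos = m["pos"].to_numpy()
        n = len(pos)
        chrom = arm.chromosome
        rec = meiosis.recovered.get(chrom, 1)
        mat_hap = hap_along_arm(events, arm, rec, pos)
        total_copies = copies.get(arm.name, 2)
        if total_copies == 0:
            continue

        if arm.name == "X":
            n_mat = {"XY": 1, "X0": 0, "XXY": 2, "XX": 1,
                     "XX_AAA": 2, "XXY_AAA": 2}.get(
                         meiosis.karyotype["label"], max(total_copies - 1, 0))
            n_pat = total_copies - n_mat
        else:
            n_mat = total_copies - 1
            n_pat = 1
        mat_haps = [mat_hap]
        if n_mat >= 2:
            # second maternal chromatid: plain parental haplotype
            other = rec % 4 + 1
            mat_haps.append(hap_along_arm(events, arm, other, pos))
        b_count = np.zeros(n)
        for h in mat_haps[:n_mat]:
            b_count += (h == "B")
        if n_pat > 0:
            b_count += n_pat * (1 if pat_b else 0)
        b_frac = b_count / total_copies

        dp = _site_depth(rng, config.combined_depth * total_copies / 2.0, n)
        ad_alt = rng.binomial(dp, b_frac)
        # genotype from the true allele content; AD carries sampling noise
        gt_frac = b_frac.copy()
        if config.marker_error_rate > 0:
            flip = rng.random(n) < config.marker_error_rate
            ad_alt[flip] = dp[flip] - ad_alt[flip]
            gt_frac[flip] = 1.0 - gt_frac[flip]
        gt = np.where(gt_frac >= 0.85, "1/1",
                      np.where(gt_frac <= 0.15, "0/0", "0/1"))
        gq = rng.integers(60, 100, size=n)
        out.append(pd.DataFrame({
            "arm": arm.name, "pos": pos, "ref": m["ref"].to_numpy(),
            "alt": m["alt"].to_numpy(), "qual": gq.astype(float), "gt": gt,
            "depth": dp, "ad_alt": ad_alt, "gq": gq}))
    return (pd.concat(out, ignore_index=True) if out
            else pd.DataFrame(columns=sio.VCF_COLUMNS))


def _random_seq(rng, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


def _indel_calls(panel, meiosis, recovered_events, config, rng) -> pd.DataFrame:
    """Small-deletion VCF: de novo DSB deletions plus inherited polymorphisms.

    Quality scores are two-component: most true calls score high
    (N(900, 80) clipped), a configurable tail lands below the 200-point
    screen so the quality filter is exercised.
    """
    rows = []

    def qual_draw():
        if rng.random() < config.noise_low_qual_prob:
            return float(rng.uniform(50, 200))
        return float(np.clip(rng.normal(900, 80), 300, 2000))

    for e in recovered_events:
        if e.kind != "DSB_DELETION":
            continue
        size = e.end - e.start + 1
        if size > config.indel_vcf_max:
            continue
        anchor = e.start - 1 if e.start > 1 else e.start
        ref = _random_seq(rng, size + 1)
        dp = max(int(rng.poisson(config.combined_depth)), 2)
        rows.append((e.arm, anchor, ref, ref[0], qual_draw(), "0/1",
                     dp, int(rng.binomial(dp, 0.5)), 99))
    bg = panel.background_indels
    if bg is not None:
        for r in bg.itertuples():
            if rng.random() < r.freq:
                ref = _random_seq(rng, int(r.size) + 1)
                dp = max(int(rng.poisson(config.combined_depth)), 2)
                rows.append((r.arm, int(r.pos), ref, ref[0],
                             float(np.clip(rng.normal(900, 80), 300, 2000)),
                             "0/1", dp, int(rng.binomial(dp, 0.5)), 99))
    return pd.DataFrame(rows, columns=sio.VCF_COLUMNS)


def _effective_copy(arm: Arm, bins_start: np.ndarray, bin_size: int,
                    base_copy: float, recovered_events, kary) -> np.ndarray:
    eff = np.full(len(bins_start), float(base_copy))
    mosaic = kary.get("mosaic", {})
    if arm.name in mosaic:
        lo_copy, frac = mosaic[arm.name]
        eff[:] = base_copy * (1 - frac) + lo_copy * frac
    for e in recovered_events:
        if e.arm != arm.name:
            continue
        if e.kind in ("CNV_DUP", "CNV_DEL"):
            f = e.payload.get("cell_fraction", 1.0)
            cn = e.payload.get("copy_number",
                               base_copy + (1 if e.kind == "CNV_DUP" else -1))
            delta = (cn - base_copy) * f
        elif e.kind == "DSB_DELETION":
            delta = -1.0
        else:
            continue
        # overlap fraction of each bin with the event interval
        b0 = bins_start
        b1 = bins_start + bin_size
        ov = np.clip(np.minimum(b1, e.end) - np.maximum(b0, e.start - 1), 0, None)
        eff += delta * ov / bin_size
    return np.maximum(eff, 0.0)


def _depth_track(meiosis, recovered_events, config, rng) -> pd.DataFrame:
    out = []
    copies = meiosis.karyotype["copies"]
    for arm in config.arm_table:
        nb = int(np.ceil(arm.length / config.depth_bin))
        starts = np.arange(nb) * config.depth_bin
        ends = np.minimum(starts + config.depth_bin, arm.length)
        eff = _effective_copy(arm, starts, config.depth_bin,
                              copies.get(arm.name, 2), recovered_events,
                              meiosis.karyotype)
        lam = config.combined_depth * eff / 2.0
        vals = rng.poisson(lam)
        out.append(pd.DataFrame({"arm": arm.name, "start": starts,
                                 "end": ends, "value": vals}))
    return pd.concat(out, ignore_index=True)


def _junction_evidence(panel, meiosis, recovered_events, config, rng,
                       offspring_id) -> pd.DataFrame:
    """Split/discordant/spanning records at TE, large-deletion and CNV junctions."""
    rows = []
    copies = meiosis.karyotype["copies"]
    cap = config.capture_prob
    rid = 0

    def emit(arm, position, ev_type, mate, seq="."):
        nonlocal rid
        rows.append((offspring_id, arm, int(position), ev_type, mate,
                     f"r{rid}", seq))
        rid += 1

    for e in recovered_events:
        total = copies.get(e.arm, 2)
        if total == 0:
            continue
        local_depth = config.combined_depth * total / 2.0
        if e.kind == "TE_INSERTION":
            frac = e.payload.get("cell_fraction", 1.0)
            kappa = frac / total          # carrier-copy read fraction
            fam = e.payload["family"]
            cons = panel.te_library[fam]
            n_junc = rng.poisson(local_depth * kappa * cap)
            n_span = rng.poisson(local_depth * (1 - kappa) * cap)
            for _ in range(n_junc):
                off = int(rng.integers(-25, 26))
                s0 = int(rng.integers(0, max(len(cons) - config.read_len, 1)))
                seq = cons[s0:s0 + config.read_len]
                if rng.random() < 0.5:
                    emit(e.arm, e.start + off, "split", fam, seq)
                else:
                    emit(e.arm, e.start + int(rng.integers(-config.insert_size, 0)),
                         "discordant", fam, seq)
            for _ in range(n_span):
                emit(e.arm, e.start + int(rng.integers(-25, 26)), "spanning",
                     f"{e.arm}:{e.start}")
        elif e.kind == "DSB_DELETION" and (e.end - e.start + 1) > config.indel_vcf_max:
            kappa = 1.0 / total
            n_split = max(int(rng.poisson(local_depth * kappa * cap)), 0)
            left, right = e.start - 1, e.end + 1
            for _ in range(n_split):
                jitter = int(rng.integers(-3, 4))
                emit(e.arm, left + jitter, "split", f"{e.arm}:{right + jitter}")
        elif e.kind == "CNV_DUP" and e.payload.get("tandem", True):
            f = e.payload.get("cell_fraction", 1.0)
            n_disc = rng.poisson(local_depth * (f / total) * cap)
            for _ in range(n_disc):
                emit(e.arm, e.end - int(rng.integers(0, config.insert_size)),
                     "discordant", f"{e.arm}:{e.start}")
        elif e.kind == "CNV_DEL" and e.payload.get("cell_fraction", 1.0) >= 1.0:
            n_split = rng.poisson(local_depth * cap / total)
            for _ in range(n_split):
                jitter = int(rng.integers(-3, 4))
                emit(e.arm, e.start - 1 + jitter, "split",
                     f"{e.arm}:{e.end + 1 + jitter}")
    return pd.DataFrame(rows, columns=sio.EVIDENCE_COLUMNS)


def simulate_cohort(
    config: SimConfig,
    genotype: str = "wildtype",
    n_offspring: int = 10,
    id_prefix: str | None = None,
    components: Sequence[str] = ("markers", "indels", "depth", "evidence"),
    panel: ParentalPanel | None = None,
    extra_events: dict[int, list[TruthEvent]] | None = None,
) -> tuple[ParentalPanel, list[OffspringDataset]]:
    """Generate a full cohort of offspring datasets from one parental panel."""
    if panel is None:
        panel = generate_parents(config)
    prefix = id_prefix or genotype
    datasets = []
    for i in range(n_offspring):
        meiosis = simulate_meiosis(panel, config, genotype, meiosis_index=i)
        extra = (extra_events or {}).get(i)
        datasets.append(synthesize_offspring(
            panel, meiosis, config, offspring_id=f"{prefix}_{i}",
            offspring_index=i, extra_events=extra, components=components))
    return panel, datasets


@dataclass
class BenchmarkSet:
    """Synthetic deletion-detection benchmark: truth plus per-genome datasets."""

    size_class: str
    individuals: list[OffspringDataset]
    truth: pd.DataFrame      # offspring_id, arm, start, end, size, size_class


def make_deletion_benchmark(
    config: SimConfig,
    size_class: str | None = None,
    n_genomes: int = 100,
    components: Sequence[str] = ("indels", "depth", "evidence"),
) -> BenchmarkSet:
    """Regenerate the deletion-sensitivity benchmark design.

    Each individual merges two haploid genome draws (one carrying the X,
    one the Y) into a ~20x male dataset; the X-bearing genome carries
    2-6 DSB-site deletions of the requested size class placed uniformly
    in euchromatin.
    """
    size_class = size_class or config.deletion_size_class
    if size_class not in DELETION_CLASSES:
        raise ConfigurationError(f"unknown size class {size_class!r}")
    lo, hi = DELETION_CLASSES[size_class]
    lo_b, hi_b = config.dsb_per_genome_benchmark
    arms = [a for a in config.arm_table if a.name != "Y"]
    eu = np.array([a.eu_length for a in arms], dtype=float)
    p_arm = eu / eu.sum()
    class_key = 10 if size_class == "1-10" else 11

    individuals, truth_rows = [], []
    for i in range(n_genomes):
        rng = _rng(config, 3, class_key, i)
        oid = f"bench{size_class}_{i}"
        k = int(rng.integers(lo_b, hi_b + 1))
        events: list[TruthEvent] = []
        taken: dict[str, list[tuple[int, int]]] = {}
        while len(events) < k:
            arm = arms[int(rng.choice(len(arms), p=p_arm))]
            size = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(arm.eu_start, max(arm.eu_end - size, arm.eu_start) + 1))
            end = min(start + size - 1, arm.eu_end)
            if any(s <= end + 50 and start <= e2 + 50
                   for s, e2 in taken.get(arm.name, [])):
                continue
            taken.setdefault(arm.name, []).append((start, end))
            events.append(TruthEvent("DSB_DELETION", arm.name, start, end, 1,
                                     {"size": end - start + 1}))
            truth_rows.append((oid, arm.name, start, end, end - start + 1,
                               size_class))
        copies = {a.name: 2 for a in config.arm_table}
        copies["X"], copies["Y"] = 1, 1
        meiosis = MeiosisResult(
            events=events, recovered={a.chromosome: 1 for a in arms},
            karyotype={"copies": copies, "label": "XY", "mosaic": {}},
            genotype="benchmark")
        cfg_i = copy.copy(config)
        cfg_i.seed = config.seed  # per-genome substream via offspring_index
        individuals.append(synthesize_offspring(
            panel_for_benchmark(config), meiosis, cfg_i, offspring_id=oid,
            offspring_index=1000 * class_key + i, components=components))
    truth = pd.DataFrame(
        truth_rows,
        columns=["offspring_id", "arm", "start", "end", "size", "size_class"])
    return BenchmarkSet(size_class=size_class, individuals=individuals,
                        truth=truth)


_BENCH_PANEL_CACHE: dict[int, ParentalPanel] = {}


def panel_for_benchmark(config: SimConfig) -> ParentalPanel:
    """Benchmark genomes share one marker panel (cached per seed)."""
    panel = _BENCH_PANEL_CACHE.get(config.seed)
    if panel is None:
        cfg = copy.copy(config)
        cfg.background_indel_count = 0
        panel = generate_parents(cfg)
        _BENCH_PANEL_CACHE[config.seed] = panel
    return panel
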