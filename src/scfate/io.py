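"""Readers and writers for the on-disk formats the pipeline stages exchange.

VCF is read with cyvcf2 and written as plain VCF v4.2 text. Depth tracks
are bedGraph (0-based half-open), masks are BED, junction evidence is a
TSV with a fixed schema.
"""
from __future__ import annotations

import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

VCF_COLUMNS = ["arm", "pos", "ref", "alt", "qual", "gt", "depth", "ad_alt", "gq"]

EVIDENCE_COLUMNS = [
    "offspring_id",
    "arm",
    "position",
    "evidence_type",  # split | discordant | spanning
    "mate_target",    # TE family name or "arm:pos" genomic locus
    "read_id",
    "sequence",       # TE-side read sequence where applicable, else "."
]


def write_vcf(
    records: pd.DataFrame,
    path,
    sample: str,
    contigs: Mapping[str, int],
) -> None:
    """Write a single-sample VCF v4.2.

    ``records`` columns: arm, pos, ref, alt, qual, gt (e.g. "0/1"),
    depth, ad_alt (reads supporting ALT), gq.
    """
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=scfate\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths (ref,alt)">\n'
        )
        fh.write(
            '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
        )
        if len(records) == 0:
            return
        rec = records.sort_values(["arm", "pos"], kind="stable")
        for r in rec.itertuples():
            dp = int(r.depth)
            ad_alt = int(r.ad_alt)
            ad_ref = max(dp - ad_alt, 0)
            fh.write(
                f"{r.arm}\t{int(r.pos)}\t.\t{r.ref}\t{r.alt}\t{r.qual:g}\t.\t.\t"
                f"GT:DP:AD:GQ\t{r.gt}:{dp}:{ad_ref},{ad_alt}:{int(r.gq)}\n"
            )


def read_vcf(path) -> pd.DataFrame:
    """Read a single-sample VCF into the same frame schema write_vcf emits."""
    from cyvcf2 import VCF

    rows = []
    vcf = VCF(str(path))
    for v in vcf:
        alt = v.ALT[0] if v.ALT else "."
        gts = v.genotypes[0] if v.genotypes else [-1, -1, False]
        alleles = [a for a in gts[:-1] if a is not None]
        gt = "/".join(str(a) if a >= 0 else "." for a in alleles)
        try:
            depth = int(v.format("DP")[0][0]) if v.format("DP") is not None else -1
        except (TypeError, ValueError):
            depth = -1
        ad_alt = -1
        ad = v.format("AD")
        if ad is not None and ad.shape[1] >= 2:
            ad_alt = int(ad[0][1])
        gq = -1
        gqf = v.format("GQ")
        if gqf is not None:
            gq = int(np.asarray(gqf).ravel()[0])
        rows.append(
            (v.CHROM, v.POS, v.REF, alt, v.QUAL if v.QUAL is not None else 0.0,
             gt, depth, ad_alt, gq)
        )
    vcf.close()
    return pd.DataFrame(rows, columns=VCF_COLUMNS)


def write_bedgraph(track: pd.DataFrame, path) -> None:
    """Write a depth track. Columns: arm, start (0-based), end, value."""
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    track.to_csv(path, sep="\t", header=False, index=False,
                 columns=["arm", "start", "end", "value"])


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["arm", "start", "end", "value"],
                     dtype={"arm": str})
    return df


def write_bed(intervals: pd.DataFrame, path) -> None:
    """Write BED3(+name). Columns: arm, start (0-based), end [, name]."""
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    intervals.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    cols = ["arm", "start", "end", "name"][: df.shape[1]]
    df.columns = cols + list(df.columns[len(cols):])
    return df


def write_evidence(records: pd.DataFrame, path) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    records.to_csv(path, sep="\t", index=False, columns=EVIDENCE_COLUMNS)


def read_evidence(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"arm": str, "mate_target": str})
    missing = set(EVIDENCE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"evidence file {path} missing columns: {sorted(missing)}")
    return df


def write_fasta(seqs: Mapping[str, str], path, width: int = 70) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs
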