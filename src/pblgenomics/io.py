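"""Readers and writers for the pipeline's interchange formats.

Conventions: TSVs are tab-delimited UTF-8 with '.' decimals and explicit
``NA`` for missing values; VCF and SEG coordinates are 1-based inclusive;
BED output is 0-based half-open (converted at the boundary, round-trip
exact).
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd

NA = "NA"

VCF_INFO_KEYS = ("AF", "DP", "F1R2", "F2R1")

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=pblgenomics
##INFO=<ID=AF,Number=A,Type=Float,Description="Variant allele frequency">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Effective read depth">
##INFO=<ID=F1R2,Number=A,Type=Integer,Description="Alt reads in F1R2 orientation">
##INFO=<ID=F2R1,Number=A,Type=Integer,Description="Alt reads in F2R1 orientation">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf_minimal(calls: pd.DataFrame, path: str) -> None:
    """Write one sample's calls as a minimal single-sample VCF."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        if calls.empty:
            return
        for _, r in calls.sort_values(["chrom", "pos"]).iterrows():
            info = (
                f"AF={float(r['vaf']):g};DP={int(r['depth'])};"
                f"F1R2={int(r['alt_f1r2'])};F2R1={int(r['alt_f2r1'])}"
            )
            fh.write(
                f"{r['chrom']}\t{int(r['pos'])}\t.\t{r['ref']}\t{r['alt']}\t.\t.\t{info}\n"
            )


def read_vcf_minimal(path: str) -> pd.DataFrame:
    """Read a minimal VCF into the variant-call table.

    1-based coordinates are preserved; multi-allelic records are split
    into one call per alt allele (depth shared, per-alt AF and orientation
    counts). Raises a schema error naming any missing required INFO key.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    declared = {
        f["ID"] for f in (vcf.header_iter()) if f["HeaderType"] == "INFO"
    }
    missing = [k for k in VCF_INFO_KEYS if k not in declared]
    if missing:
        raise ValueError(f"VCF header missing required INFO key(s): {missing}")
    rows = []
    for rec in vcf:
        alts = rec.ALT
        af = np.atleast_1d(rec.INFO.get("AF"))
        f1r2 = np.atleast_1d(rec.INFO.get("F1R2"))
        f2r1 = np.atleast_1d(rec.INFO.get("F2R1"))
        dp = int(rec.INFO.get("DP"))
        for i, alt in enumerate(alts):
            rows.append(
                {
                    "chrom": rec.CHROM,
                    "pos": rec.POS,
                    "ref": rec.REF,
                    "alt": alt,
                    "vaf": float(af[i]),
                    "depth": dp,
                    "alt_f1r2": int(f1r2[i]),
                    "alt_f2r1": int(f2r1[i]),
                }
            )
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "vaf", "depth", "alt_f1r2", "alt_f2r1"]
    )


def write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=NA)


def _read_tsv(path: str, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{os.path.basename(path)}: missing column(s) {missing}")
    return df


def read_variants_tsv(path: str) -> pd.DataFrame:
    return _read_tsv(
        path,
        ["sample_id", "chrom", "pos", "ref", "alt", "vaf", "depth", "alt_f1r2", "alt_f2r1"],
    )


def read_seg(path: str) -> pd.DataFrame:
    """SEG-like TSV: sample_id, chrom, start, end, n_major, n_minor.

    Coordinates 1-based inclusive. Rejects ``end < start`` (with the
    offending line) and overlapping segments within a sample+chromosome
    (segments must tile each arm).
    """
    df = _read_tsv(path, ["sample_id", "chrom", "start", "end", "n_major", "n_minor"])
    bad = df[df["end"] < df["start"]]
    if len(bad):
        raise ValueError(f"segment end < start at data line {bad.index[0] + 2}")
    for (sid, chrom), g in df.groupby(["sample_id", "chrom"]):
        g = g.sort_values("start")
        overlap = g["start"].to_numpy()[1:] <= g["end"].to_numpy()[:-1]
        if overlap.any():
            raise ValueError(f"overlapping segments for sample {sid} on {chrom}")
    return df


def read_purity_ploidy(path: str) -> pd.DataFrame:
    df = _read_tsv(path, ["sample_id", "purity", "ploidy"])
    if ((df["purity"] <= 0) | (df["purity"] > 1)).any():
        raise ValueError("purity must lie in (0, 1]")
    return df


def read_clinical(path: str) -> pd.DataFrame:
    return _read_tsv(path, ["sample_id", "os_months", "os_event"])


def read_counts(path: str) -> pd.DataFrame:
    from .screen import COUNT_COLUMNS

    return _read_tsv(path, ["shrna_id", "gene"] + COUNT_COLUMNS)


def seg_interval_to_bed(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end


def bed_interval_to_seg(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end


def write_peaks_bed(report: pd.DataFrame, path: str) -> None:
    """Write the peak report's extended intervals as BED."""
    with open(path, "w") as fh:
        for _, r in report.iterrows():
            b_start, b_end = seg_interval_to_bed(
                int(r["extended_start"]), int(r["extended_end"])
            )
            name = f"{r['kind']}_{r['arm']}"
            fh.write(f"{r['arm']}\t{b_start}\t{b_end}\t{name}\t{r['n_peak']:.3f}\n")
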