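"""Mutation clonality from integrated WES and SNP-array measurements.

The cancer cell fraction (CCF) of a mutation — the fraction of tumor cells
that carry it in at least one allele — is estimated from the observed variant
allele frequency (VAF), the tumor purity of the specimen, and the local total
copy number of the tumor cells:

    f_CCF = (f_VAF / f_purity) * ((1 - f_purity) * n_CN,normal
                                  + f_purity * n_CN,tumor)

with ``n_CN,normal = 2`` assuming diploid normal bystander cells. Mutations
with ``f_CCF >= 0.9`` are called clonal (present in essentially all tumor
cells, hence candidate early events).

The formula is evaluated exactly and is *not* clipped at 1 by default:
values above 1 indicate inconsistent inputs (purity or copy-number errors)
and are worth surfacing rather than hiding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CLONALITY_THRESHOLD = 0.9
"""Default CCF threshold above which a mutation is called clonal (inclusive)."""


def estimate_ccf(
    f_vaf,
    f_purity,
    n_cn_tumor,
    n_cn_normal: float = 2.0,
    clip: bool = False,
):
    """Estimate the cancer cell fraction of a mutation.

    Parameters
    ----------
    f_vaf : float or array-like
        Variant allele frequency in [0, 1].
    f_purity : float or array-like
        Tumor purity in (0, 1]; the fraction of cells in the specimen that
        are tumor-derived.
    n_cn_tumor : float or array-like
        Local total copy number of the tumor cells at the variant position
        (non-negative; need not be an integer for subclonal copy states).
    n_cn_normal : float
        Copy number of the normal bystander cells, 2 by default.
    clip : bool
        If True, clip the result at 1.0. Off by default; CCF > 1 signals
        inconsistent purity/copy-number input.

    Returns
    -------
    float or ndarray
        The estimated CCF (scalar in, scalar out).
    """
    f_vaf = np.asarray(f_vaf, dtype=float)
    f_purity = np.asarray(f_purity, dtype=float)
    n_cn_tumor = np.asarray(n_cn_tumor, dtype=float)
    if np.any(f_purity <= 0) or np.any(f_purity > 1):
        raise ValueError("purity must lie in (0, 1]")
    if np.any((f_vaf < 0) | (f_vaf > 1)):
        raise ValueError("VAF must lie in [0, 1]")
    if np.any(n_cn_tumor < 0):
        raise ValueError("tumor copy number must be non-negative")
    ccf = (f_vaf / f_purity) * ((1.0 - f_purity) * n_cn_normal + f_purity * n_cn_tumor)
    if clip:
        ccf = np.minimum(ccf, 1.0)
    return ccf if ccf.ndim else float(ccf)


def vaf_from_ccf(f_ccf, f_purity, n_cn_tumor, n_cn_normal: float = 2.0):
    """Invert the CCF formula: expected VAF of a single-allele mutation.

    Used by the synthetic cohort generator; by construction
    ``estimate_ccf(vaf_from_ccf(c, p, n), p, n) == c`` exactly.
    """
    f_ccf = np.asarray(f_ccf, dtype=float)
    f_purity = np.asarray(f_purity, dtype=float)
    n_cn_tumor = np.asarray(n_cn_tumor, dtype=float)
    denom = (1.0 - f_purity) * n_cn_normal + f_purity * n_cn_tumor
    vaf = f_ccf * f_purity / denom
    return vaf if vaf.ndim else float(vaf)


def call_clonality(f_ccf, threshold: float = CLONALITY_THRESHOLD):
    """Clonal flag: ``f_ccf >= threshold`` (boundary inclusive)."""
    f_ccf = np.asarray(f_ccf, dtype=float)
    if np.any(f_ccf < 0):
        raise ValueError("CCF must be non-negative")
    flag = f_ccf >= threshold
    return flag if flag.ndim else bool(flag)


@dataclass(frozen=True)
class GeneClonalitySummary:
    """Per-gene clonality summary over mutated samples with CN measurement."""

    gene_id: str
    n_mutated_samples: int
    n_samples_with_clonal_mutation: int
    clonal_percentage: float
    median_ccf: float


def annotate_ccf(
    variants: pd.DataFrame,
    segments: pd.DataFrame,
    purity_ploidy: pd.DataFrame,
    threshold: float = CLONALITY_THRESHOLD,
    clip: bool = False,
) -> pd.DataFrame:
    """Join variants to copy-number segments and annotate CCF + clonality.

    ``variants`` needs columns ``sample_id, chrom, pos, vaf``; ``segments``
    needs ``sample_id, chrom, start, end, n_major, n_minor`` (1-based
    inclusive); ``purity_ploidy`` needs ``sample_id, purity``. Variants in
    samples without any copy-number measurement are dropped (the CCF is only
    defined where purity and local CN are known). A variant lying exactly on
    a segment boundary takes the left (earlier-start) segment.

    Returns a copy of the retained variants with ``n_cn_tumor``, ``f_ccf``
    and ``clonal`` columns appended.
    """
    purity = purity_ploidy.set_index("sample_id")["purity"]
    seg_by_sample = {s: g.sort_values("start") for s, g in segments.groupby("sample_id")}
    rows = []
    for idx, v in variants.iterrows():
        sid = v["sample_id"]
        if sid not in purity.index or sid not in seg_by_sample:
            continue
        segs = seg_by_sample[sid]
        arm = segs[segs["chrom"] == v["chrom"]]
        hit = arm[(arm["start"] <= v["pos"]) & (v["pos"] <= arm["end"])]
        if hit.empty:
            continue
        seg = hit.iloc[0]  # left segment wins on boundary ties
        cn = float(seg["n_major"] + seg["n_minor"])
        ccf = estimate_ccf(float(v["vaf"]), float(purity[sid]), cn, clip=clip)
        rows.append((idx, cn, ccf, ccf >= threshold))
    if not rows:
        out = variants.iloc[0:0].copy()
        out["n_cn_tumor"] = pd.Series(dtype=float)
        out["f_ccf"] = pd.Series(dtype=float)
        out["clonal"] = pd.Series(dtype=bool)
        return out
    idxs, cns, ccfs, flags = zip(*rows)
    out = variants.loc[list(idxs)].copy()
    out["n_cn_tumor"] = cns
    out["f_ccf"] = ccfs
    out["clonal"] = flags
    return out


def summarize_gene_clonality(ccf_records: pd.DataFrame) -> pd.DataFrame:
    """Per-gene clonal fractions over samples with CCF estimates.

    A sample counts as clonally mutated in a gene if at least one of its
    mutations in that gene is clonal. The median CCF is taken over all of
    the gene's mutation records. Genes with zero mutated samples are
    omitted (there is nothing to summarize).

    Parameters
    ----------
    ccf_records : DataFrame
        Output of :func:`annotate_ccf`; must carry ``gene, sample_id,
        f_ccf, clonal``.

    Returns
    -------
    DataFrame with one row per gene: ``gene, n_mutated_samples,
    n_clonal_samples, clonal_percentage, median_ccf``.
    """
    recs = []
    for gene, g in ccf_records.groupby("gene"):
        per_sample = g.groupby("sample_id")["clonal"].any()
        n_mut = int(per_sample.size)
        n_clonal = int(per_sample.sum())
        recs.append(
            {
                "gene": gene,
                "n_mutated_samples": n_mut,
                "n_clonal_samples": n_clonal,
                "clonal_percentage": 100.0 * n_clonal / n_mut,
                "median_ccf": float(g["f_ccf"].median()),
            }
        )
    return pd.DataFrame(
        recs,
        columns=[
            "gene",
            "n_mutated_samples",
            "n_clonal_samples",
            "clonal_percentage",
            "median_ccf",
        ],
    )
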