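"""Pooled shRNA dropout-screen scoring.

In a dropout screen, cells expressing shRNAs against genes the cell line
depends on are lost from the population; the readout is the change in
shRNA abundance after 12 days of induction (on-dox) relative to the
uninduced control (off-dox), sequenced in duplicate. The scoring pipeline:

1. median-of-ratios size-factor normalization per sequencing column;
2. removal of shRNAs with a raw day-12 on+off read sum below 50;
3. per-shRNA log2 depletion ratio (normalized on-dox vs off-dox day-12
   counts, pseudocount-stabilized), averaged over replicates;
4. z-scoring of the log2 ratios over all scored shRNAs and ranking,
   most-depleted (lowest z) first.

Expected column layout of the count matrix: ``shrna_id``, ``gene``, then
``d0_r1 d0_r2 d12_on_r1 d12_on_r2 d12_off_r1 d12_off_r2``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

D12_ON = ["d12_on_r1", "d12_on_r2"]
D12_OFF = ["d12_off_r1", "d12_off_r2"]
COUNT_COLUMNS = ["d0_r1", "d0_r2"] + D12_ON + D12_OFF


def normalize_counts(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Median-of-ratios size factors (DESeq-style) and normalized counts.

    The reference per shRNA is the geometric mean of its counts across
    columns; only rows positive in every column inform the size factors
    (all-zero or partially-zero rows are retained in the matrix but
    ignored for estimation). Normalized count = raw / column size factor.
    """
    counts = matrix[COUNT_COLUMNS].to_numpy(dtype=float)
    allpos = np.all(counts > 0, axis=1)
    if not allpos.any():
        raise ValueError("no shRNA with positive counts in all columns")
    logc = np.log(counts[allpos])
    logref = logc.mean(axis=1, keepdims=True)
    size_factors = np.exp(np.median(logc - logref, axis=0))
    out = matrix.copy()
    out[COUNT_COLUMNS] = counts / size_factors
    return out, pd.Series(size_factors, index=COUNT_COLUMNS, name="size_factor")


def filter_low_coverage(
    matrix: pd.DataFrame, min_sum: int = 50
) -> tuple[pd.DataFrame, int]:
    """Drop shRNAs whose raw day-12 on+off read sum is below ``min_sum``.

    The sum runs over both conditions and both replicates at day 12;
    the boundary is inclusive (a sum of exactly ``min_sum`` is kept).
    Returns the kept matrix and the number of removed rows.
    """
    d12_sum = matrix[D12_ON + D12_OFF].sum(axis=1)
    keep = d12_sum >= min_sum
    return matrix[keep].copy(), int((~keep).sum())


def score_depletion(matrix: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """z-scored, replicate-averaged log2 depletion ratios.

    Expects a normalized, low-coverage-filtered matrix. Per replicate,
    ``log2((on + c) / (off + c))`` with pseudocount ``c``; the replicate
    mean is z-scored over all scored shRNAs (sample standard deviation)
    and ranked ascending — rank 1 is the most depleted shRNA.
    """
    if len(matrix) < 2:
        raise ValueError("need at least two shRNAs to z-score")
    ratios = np.column_stack(
        [
            np.log2(
                (matrix[on].to_numpy(dtype=float) + pseudocount)
                / (matrix[off].to_numpy(dtype=float) + pseudocount)
            )
            for on, off in zip(D12_ON, D12_OFF)
        ]
    )
    mean_log2 = ratios.mean(axis=1)
    sd = mean_log2.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate screen: zero variance of log2 ratios")
    z = (mean_log2 - mean_log2.mean()) / sd
    out = pd.DataFrame(
        {
            "shrna_id": matrix["shrna_id"].to_numpy(),
            "gene": matrix["gene"].to_numpy(),
            "mean_log2_ratio": mean_log2,
            "z_score": z,
        }
    )
    out = out.sort_values("z_score", kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def gene_summary(scores: pd.DataFrame, z_threshold: float = -2.0) -> pd.DataFrame:
    """Per-gene depletion summary.

    Reports, per gene, the number of scored shRNAs, how many fall below
    the z threshold (depleted), and the median z. Genes without scored
    shRNAs simply do not appear.
    """
    rows = []
    for gene, g in scores.groupby("gene"):
        rows.append(
            {
                "gene": gene,
                "n_shrnas": len(g),
                "n_depleted": int((g["z_score"] < z_threshold).sum()),
                "median_z": float(g["z_score"].median()),
            }
        )
    out = pd.DataFrame(rows, columns=["gene", "n_shrnas", "n_depleted", "median_z"])
    return out.sort_values("median_z", kind="mergesort").reset_index(drop=True)


def run_screen(
    matrix: pd.DataFrame, min_sum: int = 50, pseudocount: float = 0.5
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Full scoring pipeline: normalize -> filter -> score -> summarize.

    The low-coverage filter uses *raw* counts (as deposited), then the
    surviving rows are normalized and scored. Returns (shRNA scores, gene
    summary, number of filtered shRNAs).
    """
    kept, n_removed = filter_low_coverage(matrix, min_sum=min_sum)
    normalized, _ = normalize_counts(kept)
    scores = score_depletion(normalized, pseudocount=pseudocount)
    return scores, gene_summary(scores), n_removed
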