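"""Lesion-by-subcohort association testing.

For each genetic lesion (binary indicator over samples: a gene mutated /
an SCNA present) and each clinically defined pair of subcohorts, a
one-tailed Wilcoxon rank-sum test asks whether the lesion indicator is
stochastically larger in one subcohort. The lesion family is declared
before testing; Benjamini-Hochberg FDR is applied within each comparison's
family, with significance at q < 0.1.

Small subcohorts (n as low as 2) and heavy ties (binary data) make the
normal approximation anti-conservative, so the exact permutation
distribution of the rank-sum (mid-ranks for ties) is used whenever the
total sample size is <= ``EXACT_LIMIT``; above it, the tie-corrected
normal approximation takes over. For binary indicators the exact
one-tailed p coincides with a hypergeometric tail probability, which
serves as an independent cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

EXACT_LIMIT = 50
SIGNIFICANCE_Q = 0.1


def _exact_rank_sum_sf(ranks_a_sum: float, ranks: np.ndarray, n_a: int) -> float:
    """P(rank-sum of a random size-``n_a`` subset >= observed), exactly.

    Dynamic program over the permutation distribution of the rank-sum.
    Ranks are mid-ranks; they are doubled to make them integers (mid-ranks
    are multiples of 1/2), keeping the DP table exact.
    """
    r2 = np.round(2 * ranks).astype(np.int64)
    target = int(round(2 * ranks_a_sum))
    max_sum = int(r2.sum())
    # dp[k][s] = number of k-subsets with doubled-rank-sum s
    dp = np.zeros((n_a + 1, max_sum + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in r2:
        upper = min(n_a, len(r2))
        for k in range(upper - 1, -1, -1):
            row = dp[k]
            nz = np.nonzero(row)[0]
            if nz.size:
                dp[k + 1, nz + r] += row[nz]
    total = dp[n_a].sum()
    tail = dp[n_a, target:].sum()
    return float(tail / total)


def wilcoxon_rank_sum_one_tailed(
    values_a: Sequence[float],
    values_b: Sequence[float],
    direction: str = "greater",
    method: str = "auto",
) -> float:
    """One-tailed Wilcoxon rank-sum p-value.

    ``direction='greater'`` tests whether group A tends to have larger
    values than group B (``'less'`` the opposite). ``method='auto'`` uses
    the exact permutation distribution with mid-ranks for N <= 50 and the
    tie-corrected normal approximation (with continuity correction)
    otherwise; ``'exact'``/``'asymptotic'`` force one path. Identical
    values throughout both groups give p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("both groups need at least one observation")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    if method not in ("auto", "exact", "asymptotic"):
        raise ValueError("method must be 'auto', 'exact' or 'asymptotic'")
    if direction == "less":
        return wilcoxon_rank_sum_one_tailed(b, a, "greater", method)
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    ranks = stats.rankdata(pooled)
    w_a = float(ranks[: len(a)].sum())
    n = len(pooled)
    if method == "exact" or (method == "auto" and n <= EXACT_LIMIT):
        return _exact_rank_sum_sf(w_a, ranks, len(a))
    # tie-corrected normal approximation on the rank-sum
    n_a, n_b = len(a), len(b)
    mu = n_a * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    z = (w_a - mu - 0.5) / np.sqrt(var)  # continuity-corrected
    return float(stats.norm.sf(z))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    ``q_(i) = min_{j >= i} p_(j) * m / j`` over the ordered family; the
    output is order-aligned with the input. Delegates to statsmodels'
    ``fdr_bh`` adjustment.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class Comparison:
    """One subcohort comparison: membership masks for groups A and B.

    ``column`` names a clinical covariate; samples whose covariate is
    missing are excluded from this comparison only (pairwise deletion).
    ``value_a``/``value_b`` are the covariate levels defining the groups;
    ``where`` optionally restricts the comparison to a stratum first
    (e.g. HIV-positive patients only). ``direction`` declares the tested
    alternative: 'greater' means the lesion is tested for a higher rate in
    group A.
    """

    name: str
    column: str
    value_a: object
    value_b: object
    direction: str = "greater"
    where: tuple[str, object] | None = None

    def groups(self, clinical: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
        df = clinical
        scope = pd.Series(True, index=df.index)
        if self.where is not None:
            col, val = self.where
            scope = df[col].notna() & (df[col] == val)
        avail = scope & df[self.column].notna()
        return (
            avail & (df[self.column] == self.value_a),
            avail & (df[self.column] == self.value_b),
        )


def default_comparisons() -> list[Comparison]:
    """The ten clinically predefined subcohort comparisons of the screen."""
    return [
        Comparison("EBV+ vs EBV-", "ebv_positive", 1, 0),
        Comparison("HIV+ vs HIV-", "hiv_positive", 1, 0),
        Comparison("HIV+: EBV+ vs EBV-", "ebv_positive", 1, 0, where=("hiv_positive", 1)),
        Comparison("HIV-: EBV+ vs EBV-", "ebv_positive", 1, 0, where=("hiv_positive", 0)),
        Comparison("oral cavity vs elsewhere", "site_oral", 1, 0),
        Comparison("MYC translocated vs not", "myc_translocated", 1, 0),
        Comparison("immunosuppressed vs not", "immunosuppression", 1, 0),
        Comparison("IPI high vs low/intermediate", "ipi_high", 1, 0),
        Comparison("LSS <12m vs >24m", "lss_class", "short", "long"),
        Comparison("CD20- vs CD20 weak+", "cd20_positive", 0, 1),
    ]


def run_subcohort_screen(
    lesions: pd.DataFrame,
    clinical: pd.DataFrame,
    comparisons: Sequence[Comparison] | None = None,
    both_directions: bool = False,
) -> pd.DataFrame:
    """Test every lesion in every configured subcohort comparison.

    Parameters
    ----------
    lesions : DataFrame
        Binary lesion indicators, samples as rows and lesions as columns
        (entries 0/1 or NA). The column set is the preselected family —
        BH adjustment runs within each comparison over exactly these
        lesions.
    clinical : DataFrame
        Covariates indexed like ``lesions``.
    comparisons :
        Defaults to :func:`default_comparisons`.
    both_directions :
        Also test the reversed alternative as separate rows.

    Returns
    -------
    Long-format DataFrame: one row per lesion x comparison (x direction),
    with counts, one-tailed p, BH q within the comparison family, and a
    ``significant`` flag at q < 0.1. Comparisons with an empty group are
    skipped.
    """
    comparisons = list(comparisons) if comparisons is not None else default_comparisons()
    rows = []
    for comp in comparisons:
        mask_a, mask_b = comp.groups(clinical)
        if not mask_a.any() or not mask_b.any():
            import warnings

            warnings.warn(f"comparison {comp.name!r} skipped: empty subgroup")
            continue
        directions = [comp.direction] + (
            [{"greater": "less", "less": "greater"}[comp.direction]]
            if both_directions
            else []
        )
        for direction in directions:
            block = []
            for lesion in lesions.columns:
                vals = lesions[lesion]
                a = vals[mask_a].dropna().astype(float)
                b = vals[mask_b].dropna().astype(float)
                if len(a) == 0 or len(b) == 0:
                    continue  # this lesion unobservable in this comparison
                p = wilcoxon_rank_sum_one_tailed(a, b, direction)
                block.append(
                    {
                        "comparison": comp.name,
                        "direction": direction,
                        "lesion": lesion,
                        "n_a": len(a),
                        "n_b": len(b),
                        "count_a": int(a.sum()),
                        "count_b": int(b.sum()),
                        "p_one_tailed": p,
                    }
                )
            if block:
                q = bh_fdr([r["p_one_tailed"] for r in block])
                for r, qv in zip(block, q):
                    r["q_bh"] = float(qv)
                    r["significant"] = qv < SIGNIFICANCE_Q
                rows.extend(block)
    return pd.DataFrame(
        rows,
        columns=[
            "comparison", "direction", "lesion", "n_a", "n_b",
            "count_a", "count_b", "p_one_tailed", "q_bh", "significant",
        ],
    )
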