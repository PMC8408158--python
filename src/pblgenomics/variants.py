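"""Multistage somatic-variant filter hierarchy and its evaluation harness.

Candidate calls arrive pre-scored by an upstream caller (the statistical
discovery model is not recomputed here); the hierarchy's job is to remove
germline variants and FFPE/pipeline artifacts with maximal specificity.
Steps are applied in a fixed order and every removal is attributed to the
first failing step, so the attrition table always conserves counts:
``inputs = survivors + sum(per-step removals)``.

Step order (all steps are evaluated for every call; attribution is to the
first failure):

1. ``depth``        — effective coverage >= ``min_depth`` (default 20 reads).
2. ``pon``          — exclusion by the panel of normals (variants seen in at
                      least ``pon_min_subjects`` independent normal subjects).
3. ``population_af`` — germline exclusion by population allele frequency
                      (gnomAD-style resource), > ``max_population_af`` fails.
4. ``matched_normal`` — in paired mode, any alt support in the patient's
                      matched normal fails the call.
5. ``orientation``  — FFPE read-orientation-bias flag: an exact two-sided
                      binomial symmetry test on the F1R2/F2R1 alt read
                      counts (stands in for a learned read-orientation
                      model; the requirement is only to flag a significant
                      forward/reverse imbalance).
6. ``vaf``          — allele-frequency floor (default 10%).
7. ``gene_denylist`` — optional exclusion of homology-prone genes (e.g.
                      MUC* family) by symbol; empty by default because the
                      list is database-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

VARIANT_KEY = ["chrom", "pos", "ref", "alt"]

FILTER_STEPS = [
    "depth",
    "pon",
    "population_af",
    "matched_normal",
    "orientation",
    "vaf",
    "gene_denylist",
]


@dataclass
class FilterConfig:
    """Thresholds of the filter hierarchy.

    ``mode`` selects paired (matched-normal available) or unpaired
    (tumor-only) filtering; the matched-normal step only acts in paired
    mode.
    """

    min_vaf: float = 0.10
    pon_min_subjects: int = 2
    max_population_af: float = 0.001
    orientation_bias_alpha: float = 0.05
    min_depth: int = 20
    mode: str = "paired"
    gene_denylist: tuple[str, ...] = ()

    def __post_init__(self):
        if self.mode not in ("paired", "unpaired"):
            raise ValueError(f"unknown mode {self.mode!r}; use 'paired' or 'unpaired'")
        if not (0 <= self.min_vaf <= 1 and 0 <= self.max_population_af <= 1):
            raise ValueError("vaf/population-af thresholds must lie in [0, 1]")
        if not (0 < self.orientation_bias_alpha < 1):
            raise ValueError("orientation_bias_alpha must lie in (0, 1)")
        if self.min_depth < 0 or self.pon_min_subjects < 1:
            raise ValueError("min_depth must be >= 0 and pon_min_subjects >= 1")


class PanelOfNormals:
    """Catalog of variants recurrently called in normal controls.

    A variant key enters the panel when called in at least ``min_subjects``
    *distinct* normal subjects; the full per-key subject counts are retained
    for reporting.
    """

    def __init__(self, counts: Mapping[tuple, int], min_subjects: int = 2):
        self.min_subjects = int(min_subjects)
        self.full_counts: dict[tuple, int] = dict(counts)
        self.keys = frozenset(
            k for k, c in self.full_counts.items() if c >= self.min_subjects
        )

    def __contains__(self, key: tuple) -> bool:
        return key in self.keys

    def __len__(self) -> int:
        return len(self.keys)


def build_pon(
    normal_call_sets: Sequence[tuple[str, pd.DataFrame]] | pd.DataFrame,
    min_subjects: int = 2,
) -> PanelOfNormals:
    """Build a panel of normals from per-subject call sets.

    Parameters
    ----------
    normal_call_sets :
        Either a sequence of ``(subject_id, calls)`` pairs (each ``calls`` a
        DataFrame with columns ``chrom, pos, ref, alt``) or a single
        DataFrame carrying a ``sample_id`` column. Subject ids must be
        distinct.
    min_subjects :
        Minimum number of independent subjects supporting a variant for it
        to enter the panel (default 2).
    """
    if isinstance(normal_call_sets, pd.DataFrame):
        pairs = [(sid, g) for sid, g in normal_call_sets.groupby("sample_id")]
    else:
        pairs = list(normal_call_sets)
        ids = [sid for sid, _ in pairs]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate subject id in normal call sets")
    counts: dict[tuple, int] = {}
    for _, calls in pairs:
        seen = set(map(tuple, calls[VARIANT_KEY].itertuples(index=False)))
        for key in seen:
            counts[key] = counts.get(key, 0) + 1
    return PanelOfNormals(counts, min_subjects=min_subjects)


@lru_cache(maxsize=100_000)
def _binom_two_sided_p(k: int, n: int) -> float:
    return float(stats.binomtest(k, n, 0.5).pvalue)


def orientation_bias_test(
    alt_f1r2: int, alt_f2r1: int, alpha: float = 0.05
) -> tuple[bool, float]:
    """Two-sided exact binomial symmetry test on oriented alt read counts.

    FFPE deamination artifacts (C>T on one strand) produce alt reads almost
    exclusively in one read-pair orientation; true somatic variants are
    sampled symmetrically from both. Tests ``alt_f1r2`` successes in
    ``alt_f1r2 + alt_f2r1`` trials against proportion 0.5.

    Returns ``(passed, p_value)``; the variant fails (is flagged as an
    artifact) iff ``p < alpha``. With both counts zero the test is
    indeterminate and reported as a pass with p = 1 — such calls carry no
    alt reads and are disposed of by the depth and VAF steps.
    """
    if alt_f1r2 < 0 or alt_f2r1 < 0:
        raise ValueError("orientation counts must be non-negative")
    n = alt_f1r2 + alt_f2r1
    if n == 0:
        return True, 1.0
    p = _binom_two_sided_p(int(alt_f1r2), int(n))
    return p >= alpha, p


@dataclass
class FilterResult:
    """Outcome of one filter-hierarchy run."""

    survivors: pd.DataFrame
    attrition: pd.DataFrame  # rows: step, removed; plus input/survivor totals
    trail: pd.DataFrame  # bool per call x step (True = passed)

    @property
    def n_input(self) -> int:
        return int(self.attrition.attrs["n_input"])


def apply_filter_hierarchy(
    calls: pd.DataFrame, pon: PanelOfNormals | None, config: FilterConfig
) -> FilterResult:
    """Apply the full filter hierarchy to a set of candidate calls.

    Every step is evaluated for every call (the trail records each
    decision); a call is removed at its first failing step. Calls need
    columns ``chrom, pos, ref, alt, vaf, depth, alt_f1r2, alt_f2r1`` and
    optionally ``population_af``, ``matched_normal_support``, ``gene``
    (missing optional fields pass the corresponding step).
    """
    n = len(calls)
    passed = pd.DataFrame(True, index=calls.index, columns=FILTER_STEPS)

    if n:
        passed["depth"] = calls["depth"].to_numpy() >= config.min_depth

        if pon is not None and len(pon.full_counts):
            keys = list(map(tuple, calls[VARIANT_KEY].itertuples(index=False)))
            passed["pon"] = [k not in pon for k in keys]

        if "population_af" in calls:
            paf = calls["population_af"].astype(float)
            passed["population_af"] = ~(paf > config.max_population_af) | paf.isna()

        if config.mode == "paired" and "matched_normal_support" in calls:
            mns = calls["matched_normal_support"].astype(float)
            passed["matched_normal"] = ~(mns > 0) | mns.isna()

        ob = [
            orientation_bias_test(int(a), int(b), config.orientation_bias_alpha)[0]
            for a, b in zip(calls["alt_f1r2"], calls["alt_f2r1"])
        ]
        passed["orientation"] = ob

        passed["vaf"] = calls["vaf"].to_numpy() >= config.min_vaf

        if config.gene_denylist and "gene" in calls:
            deny = set(config.gene_denylist)
            passed["gene_denylist"] = [g not in deny for g in calls["gene"]]

    # first-failing-step attribution
    removed_at = pd.Series(pd.NA, index=calls.index, dtype=object)
    still_in = pd.Series(True, index=calls.index)
    removals = {}
    for step in FILTER_STEPS:
        fail_here = still_in & ~passed[step]
        removals[step] = int(fail_here.sum())
        removed_at[fail_here] = step
        still_in &= passed[step]

    survivors = calls[still_in].copy()
    attrition = pd.DataFrame(
        {"step": FILTER_STEPS, "removed": [removals[s] for s in FILTER_STEPS]}
    )
    attrition.attrs["n_input"] = n
    attrition.attrs["n_survivors"] = int(still_in.sum())
    trail = passed.copy()
    trail["removed_at"] = removed_at
    return FilterResult(survivors=survivors, attrition=attrition, trail=trail)


@dataclass(frozen=True)
class EvalMetrics:
    """Sensitivity / precision / F of a call set against a truth set."""

    tp: int
    fp: int
    fn: int
    sensitivity: float | None
    precision: float | None
    f_score: float | None


def evaluate_calls(
    called: Iterable[tuple], truth: Iterable[tuple]
) -> EvalMetrics:
    """Compare called variant keys to a truth set by exact key match.

    ``sensitivity = tp/(tp+fn)``, ``precision = tp/(tp+fp)``, F is their
    harmonic mean. An empty truth set leaves sensitivity (and F) undefined,
    reported as None.
    """
    called = set(map(tuple, called))
    truth = set(map(tuple, truth))
    tp = len(called & truth)
    fp = len(called - truth)
    fn = len(truth - called)
    sens = tp / (tp + fn) if truth else None
    prec = tp / (tp + fp) if called else None
    if sens and prec:
        f = 2 * sens * prec / (sens + prec)
    elif sens is None or prec is None:
        f = None
    else:
        f = 0.0
    return EvalMetrics(tp=tp, fp=fp, fn=fn, sensitivity=sens, precision=prec, f_score=f)


def tmb(calls_per_sample: Mapping[str, int] | pd.Series, covered_mb: float) -> pd.Series:
    """Tumor mutational burden: somatic calls per megabase, per sample."""
    if covered_mb <= 0:
        raise ValueError("covered_mb must be positive")
    s = pd.Series(calls_per_sample, dtype=float)
    return s / covered_mb
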