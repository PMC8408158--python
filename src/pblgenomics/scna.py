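"""Recurrent somatic copy-number alteration (SCNA) discovery over probe grids.

Per-sample allele-specific copy-number segments are classified into
amplification/deletion events (focal vs. broad), piled up over an
SNP-probe grid, scanned for minimal common regions (MCRs), and the MCRs
are widened by a robust peak-extension rule.

The extension rule addresses a failure mode of plain MCR reporting: the
narrowest shared interval of a recurrent focal event can be much smaller
than the biologically coherent peak (e.g. a handful of samples whose
breakpoints happen to coincide sitting on top of a wider, well-defined
shoulder carried by many more samples). The rule is:

* ``n_base`` — local baseline, the mean *broad-event* sample count over all
  probes within the MCR extended by 20% of the chromosome-arm length to
  each side (clipped to the arm). Using the broad-only pileup means focal
  peaks never inflate their own baseline.
* ``n_max`` — maximum all-event sample count over the MCR probes;
  ``n_peak = n_max - n_base``.
* Extend probe-by-probe left and right while at least ``40% * n_peak``
  samples above baseline remain (retention rule — cuts well-defined peaks
  at their flanks).
* Per direction, once the above-baseline count has fallen below
  ``80% * n_peak``, stop before any probe where it climbs back to
  ``>= 80% * n_peak`` (regrowth rule — avoids walking uphill into a
  neighboring peak across a dip).
* An MCR (or extension) reaching the first/last probe of the arm is
  extrapolated to the arm boundary, since no probe constrains it there.
* A degenerate peak (``n_peak <= 0``) is returned unchanged.

Counts above baseline are fractional (``n_base`` is a mean); comparisons
use ``>=`` with exact floating arithmetic, no rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

AMP, DEL = "amp", "del"


@dataclass(frozen=True)
class ProbeGrid:
    """Ordered SNP-probe positions on one chromosome arm (bp, 1-based)."""

    arm: str
    positions: np.ndarray  # strictly increasing
    arm_start: int
    arm_end: int

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=np.int64)
        object.__setattr__(self, "positions", pos)
        if len(pos) and (np.any(np.diff(pos) <= 0)):
            raise ValueError("probe positions must be strictly increasing")
        if len(pos) and (pos[0] < self.arm_start or pos[-1] > self.arm_end):
            raise ValueError("probe positions must lie within arm bounds")

    @property
    def arm_length(self) -> int:
        return self.arm_end - self.arm_start + 1

    @classmethod
    def uniform(cls, arm: str, arm_length: int, spacing: int, arm_start: int = 1):
        """Evenly spaced grid covering the arm, first probe at ``arm_start``."""
        if spacing <= 0:
            raise ValueError("spacing must be positive")
        positions = np.arange(arm_start, arm_start + arm_length, spacing, dtype=np.int64)
        return cls(arm=arm, positions=positions, arm_start=arm_start,
                   arm_end=arm_start + arm_length - 1)


@dataclass
class Event:
    """One classified copy-number event in one sample."""

    sample_id: str
    arm: str
    kind: str  # amp | del
    start: int  # bp, 1-based inclusive
    end: int
    scope: str  # focal | broad


@dataclass
class ProbePileup:
    """Per-probe counts of samples carrying an aberration type.

    ``count_all`` counts samples with *any* event of the kind covering the
    probe; ``count_broad`` only samples whose covering event is broad.
    Each sample contributes at most 1 to each probe.
    """

    kind: str
    grid: ProbeGrid
    count_all: np.ndarray
    count_broad: np.ndarray

    def __post_init__(self):
        self.count_all = np.asarray(self.count_all, dtype=float)
        self.count_broad = np.asarray(self.count_broad, dtype=float)
        if np.any(self.count_broad > self.count_all):
            raise ValueError("count_broad cannot exceed count_all")


@dataclass(frozen=True)
class ExtensionParams:
    """Tuning of the robust peak extension."""

    retention_fraction: float = 0.40
    regrowth_fraction: float = 0.80
    baseline_window_fraction: float = 0.20

    def __post_init__(self):
        if not (0 < self.retention_fraction <= self.regrowth_fraction <= 1):
            raise ValueError("need 0 < retention <= regrowth <= 1")
        if not (0 < self.baseline_window_fraction <= 1):
            raise ValueError("baseline_window_fraction must lie in (0, 1]")


@dataclass
class PeakRegion:
    """An MCR with baseline statistics and the extended interval."""

    arm: str
    kind: str
    mcr_probes: tuple[int, int]  # probe indices, inclusive
    mcr_bp: tuple[int, int]
    n_base: float
    n_max: float
    n_peak: float
    extended_probes: tuple[int, int]
    extended_bp: tuple[int, int]
    genes: tuple[str, ...] = ()

    @property
    def extended_width_bp(self) -> int:
        return self.extended_bp[1] - self.extended_bp[0]


def classify_events(
    segments: pd.DataFrame,
    ploidy: float,
    arm_bounds: dict[str, tuple[int, int]],
    amp_log2: float = 0.1,
    del_log2: float = -0.1,
    broad_fraction: float = 0.5,
) -> list[Event]:
    """Classify one sample's segments into amp/del events, focal vs broad.

    A segment is amplified iff ``log2(total_cn / ploidy) > amp_log2`` and
    deleted iff ``< del_log2`` (GISTIC-convention thresholds of +-0.1);
    contiguous same-kind segments are merged into one event. An event is
    broad when it spans more than ``broad_fraction`` of the arm length.
    Total copy number 0 is treated as a deep deletion (log2 of -inf).

    ``segments`` needs columns ``sample_id, chrom, start, end, n_major,
    n_minor`` for a *single* sample; coordinates 1-based inclusive.
    """
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    events: list[Event] = []
    for arm, g in segments.groupby("chrom"):
        if arm not in arm_bounds:
            raise KeyError(f"no arm bounds for {arm!r}")
        a_start, a_end = arm_bounds[arm]
        arm_len = a_end - a_start + 1
        g = g.sort_values("start")
        total = (g["n_major"] + g["n_minor"]).to_numpy(dtype=float)
        if np.any(total < 0):
            raise ValueError("total copy number must be non-negative")
        with np.errstate(divide="ignore"):
            ratio = np.log2(total / float(ploidy))
        kinds = np.where(ratio > amp_log2, AMP, np.where(ratio < del_log2, DEL, "none"))
        sample_id = str(g["sample_id"].iloc[0]) if "sample_id" in g else ""
        # merge runs of contiguous same-kind segments
        i = 0
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        while i < len(g):
            if kinds[i] == "none":
                i += 1
                continue
            j = i
            while (
                j + 1 < len(g)
                and kinds[j + 1] == kinds[i]
                and starts[j + 1] == ends[j] + 1
            ):
                j += 1
            ev_start, ev_end = int(starts[i]), int(ends[j])
            scope = "broad" if (ev_end - ev_start + 1) > broad_fraction * arm_len else "focal"
            events.append(
                Event(sample_id=sample_id, arm=str(arm), kind=str(kinds[i]),
                      start=ev_start, end=ev_end, scope=scope)
            )
            i = j + 1
    return events


def build_pileup(events: Sequence[Event], grid: ProbeGrid, kind: str) -> ProbePileup:
    """Count, per probe, the samples carrying a ``kind`` event over it.

    Overlapping events within one sample are deduplicated per probe; a
    sample whose covering event at a probe is broad contributes to
    ``count_broad`` there as well.
    """
    n_probes = len(grid.positions)
    count_all = np.zeros(n_probes)
    count_broad = np.zeros(n_probes)
    by_sample: dict[str, list[Event]] = {}
    for ev in events:
        if ev.kind == kind and ev.arm == grid.arm:
            by_sample.setdefault(ev.sample_id, []).append(ev)
    pos = grid.positions
    for sample_events in by_sample.values():
        covered = np.zeros(n_probes, dtype=bool)
        covered_broad = np.zeros(n_probes, dtype=bool)
        for ev in sample_events:
            lo = np.searchsorted(pos, ev.start, side="left")
            hi = np.searchsorted(pos, ev.end, side="right")
            covered[lo:hi] = True
            if ev.scope == "broad":
                covered_broad[lo:hi] = True
        count_all += covered
        count_broad += covered_broad
    return ProbePileup(kind=kind, grid=grid, count_all=count_all, count_broad=count_broad)


@dataclass
class MCRCandidate:
    """A maximal run of consecutive probes at a local maximum of the pileup."""

    probes: tuple[int, int]  # inclusive probe-index interval
    height: float
    q_value: float | None = None


def find_mcr(
    pileup: ProbePileup,
    n_permutations: int = 0,
    rng: np.random.Generator | None = None,
) -> list[MCRCandidate]:
    """Detect candidate minimal common regions in a pileup.

    A candidate is a maximal run of consecutive equal-count probes that is
    a strict local maximum of ``count_all`` (every existing neighbor probe
    is lower) and whose count exceeds the broad-only level at its probes.
    A run spanning the whole arm has no neighbors and is not a candidate
    (a flat pileup yields none). Candidates are ranked by height, then
    width, ties broken by leftmost position.

    With ``n_permutations > 0`` a permutation q-value is attached: the
    fraction of probe-label shufflings of ``count_all`` whose maximal
    plateau height reaches the candidate's height.
    """
    c = pileup.count_all
    n = len(c)
    if n == 0:
        raise ValueError("empty pileup")
    candidates: list[MCRCandidate] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and c[j + 1] == c[i]:
            j += 1
        left_lower = i == 0 or c[i - 1] < c[i]
        right_lower = j == n - 1 or c[j + 1] < c[i]
        has_neighbor = i > 0 or j < n - 1
        if has_neighbor and left_lower and right_lower:
            if np.all(c[i : j + 1] > pileup.count_broad[i : j + 1]):
                candidates.append(MCRCandidate(probes=(i, j), height=float(c[i])))
        i = j + 1
    candidates.sort(key=lambda m: (-m.height, -(m.probes[1] - m.probes[0]), m.probes[0]))
    if n_permutations > 0 and candidates:
        rng = rng or np.random.default_rng()
        null_max = np.empty(n_permutations)
        for b in range(n_permutations):
            null_max[b] = rng.permutation(c).max()
        for cand in candidates:
            cand.q_value = float((null_max >= cand.height).mean())
    return candidates


def extend_peak(
    pileup: ProbePileup,
    mcr: tuple[int, int] | MCRCandidate,
    params: ExtensionParams = ExtensionParams(),
) -> PeakRegion:
    """Extend an MCR by the retention/regrowth rules described above."""
    if isinstance(mcr, MCRCandidate):
        mcr = mcr.probes
    lo, hi = int(mcr[0]), int(mcr[1])
    grid = pileup.grid
    n = len(grid.positions)
    if not (0 <= lo <= hi < n):
        raise ValueError("MCR probe indices out of grid range")
    pos = grid.positions

    # baseline from the broad-only track over MCR +- 20% of arm length
    halo = params.baseline_window_fraction * grid.arm_length
    w_lo = max(grid.arm_start, pos[lo] - halo)
    w_hi = min(grid.arm_end, pos[hi] + halo)
    in_window = (pos >= w_lo) & (pos <= w_hi)
    if not in_window.any():
        raise ValueError("empty baseline window; cannot estimate n_base")
    n_base = float(pileup.count_broad[in_window].mean())
    n_max = float(pileup.count_all[lo : hi + 1].max())
    n_peak = n_max - n_base

    mcr_bp = (int(pos[lo]), int(pos[hi]))
    if n_peak <= 0:
        ext = (lo, hi)
    else:
        retain = params.retention_fraction * n_peak
        regrow = params.regrowth_fraction * n_peak
        height = pileup.count_all - n_base

        def walk(start: int, step: int, stop: int) -> int:
            fallen = False
            i = start
            while i != stop:
                nxt = i + step
                h = height[nxt]
                if h < retain:
                    break
                if fallen and h >= regrow:
                    break
                i = nxt
                if h < regrow:
                    fallen = True
            return i

        left = walk(lo, -1, 0)
        right = walk(hi, +1, n - 1)
        ext = (left, right)

    # extrapolate to the arm boundary when no probe constrains the flank
    bp_lo = grid.arm_start if ext[0] == 0 else int(pos[ext[0]])
    bp_hi = grid.arm_end if ext[1] == n - 1 else int(pos[ext[1]])
    return PeakRegion(
        arm=grid.arm,
        kind=pileup.kind,
        mcr_probes=(lo, hi),
        mcr_bp=mcr_bp,
        n_base=n_base,
        n_max=n_max,
        n_peak=n_peak,
        extended_probes=ext,
        extended_bp=(bp_lo, bp_hi),
    )


def peak_report(
    regions: Sequence[PeakRegion],
    annotation: pd.DataFrame | None,
    n_samples: int,
) -> pd.DataFrame:
    """Per-peak gene content and cohort frequency.

    ``annotation`` (optional) has columns ``gene, chrom, start, end``
    (1-based inclusive); genes overlapping the extended interval are
    listed. Frequency is the all-event count at the peak maximum over the
    cohort size.
    """
    rows = []
    for reg in regions:
        genes: list[str] = []
        if annotation is not None and len(annotation):
            on_arm = annotation[annotation["chrom"] == reg.arm]
            lo, hi = reg.extended_bp
            hit = on_arm[(on_arm["start"] <= hi) & (on_arm["end"] >= lo)]
            genes = list(hit["gene"])
        rows.append(
            {
                "arm": reg.arm,
                "kind": reg.kind,
                "mcr_start": reg.mcr_bp[0],
                "mcr_end": reg.mcr_bp[1],
                "extended_start": reg.extended_bp[0],
                "extended_end": reg.extended_bp[1],
                "n_base": reg.n_base,
                "n_max": reg.n_max,
                "n_peak": reg.n_peak,
                "frequency": reg.n_max / n_samples if n_samples else np.nan,
                "genes": ",".join(genes),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "arm", "kind", "mcr_start", "mcr_end", "extended_start",
            "extended_end", "n_base", "n_max", "n_peak", "frequency", "genes",
        ],
    )
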