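"""Pileups, MCR detection and the robust peak-extension rules."""

import numpy as np
import pandas as pd
import pytest

from pblgenomics.scna import (
    AMP,
    DEL,
    Event,
    ExtensionParams,
    ProbeGrid,
    ProbePileup,
    build_pileup,
    classify_events,
    extend_peak,
    find_mcr,
    peak_report,
)

MB = 1_000_000


def segs(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "chrom", "start", "end", "n_major", "n_minor"]
    )


class TestClassifyEvents:
    BOUNDS = {"q": (1, 100 * MB)}

    def test_focal_amp_in_diploid(self):
        df = segs(
            [
                ("s", "q", 1, 10 * MB, 2, 1),  # CN 3 over 10% of arm
                ("s", "q", 10 * MB + 1, 100 * MB, 1, 1),
            ]
        )
        (ev,) = classify_events(df, 2.0, self.BOUNDS)
        assert (ev.kind, ev.scope) == (AMP, "focal")

    def test_tetraploid_baseline_is_no_event(self):
        df = segs([("s", "q", 1, 100 * MB, 2, 2)])  # CN 4 at ploidy 4
        assert classify_events(df, 4.0, self.BOUNDS) == []

    def test_broad_amp_above_half_arm(self):
        df = segs(
            [
                ("s", "q", 1, 60 * MB, 2, 1),  # CN 3 over 60% of arm
                ("s", "q", 60 * MB + 1, 100 * MB, 1, 1),
            ]
        )
        (ev,) = classify_events(df, 2.0, self.BOUNDS)
        assert (ev.kind, ev.scope) == (AMP, "broad")

    def test_contiguous_same_kind_segments_merge(self):
        df = segs(
            [
                ("s", "q", 1, 30 * MB, 2, 1),
                ("s", "q", 30 * MB + 1, 60 * MB, 3, 1),  # still amp, merges
                ("s", "q", 60 * MB + 1, 100 * MB, 1, 1),
            ]
        )
        (ev,) = classify_events(df, 2.0, self.BOUNDS)
        assert ev.scope == "broad" and ev.end == 60 * MB

    def test_negative_cn_rejected(self):
        df = segs([("s", "q", 1, 100 * MB, -1, 0)])
        with pytest.raises(ValueError):
            classify_events(df, 2.0, self.BOUNDS)


class TestPileup:
    def test_no_events_all_zero(self):
        grid = ProbeGrid.uniform("q", 1000, 100)
        p = build_pileup([], grid, AMP)
        assert not p.count_all.any() and not p.count_broad.any()

    def test_focal_on_broad_counts(self):
        """3 focal samples over probes 5-10 on top of 10 arm-wide broad
        samples: 13 on the focal probes, 10 elsewhere."""
        grid = ProbeGrid.uniform("q", 2000, 100)  # probes at 1,101,...,1901
        events = []
        for i in range(3):
            events.append(Event(f"f{i}", "q", AMP, 501, 1001, "focal"))
        for i in range(10):
            events.append(Event(f"b{i}", "q", AMP, 1, 2000, "broad"))
        p = build_pileup(events, grid, AMP)
        focal_probes = (grid.positions >= 501) & (grid.positions <= 1001)
        assert np.all(p.count_all[focal_probes] == 13)
        assert np.all(p.count_all[~focal_probes] == 10)
        assert np.all(p.count_broad == 10)

    def test_overlapping_events_in_one_sample_count_once(self):
        grid = ProbeGrid.uniform("q", 1000, 100)
        events = [
            Event("s", "q", AMP, 1, 600, "focal"),
            Event("s", "q", AMP, 400, 1000, "focal"),
        ]
        p = build_pileup(events, grid, AMP)
        assert p.count_all.max() == 1


class TestFindMCR:
    def _pileup(self, counts, broad=None):
        grid = ProbeGrid.uniform("q", len(counts) * 10, 10)
        return ProbePileup(
            kind=AMP,
            grid=grid,
            count_all=np.asarray(counts, dtype=float),
            count_broad=np.zeros(len(counts)) if broad is None else np.asarray(broad, float),
        )

    def test_single_plateau(self):
        p = self._pileup([0, 0, 5, 5, 5, 0])
        (cand,) = find_mcr(p)
        assert cand.probes == (2, 4) and cand.height == 5

    def test_nested_plateau_returns_inner_maximum(self):
        p = self._pileup([0, 10, 13, 13, 10, 0])
        cands = find_mcr(p)
        assert cands[0].probes == (2, 3) and cands[0].height == 13

    def test_flat_pileup_yields_nothing(self):
        assert find_mcr(self._pileup([4, 4, 4, 4])) == []

    def test_candidates_must_exceed_broad_level(self):
        p = self._pileup([0, 5, 5, 0], broad=[0, 5, 5, 0])
        assert find_mcr(p) == []

    def test_permutation_q_value_attached(self):
        p = self._pileup([0, 0, 9, 9, 0, 0, 1, 0])
        cands = find_mcr(p, n_permutations=50, rng=np.random.default_rng(0))
        assert cands[0].q_value is not None and 0 <= cands[0].q_value <= 1


def nested_peak_pileup(
    arm_mb=50,
    spacing=10_000,
    baseline=5,
    outer_extra=10,
    inner_extra=13,
    outer_mb=0.4,
    inner_mb=0.3,
    center_mb=25.0,
):
    """Synthetic profile like the published IRF4-locus pileup: a narrow
    inner plateau (MCR) nested centrally in a wider, lower plateau, on a
    flat broad-event baseline."""
    grid = ProbeGrid.uniform("6p-like", arm_mb * MB, spacing)
    pos = grid.positions
    count_broad = np.full(len(pos), float(baseline))
    count_all = count_broad.copy()
    # probe-aligned plateaus: a 0.4 Mb-wide plateau spans 41 probes at
    # 10 kb spacing (inclusive ends), so first-to-last probe = 0.4 Mb
    idx = np.arange(len(pos))
    center = int(np.argmin(np.abs(pos - center_mb * MB)))
    outer = np.abs(idx - center) <= round(outer_mb * MB / 2 / spacing)
    inner = np.abs(idx - center) <= round(inner_mb * MB / 2 / spacing)
    count_all[outer] += outer_extra
    count_all[inner] += inner_extra - outer_extra
    return ProbePileup(kind=AMP, grid=grid, count_all=count_all, count_broad=count_broad)


class TestExtendPeak:
    def test_published_worked_profile_spans_full_outer_plateau(self):
        """0.3 Mb inner plateau 13 above baseline nested in a 0.4 Mb
        plateau 10 above baseline: the extension keeps the whole outer
        plateau (10 >= 0.4 * 13 = 5.2)."""
        pileup = nested_peak_pileup()
        (mcr,) = find_mcr(pileup)[:1]
        region = extend_peak(pileup, mcr)
        assert region.n_base == pytest.approx(5.0)
        assert region.n_max == 18
        assert region.n_peak == pytest.approx(13.0)
        lo, hi = region.extended_probes
        # extended interval == outer plateau plus the inner plateau
        covered = np.arange(lo, hi + 1)
        expected = np.nonzero(pileup.count_all >= 15)[0]
        assert np.array_equal(covered, expected)
        assert region.extended_width_bp == pytest.approx(0.4 * MB, abs=2 * 10_000)

    def test_degenerate_peak_returns_mcr(self):
        grid = ProbeGrid.uniform("q", 1000, 100)
        p = ProbePileup(AMP, grid, np.full(10, 5.0), np.full(10, 5.0))
        region = extend_peak(p, (4, 5))
        assert region.n_peak <= 0
        assert region.extended_probes == (4, 5)

    def test_retention_drops_low_shoulder_and_regrowth_blocks_bump(self):
        """Peak 13: a left shoulder at 10 is retained (>= 5.2); a right
        shoulder at 4 is dropped (< 5.2); a distant right bump rising back
        to 12 after a dip to 3 is never entered (regrowth stop at
        >= 0.8*13 = 10.4 after falling below)."""
        counts = [0, 0, 10, 10, 13, 13, 4, 3, 12, 12, 0]
        grid = ProbeGrid.uniform("q", len(counts) * 10, 10)
        p = ProbePileup(AMP, grid, np.array(counts, float), np.zeros(len(counts)))
        region = extend_peak(p, (4, 5))
        assert region.n_base == 0.0
        assert region.extended_probes == (2, 5)

    def test_regrowth_without_prior_fall_does_not_stop(self):
        # counts never fall below 80% of the peak: the 40% rule alone governs
        counts = [0, 11, 12, 11, 13, 0]
        grid = ProbeGrid.uniform("q", len(counts) * 10, 10)
        p = ProbePileup(AMP, grid, np.array(counts, float), np.zeros(len(counts)))
        region = extend_peak(p, (4, 4))
        assert region.extended_probes == (1, 4)

    def test_arm_boundary_extrapolation(self):
        counts = [9, 9, 9, 2, 0, 0]
        grid = ProbeGrid.uniform("q", 60, 10)  # probes 1,11,...,51
        p = ProbePileup(AMP, grid, np.array(counts, float), np.zeros(6))
        region = extend_peak(p, (0, 2))
        assert region.extended_probes[0] == 0
        assert region.extended_bp[0] == grid.arm_start  # extrapolated leftward

    def test_empty_baseline_window_impossible_on_grid(self):
        # the window always contains the MCR probes themselves
        pileup = nested_peak_pileup()
        region = extend_peak(pileup, find_mcr(pileup)[0])
        assert region.n_base > 0


def brute_force_extension(count_all, count_broad, positions, arm_start, arm_end,
                          mcr, retention=0.4, regrowth=0.8, window=0.2):
    """Plain-python re-derivation of the extension rules, kept deliberately
    naive (explicit list walks, no shared code) as an independent oracle."""
    lo, hi = mcr
    arm_len = arm_end - arm_start + 1
    w_lo = positions[lo] - window * arm_len
    w_hi = positions[hi] + window * arm_len
    window_vals = [
        count_broad[i]
        for i in range(len(positions))
        if max(arm_start, w_lo) <= positions[i] <= min(arm_end, w_hi)
    ]
    n_base = sum(window_vals) / len(window_vals)
    n_max = max(count_all[lo : hi + 1])
    n_peak = n_max - n_base
    if n_peak <= 0:
        return (lo, hi)
    left = lo
    fallen = False
    while left > 0:
        h = count_all[left - 1] - n_base
        if h < retention * n_peak:
            break
        if fallen and h >= regrowth * n_peak:
            break
        left -= 1
        if h < regrowth * n_peak:
            fallen = True
    right = hi
    fallen = False
    while right < len(positions) - 1:
        h = count_all[right + 1] - n_base
        if h < retention * n_peak:
            break
        if fallen and h >= regrowth * n_peak:
            break
        right += 1
        if h < regrowth * n_peak:
            fallen = True
    return (left, right)


def random_pileup_and_mcr(rng, max_probes=120):
    n = int(rng.integers(10, max_probes))
    broad = rng.integers(0, 8, size=n).astype(float)
    extra = rng.integers(0, 15, size=n).astype(float)
    # smooth a little so plateaus exist
    if rng.random() < 0.5:
        extra = np.round(np.convolve(extra, np.ones(3) / 3, mode="same"))
    count_all = broad + extra
    grid = ProbeGrid.uniform("q", n * 1000, 1000)
    pileup = ProbePileup(AMP, grid, count_all, broad)
    peak = int(np.argmax(count_all))
    lo = hi = peak
    while lo > 0 and count_all[lo - 1] == count_all[peak]:
        lo -= 1
    while hi < n - 1 and count_all[hi + 1] == count_all[peak]:
        hi += 1
    return pileup, (lo, hi)


def test_extension_matches_brute_force_on_random_pileups(rng):
    for _ in range(300):
        pileup, mcr = random_pileup_and_mcr(rng)
        region = extend_peak(pileup, mcr)
        expected = brute_force_extension(
            pileup.count_all,
            pileup.count_broad,
            pileup.grid.positions,
            pileup.grid.arm_start,
            pileup.grid.arm_end,
            mcr,
        )
        assert region.extended_probes == expected


def test_lower_retention_never_shrinks_extension(rng):
    for _ in range(200):
        pileup, mcr = random_pileup_and_mcr(rng)
        wide = extend_peak(pileup, mcr, ExtensionParams(retention_fraction=0.2))
        narrow = extend_peak(pileup, mcr, ExtensionParams(retention_fraction=0.4))
        assert wide.extended_probes[0] <= narrow.extended_probes[0]
        assert wide.extended_probes[1] >= narrow.extended_probes[1]


def test_baseline_ignores_focal_events_outside_window():
    """n_base is computed on the broad-only track, so extra focal events
    anywhere leave it unchanged."""
    pileup = nested_peak_pileup()
    (mcr,) = find_mcr(pileup)[:1]
    base = extend_peak(pileup, mcr).n_base
    spiked = ProbePileup(
        AMP,
        pileup.grid,
        pileup.count_all + (pileup.grid.positions > 45 * MB) * 7.0,
        pileup.count_broad,
    )
    assert extend_peak(spiked, mcr).n_base == base


class TestPeakReport:
    def test_gene_overlap_and_frequency(self):
        pileup = nested_peak_pileup()
        region = extend_peak(pileup, find_mcr(pileup)[0])
        lo, hi = region.extended_bp
        annotation = pd.DataFrame(
            {
                "gene": ["IRF4-like", "EXOC2-like", "DUSP22-like", "far_away"],
                "chrom": ["6p-like"] * 4,
                "start": [lo + 10, lo - 5000, hi - 100, hi + 5 * MB],
                "end": [lo + 20_000, lo + 1000, hi + 50_000, hi + 6 * MB],
            }
        )
        report = peak_report([region], annotation, n_samples=82)
        genes = report.iloc[0]["genes"].split(",")
        assert set(genes) == {"IRF4-like", "EXOC2-like", "DUSP22-like"}
        assert report.iloc[0]["frequency"] == pytest.approx(18 / 82)

    def test_empty_annotation(self):
        pileup = nested_peak_pileup()
        region = extend_peak(pileup, find_mcr(pileup)[0])
        report = peak_report([region], None, n_samples=82)
        assert report.iloc[0]["genes"] == ""
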