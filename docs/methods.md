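# Methods

This note documents the models, defaults and numerical choices behind
`pblgenomics`, and what the synthetic-data tests do and do not establish
about real cohorts.

## Variant filter hierarchy

Candidate calls arrive pre-scored by an upstream caller; the package's job
is post-discovery filtering. Steps run in a fixed order — depth ≥ 20,
panel-of-normals (PON) exclusion, population allele frequency ≤ 0.001,
matched-normal exclusion (paired mode only), read-orientation bias,
VAF ≥ 0.10, optional gene deny-list — and each removal is attributed to the
first failing step, so the attrition table always satisfies
`inputs = survivors + Σ removals`. All steps are nevertheless evaluated for
every call, so the per-call trail is complete. The six-step order is a
deliberately compact skeleton of production hierarchies that chain many
database-specific annotations; the deny-list step exists because
homology-prone genes (MUC-family and similar) are a database-dependent
exclusion that should be configurable, not hard-coded.

The PON admits a variant key once it is called in ≥ 2 *distinct* normal
subjects; per-key subject counts are retained for reporting.

**Orientation bias.** FFPE deamination artifacts present alt reads almost
exclusively in one read-pair orientation. Instead of a learned
read-orientation mixture model, the package uses an exact two-sided
binomial test of F1R2 vs F2R1 alt counts against 0.5, failing a call at
p < 0.05. This is a closed-form, verifiable operationalization of
"flag a significant forward/reverse imbalance"; it is less powerful than a
learned model at very low alt counts (both-zero counts are indeterminate
and left to the depth/VAF steps), which is an accepted trade-off.

## Robust SCNA peak extension

Segments are classified per sample as amplification/deletion when
`log2(total_cn / ploidy)` exceeds ±0.1 (GISTIC-convention amplitude), and
as broad when the merged event spans > 50% of the arm. Pileups count, per
SNP probe, the samples carrying an event of a kind (`count_all`) and those
whose covering event is broad (`count_broad`); a sample counts at most once
per probe.

An MCR candidate is a maximal run of equal-count probes forming a strict
local maximum of `count_all` that exceeds the broad-only level; candidates
rank by height, then width, ties broken leftmost for determinism. A run
spanning the whole arm has no neighbors and is not a candidate, so a flat
pileup yields none. An optional permutation q-value shuffles probe labels.

The extension around an MCR:

1. `n_base` = mean of `count_broad` over probes within the MCR ± 20% of the
   arm length (clipped to the arm). Using the broad-only track makes the
   baseline insensitive to focal peaks — including the peak under study, so
   whether the MCR's own probes sit inside the window is immaterial and
   they are included.
2. `n_max` = max `count_all` within the MCR; `n_peak = n_max − n_base`
   (fractional; all comparisons use ≥ on exact floats, no rounding).
3. Walk outward probe-by-probe while `count_all − n_base ≥ 0.40·n_peak`.
4. Per direction, once the above-baseline count has dropped below
   `0.80·n_peak` at any probe beyond the MCR, stop before any probe where
   it climbs back to ≥ `0.80·n_peak` (prevents crossing a dip into a
   neighboring peak). If counts never fall below the regrowth threshold,
   the retention rule alone governs — the degenerate case is explicitly
   tested.
5. An extension (or MCR) reaching the arm's first/last probe is
   extrapolated to the arm boundary, since no probe constrains that flank.
6. `n_peak ≤ 0` returns the MCR unchanged.

Lowering the retention fraction can only lengthen the walk, so the
extended interval is monotone in that parameter; this and exact agreement
with an independently coded brute-force simulator over random pileups are
enforced by tests.

## Cancer cell fraction and clonality

`f_CCF = (f_VAF/f_purity)·((1−f_purity)·2 + f_purity·n_CN,tumor)`, with the
local tumor copy number taken from the segment overlapping the variant
(left segment on boundary ties). Values are *not* clipped at 1 by default:
CCF > 1 flags inconsistent purity/CN input and is worth surfacing; a clip
option exists. Clonality is `f_CCF ≥ 0.9`, boundary inclusive. Allelic
multiplicity is not modeled (total-CN formula); per-gene summaries count a
sample as clonally mutated if any of its mutations in the gene is clonal,
and report the median CCF over mutation records.

## Association screen

Lesion indicators are binary; subcohort comparisons are declared before
testing and missing covariates are excluded per comparison (pairwise), not
listwise. The one-tailed Wilcoxon rank-sum test uses the exact permutation
distribution of the mid-rank sum (a subset-sum dynamic program over doubled
ranks, exact in integer arithmetic) for N ≤ 50, because the cohort's
subgroups are small (n as low as 2) and binary data are maximally tied; for
larger N a tie-corrected, continuity-corrected normal approximation is
used, and either path can be forced via `method=`. For binary data the
exact tail coincides with a hypergeometric tail, which the tests exploit as
an independent oracle. Note the two paths differ noticeably in small
samples (e.g. 7/15 vs 3/31 positives: exact 0.0079, asymptotic 0.0025);
published Wilcoxon p-values from standard software correspond to the
asymptotic path. BH FDR is applied within each comparison's lesion family,
significance at q < 0.1.

## Survival

OS is time to death from any cause; LSS censors patients alive or dead
from other causes at the last follow-up/death time, so `lss_event = 1`
implies `os_event = 1` and the time scales coincide. Estimation uses
lifelines: Kaplan–Meier product-limit (read right-continuously; a 2-year
rate is S(24 months)), two-sided log-rank with k−1 df, univariate Cox with
Efron tie handling (month-granularity times are heavily tied; Efron is the
accurate default). Complete separation is flagged as an unbounded HR rather
than silently reported. Screens run each preselected condition on the
CHOP-like-treated subset when configured, with BH FDR over the declared
family.

## Screen scoring

Size factors are DESeq-style median-of-ratios against a geometric-mean
reference over rows positive in all columns. Note that rescaling one of m
columns by k rescales all normalized counts by a common k^(1/m); every
depletion ratio and z-score contrast is invariant, and the property tests
assert exactly this form of invariance. shRNAs with raw day-12 on+off read
sums < 50 are removed before scoring (boundary inclusive on 50). Depletion
is `log2((on + 0.5)/(off + 0.5))` per replicate, averaged, then z-scored
over all scored shRNAs with the sample standard deviation; ranking is
ascending (most depleted first). The z-score of replicate-averaged ratios
(rather than per-replicate z averaging) matches the "mean log2 ratio"
reading and is the documented choice. A negative-binomial Wald test was
deliberately not wrapped; the scored quantity is the plotted one.

## Synthetic cohort generator

The generator's defaults are the study conditions and are versioned in
`CohortConfig`, not buried in logic: 85 tumors, 38 normal controls, gene
mutation probabilities set to the published cohort frequencies (NRAS 0.31,
STAT3 0.25, TP53 0.14, KRAS 0.11, SOCS1 0.12, ATM 0.08, KLHL6 0.08,
BRAF 0.06, TET2 0.06, JAK1 0.05) with hotspot clustering and per-gene
clonal probabilities (high for RAS-pathway drivers, 0.5 for STAT3, 0.27
for TP53); SCNA event probabilities matching the published recurrent
lesions (e.g. focal 1q23.1-like 0.61, 1q21.3-like 0.52, 6p25.3-like 0.29;
broad 1q 0.42, 7p 0.32, 7q 0.33); purity uniform on [0.3, 0.95] with a 16%
tetraploid minority; sequencing depth 80 (the cohort's median effective
coverage); covariate prevalences EBV+ 0.57, HIV+ 0.33, IPI low/int/high
0.32/0.46/0.22, CHOP-like 0.82. Passenger somatic SNVs (Poisson, mean 150
per tumor, 70% clonal) provide a realistic mutation burden of a few
mutations/Mb over an ~50 Mb exome-scale target. Contaminant rates
(orientation artifacts 25, germline leaks 40, recurrent pipeline artifacts
10 per tumor in expectation) were chosen once so that unpaired calling
visibly loses precision while the hierarchy recovers most of it — the
direction of effect reported for real data.

VAFs are generated by inverting the CCF formula (clonal CCF = 1, subclonal
CCF ~ U(0.1, 0.9), single mutated allele) and adding binomial sampling at
the configured depth; the noise-free VAF is kept in the ground truth so the
CCF round trip is testable to machine precision. Survival is exponential
with multiplicative hazards (baseline lymphoma hazard 0.007/month;
multipliers 8 for high IPI and 3.5 for EBV-negative disease; independent
other-cause hazard 0.004/month) and administrative uniform censoring on
[0, 72] months — the published generative model is unspecified, so these
are the package's own choices targeting the reported ballpark of ~60%
2-year OS and a strongly inferior high-IPI stratum. Screen counts are
negative-binomial (dispersion 0.1) in duplicate over the published library
layout (2669 shRNAs / 768 genes; MYC 2, IRF4 4, STAT3 1 shRNAs plus a
planted essential-gene set, ~100 depleted shRNAs at −2 log2).

Lesions, covariates and screen effects are generated independently; the
mutual exclusivities seen in real cohorts (e.g. between RAS-family genes)
are not modeled unless configured, because no joint distribution is
published. All randomness derives from one seed via named substreams, so a
fixed seed gives byte-identical outputs.

**What passing tests show — and don't.** The synthetic cohort has clean
segment tiling, exactly exponential hazards, independent lesions and
idealized binomial read sampling. Passing the calibration/power tests
demonstrates the estimators and rules are implemented correctly under
these stated conditions; it does not certify performance on real FFPE
data, where artifact structure, subclonal copy number and covariate
correlations are richer.

## Problem sizes in tests

The test suite runs the full generator at default scale (85 tumors), the
brute-force extension comparison on 1,000 random pileups, the exact-test
sweep over all binary tables with N ≤ 20, 200-replicate power/FDR
simulations for the association screen, and 200 Cox fits at n = 500; the
whole suite completes in about half a minute on one CPU. The cohort-level
checks that depend on the study's deposited supplementary tables
(mutation, clinical and screen-count tables) expect those files under
`data/published/` and fail cleanly when absent, since third-party data are
not redistributed here.

## Known limitations

* The filter hierarchy is a six-step skeleton; production pipelines
  interleave many annotation-dependent steps whose exact order is not
  public.
* No subclonal deconvolution (no mixture model over CCFs); only the
  threshold rule.
* No GISTIC background model or arm-level significance — the permutation
  q-value on MCR candidates is a simple stand-in; the extension algorithm
  itself is exact.
* No multivariable Cox, no competing-risks model (LSS uses censoring).
* CLI `scna` operates per arm; genome-wide orchestration is in
  `pipeline.run_pipeline`.
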