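"""Seeded generator of a synthetic plasmablastic-lymphoma-like cohort.

Every downstream stage of the pipeline (variant filtering, SCNA
recurrence, clonality, association, survival, screen scoring) is testable
against this generator's known ground truth, without any external data.

What is emulated
----------------
* Per-gene somatic mutation frequencies calibrated to the published PBL
  cohort landscape (NRAS 31%, STAT3 25%, TP53 14%, KRAS 11%, ...), with
  hotspot clustering and per-gene clonal probabilities.
* Tumor VAFs generated by inverting the CCF formula: clonal mutations get
  CCF = 1, subclonal CCF ~ Uniform(0.1, 0.9); the expected VAF follows
  from purity and local tumor copy number, and the observed VAF is a
  binomial draw at the configured sequencing depth (default 80 reads,
  the cohort's median effective coverage).
* Focal and broad SCNAs over per-arm SNP-probe grids with breakpoint
  jitter, sample purity and ploidy variation (a polyploid minority).
* Contaminant records with ground-truth labels: leaked germline variants
  (a shared common-site catalog plus private novel sites, with matched
  -normal support), FFPE orientation-bias artifacts (strand-skewed alt
  reads), and recurrent pipeline artifacts shared with the normal
  controls (caught by a panel of normals).
* Censored survival with covariate-dependent hazards (high IPI, EBV-
  negative disease) and a CHOP-like treatment flag.
* Negative-binomial shRNA screen counts in duplicate with a planted
  depleted set.

All randomness flows from a single integer seed, split into named
substreams, so a fixed seed yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .clonality import vaf_from_ccf
from .scna import ProbeGrid

MB = 1_000_000

#: Chromosome arms of the simulated genome (lengths in bp, roughly hg38).
DEFAULT_ARMS: dict[str, int] = {
    "1p": 123 * MB,
    "1q": 125 * MB,
    "3q": 103 * MB,
    "4q": 140 * MB,
    "6p": 61 * MB,
    "6q": 110 * MB,
    "7p": 60 * MB,
    "7q": 99 * MB,
    "8q": 101 * MB,
    "11q": 83 * MB,
    "12p": 34 * MB,
    "13q": 98 * MB,
    "16p": 36 * MB,
    "17p": 25 * MB,
    "17q": 58 * MB,
    "18p": 18 * MB,
}

NUCLEOTIDES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GeneModel:
    """Mutation model of one gene: locus, cohort frequency, clonality."""

    gene: str
    arm: str
    start: int
    end: int
    mutation_probability: float
    clonal_probability: float
    hotspots: tuple[int, ...] = ()
    hotspot_weight: float = 0.8  # probability that a mutation hits a hotspot


@dataclass(frozen=True)
class ScnaEventModel:
    """One recurrent SCNA: locus, kind, focal/broad, per-sample probability."""

    arm: str
    kind: str  # amp | del
    scope: str  # focal | broad
    start: int | None  # bp for focal events; broad events span the arm
    end: int | None
    probability: float
    delta: int  # copy-number change relative to ploidy
    jitter_fraction: float = 0.10  # breakpoint jitter, fraction of event length


@dataclass(frozen=True)
class ClinicalModel:
    """Covariate prevalences and survival-model parameters.

    Hazards are exponential, in units of events per month; covariate
    effects are multiplicative on the lymphoma-death hazard. Censoring is
    administrative: uniform on [0, max_followup_months].
    """

    ebv_positive_rate: float = 0.57
    hiv_positive_rate: float = 0.33
    ipi_distribution: tuple[float, float, float] = (0.32, 0.46, 0.22)  # low/int/high
    myc_translocation_rate: float = 0.47
    cd20_positive_rate: float = 0.14
    site_oral_rate: float = 0.33
    immunosuppression_rate: float = 0.52
    chop_like_rate: float = 0.82
    baseline_lymphoma_hazard: float = 0.007
    other_cause_hazard: float = 0.004
    hazard_multipliers: dict = field(
        default_factory=lambda: {"ipi_high": 8.0, "ebv_negative": 3.5}
    )
    max_followup_months: float = 72.0
    missingness: dict = field(
        default_factory=lambda: {"hiv_positive": 0.45, "myc_translocated": 0.35}
    )


@dataclass(frozen=True)
class ScreenModel:
    """Layout and noise model of the pooled shRNA screen."""

    n_shrnas: int = 2669
    n_genes: int = 768
    dispersion: float = 0.1
    depleted_genes: tuple[str, ...] = ("MYC", "IRF4", "STAT3") + tuple(
        f"ESS{i:03d}" for i in range(1, 26)
    )
    depletion_log2: float = -2.0
    special_gene_shrnas: dict = field(
        default_factory=lambda: {"MYC": 2, "IRF4": 4, "STAT3": 1}
    )
    abundance_log_mean: float = np.log(500.0)
    abundance_log_sd: float = 1.0
    column_factor_log_sd: float = 0.15


@dataclass(frozen=True)
class ArtifactRates:
    """Expected contaminant record counts per tumor sample."""

    orientation_bias: float = 25.0
    germline_contaminant: float = 40.0
    pon_artifact: float = 10.0


def default_gene_models() -> tuple[GeneModel, ...]:
    """Cohort-frequency calibration table (versioned default, not hard-coded
    in generator logic)."""

    def gm(gene, arm, start_mb, p, clonal, hotspots=()):
        start = int(start_mb * MB)
        return GeneModel(
            gene=gene, arm=arm, start=start, end=start + 50_000,
            mutation_probability=p, clonal_probability=clonal,
            hotspots=tuple(start + h for h in hotspots),
        )

    return (
        gm("NRAS", "1p", 8.0, 0.31, 0.85, hotspots=(1_200, 1_260, 5_700)),
        gm("STAT3", "17q", 17.0, 0.25, 0.50, hotspots=(21_000, 22_100)),
        gm("TP53", "17p", 7.6, 0.14, 0.27),
        gm("SOCS1", "16p", 11.3, 0.12, 0.60),
        gm("KRAS", "12p", 9.0, 0.11, 0.85, hotspots=(800, 860)),
        gm("ATM", "11q", 55.0, 0.08, 0.50),
        gm("KLHL6", "3q", 92.0, 0.08, 0.60),
        gm("BRAF", "7q", 81.0, 0.06, 0.85, hotspots=(33_000,)),
        gm("TET2", "4q", 55.0, 0.06, 0.60),
        gm("JAK1", "1p", 56.0, 0.05, 0.50),
    )


def default_scna_events() -> tuple[ScnaEventModel, ...]:
    """Recurrent SCNA calibration table (cohort frequencies of the study)."""
    f = ScnaEventModel
    return (
        f("1q", "amp", "broad", None, None, 0.42, +1),
        f("7p", "amp", "broad", None, None, 0.32, +1),
        f("7q", "amp", "broad", None, None, 0.33, +1),
        f("1q", "amp", "focal", int(33.5 * MB), int(34.6 * MB), 0.61, +2),  # FCRL1-5
        f("1q", "amp", "focal", int(30.5 * MB), int(32.5 * MB), 0.52, +2),  # MCL1
        f("6p", "amp", "focal", int(0.2 * MB), int(0.6 * MB), 0.29, +2),    # IRF4
        f("8q", "amp", "focal", int(75.0 * MB), int(76.5 * MB), 0.32, +2),  # TRIB1
        f("17q", "amp", "focal", int(30.0 * MB), int(31.5 * MB), 0.21, +2), # MSI2
        f("1p", "del", "focal", int(72.0 * MB), int(73.0 * MB), 0.24, -1),  # RPL5
        f("4q", "del", "focal", int(138.0 * MB), int(139.5 * MB), 0.26, -1),  # FAT1
        f("6q", "del", "focal", int(101.0 * MB), int(103.0 * MB), 0.25, -1),  # PRKN
        f("13q", "del", "broad", None, None, 0.16, -1),
        f("17p", "del", "broad", None, None, 0.15, -1),
        f("18p", "del", "broad", None, None, 0.16, -1),
    )


@dataclass(frozen=True)
class CohortConfig:
    """Full configuration of the synthetic cohort.

    Defaults are calibrated once to the published cohort's marginal
    frequencies; they define the study conditions for every test.
    """

    n_tumors: int = 85
    n_normals: int = 38
    arms: dict = field(default_factory=lambda: dict(DEFAULT_ARMS))
    gene_models: tuple[GeneModel, ...] = field(default_factory=default_gene_models)
    scna_events: tuple[ScnaEventModel, ...] = field(default_factory=default_scna_events)
    probe_spacing: int = 100_000
    purity_range: tuple[float, float] = (0.3, 0.95)
    ploidy_options: tuple[float, ...] = (2.0, 4.0)
    ploidy_weights: tuple[float, ...] = (0.84, 0.16)
    sequencing_depth: int = 80
    subclonal_ccf_range: tuple[float, float] = (0.1, 0.9)
    passenger_rate: float = 150.0  # mean somatic passenger SNVs per tumor
    passenger_clonal_probability: float = 0.7
    artifact_rates: ArtifactRates = field(default_factory=ArtifactRates)
    orientation_bias_strength: float = 0.95  # strand skew of FFPE artifacts
    n_germline_catalog_sites: int = 300
    n_pon_artifact_sites: int = 50
    clinical_model: ClinicalModel = field(default_factory=ClinicalModel)
    screen_model: ScreenModel = field(default_factory=ScreenModel)
    seed: int = 0

    def validate(self) -> None:
        if self.n_tumors < 0 or self.n_normals < 0:
            raise ValueError("sample counts must be non-negative")
        if not self.gene_models:
            raise ValueError("gene_models must not be empty")
        if self.probe_spacing <= 0:
            raise ValueError("probe spacing must be positive")
        for g in self.gene_models:
            if not (0 <= g.mutation_probability <= 1 and 0 <= g.clonal_probability <= 1):
                raise ValueError(f"invalid probability for gene {g.gene}")
            if g.arm not in self.arms:
                raise ValueError(f"gene {g.gene} on unknown arm {g.arm}")
        for ev in self.scna_events:
            if not 0 <= ev.probability <= 1:
                raise ValueError("SCNA event probability outside [0, 1]")
            if ev.arm not in self.arms:
                raise ValueError(f"SCNA event on unknown arm {ev.arm}")
        if not (0 < self.purity_range[0] <= self.purity_range[1] <= 1):
            raise ValueError("purity_range must lie in (0, 1]")
        if self.screen_model.dispersion <= 0:
            raise ValueError("screen dispersion must be positive")


@dataclass
class GroundTruth:
    """Truth labels for every emitted record.

    ``variants`` carries one row per emitted tumor variant record with a
    ``label`` in {somatic, germline, artifact_orientation, artifact_pon},
    the true CCF/copy-number/VAF (before sampling noise) and clonal flag
    for somatic records. ``scna`` lists the true per-sample events.
    """

    variants: pd.DataFrame
    scna: pd.DataFrame
    survival_params: dict
    depleted_shrnas: tuple[str, ...]


@dataclass
class SyntheticCohort:
    """Everything :func:`generate_cohort` produces."""

    tumor_calls: pd.DataFrame
    normal_calls: pd.DataFrame
    segments: pd.DataFrame
    purity_ploidy: pd.DataFrame
    clinical: pd.DataFrame
    truth: GroundTruth
    config: CohortConfig

    def probe_grid(self, arm: str) -> ProbeGrid:
        return ProbeGrid.uniform(arm, self.config.arms[arm], self.config.probe_spacing)


VARIANT_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt", "gene", "vaf", "depth",
    "alt_f1r2", "alt_f2r1", "population_af", "matched_normal_support",
]
TRUTH_COLUMNS = VARIANT_COLUMNS[:6] + [
    "label", "clonal", "ccf_true", "cn_true", "vaf_true", "purity",
]


def _rngs(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    """Named independent substreams derived from one root seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {name: np.random.default_rng(c) for name, c in zip(names, children)}


def _random_site(rng, arms: dict[str, int]) -> tuple[str, int, str, str]:
    arm_names = sorted(arms)
    arm = arm_names[rng.integers(len(arm_names))]
    pos = int(rng.integers(1, arms[arm] + 1))
    ref, alt = rng.choice(4, size=2, replace=False)
    return arm, pos, str(NUCLEOTIDES[ref]), str(NUCLEOTIDES[alt])


def _cn_profile(
    ploidy: float, arm_len: int, events: list[tuple[int, int, int]]
) -> list[tuple[int, int, float]]:
    """Piecewise-constant total copy number over one arm.

    ``events`` are (start, end, delta) intervals; deltas add on top of the
    ploidy baseline, floored at 0. Returns merged (start, end, cn) pieces
    tiling [1, arm_len] without gaps.
    """
    cuts = {1, arm_len + 1}
    for s, e, _ in events:
        cuts.add(s)
        cuts.add(e + 1)
    edges = sorted(cuts)
    pieces = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        cn = ploidy + sum(d for s, e, d in events if s <= lo and hi - 1 <= e)
        pieces.append((lo, hi - 1, max(cn, 0.0)))
    merged = [pieces[0]]
    for lo, hi, cn in pieces[1:]:
        plo, phi, pcn = merged[-1]
        if cn == pcn:
            merged[-1] = (plo, hi, cn)
        else:
            merged.append((lo, hi, cn))
    return merged


def _split_alleles(total: float, ploidy: float) -> tuple[float, float]:
    """Allocate a total copy number to major/minor alleles."""
    base_minor = ploidy / 2.0
    minor = min(np.floor(total / 2.0), base_minor)
    if total <= 0:
        return 0.0, 0.0
    minor = max(min(minor, total), 0.0)
    return total - minor, minor


def _profile_cn_at(profile: list[tuple[int, int, float]], pos: int) -> float:
    for lo, hi, cn in profile:
        if lo <= pos <= hi:
            return cn
    raise ValueError("position outside arm profile")


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate the full synthetic cohort (see module docstring).

    Deterministic for a fixed ``config.seed``.
    """
    config = config or CohortConfig()
    config.validate()
    rngs = _rngs(
        config.seed,
        [
            "sites", "purity", "scna", "mutations", "artifacts",
            "germline", "normals", "clinical", "screen",
        ],
    )

    # shared site catalogs (germline contaminants, recurrent PON artifacts)
    rng = rngs["sites"]
    germline_catalog = []
    for _ in range(config.n_germline_catalog_sites):
        arm, pos, ref, alt = _random_site(rng, config.arms)
        germline_catalog.append((arm, pos, ref, alt, float(rng.uniform(0.01, 0.5))))
    pon_sites = [_random_site(rng, config.arms) for _ in range(config.n_pon_artifact_sites)]

    tumor_ids = [f"PBL{i + 1:03d}" for i in range(config.n_tumors)]
    normal_ids = [f"NRM{i + 1:03d}" for i in range(config.n_normals)]

    # --- purity / ploidy -------------------------------------------------
    rng = rngs["purity"]
    purities = rng.uniform(*config.purity_range, size=config.n_tumors)
    ploidies = rng.choice(
        config.ploidy_options, size=config.n_tumors, p=config.ploidy_weights
    )
    purity_ploidy = pd.DataFrame(
        {"sample_id": tumor_ids, "purity": purities, "ploidy": ploidies}
    )

    # --- SCNAs -----------------------------------------------------------
    rng = rngs["scna"]
    seg_rows = []
    scna_truth_rows = []
    profiles: list[dict[str, list[tuple[int, int, float]]]] = []
    for i, sid in enumerate(tumor_ids):
        per_arm: dict[str, list[tuple[int, int, int]]] = {}
        for ev in config.scna_events:
            if rng.random() >= ev.probability:
                continue
            arm_len = config.arms[ev.arm]
            if ev.scope == "broad":
                start, end = 1, arm_len
            else:
                length = ev.end - ev.start
                j = ev.jitter_fraction * length
                start = int(np.clip(ev.start + rng.uniform(-j, j), 1, arm_len))
                end = int(np.clip(ev.end + rng.uniform(-j, j), start, arm_len))
            per_arm.setdefault(ev.arm, []).append((start, end, ev.delta))
            scna_truth_rows.append(
                {
                    "sample_id": sid, "arm": ev.arm, "kind": ev.kind,
                    "scope": ev.scope, "start": start, "end": end,
                    "delta": ev.delta,
                }
            )
        sample_profiles = {}
        for arm, arm_len in config.arms.items():
            profile = _cn_profile(ploidies[i], arm_len, per_arm.get(arm, []))
            sample_profiles[arm] = profile
            for lo, hi, cn in profile:
                major, minor = _split_alleles(cn, ploidies[i])
                seg_rows.append(
                    {
                        "sample_id": sid, "chrom": arm, "start": lo, "end": hi,
                        "n_major": major, "n_minor": minor,
                    }
                )
        profiles.append(sample_profiles)

    segments = pd.DataFrame(
        seg_rows, columns=["sample_id", "chrom", "start", "end", "n_major", "n_minor"]
    )

    # --- somatic mutations ----------------------------------------------
    rng = rngs["mutations"]
    call_rows = []
    truth_rows = []
    depth = config.sequencing_depth

    def emit(sid, arm, pos, ref, alt, gene, vaf_true, label, clonal, ccf, cn,
             purity, pop_af, normal_support, strand_p=0.5):
        alt_reads = int(rng.binomial(depth, min(vaf_true, 1.0)))
        f1r2 = int(rng.binomial(alt_reads, strand_p)) if alt_reads else 0
        call_rows.append(
            {
                "sample_id": sid, "chrom": arm, "pos": pos, "ref": ref,
                "alt": alt, "gene": gene, "vaf": alt_reads / depth,
                "depth": depth, "alt_f1r2": f1r2, "alt_f2r1": alt_reads - f1r2,
                "population_af": pop_af, "matched_normal_support": normal_support,
            }
        )
        truth_rows.append(
            {
                "sample_id": sid, "chrom": arm, "pos": pos, "ref": ref,
                "alt": alt, "gene": gene, "label": label, "clonal": clonal,
                "ccf_true": ccf, "cn_true": cn, "vaf_true": vaf_true,
                "purity": purity,
            }
        )

    for i, sid in enumerate(tumor_ids):
        purity = float(purities[i])
        for g in config.gene_models:
            if rng.random() >= g.mutation_probability:
                continue
            if g.hotspots and rng.random() < g.hotspot_weight:
                pos = int(g.hotspots[rng.integers(len(g.hotspots))])
            else:
                pos = int(rng.integers(g.start, g.end + 1))
            ref_i, alt_i = rng.choice(4, size=2, replace=False)
            clonal = bool(rng.random() < g.clonal_probability)
            ccf = 1.0 if clonal else float(rng.uniform(*config.subclonal_ccf_range))
            cn = _profile_cn_at(profiles[i][g.arm], pos)
            if cn <= 0:
                continue  # homozygously deleted locus cannot carry a detectable SNV
            vaf_true = vaf_from_ccf(ccf, purity, cn)
            emit(
                sid, g.arm, pos, str(NUCLEOTIDES[ref_i]), str(NUCLEOTIDES[alt_i]),
                g.gene, vaf_true, "somatic", clonal, ccf, cn, purity,
                pop_af=0.0, normal_support=0,
            )
        # somatic passenger SNVs spread over the exome (drive the TMB)
        for _ in range(rng.poisson(config.passenger_rate)):
            arm, pos, ref, alt = _random_site(rng, config.arms)
            clonal = bool(rng.random() < config.passenger_clonal_probability)
            ccf = 1.0 if clonal else float(rng.uniform(*config.subclonal_ccf_range))
            cn = _profile_cn_at(profiles[i][arm], pos)
            if cn <= 0:
                continue
            emit(sid, arm, pos, ref, alt, "", vaf_from_ccf(ccf, purity, cn),
                 "somatic", clonal, ccf, cn, purity, pop_af=0.0, normal_support=0)

    # --- contaminants ----------------------------------------------------
    rng = rngs["artifacts"]
    rates = config.artifact_rates
    for i, sid in enumerate(tumor_ids):
        purity = float(purities[i])
        # FFPE orientation-bias artifacts: strand-skewed low-VAF records
        for _ in range(rng.poisson(rates.orientation_bias)):
            arm, pos, ref, alt = _random_site(rng, config.arms)
            vaf_true = float(rng.uniform(0.03, 0.25))
            strand_p = (
                config.orientation_bias_strength
                if rng.random() < 0.5
                else 1 - config.orientation_bias_strength
            )
            emit(sid, arm, pos, ref, alt, "", vaf_true, "artifact_orientation",
                 False, np.nan, np.nan, purity, 0.0, 0, strand_p=strand_p)
        # recurrent pipeline artifacts drawn from the shared PON site list
        n_pon_hits = rng.poisson(rates.pon_artifact)
        site_idx = rng.choice(len(pon_sites), size=min(n_pon_hits, len(pon_sites)),
                              replace=False)
        for k in site_idx:
            arm, pos, ref, alt = pon_sites[k]
            vaf_true = float(rng.uniform(0.1, 0.6))
            emit(sid, arm, pos, ref, alt, "", vaf_true, "artifact_pon",
                 False, np.nan, np.nan, purity, 0.0, 0)
    # leaked germline variants (heterozygous; removable via population AF,
    # PON, or — for novel private sites — only via the matched normal)
    rng = rngs["germline"]
    for i, sid in enumerate(tumor_ids):
        purity = float(purities[i])
        for _ in range(rng.poisson(rates.germline_contaminant)):
            if rng.random() < 0.6:
                arm, pos, ref, alt, af = germline_catalog[
                    rng.integers(len(germline_catalog))
                ]
            else:
                arm, pos, ref, alt = _random_site(rng, config.arms)
                af = 0.0
            support = int(rng.binomial(40, 0.5))
            emit(sid, arm, pos, ref, alt, "", 0.5, "germline", False,
                 np.nan, np.nan, purity, af, max(support, 1))

    tumor_calls = pd.DataFrame(call_rows, columns=VARIANT_COLUMNS)
    truth_variants = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)

    # --- normal controls (for PON construction) --------------------------
    rng = rngs["normals"]
    normal_rows = []
    for sid in normal_ids:
        for arm, pos, ref, alt in pon_sites:
            if rng.random() < 0.5:
                normal_rows.append(
                    {"sample_id": sid, "chrom": arm, "pos": pos, "ref": ref, "alt": alt}
                )
        for arm, pos, ref, alt, af in germline_catalog:
            if rng.random() < af:
                normal_rows.append(
                    {"sample_id": sid, "chrom": arm, "pos": pos, "ref": ref, "alt": alt}
                )
        for _ in range(rng.poisson(5)):
            arm, pos, ref, alt = _random_site(rng, config.arms)
            normal_rows.append(
                {"sample_id": sid, "chrom": arm, "pos": pos, "ref": ref, "alt": alt}
            )
    normal_calls = pd.DataFrame(
        normal_rows, columns=["sample_id", "chrom", "pos", "ref", "alt"]
    )

    # --- clinical covariates and survival --------------------------------
    cm = config.clinical_model
    rng = rngs["clinical"]
    n = config.n_tumors
    ebv = (rng.random(n) < cm.ebv_positive_rate).astype(float)
    hiv = (rng.random(n) < cm.hiv_positive_rate).astype(float)
    ipi = rng.choice(["low", "intermediate", "high"], size=n, p=cm.ipi_distribution)
    myc = (rng.random(n) < cm.myc_translocation_rate).astype(float)
    cd20 = (rng.random(n) < cm.cd20_positive_rate).astype(float)
    oral = (rng.random(n) < cm.site_oral_rate).astype(float)
    immsup = (rng.random(n) < cm.immunosuppression_rate).astype(float)
    chop = (rng.random(n) < cm.chop_like_rate).astype(float)

    mult = np.ones(n)
    mult *= np.where(ipi == "high", cm.hazard_multipliers.get("ipi_high", 1.0), 1.0)
    mult *= np.where(ebv == 0, cm.hazard_multipliers.get("ebv_negative", 1.0), 1.0)
    lym_hazard = cm.baseline_lymphoma_hazard * mult
    if n:
        t_lym = rng.exponential(1.0 / lym_hazard)
        t_other = rng.exponential(1.0 / cm.other_cause_hazard, size=n)
        censor = rng.uniform(0, cm.max_followup_months, size=n)
    else:
        t_lym = t_other = censor = np.array([])
    t_death = np.minimum(t_lym, t_other)
    os_months = np.minimum(t_death, censor)
    os_event = (t_death <= censor).astype(int)
    lss_event = ((t_lym <= censor) & (t_lym <= t_other)).astype(int)

    clinical = pd.DataFrame(
        {
            "sample_id": tumor_ids,
            "ebv_positive": ebv,
            "hiv_positive": hiv,
            "ipi_group": ipi,
            "ipi_high": (ipi == "high").astype(float),
            "myc_translocated": myc,
            "cd20_positive": cd20,
            "site_oral": oral,
            "immunosuppression": immsup,
            "chop_like": chop,
            "os_months": os_months,
            "os_event": os_event,
            "lss_months": os_months,
            "lss_event": lss_event,
        }
    )
    for col, rate in cm.missingness.items():
        if col in clinical and rate > 0 and n:
            miss = rng.random(n) < rate
            clinical.loc[miss, col] = np.nan

    truth = GroundTruth(
        variants=truth_variants,
        scna=pd.DataFrame(
            scna_truth_rows,
            columns=["sample_id", "arm", "kind", "scope", "start", "end", "delta"],
        ),
        survival_params={
            "baseline_lymphoma_hazard": cm.baseline_lymphoma_hazard,
            "other_cause_hazard": cm.other_cause_hazard,
            "hazard_multipliers": dict(cm.hazard_multipliers),
            "max_followup_months": cm.max_followup_months,
        },
        depleted_shrnas=(),
    )
    return SyntheticCohort(
        tumor_calls=tumor_calls,
        normal_calls=normal_calls,
        segments=segments,
        purity_ploidy=purity_ploidy,
        clinical=clinical,
        truth=truth,
        config=config,
    )


def generate_screen_counts(
    config: CohortConfig | None = None,
) -> tuple[pd.DataFrame, tuple[str, ...]]:
    """Negative-binomial shRNA screen counts in duplicate.

    Returns the count matrix (columns ``shrna_id, gene, d0_r1, d0_r2,
    d12_on_r1, d12_on_r2, d12_off_r1, d12_off_r2``) and the tuple of truly
    depleted shRNA ids. Depleted shRNAs have their day-12 on-dox mean
    reduced by ``2**depletion_log2``; counts are NB with the configured
    dispersion (variance = mu + dispersion * mu^2) and per-column
    size-factor batch effects. Deterministic for a fixed seed.
    """
    config = config or CohortConfig()
    sm = config.screen_model
    if sm.dispersion <= 0:
        raise ValueError("screen dispersion must be positive")
    rng = _rngs(config.seed, ["screen"])["screen"]

    # gene assignment: named special genes keep their published shRNA
    # counts; the rest of the library is spread evenly
    genes: list[str] = []
    for gene, k in sm.special_gene_shrnas.items():
        genes.extend([gene] * k)
    n_special_genes = len(sm.special_gene_shrnas)
    n_rest = sm.n_shrnas - len(genes)
    rest_gene_names = [
        name for name in sm.depleted_genes if name not in sm.special_gene_shrnas
    ]
    n_filler = sm.n_genes - n_special_genes - len(rest_gene_names)
    rest_gene_names += [f"G{i + 1:04d}" for i in range(max(n_filler, 0))]
    for i in range(n_rest):
        genes.append(rest_gene_names[i % len(rest_gene_names)])
    genes = genes[: sm.n_shrnas]
    shrna_ids = [f"sh{i + 1:05d}_{g}" for i, g in enumerate(genes)]
    depleted_set = set(sm.depleted_genes)
    depleted_mask = np.array([g in depleted_set for g in genes])

    mu0 = rng.lognormal(sm.abundance_log_mean, sm.abundance_log_sd, size=sm.n_shrnas)
    col_factors = {
        col: rng.lognormal(0.0, sm.column_factor_log_sd)
        for col in ["d0_r1", "d0_r2", "d12_on_r1", "d12_on_r2", "d12_off_r1", "d12_off_r2"]
    }

    def nb(mean):
        r = 1.0 / sm.dispersion
        p = r / (r + mean)
        return rng.negative_binomial(r, p)

    data = {"shrna_id": shrna_ids, "gene": genes}
    on_mu = mu0 * np.where(depleted_mask, 2.0**sm.depletion_log2, 1.0)
    means = {
        "d0_r1": mu0, "d0_r2": mu0,
        "d12_on_r1": on_mu, "d12_on_r2": on_mu,
        "d12_off_r1": mu0, "d12_off_r2": mu0,
    }
    for col, mu in means.items():
        data[col] = nb(mu * col_factors[col]).astype(np.int64)
    matrix = pd.DataFrame(data)
    depleted_ids = tuple(np.array(shrna_ids)[depleted_mask])
    return matrix, depleted_ids
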