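"""End-to-end orchestration of the cohort analysis.

``run_pipeline`` executes: simulate (optional) -> variant filtering ->
SCNA recurrence -> clonality -> subgroup association -> survival ->
screen scoring, writing every intermediate table as TSV plus a
machine-readable ``summary.json`` (cohort mutation frequencies, peak
coordinates, q-values, Kaplan-Meier curve points) and a run log recording
the seed and package version.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__, association, clonality, io, scna, screen, survival, variants
from .synthetic import CohortConfig, generate_cohort, generate_screen_counts

log = logging.getLogger("pblgenomics")


@dataclass
class PipelineConfig:
    """Run configuration; unknown keys in a YAML config are rejected."""

    out_dir: str = "pbl_run"
    seed: int = 0
    n_tumors: int = 85
    n_normals: int = 38
    covered_mb: float = 50.0
    filter: variants.FilterConfig = field(default_factory=variants.FilterConfig)
    extension: scna.ExtensionParams = field(default_factory=scna.ExtensionParams)
    clonality_threshold: float = clonality.CLONALITY_THRESHOLD
    screen_min_sum: int = 50
    screen_pseudocount: float = 0.5
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "filter" in raw:
            raw["filter"] = variants.FilterConfig(**raw["filter"])
        if "extension" in raw:
            raw["extension"] = scna.ExtensionParams(**raw["extension"])
        return cls(**raw)


def _json_default(o: Any):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on a freshly simulated cohort; returns the summary."""
    os.makedirs(config.out_dir, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    summary: dict[str, Any] = {"seed": config.seed, "version": __version__}

    current = {"stage": "init"}

    def stage(name):
        current["stage"] = name
        log.info("stage: %s", name)

    try:
        stage("simulate")
        cohort_cfg = CohortConfig(
            n_tumors=config.n_tumors, n_normals=config.n_normals, seed=config.seed
        )
        cohort = generate_cohort(cohort_cfg)
        io.write_tsv(cohort.tumor_calls, f"{config.out_dir}/variants_raw.tsv")
        io.write_tsv(cohort.segments, f"{config.out_dir}/segments.tsv")
        io.write_tsv(cohort.purity_ploidy, f"{config.out_dir}/purity_ploidy.tsv")
        io.write_tsv(cohort.clinical, f"{config.out_dir}/clinical.tsv")

        stage("filter")
        pon = variants.build_pon(cohort.normal_calls, config.filter.pon_min_subjects)
        result = variants.apply_filter_hierarchy(cohort.tumor_calls, pon, config.filter)
        io.write_tsv(result.survivors, f"{config.out_dir}/variants_somatic.tsv")
        io.write_tsv(result.attrition, f"{config.out_dir}/filter_attrition.tsv")
        per_sample = result.survivors.groupby("sample_id").size()
        per_sample = per_sample.reindex(
            cohort.purity_ploidy["sample_id"], fill_value=0
        )
        burden = variants.tmb(per_sample, config.covered_mb)
        summary["filter"] = {
            "n_input": result.n_input,
            "n_somatic": len(result.survivors),
            "attrition": dict(zip(result.attrition["step"], result.attrition["removed"])),
            "mean_tmb_per_mb": float(burden.mean()) if len(burden) else None,
        }
        gene_calls = result.survivors[result.survivors["gene"] != ""]
        freq = (
            gene_calls.groupby("gene")["sample_id"].nunique()
            / max(config.n_tumors, 1)
        )
        summary["mutation_frequencies"] = freq.sort_values(ascending=False).to_dict()

        stage("scna")
        peaks = []
        for arm in sorted(cohort.config.arms):
            grid = cohort.probe_grid(arm)
            events = []
            for sid, g in cohort.segments.groupby("sample_id"):
                pl = cohort.purity_ploidy.set_index("sample_id")["ploidy"][sid]
                events.extend(
                    scna.classify_events(
                        g[g["chrom"] == arm], pl, {arm: (1, cohort.config.arms[arm])}
                    )
                )
            for kind in (scna.AMP, scna.DEL):
                pileup = scna.build_pileup(events, grid, kind)
                for cand in scna.find_mcr(pileup)[:3]:
                    region = scna.extend_peak(pileup, cand, config.extension)
                    if region.n_peak > 0:
                        peaks.append(region)
        report = scna.peak_report(peaks, None, config.n_tumors)
        io.write_tsv(report, f"{config.out_dir}/scna_peaks.tsv")
        io.write_peaks_bed(report, f"{config.out_dir}/scna_peaks.bed")
        summary["scna_peaks"] = report.drop(columns=["genes"]).to_dict("records")

        stage("clonality")
        ccf = clonality.annotate_ccf(
            result.survivors[result.survivors["gene"] != ""],
            cohort.segments,
            cohort.purity_ploidy,
            threshold=config.clonality_threshold,
        )
        gene_clonality = clonality.summarize_gene_clonality(ccf)
        io.write_tsv(ccf, f"{config.out_dir}/ccf.tsv")
        io.write_tsv(gene_clonality, f"{config.out_dir}/gene_clonality.tsv")
        summary["clonality"] = gene_clonality.set_index("gene")[
            "clonal_percentage"
        ].to_dict()

        stage("associate")
        lesion_matrix = (
            gene_calls.assign(present=1.0)
            .pivot_table(index="sample_id", columns="gene", values="present", fill_value=0.0)
            .reindex(cohort.clinical["sample_id"], fill_value=0.0)
        )
        clin_idx = cohort.clinical.set_index("sample_id")
        lss_class = pd.Series(np.nan, index=clin_idx.index, dtype=object)
        dead = clin_idx["lss_event"] == 1
        lss_class[dead & (clin_idx["lss_months"] < 12)] = "short"
        lss_class[clin_idx["lss_months"] > 24] = "long"
        clin_idx = clin_idx.assign(lss_class=lss_class)
        assoc = association.run_subcohort_screen(lesion_matrix, clin_idx)
        io.write_tsv(assoc, f"{config.out_dir}/associations.tsv")
        summary["associations_significant"] = assoc[assoc["significant"]][
            ["comparison", "lesion", "p_one_tailed", "q_bh"]
        ].to_dict("records")

        stage("survive")
        clin = cohort.clinical
        km = survival.km_estimate(clin["os_months"], clin["os_event"])
        io.write_tsv(km.as_frame(), f"{config.out_dir}/km_os_all.tsv")
        conditions = ["ipi_high", "ebv_positive", "hiv_positive", "myc_translocated"]
        lesion_cols = {}
        for gene_name in ("NRAS", "KRAS", "STAT3", "TP53"):
            if gene_name in lesion_matrix:
                col = f"mut_{gene_name}"
                lesion_cols[col] = lesion_matrix[gene_name]
        surv_records = clin.set_index("sample_id").assign(**lesion_cols).reset_index()
        screen_results = survival.run_survival_screen(
            surv_records,
            conditions + list(lesion_cols),
            endpoint="lss",
            treatment_filter="chop_like",
        )
        io.write_tsv(screen_results, f"{config.out_dir}/survival_screen.tsv")
        summary["survival"] = {
            "os_2yr": km.survival_at(24.0),
            "screen": screen_results[["condition", "p", "q_bh"]].to_dict("records"),
        }

        stage("screen")
        counts, depleted = generate_screen_counts(cohort_cfg)
        io.write_tsv(counts, f"{config.out_dir}/screen_counts.tsv")
        scores, genes, n_removed = screen.run_screen(
            counts, min_sum=config.screen_min_sum, pseudocount=config.screen_pseudocount
        )
        io.write_tsv(scores, f"{config.out_dir}/screen_scores.tsv")
        io.write_tsv(genes, f"{config.out_dir}/screen_genes.tsv")
        summary["screen"] = {
            "n_low_coverage_removed": n_removed,
            "top_genes": genes.head(10)["gene"].tolist(),
        }
    except Exception as exc:  # abort with stage provenance
        raise RuntimeError(
            f"pipeline failed at stage {current['stage']!r}: {exc}"
        ) from exc

    with open(f"{config.out_dir}/summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_json_default)
    with open(f"{config.out_dir}/run.log", "w") as fh:
        fh.write(f"pblgenomics {__version__}\nseed {config.seed}\n")
    return summary
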