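"""End-to-end orchestration and group-level reporting.

``run_pipeline`` executes the full screening chain on either a synthetic
scenario or user-supplied CSV tables:

    constrain to core analytes → ∑TQ → ∑EAR → ∑EAR-MED →
    PERMANOVA group comparison → group distribution summaries →
    driver attribution

All result tables are returned in memory and, when ``outdir`` is given,
written as CSV alongside a JSON run manifest recording seeds, sizes and
the conventions in effect (quantiles: linear interpolation; exceedance:
strict >).  Stages degrade gracefully: without an ACC table the EAR and
EAR-MED stages are skipped and recorded as uncovered rather than
failing the TQ screen.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .benchmarks import (SubstitutionRules, benchmark_coverage, compute_tq,
                         individual_exceedance_table, resolve_benchmarks,
                         summarize_sample_tq)
from .bioactivity import (acc_in_ugL, compute_ear, ear_coverage,
                          filter_endpoints, summarize_sample_ear)
from .datamodel import (AnalyteCatalog, Dataset, constrain_to_core,
                        read_acc, read_benchmarks, read_detections,
                        read_tk_params, write_table)
from .permanova import permanova_metric
from .synthetic import ScenarioConfig, generate_dataset, paper_like_scenario
from .toxicokinetics import (Physiology, VariabilitySpec, build_aed_floors,
                             summarize_sample_ear_med)

logger = logging.getLogger("dwscreen")

DEFAULT_THRESHOLDS = {
    "sum_tq": (0.1, 1.0),
    "sum_ear": (0.001, 1.0),
    "sum_ear_med": (0.001, 1.0),
}


@dataclass
class PipelineConfig:
    """Inputs for one pipeline run: either a scenario or file paths."""

    scenario: ScenarioConfig | None = None
    detections_path: str | None = None
    catalog_path: str | None = None
    benchmarks_path: str | None = None
    acc_path: str | None = None
    tk_path: str | None = None
    substitution_rules: SubstitutionRules = field(default_factory=SubstitutionRules)
    ear_aggregation: str = "max_endpoint"
    physiology: Physiology = field(default_factory=Physiology)
    variability: VariabilitySpec = field(default_factory=VariabilitySpec)
    n_permutations: int = 9999
    seed: int = 0
    outdir: str | None = None


@dataclass
class PipelineResult:
    dataset: Dataset
    tq_per_detection: pd.DataFrame
    tq_per_sample: pd.DataFrame
    tq_contributions: pd.DataFrame
    individual_exceedances: pd.DataFrame
    tq_coverage: pd.DataFrame
    ear_per_endpoint: pd.DataFrame | None
    ear_per_sample: pd.DataFrame | None
    ear_contributions: pd.DataFrame | None
    ear_med_per_sample: pd.DataFrame | None
    ear_med_contributions: pd.DataFrame | None
    aed_floors: pd.DataFrame | None
    permanova_results: pd.DataFrame
    group_summaries: pd.DataFrame
    driver_reports: pd.DataFrame
    manifest: dict


def summarize_groups(
    summaries: pd.DataFrame,
    metric: str,
    thresholds: tuple[float, ...],
    group_col: str = "supply_class",
) -> pd.DataFrame:
    """Per-group distribution summary of one per-sample metric.

    Quantiles (5th, 25th, 50th, 75th, 95th) use linear interpolation;
    ``fraction_exceeding`` per threshold uses strict >.  Empty groups
    are omitted with a warning.
    """
    rows = []
    for grp, sub in summaries.groupby(group_col, sort=True):
        vals = sub[metric].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            logger.warning("group %s has no values for %s; omitted", grp, metric)
            continue
        p5, q25, med, q75, p95 = np.percentile(vals, [5, 25, 50, 75, 95])
        row = {"supply_class": grp, "metric": metric, "n": vals.size,
               "p5": p5, "q25": q25, "median": med, "q75": q75, "p95": p95}
        for t in thresholds:
            row[f"fraction_exceeding_{t:g}"] = float(np.mean(vals > t))
        rows.append(row)
    return pd.DataFrame(rows)


def driver_report(
    contributions: pd.DataFrame,
    samples: pd.DataFrame,
    metric_name: str,
    top_k: int = 10,
) -> pd.DataFrame:
    """Rank analytes by how often they dominate a sample's cumulative quotient.

    Returns per (supply_class, analyte): number of samples in which the
    analyte was the largest contributor and its mean contribution
    fraction; the top ``top_k`` per supply by top-driver count.
    """
    if contributions.empty:
        return pd.DataFrame(columns=["supply_class", "analyte_id", "metric",
                                     "n_samples_as_top_driver", "mean_contribution"])
    c = contributions.merge(samples[["sample_id", "supply_class"]], on="sample_id")
    tops = c.loc[c["rank"] == 1].groupby(
        ["supply_class", "analyte_id"]).size().rename("n_samples_as_top_driver")
    means = c.groupby(["supply_class", "analyte_id"])["contribution_fraction"] \
        .mean().rename("mean_contribution")
    out = pd.concat([tops, means], axis=1).fillna({"n_samples_as_top_driver": 0}).reset_index()
    out["n_samples_as_top_driver"] = out["n_samples_as_top_driver"].astype(int)
    out["metric"] = metric_name
    out = out.sort_values(["supply_class", "n_samples_as_top_driver", "mean_contribution"],
                          ascending=[True, False, False], kind="mergesort")
    out = out.groupby("supply_class", group_keys=False).head(top_k)
    cols = ["supply_class", "analyte_id", "metric", "n_samples_as_top_driver", "mean_contribution"]
    return out[cols].reset_index(drop=True)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full screening pipeline; see the module docstring."""
    manifest: dict = {
        "dwscreen_version": __version__,
        "seed": config.seed,
        "ear_aggregation": config.ear_aggregation,
        "n_permutations": config.n_permutations,
        "quantile_convention": "linear interpolation between order statistics",
        "exceedance_convention": "strict greater-than",
        "stages": {},
    }

    # ingest / simulate
    try:
        if config.scenario is not None:
            scenario = config.scenario
            ds, benchmarks, acc, tk, ground_truth = generate_dataset(scenario)
            manifest["input"] = {"kind": "scenario", "scenario_seed": scenario.seed}
            rules = scenario.substitution_rules
        else:
            catalog = AnalyteCatalog.from_csv(config.catalog_path)
            ds = read_detections(config.detections_path, catalog)
            benchmarks = read_benchmarks(config.benchmarks_path) \
                if config.benchmarks_path else pd.DataFrame(
                    columns=["analyte_id", "benchmark_type", "value"])
            acc = read_acc(config.acc_path) if config.acc_path else None
            tk = read_tk_params(config.tk_path) if config.tk_path else None
            ground_truth = None
            rules = config.substitution_rules
            manifest["input"] = {"kind": "files", "detections": config.detections_path}
    except Exception as e:  # noqa: BLE001 - stage-named abort contract
        raise StageError("ingest", e) from e

    ds = constrain_to_core(ds)
    manifest["n_samples"] = int(ds.n_samples)
    manifest["n_detections"] = int(ds.detections["detected"].sum())
    manifest["group_sizes"] = ds.samples["supply_class"].value_counts().to_dict()

    # ∑TQ screen
    try:
        resolved = resolve_benchmarks(benchmarks, rules, ds.catalog.table) \
            if len(benchmarks) else pd.DataFrame(
                columns=["analyte_id", "effective_value", "source_type", "substitution_applied"])
        tq = compute_tq(ds.detections, resolved)
        tq_sum, tq_contrib = summarize_sample_tq(tq, ds.samples)
        exceed = individual_exceedance_table(ds, benchmarks) if len(benchmarks) else \
            pd.DataFrame(columns=["sample_id", "analyte_id", "concentration",
                                  "benchmark_type", "value", "exceeds"])
        tq_cov = benchmark_coverage(ds, resolved)
        manifest["stages"]["tq"] = "ok"
    except Exception as e:  # noqa: BLE001
        raise StageError("tq", e) from e

    # ∑EAR screen (optional coverage)
    ear_ep = ear_sum = ear_contrib = None
    acc_kept = None
    if acc is not None and len(acc):
        try:
            acc_kept, removals = filter_endpoints(acc)
            acc_kept = acc_in_ugL(acc_kept, ds.catalog.table)
            ear_ep = compute_ear(ds.detections, acc_kept)
            ear_sum, ear_contrib = summarize_sample_ear(
                ear_ep, ds.samples, aggregation=config.ear_aggregation)
            manifest["stages"]["ear"] = "ok"
            manifest["ear_endpoint_removals"] = {k: int(v) for k, v in removals.items()}
        except Exception as e:  # noqa: BLE001
            raise StageError("ear", e) from e
    else:
        manifest["stages"]["ear"] = "skipped: no ACC table (no bioactivity coverage)"

    # ∑EAR-MED screen (optional coverage)
    earmed_sum = earmed_contrib = floors = None
    if acc_kept is not None and tk is not None and len(tk):
        try:
            var = VariabilitySpec(
                cv_intrinsic_clearance=config.variability.cv_intrinsic_clearance,
                cv_fraction_unbound=config.variability.cv_fraction_unbound,
                cv_liver_blood_flow=config.variability.cv_liver_blood_flow,
                cv_glomerular_filtration_rate=config.variability.cv_glomerular_filtration_rate,
                n_draws=config.variability.n_draws,
                seed=config.seed,
                truncation=config.variability.truncation)
            floors, aed_ep, tk_cov = build_aed_floors(
                acc_kept, tk, config.physiology, var, ds.catalog.table)
            earmed_sum, earmed_contrib = summarize_sample_ear_med(
                ds.detections, floors, ds.samples)
            manifest["stages"]["ear_med"] = "ok"
        except Exception as e:  # noqa: BLE001
            raise StageError("ear_med", e) from e
    else:
        manifest["stages"]["ear_med"] = "skipped: no ACC or TK coverage"

    # PERMANOVA per metric
    try:
        perm_rows = []
        metric_tables = {"sum_tq": tq_sum, "sum_ear": ear_sum, "sum_ear_med": earmed_sum}
        for metric, table in metric_tables.items():
            if table is None or table[metric].sum() == 0:
                continue
            if table["supply_class"].nunique() < 2:
                continue
            res = permanova_metric(table, metric, n_permutations=config.n_permutations,
                                   seed=config.seed)
            perm_rows.append({
                "metric": metric, "f_stat": res.f_stat, "p_value": res.p_value,
                "n_permutations": res.n_permutations,
                "ss_total": res.ss_total, "ss_among": res.ss_among,
                "ss_within": res.ss_within, "seed": config.seed})
        permanova_results = pd.DataFrame(perm_rows)
        manifest["stages"]["permanova"] = "ok"
    except Exception as e:  # noqa: BLE001
        raise StageError("permanova", e) from e

    # group summaries and driver attribution
    group_parts, driver_parts = [], []
    for metric, table, contrib in (
            ("sum_tq", tq_sum, tq_contrib),
            ("sum_ear", ear_sum, ear_contrib),
            ("sum_ear_med", earmed_sum, earmed_contrib)):
        if table is None:
            continue
        group_parts.append(summarize_groups(table, metric, DEFAULT_THRESHOLDS[metric]))
        if contrib is not None:
            driver_parts.append(driver_report(contrib, ds.samples, metric))
    group_summaries = pd.concat(group_parts, ignore_index=True) if group_parts else pd.DataFrame()
    driver_reports = pd.concat(driver_parts, ignore_index=True) if driver_parts else pd.DataFrame()

    result = PipelineResult(
        dataset=ds, tq_per_detection=tq, tq_per_sample=tq_sum,
        tq_contributions=tq_contrib, individual_exceedances=exceed,
        tq_coverage=tq_cov, ear_per_endpoint=ear_ep, ear_per_sample=ear_sum,
        ear_contributions=ear_contrib, ear_med_per_sample=earmed_sum,
        ear_med_contributions=earmed_contrib, aed_floors=floors,
        permanova_results=permanova_results, group_summaries=group_summaries,
        driver_reports=driver_reports, manifest=manifest)

    if config.outdir:
        _write_outputs(result, Path(config.outdir))
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    tables = {
        "tq_per_detection.csv": result.tq_per_detection,
        "tq_per_sample.csv": result.tq_per_sample,
        "tq_contributions.csv": result.tq_contributions,
        "individual_exceedances.csv": result.individual_exceedances,
        "coverage.csv": result.tq_coverage,
        "ear_per_endpoint.csv": result.ear_per_endpoint,
        "ear_per_sample.csv": result.ear_per_sample,
        "ear_contributions.csv": result.ear_contributions,
        "ear_med_per_sample.csv": result.ear_med_per_sample,
        "ear_med_contributions.csv": result.ear_med_contributions,
        "aed_floors.csv": result.aed_floors,
        "permanova.csv": result.permanova_results,
        "group_summaries.csv": result.group_summaries,
        "driver_report.csv": result.driver_reports,
    }
    written = []
    for name, table in tables.items():
        if table is None:
            continue
        write_table(table, outdir / name)
        written.append(name)
    result.manifest["outputs"] = written
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True, default=str)


def run_default(seed: int = 0, outdir: str | None = None, **kwargs) -> PipelineResult:
    """Run the packaged three-supply scenario end to end."""
    cfg = PipelineConfig(scenario=paper_like_scenario(seed=seed), seed=seed,
                         outdir=outdir, **kwargs)
    return run_pipeline(cfg)
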