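"""End-to-end orchestration: simulate → quantify → analyze.

Each stage reads and writes plain files under the run directory, logs
its parameters and row counts, and is recorded in a JSON run manifest
carrying the resolved-config hash and seed, so a run is reproducible
from the manifest alone. A failing stage leaves the completed stages'
outputs in place plus an error manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortConfig, emit_cohort_csv, read_cohort_csv, simulate_cohort
from .config import PipelineConfig, dump_config, load_config
from .coverage import aggregate_case, quantify_image, summarize_qc
from .errors import CaseExcludedError
from .io import (
    list_image_files,
    read_image_stack,
    write_ground_truth_csv,
    write_image_stack,
    write_results_csv,
)
from .simulate import simulate_case
from .stats import group_contrast, results_to_frame, stratified_correlations, spearman
from .types import RunManifest

logger = logging.getLogger(__name__)

_MARKERS = ["iba1", "cd68", "tmem119"]


def _now() -> str:
    return datetime.now(timezone.utc).isoformat(timespec="seconds")


def stage_simulate_images(config: PipelineConfig, out_dir: str) -> list[str]:
    """Render the synthetic MS-like and control-like case image sets."""
    images_dir = os.path.join(out_dir, "images")
    os.makedirs(images_dir, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    truths = []
    paths = []
    layout = (
        [(f"ms_{i:02d}", config.ms_coverage, config.ms_soma_area_um2)
         for i in range(config.n_ms_cases)]
        + [(f"ctrl_{i:02d}", config.control_coverage, config.control_soma_area_um2)
           for i in range(config.n_control_cases)]
    )
    for case_id, cov, area in layout:
        case_seed = int(rng.integers(2**31))
        for stack, truth in simulate_case(
            case_id, config.neurons_per_case, cov, area,
            config.simulation.pixel_size_um, case_seed, config.simulation,
        ):
            path = os.path.join(images_dir, f"{stack.image_id}.tif")
            write_image_stack(stack, path)
            truths.append((stack.image_id, truth))
            paths.append(path)
    write_ground_truth_csv(truths, os.path.join(images_dir, "ground_truth.csv"))
    logger.info("simulate-images: %d cases, %d images", len(layout), len(paths))
    return paths


def stage_quantify(config: PipelineConfig, images_dir: str, out_dir: str) -> dict[str, str]:
    """Quantify every image: per-neuron CSV, per-case CSV, QC report."""
    os.makedirs(out_dir, exist_ok=True)
    results = []
    for path in list_image_files(images_dir):
        stack = read_image_stack(path)
        results.append(quantify_image(stack, config))
    if not results:
        raise FileNotFoundError(f"no TIFF images under {images_dir!r}")
    neurons_csv = os.path.join(out_dir, "per_neuron.csv")
    write_results_csv(results, neurons_csv)

    case_rows = []
    for case_id in sorted({r.case_id for r in results}):
        try:
            mean_cov, mean_size, n_pass = aggregate_case(results, case_id)
        except CaseExcludedError:
            logger.warning("case %s excluded: no QC-passing neurons", case_id)
            continue
        case_rows.append({
            "case_id": case_id,
            "group": "MS" if case_id.startswith("ms") else "control",
            "mean_coverage": mean_cov,
            "mean_neuron_size": mean_size,
            "n_pass": n_pass,
        })
    cases_csv = os.path.join(out_dir, "per_case.csv")
    pd.DataFrame(case_rows).to_csv(cases_csv, index=False)

    report = summarize_qc(results)
    qc_csv = os.path.join(out_dir, "qc_report.csv")
    pd.DataFrame([{
        "n_photographed": report.n_photographed,
        "n_deleted": report.n_deleted,
        "n_retained": report.n_retained,
        "percent_deleted": report.percent_deleted,
        **{f"deleted_{k}": v for k, v in report.deleted_by_reason.items()},
    }]).to_csv(qc_csv, index=False)
    logger.info("quantify: %d neurons, %d cases, %.0f%% deleted",
                len(results), len(case_rows), report.percent_deleted)
    return {"per_neuron": neurons_csv, "per_case": cases_csv, "qc_report": qc_csv}


def stage_simulate_cohort(config: PipelineConfig, out_dir: str) -> str:
    os.makedirs(out_dir, exist_ok=True)
    cohort_csv = os.path.join(out_dir, "cohort.csv")
    records = simulate_cohort(CohortConfig(seed=config.seed))
    emit_cohort_csv(records, cohort_csv)
    logger.info("simulate-cohort: %d cases", len(records))
    return cohort_csv


def stage_analyze(config: PipelineConfig, out_dir: str,
                  per_case_csv: str | None = None,
                  cohort_csv: str | None = None) -> dict[str, str]:
    """Cohort statistics: correlations, stratified correlations, contrasts."""
    os.makedirs(out_dir, exist_ok=True)
    results = []
    lines = ["synapcover analysis report", "=" * 30]

    if cohort_csv and os.path.exists(cohort_csv):
        cohort = read_cohort_csv(cohort_csv)
        ms = cohort[cohort.group == "MS"]
        lines.append(f"\ncohort: {len(cohort)} cases ({len(ms)} MS)")
        for marker in _MARKERS:
            r = spearman(ms[marker], ms["neuron_density"],
                         outcome="neuron_density", predictor=marker, stratum="MS")
            results.append(r)
            lines.append(f"  all-MS {marker} vs neuron density: "
                         f"r = {r.estimate:.3f}, p = {r.p_value:.4f} (n = {r.n})")
        strat = stratified_correlations(ms, _MARKERS, "neuron_density", "genotype")
        results.extend(strat)
        for r in strat:
            lines.append(f"  {r.stratum} {r.predictor}: r = {r.estimate:.3f}, "
                         f"p = {r.p_value:.4f} (n = {r.n})")
        gc = group_contrast(cohort, "mean_coverage", "control", "MS",
                            covariates=["age_death", "sex", "pm_interval"])
        results.append(gc)
        lines.append(f"  coverage contrast (cohort table): "
                     f"{gc.percent_difference:.1f}% lower in MS, p = {gc.adjusted_p:.4f}")

    if per_case_csv and os.path.exists(per_case_csv):
        cases = pd.read_csv(per_case_csv)
        if {"MS", "control"} <= set(cases.group):
            for outcome, label in (("mean_coverage", "coverage"),
                                   ("mean_neuron_size", "neuron size")):
                gc = group_contrast(cases, outcome, "control", "MS")
                results.append(gc)
                lines.append(
                    f"  image-pipeline {label}: control "
                    f"{gc.mean_a:.3f} ± {gc.sem_a:.3f} vs MS {gc.mean_b:.3f} ± "
                    f"{gc.sem_b:.3f} → {gc.percent_difference:.1f}% reduction, "
                    f"p = {gc.adjusted_p:.4f}"
                )

    results_csv = os.path.join(out_dir, "stat_results.csv")
    results_to_frame(results).to_csv(results_csv, index=False)
    report_txt = os.path.join(out_dir, "report.txt")
    with open(report_txt, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    logger.info("analyze: %d results", len(results))
    return {"stat_results": results_csv, "report": report_txt}


def run_pipeline(config_path: str, out_dir: str) -> RunManifest:
    """Execute all stages in order and write a run manifest.

    On stage failure, completed outputs are kept and an error manifest
    (``manifest.error.json``) records the failure before the exception
    propagates.
    """
    config = load_config(config_path)
    os.makedirs(out_dir, exist_ok=True)
    started = _now()
    stages_done: list[str] = []
    outputs: list[str] = []
    resolved = os.path.join(out_dir, "resolved_config.yaml")
    dump_config(config, resolved)
    outputs.append(resolved)
    try:
        paths = stage_simulate_images(config, out_dir)
        outputs.extend(paths)
        stages_done.append("simulate-images")

        quant = stage_quantify(config, os.path.join(out_dir, "images"), out_dir)
        outputs.extend(quant.values())
        stages_done.append("quantify")

        cohort_csv = stage_simulate_cohort(config, out_dir)
        outputs.append(cohort_csv)
        stages_done.append("simulate-cohort")

        ana = stage_analyze(config, out_dir, quant["per_case"], cohort_csv)
        outputs.extend(ana.values())
        stages_done.append("analyze")
    except Exception as err:
        manifest = RunManifest(
            config_hash=config.config_hash(), seed=config.seed,
            tool_version=__version__, input_paths=[config_path],
            output_paths=outputs, started=started, finished=_now(),
            stages=stages_done + [f"FAILED: {err}"],
        )
        with open(os.path.join(out_dir, "manifest.error.json"), "w") as fh:
            json.dump(dataclasses.asdict(manifest), fh, indent=2)
        raise
    manifest = RunManifest(
        config_hash=config.config_hash(), seed=config.seed,
        tool_version=__version__, input_paths=[config_path],
        output_paths=outputs, started=started, finished=_now(),
        stages=stages_done,
    )
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(dataclasses.asdict(manifest), fh, indent=2)
    return manifest
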