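"""End-to-end driver: calibrate -> classify -> summarize (+ qPCR, RNA-seq).

Produces a machine-readable JSON report (version, seed, thresholds, all
summaries) and per-stage CSV outputs under the configured output
directory.  The pipeline is a pure function of (inputs, config, seed):
re-running with the same inputs yields byte-identical summaries.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as tio
from .calibration import calibrate_traces
from .cohort import pool_cohort, summarize_experiments
from .qpcr import expression_matrix, percent_of_trpm7, relative_expression
from .responders import classify_cells
from .rnaseq import row_centered_log2, rpkm

log = logging.getLogger("trpquant")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                log.info("stage %s: start", name)
                out = fn(*args, **kwargs)
                log.info("stage %s: done", name)
                return out
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


@_stage("calcium")
def _run_calcium(config: tio.PipelineConfig, out: Path) -> dict:
    traces = tio.read_traces(config.traces_path)
    background = tio.read_background(config.background_path)
    windows = tio.read_windows(config.windows_path)
    calcium = calibrate_traces(traces, background, config.calibration)
    tio.write_calcium(calcium, out / "calcium.csv")
    if calcium.empty:
        return {"n_cells": 0, "note": "no cells in input", "cohorts": []}
    calls = classify_cells(calcium, windows, config.thresholds)
    tio.write_calls(calls, out / "responder_calls.csv")
    summaries = summarize_experiments(calls)
    summaries.to_csv(out / "experiment_summaries.csv", index=False)
    cohorts = [
        pool_cohort(summaries, agonist).as_dict()
        for agonist in sorted(summaries["agonist_name"].unique())
    ]
    return {
        "n_cells": int(calls.groupby(["experiment_id", "cell_id"]).ngroups),
        "cohorts": cohorts,
    }


@_stage("qpcr")
def _run_qpcr(config: tio.PipelineConfig, out: Path) -> dict:
    ct = tio.read_ct_table(config.ct_path)
    results = relative_expression(ct, config.housekeeping)
    results = percent_of_trpm7(results, config.reference_gene)
    results.to_csv(out / "qpcr_results.csv", index=False)
    tio.write_matrix(expression_matrix(results), out / "qpcr_percent_matrix.tsv")
    return {
        "n_samples": int(results["sample_id"].nunique()),
        "n_genes": int(results["gene"].nunique()),
        "reference_delta_ct": results.attrs["reference_delta_ct"],
        "categories": results.groupby("category", sort=True)["gene"].count().to_dict(),
    }


@_stage("rnaseq")
def _run_rnaseq(config: tio.PipelineConfig, out: Path) -> dict:
    cm = tio.read_count_matrix(config.counts_path, config.lengths_path)
    mat = rpkm(cm)
    heat = row_centered_log2(mat)
    tio.write_matrix(mat, out / "rpkm.tsv")
    tio.write_matrix(heat, out / "heatmap_log2_rpkm.tsv")
    return {"n_genes": int(mat.shape[0]), "n_samples": int(mat.shape[1])}


def run_pipeline(config: tio.PipelineConfig) -> dict:
    """Run every stage whose inputs are configured; return the JSON report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "calibration": vars(config.calibration).copy(),
        "thresholds": vars(config.thresholds).copy(),
        "stages": {},
    }
    if config.traces_path:
        report["stages"]["calcium"] = _run_calcium(config, out)
    if config.ct_path:
        report["stages"]["qpcr"] = _run_qpcr(config, out)
    if config.counts_path:
        report["stages"]["rnaseq"] = _run_rnaseq(config, out)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
    log.info("report written to %s", out / "report.json")
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    raise TypeError(f"not JSON serializable: {type(obj)}")
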