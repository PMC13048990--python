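"""End-to-end pipeline: stack (or scenario) in, tables out.

Stages are pure functions of (inputs, config); a fixed seed makes a scenario
run byte-reproducible.  Each run writes its resolved configuration next to
the outputs so results are traceable.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort_stats, depth_qc, preprocess, quantify, stack_io, synthetic_stack
from .config import PipelineConfig

log = logging.getLogger("coccosims")


class PipelineError(Exception):
    pass


def _load_calibration(config: PipelineConfig) -> quantify.CalibrationRelation:
    if config.calibration is None:
        return quantify.default_calibration()
    return quantify.CalibrationRelation.from_json(config.calibration)


def qc_table(
    stack: stack_io.IonImageStack,
    roi_map: stack_io.RoiMap,
    config: PipelineConfig,
) -> pd.DataFrame:
    """One row per (coccolith ROI, element): CVs, selected window, flags."""
    rows = []
    for label in roi_map.labels_of_class("coccolith"):
        for element in stack.elements:
            profile = depth_qc.build_profile(
                stack, roi_map, label, element,
                block_size_planes=config.block_size_planes,
                gate_min_ca=config.gate_min_ca,
            )
            window, qc = depth_qc.select_stable_window(
                profile, cv_target=config.cv_target, min_fraction=config.min_fraction
            )
            rows.append({
                "roi_label": label,
                "element": element,
                "n_blocks": profile.n_blocks,
                "cv_obs": qc.cv_obs,
                "cv_poisson": qc.cv_poisson,
                "cv_corrected": qc.cv_corrected,
                "window_first_block": window[0],
                "window_last_block": window[1],
                "flags": ";".join(sorted(qc.flags)),
            })
    return pd.DataFrame(rows)


def run_pipeline(
    config: PipelineConfig,
    source: str | Path,
    out_dir: str | Path,
    roi_in: str | Path | None = None,
) -> Path:
    """Run generate/read -> align -> segment -> qc -> quantify -> stats.

    ``source`` is either a stack directory or a scenario name from the
    synthetic registry.  Outputs under ``out_dir``: ``stack/`` (scenario runs
    only), ``roi.tif``/``roi.json``, ``qc.csv``, ``liths.csv``,
    ``summary.csv`` (when >= 2 samples are present), ``config.yaml``.
    Returns the path to ``liths.csv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # resolve calibration early: a bad path must fail before any output
    calibration = _load_calibration(config)

    source = str(source)
    if source in synthetic_stack.SCENARIOS:
        truth = synthetic_stack.default_scenario(source, seed=config.seed)
        log.info("generating scenario %r (seed %d)", source, config.seed)
        stack = synthetic_stack.generate_stack(truth)
        stack_io.write_stack(stack, out_dir / "stack")
    elif Path(source).is_dir():
        stack = stack_io.read_stack(source)
    else:
        raise PipelineError(f"{source!r} is neither a stack directory nor a known scenario")

    stack, trace = preprocess.align_stack(
        stack, max_shift_px=config.align_max_shift_px,
        block_size_planes=config.align_block_planes,
    )
    log.info("aligned %d planes; crop %s", stack.planes, trace.crop)
    accumulated = preprocess.accumulate(stack)

    if roi_in is not None:
        roi_map = stack_io.read_roi_map(roi_in)
        log.info("using externally supplied ROI map %s", roi_in)
    else:
        roi_map = preprocess.segment(
            accumulated,
            ca_quantile=config.ca_quantile,
            enrichment_factor=config.enrichment_factor,
            min_area_px=config.min_area_px,
        )
    if roi_map.warning:
        log.warning("segmentation: %s", roi_map.warning)
    for cls in stack_io.ROI_CLASSES:
        labels = roi_map.labels_of_class(cls)
        areas = [int(roi_map.mask(l).sum()) for l in labels]
        log.info("%d %s ROI(s), areas %s", len(labels), cls, areas)
    stack_io.write_roi_map(roi_map, out_dir / "roi.tif")

    qc = qc_table(stack, roi_map, config)
    qc.to_csv(out_dir / "qc.csv", index=False)

    results = quantify.quantify_all(
        stack, roi_map, calibration,
        block_size_planes=config.block_size_planes,
        gate_min_ca=config.gate_min_ca,
        cv_target=config.cv_target,
        min_fraction=config.min_fraction,
        delta=config.delta,
    )
    liths_path = out_dir / "liths.csv"
    stack_io.write_results(results, liths_path)
    log.info("quantified %d coccolith(s) -> %s", len(results), liths_path)

    frame = stack_io.results_to_frame(results)
    if not frame.empty and frame["sample_id"].nunique() >= 2:
        summary = cohort_stats.summarize_samples(
            frame, list(stack.elements), alpha=config.alpha
        )
        summary.to_csv(out_dir / "summary.csv", index=False)

    config.to_yaml(out_dir / "config.yaml")
    return liths_path


def stats_outputs(
    liths: pd.DataFrame,
    covariates: pd.DataFrame | None,
    elements: list[str],
    out_dir: str | Path,
    alpha: float = 0.05,
) -> None:
    """Cohort statistics for a combined per-coccolith table.

    Writes ``summary.csv`` (per-sample mean +/- SE with Tukey letters),
    ``cv_decomposition.csv`` (within- vs among-lith CVs) and, when a
    covariate table is given, ``correlations.csv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary = cohort_stats.summarize_samples(liths, elements, alpha=alpha)
    summary.to_csv(out_dir / "summary.csv", index=False)

    rows = []
    for group in sorted(liths["sample_id"].unique()):
        for element in elements:
            if cohort_stats.ratio_column(element) not in liths.columns:
                continue
            try:
                dec = cohort_stats.cv_decomposition(liths, element, group)
            except cohort_stats.CohortStatsError:
                continue
            within = np.asarray(dec["within_lith_cvs"], dtype=float)
            rows.append({
                "sample_id": group,
                "element": element,
                "n": dec["n"],
                "among_lith_cv": dec["among_lith_cv"],
                "among_exceeds_one": dec["among_exceeds_one"],
                "within_lith_cv_median": float(np.median(within)) if within.size else np.nan,
                "within_lith_cv_max": float(within.max()) if within.size else np.nan,
            })
    pd.DataFrame(rows).to_csv(out_dir / "cv_decomposition.csv", index=False)

    if covariates is not None:
        corr = cohort_stats.correlation_matrix(liths, elements, covariates, alpha=alpha)
        corr.to_csv(out_dir / "correlations.csv", index=False)
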