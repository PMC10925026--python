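"""End-to-end analysis: quantify -> classify -> map stresses -> fit -> report.

``run_pipeline`` reads a section manifest and a loading table, runs the
fluorescence quantification on every sample, classifies samples through the
localization test and the count baseline, converts indenter loads to
internal compressive stress, fits the two Boltzmann threshold curves, and
writes tables, models, a run manifest and a Markdown report.  Stages are
deterministic given the configured seed.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .config import PipelineConfig
from .damage_classification import (
    SampleResult,
    StudyDataset,
    assemble_fit_points,
    classify_dataset,
    localization_statistic,
    MIN_POSITIVES_FOR_TEST,
)
from .image_quantification import (
    SectionImage,
    control_intensity_threshold,
    preprocess,
    quantify_sample,
    restrict_to_indented_area,
    score_dye_positive,
    segment_fibers,
    tissue_mask,
)
from .report import plot_thresholds, render_report
from .stress_mapping import annotate_loading_table, calibrate_internal_map, loading_conditions
from .threshold_model import (
    REFERENCE_IN_VIVO_CELL_DEATH,
    REFERENCE_IN_VIVO_NO_DAMAGE,
    FitConstraints,
    ThresholdModel,
    fit_threshold,
    save_models,
)

log = logging.getLogger("myodti")


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage and offending sample."""

    def __init__(self, stage: str, sample_id: str, message: str):
        super().__init__(f"[{stage}] sample {sample_id!r}: {message}")
        self.stage = stage
        self.sample_id = sample_id


def read_section_tiff(path: str | Path, sample_id: str = "", section_id: str = "",
                      channel_order: tuple[str, str] = ("auto", "dye")) -> SectionImage:
    """Read a two-channel TIFF (axis 0 = channels) into a :class:`SectionImage`."""
    arr = tifffile.imread(path)
    if arr.ndim != 3 or arr.shape[0] != 2:
        raise ValueError(f"{path}: expected a 2-channel image, got shape {arr.shape}")
    channels = dict(zip(channel_order, np.asarray(arr, dtype=float)))
    return SectionImage(
        auto_channel=channels["auto"], dye_channel=channels["dye"],
        sample_id=sample_id, section_id=section_id,
    )


@dataclass
class RunArtifacts:
    """Everything a pipeline run produced."""

    dataset: StudyDataset
    models: dict[str, ThresholdModel]
    baseline: float
    section_table: pd.DataFrame
    sample_table: pd.DataFrame
    report_path: Path | None = None


def _quantify_manifest(manifest: pd.DataFrame, cfg: PipelineConfig):
    """Per-sample quantification: counts, centroids and localization inputs."""
    pre = cfg.preprocessing
    seg = cfg.segmentation
    rng = np.random.default_rng(cfg.seed)

    # control threshold per sample, falling back to the pooled study controls
    controls: dict[str, tuple[list, list]] = {}
    for _, row in manifest[manifest["role"] == "control"].iterrows():
        img = read_section_tiff(row["path"], row["sample_id"], row["section_id"])
        dye = preprocess(img.dye_channel, pre.background_radius, pre.quantize_8bit)
        auto = preprocess(img.auto_channel, pre.background_radius, pre.quantize_8bit)
        controls.setdefault(str(row["sample_id"]), ([], []))
        controls[str(row["sample_id"])][0].append(dye)
        controls[str(row["sample_id"])][1].append(tissue_mask(auto))
    if not controls:
        raise ValueError("manifest contains no control sections")
    pooled_dyes = [d for dyes, _ in controls.values() for d in dyes]
    pooled_masks = [m for _, masks in controls.values() for m in masks]
    global_threshold = control_intensity_threshold(pooled_dyes, pooled_masks)

    section_rows = []
    patterns: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    counts: dict[str, list[float]] = {}
    indented = manifest[manifest["role"] == "indented"]
    for sample_id, group in indented.groupby("sample_id", sort=False):
        sample_id = str(sample_id)
        if sample_id in controls:
            threshold = control_intensity_threshold(*controls[sample_id])
        else:
            threshold = global_threshold
        patterns[sample_id] = []
        counts[sample_id] = []
        for _, row in group.iterrows():
            try:
                img = read_section_tiff(row["path"], sample_id, row["section_id"])
                auto = preprocess(img.auto_channel, pre.background_radius, pre.quantize_8bit)
                dye = preprocess(img.dye_channel, pre.background_radius, pre.quantize_8bit)
                labels = segment_fibers(auto, seg.min_area, seg.peak_min_distance,
                                        seg.smoothing_sigma)
                if cfg.indent_radius is not None and row.get("indent_center_x") not in ("", None):
                    center = (float(row["indent_center_y"]), float(row["indent_center_x"]))
                    labels = restrict_to_indented_area(labels, center, cfg.indent_radius)
                q = score_dye_positive(labels, dye, threshold, row["section_id"])
            except FileNotFoundError as e:
                raise PipelineError("quantify", sample_id, str(e)) from e
            except ValueError as e:
                raise PipelineError("quantify", sample_id, str(e)) from e
            patterns[sample_id].append((labels.centroids, q.positive_centroids))
            counts[sample_id].append(float(q.n_positive))
            section_rows.append(dict(
                sample_id=sample_id, section_id=row["section_id"],
                n_fibers=q.n_fibers, n_positive=q.n_positive,
                threshold=q.threshold_used,
            ))
            log.info("quantified %s/%s: %d positive of %d fibers",
                     sample_id, row["section_id"], q.n_positive, q.n_fibers)
    return section_rows, patterns, counts


def _localize(patterns, counts, cfg: PipelineConfig) -> dict[str, list[float]]:
    """Two-stage localization p-values (screen all, refine each sample's best)."""
    loc = cfg.localization
    rng = np.random.default_rng(cfg.seed + 1)
    pvals: dict[str, list[float]] = {}
    for sample_id, sections in patterns.items():
        ps = []
        for centroids, positive_centroids in sections:
            _, p = localization_statistic(
                positive_centroids, centroids, n_null=loc.n_null,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            ps.append(p)
        best = int(np.argmin(ps))
        cent, pos = sections[best]
        if len(pos) >= MIN_POSITIVES_FOR_TEST:
            _, ps[best] = localization_statistic(
                pos, cent, n_null=loc.n_null_refine,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        pvals[sample_id] = ps
    return pvals


def run_pipeline(cfg: PipelineConfig) -> RunArtifacts:
    """Execute the full analysis described by ``cfg``; returns the artifacts."""
    outdir = Path(cfg.paths.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(cfg.paths.manifest)
    for col in ("sample_id", "section_id", "path", "role"):
        if col not in manifest.columns:
            raise ValueError(f"manifest missing required column {col!r}")
    missing = [p for p in manifest["path"] if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"manifest references missing file(s): {missing[:3]}")

    log.info("stage 1/5: quantify (%d sections)", len(manifest))
    section_rows, patterns, counts = _quantify_manifest(manifest, cfg)

    log.info("stage 2/5: localization test")
    pvals = _localize(patterns, counts, cfg)

    log.info("stage 3/5: stress mapping")
    calib = calibrate_internal_map(cfg.calibration_pairs)
    loading = annotate_loading_table(pd.read_csv(cfg.paths.loading_table), calib)
    conditions = loading_conditions(loading)

    samples = []
    for sample_id, section_counts in counts.items():
        if len(section_counts) != cfg.expected_sections:
            log.warning("sample %s has %d sections (expected %d)",
                        sample_id, len(section_counts), cfg.expected_sections)
        if sample_id not in conditions:
            raise PipelineError("stress_mapping", sample_id, "no loading-table row")
        samples.append(SampleResult(
            sample_id=sample_id, loading=conditions[sample_id],
            section_counts=section_counts, section_p_values=pvals[sample_id],
        ))
    dataset = StudyDataset(samples=samples, calibration=calib)

    log.info("stage 4/5: classification")
    classify_dataset(dataset, cfg.localization.alpha_loc, cfg.localization.correction)
    for exc in cfg.exclusions:
        for s in dataset.samples:
            if s.sample_id == exc.sample_id:
                s.excluded = True
                s.exclusion_reason = exc.reason or "excluded by configuration"
    death_pts, intact_pts = assemble_fit_points(
        dataset, [e.sample_id for e in cfg.exclusions]
    )

    log.info("stage 5/5: threshold fits (%d cell-death, %d no-damage points)",
             len(death_pts), len(intact_pts))
    t_all = [p[0] for p in death_pts + intact_pts]
    t_range = (min(t_all), max(t_all))
    models: dict[str, ThresholdModel] = {}
    for category, pts, c_bounds in (
        ("cell_death", death_pts, cfg.fit.cell_death_c_bounds),
        ("no_damage", intact_pts, cfg.fit.no_damage_c_bounds),
    ):
        constraints = FitConstraints.for_category(category, t_range)
        constraints = FitConstraints(
            bounds={**constraints.bounds, "C": tuple(c_bounds)}, fixed={}
        )
        models[category] = fit_threshold(
            pts, constraints, category=category, starts=cfg.fit.starts, seed=cfg.seed + 2
        )

    section_table = pd.DataFrame(section_rows)
    sample_table = pd.DataFrame([
        dict(sample_id=s.sample_id, mean_count=s.mean_count,
             n_sections=len(s.section_counts), localized=s.localized,
             label=s.label, excluded=s.excluded,
             duration_min=s.loading.t, sigma_ext_kpa=s.loading.sigma_ext,
             sigma_int_kpa=s.loading.sigma_int)
        for s in dataset.samples
    ])

    # artifacts
    section_table.to_csv(outdir / "section_counts.csv", index=False)
    sample_table.to_csv(outdir / "sample_summary.csv", index=False)
    save_models(models, outdir / "threshold_models.json")
    references = {
        "cell_death": REFERENCE_IN_VIVO_CELL_DEATH,
        "no_damage": REFERENCE_IN_VIVO_NO_DAMAGE,
    }
    report = render_report(dataset, models, references)
    report_path = outdir / "report.md"
    report_path.write_text(report)
    plot_thresholds(dataset, models, outdir / "thresholds.png")
    run_manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "myodti_version": __version__,
        "python": platform.python_version(),
        "n_samples": len(dataset.samples),
        "baseline": dataset.baseline,
    }
    (outdir / "run_manifest.json").write_text(json.dumps(run_manifest, indent=2))

    return RunArtifacts(
        dataset=dataset, models=models, baseline=dataset.baseline,
        section_table=section_table, sample_table=sample_table,
        report_path=report_path,
    )
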