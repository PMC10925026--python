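"""Ground-truthed synthetic inputs for every pipeline stage.

Two levels of simulation:

* **Scene level** — rendered two-channel cross-section images.  Fibers are
  cells of a jittered hexagonal tessellation (the polygonal packing of a
  real muscle cross-section) inside a roughly circular tissue region,
  separated by thin interstitial gaps.  Viable fibers carry lognormal green
  autofluorescence and a faint dye baseline; dead fibers get a strong dye
  gain; the interstitial network autofluoresces weakly and retains staining
  residue.  Dead fibers are planted either scattered (uniform over fibers)
  or localized (probability proportional to a Gaussian kernel around the
  indentation site).  Additive and signal-dependent Gaussian noise is
  applied last.  Everything is deterministic given the seed.

* **Study level** — a full stress-time loading study: a grid of
  (duration, internal stress) conditions labelled by ground-truth Boltzmann
  threshold curves, per-section dye-positive counts from an overdispersed
  (gamma-Poisson) count model, and per-section centroid point patterns
  (localized for damaged samples, scattered otherwise) feeding the
  localization test — with or without full image rendering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from skimage.segmentation import find_boundaries

from .damage_classification import SampleResult, StudyDataset
from .image_quantification import SectionImage
from .stress_mapping import LoadingCondition, default_calibration
from .threshold_model import (
    CELL_DEATH_THRESHOLD,
    NO_DAMAGE_THRESHOLD,
    ThresholdModel,
    evaluate_threshold,
)

__all__ = [
    "RenderParams",
    "SyntheticScene",
    "StudyDesign",
    "SyntheticStudy",
    "generate_fiber_centroids",
    "generate_scene",
    "generate_control_sections",
    "generate_study",
    "generate_fit_points",
    "DEFAULT_CONDITIONS",
]


@dataclass(frozen=True)
class RenderParams:
    """Intensity model for the two channels (arbitrary units in [0, ~1]).

    Autofluorescence: per-fiber lognormal around ``auto_fiber_median``;
    interstitium at a dimmer constant level (collagen autofluorescence).
    Dye: faint per-fiber viable baseline, staining residue in the
    interstitium, and a strong per-fiber gain on dead fibers.  Noise is
    additive Gaussian plus a signal-dependent (shot-noise-like) term.
    """

    auto_fiber_median: float = 0.6
    auto_fiber_sigma: float = 0.2  # lognormal sigma (log-space)
    auto_interstitial: float = 0.2
    dye_viable_median: float = 0.04
    dye_viable_sigma: float = 0.15
    dye_interstitial: float = 0.3
    dye_dead_level: float = 0.55
    dye_dead_sigma: float = 0.1
    noise_sd: float = 0.01
    shot_noise_coeff: float = 0.05


@dataclass(frozen=True)
class SyntheticScene:
    """Ground truth for one rendered section."""

    fiber_labels: np.ndarray  # tessellation cells, 0 = background/interstitium
    fiber_centroids: np.ndarray  # (n, 2) row/col
    dead_fiber_ids: np.ndarray  # indices into fibers (0-based)
    pattern: str  # localized | scattered | none
    indent_center: tuple[float, float] | None
    kernel_width: float | None
    render_params: RenderParams
    seed: int | None

    @property
    def n_fibers(self) -> int:
        return len(self.fiber_centroids)


def generate_fiber_centroids(
    n_fibers: int,
    image_shape: tuple[int, int],
    rng: np.random.Generator,
    tissue_radius_frac: float = 0.47,
) -> tuple[np.ndarray, float]:
    """Jittered hexagonal lattice of fiber centers inside a circular section.

    Returns ``(centroids, spacing)``; exactly ``n_fibers`` centers, those
    closest to the image center, giving a roughly circular tissue region.
    """
    if n_fibers < 1:
        raise ValueError("n_fibers must be >= 1")
    h, w = image_shape
    radius = tissue_radius_frac * min(h, w)
    # hex lattice density is one point per (sqrt(3)/2) s^2
    spacing = math.sqrt(2.0 * math.pi * radius**2 / (math.sqrt(3) * n_fibers))
    rows = np.arange(0, h + spacing, spacing * math.sqrt(3) / 2)
    pts = []
    for i, r in enumerate(rows):
        offset = 0.0 if i % 2 == 0 else spacing / 2
        cols = np.arange(offset, w + spacing, spacing)
        pts.append(np.column_stack([np.full_like(cols, r), cols]))
    pts = np.vstack(pts)
    pts = pts + rng.uniform(-0.22 * spacing, 0.22 * spacing, size=pts.shape)
    center = np.array([h / 2, w / 2])
    order = np.argsort(np.linalg.norm(pts - center, axis=1))
    if len(pts) < n_fibers:  # pragma: no cover - spacing formula guarantees enough
        raise RuntimeError("lattice produced too few candidate centers")
    return pts[order[:n_fibers]], spacing


def _sample_dead(
    centroids: np.ndarray,
    k: int,
    pattern: str,
    indent_center: tuple[float, float] | None,
    kernel_width: float,
    rng: np.random.Generator,
) -> np.ndarray:
    n = len(centroids)
    k = min(k, n)
    if k == 0:
        return np.empty(0, dtype=int)
    if pattern == "scattered":
        return rng.choice(n, size=k, replace=False)
    if pattern == "localized":
        if indent_center is None:
            raise ValueError("localized pattern requires indent_center")
        d2 = np.sum((centroids - np.asarray(indent_center)) ** 2, axis=1)
        w = np.exp(-d2 / (2.0 * kernel_width**2))
        w = np.maximum(w, 1e-300)
        return rng.choice(n, size=k, replace=False, p=w / w.sum())
    raise ValueError(f"unknown pattern {pattern!r}")


def generate_scene(
    n_fibers: int = 800,
    image_shape: tuple[int, int] = (512, 512),
    pattern: str = "scattered",
    dead_fraction: float = 0.0,
    dead_count: int | None = None,
    indent_center: tuple[float, float] | None = None,
    kernel_width: float | None = None,
    render_params: RenderParams | None = None,
    extra_gap: int = 0,
    seed: int | None = 0,
) -> tuple[SyntheticScene, SectionImage]:
    """Render one two-channel synthetic cross-section with known ground truth.

    Exactly ``round(dead_fraction * n_fibers)`` dead fibers are planted
    (``dead_count``, when given, overrides the fraction).
    ``pattern="localized"`` concentrates them around ``indent_center``
    (default: image center) with a Gaussian kernel of ``kernel_width``
    pixels (default: 10 % of the image side).  ``extra_gap`` erodes every
    fiber by that many extra pixels, widening the interstitial gaps from the
    default densely-packed geometry towards well-separated fibers.
    """
    if not 0.0 <= dead_fraction <= 1.0:
        raise ValueError("dead_fraction must lie in [0, 1]")
    params = render_params or RenderParams()
    rng = np.random.default_rng(seed)
    h, w = image_shape

    centroids, spacing = generate_fiber_centroids(n_fibers, image_shape, rng)
    tree = cKDTree(centroids)
    rr, cc = np.mgrid[0:h, 0:w]
    dist, nearest = tree.query(np.column_stack([rr.ravel(), cc.ravel()]))
    labels = (nearest + 1).reshape(h, w)
    labels[dist.reshape(h, w) > 0.75 * spacing] = 0  # outside tissue
    interstitium = find_boundaries(labels, mode="thick") & (labels > 0)
    labels[interstitium] = 0
    if extra_gap > 0:
        from scipy import ndimage as ndi

        shrunk = ndi.binary_erosion(labels > 0, iterations=extra_gap)
        interstitium |= (labels > 0) & ~shrunk
        labels[~shrunk] = 0

    k = round(dead_fraction * n_fibers) if dead_count is None else min(dead_count, n_fibers)
    if pattern == "localized" and indent_center is None:
        indent_center = (h / 2.0, w / 2.0)
    if kernel_width is None:
        kernel_width = 0.1 * min(h, w)
    if k == 0:
        dead = np.empty(0, dtype=int)
        pattern_out = "none" if pattern == "none" or k == 0 else pattern
    else:
        dead = _sample_dead(centroids, k, pattern, indent_center, kernel_width, rng)
        pattern_out = pattern

    # per-fiber intensities (index 0 unused; labels are 1-based)
    auto_levels = np.zeros(n_fibers + 1)
    auto_levels[1:] = params.auto_fiber_median * np.exp(
        rng.normal(0.0, params.auto_fiber_sigma, n_fibers)
    )
    dye_levels = np.zeros(n_fibers + 1)
    dye_levels[1:] = params.dye_viable_median * np.exp(
        rng.normal(0.0, params.dye_viable_sigma, n_fibers)
    )
    dye_levels[dead + 1] = params.dye_dead_level * np.exp(
        rng.normal(0.0, params.dye_dead_sigma, len(dead))
    )

    auto = auto_levels[labels]
    auto[interstitium] = params.auto_interstitial
    dye = dye_levels[labels]
    dye[interstitium] = params.dye_interstitial

    def add_noise(img: np.ndarray) -> np.ndarray:
        noisy = (
            img
            + rng.normal(0.0, params.noise_sd, img.shape)
            + rng.normal(0.0, 1.0, img.shape) * params.shot_noise_coeff * np.sqrt(img)
        )
        return np.clip(noisy, 0.0, None)

    scene = SyntheticScene(
        fiber_labels=labels,
        fiber_centroids=centroids,
        dead_fiber_ids=np.sort(dead),
        pattern=pattern_out,
        indent_center=indent_center,
        kernel_width=kernel_width,
        render_params=params,
        seed=seed,
    )
    image = SectionImage(auto_channel=add_noise(auto), dye_channel=add_noise(dye))
    return scene, image


def generate_control_sections(
    n_sections: int = 6,
    n_fibers: int = 800,
    image_shape: tuple[int, int] = (512, 512),
    render_params: RenderParams | None = None,
    seed: int | None = 0,
) -> list[SectionImage]:
    """Unloaded control sections: identical render model, zero dead fibers."""
    if n_sections < 1:
        raise ValueError("n_sections must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_sections):
        _, img = generate_scene(
            n_fibers=n_fibers,
            image_shape=image_shape,
            pattern="none",
            dead_fraction=0.0,
            render_params=render_params,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        out.append(
            SectionImage(
                auto_channel=img.auto_channel,
                dye_channel=img.dye_channel,
                section_id=f"control_{i}",
            )
        )
    return out


#: Default loading grid: four durations, three internal stress levels each,
#: anchored at the protocol's printed stresses (3.4, 21.1, 22.5, 69 kPa) with
#: mid levels interpolated into the uncertainty band of the truth curves.
DEFAULT_CONDITIONS: tuple[tuple[float, float], ...] = (
    (30.0, 3.4), (30.0, 18.0), (30.0, 69.0),
    (60.0, 3.4), (60.0, 19.0), (60.0, 69.0),
    (90.0, 3.4), (90.0, 12.0), (90.0, 21.1),
    (120.0, 3.4), (120.0, 5.0), (120.0, 22.5),
)


@dataclass(frozen=True)
class StudyDesign:
    """Design of a synthetic stress-time loading study.

    ``conditions`` are (duration min, internal stress kPa) pairs, one sample
    each; defaults span 30-120 min and 3.4-69 kPa.  Truth curves default to
    the fitted ex vivo thresholds; the count model is gamma-Poisson
    (negative binomial) with damaged means well above undamaged ones,
    emulating — not reproducing — the observed 53-254 count range.
    """

    conditions: tuple[tuple[float, float], ...] = DEFAULT_CONDITIONS
    sections_per_sample: int = 6
    truth_death: ThresholdModel = CELL_DEATH_THRESHOLD
    truth_no_damage: ThresholdModel = NO_DAMAGE_THRESHOLD
    count_mean_damaged: float = 170.0
    count_mean_undamaged: float = 70.0
    count_dispersion: float = 30.0
    n_fibers: int = 800
    image_shape: tuple[int, int] = (512, 512)
    kernel_width: float | None = None

    def __post_init__(self) -> None:
        if len(self.conditions) == 0:
            raise ValueError("study design needs at least one condition")
        for t, s in self.conditions:
            if t <= 0 or s < 0:
                raise ValueError(f"invalid condition (t={t}, sigma={s})")


@dataclass
class SyntheticStudy:
    """A generated study: unclassified dataset + ground truth + point patterns."""

    dataset: StudyDataset
    truth_labels: dict[str, str]
    #: per sample: list of (all_centroids, positive_indices) per section
    section_patterns: dict[str, list[tuple[np.ndarray, np.ndarray]]]


def _truth_label(
    t: float,
    sigma: float,
    death: ThresholdModel,
    no_damage: ThresholdModel,
    rng: np.random.Generator,
) -> str:
    hi = evaluate_threshold(death, t)
    lo = evaluate_threshold(no_damage, t)
    if sigma >= hi:
        return "cell_death"
    if sigma <= lo:
        return "no_damage"
    # uncertainty band between the curves: stochastic fate, interpolated
    p_death = (sigma - lo) / (hi - lo)
    return "cell_death" if rng.random() < p_death else "no_damage"


def _nb_counts(mean: float, dispersion: float, size: int, rng: np.random.Generator) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def generate_study(design: StudyDesign | None = None, seed: int | None = 0) -> SyntheticStudy:
    """Generate a full labelled stress-time study at centroid level.

    Each condition becomes one sample with ground-truth label from the truth
    curves (stochastic inside the uncertainty band), per-section
    dye-positive counts from the negative-binomial count model, and
    per-section fiber point patterns: localized around the section center
    for damaged samples, scattered for undamaged ones.
    """
    design = design or StudyDesign()
    rng = np.random.default_rng(seed)
    h, w = design.image_shape
    kernel = design.kernel_width if design.kernel_width is not None else 0.1 * min(h, w)
    calib = default_calibration()
    # invert the internal map to recover the external stress coordinate
    samples: list[SampleResult] = []
    truth: dict[str, str] = {}
    patterns: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    for t, sigma_int in design.conditions:
        sample_id = f"t{t:g}_s{sigma_int:g}"
        label = _truth_label(t, sigma_int, design.truth_death, design.truth_no_damage, rng)
        truth[sample_id] = label
        mean = design.count_mean_damaged if label == "cell_death" else design.count_mean_undamaged
        counts = _nb_counts(mean, design.count_dispersion, design.sections_per_sample, rng)
        sections = []
        for c in counts:
            centroids, _ = generate_fiber_centroids(design.n_fibers, design.image_shape, rng)
            pos = _sample_dead(
                centroids,
                int(c),
                "localized" if label == "cell_death" else "scattered",
                (h / 2.0, w / 2.0),
                kernel,
                rng,
            )
            sections.append((centroids, np.sort(pos)))
        sigma_ext = (sigma_int + calib.c0) / (1.0 - calib.c1)
        samples.append(
            SampleResult(
                sample_id=sample_id,
                loading=LoadingCondition(t=t, sigma_ext=max(sigma_ext, sigma_int), sigma_int=sigma_int),
                section_counts=[float(len(p[1])) for p in sections],
            )
        )
        patterns[sample_id] = sections
    dataset = StudyDataset(samples=samples, calibration=calib)
    return SyntheticStudy(dataset=dataset, truth_labels=truth, section_patterns=patterns)


def attach_localization_pvalues(
    study: SyntheticStudy,
    n_null_screen: int = 199,
    n_null_refine: int = 2999,
    seed: int | None = 0,
) -> SyntheticStudy:
    """Score every section's point pattern with the localization test.

    Fills ``section_p_values`` on each sample of ``study.dataset`` (two-stage
    screening/refinement; see
    :func:`myodti.damage_classification.score_study_sections`) so the
    dataset can be classified.
    """
    from .damage_classification import score_study_sections

    pvals = score_study_sections(
        study.section_patterns, n_null_screen, n_null_refine, seed
    )
    for s in study.dataset.samples:
        s.section_p_values = pvals[s.sample_id]
    return study


def simulate_study_to_dir(
    outdir,
    design: StudyDesign | None = None,
    controls_per_sample: int = 2,
    seed: int | None = 0,
):
    """Write a rendered synthetic study to disk in the pipeline's input format.

    Produces per-section two-channel TIFFs (axis 0 = auto, dye), a manifest
    CSV (``sample_id, section_id, path, role, indent_center_x/y``), a loading
    CSV (``sample_id, force_N, radius_mm, duration_min``) and a ground-truth
    JSON with the planted dead counts and labels.  Returns the output paths.
    """
    import json
    from pathlib import Path

    import pandas as pd
    import tifffile

    design = design or StudyDesign()
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    study = generate_study(design, seed=int(rng.integers(0, 2**31 - 1)))
    h, w = design.image_shape
    calib = study.dataset.calibration
    radius_m = 0.001  # 1 mm indenter on the loading rig

    manifest_rows, loading_rows = [], []
    truth: dict = {"labels": study.truth_labels, "sections": {}}
    for sample in study.dataset.samples:
        sid = sample.sample_id
        label = study.truth_labels[sid]
        pattern = "localized" if label == "cell_death" else "scattered"
        for i, count in enumerate(sample.section_counts):
            scene, img = generate_scene(
                n_fibers=design.n_fibers,
                image_shape=design.image_shape,
                pattern=pattern,
                dead_count=int(count),
                kernel_width=design.kernel_width,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            path = outdir / "images" / f"{sid}_sec{i}.tif"
            tifffile.imwrite(
                path, np.stack([img.auto_channel, img.dye_channel]).astype(np.float32)
            )
            manifest_rows.append(
                dict(sample_id=sid, section_id=f"{sid}_sec{i}", path=str(path),
                     role="indented", indent_center_x=w / 2, indent_center_y=h / 2)
            )
            truth["sections"][f"{sid}_sec{i}"] = {
                "dead_count": int(len(scene.dead_fiber_ids)),
                "pattern": scene.pattern,
            }
        for i in range(controls_per_sample):
            _, img = generate_scene(
                n_fibers=design.n_fibers,
                image_shape=design.image_shape,
                pattern="none",
                dead_fraction=0.0,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            path = outdir / "images" / f"{sid}_ctrl{i}.tif"
            tifffile.imwrite(
                path, np.stack([img.auto_channel, img.dye_channel]).astype(np.float32)
            )
            manifest_rows.append(
                dict(sample_id=sid, section_id=f"{sid}_ctrl{i}", path=str(path),
                     role="control", indent_center_x="", indent_center_y="")
            )
        sigma_ext_kpa = sample.loading.sigma_ext
        force_n = sigma_ext_kpa * 1000.0 * math.pi * radius_m**2
        loading_rows.append(
            dict(sample_id=sid, force_N=force_n, radius_mm=radius_m * 1000.0,
                 duration_min=sample.loading.t)
        )

    manifest_path = outdir / "manifest.csv"
    loading_path = outdir / "loading.csv"
    truth_path = outdir / "ground_truth.json"
    pd.DataFrame(manifest_rows).to_csv(manifest_path, index=False)
    pd.DataFrame(loading_rows).to_csv(loading_path, index=False)
    truth_path.write_text(json.dumps(truth, indent=2))
    return {"manifest": manifest_path, "loading": loading_path, "truth": truth_path}


def generate_fit_points(
    truth: ThresholdModel,
    t_grid: Sequence[float],
    noise_sd: float = 0.3,
    replicates: int = 1,
    seed: int | None = 0,
) -> np.ndarray:
    """Stress-time points on a truth curve plus Gaussian stress noise.

    Returns an ``(len(t_grid) * replicates, 2)`` array of (t, sigma).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.repeat(np.asarray(t_grid, dtype=float), replicates)
    sigma = evaluate_threshold(truth, t) + rng.normal(0.0, noise_sd, size=t.shape)
    return np.column_stack([t, sigma])
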