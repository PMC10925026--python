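"""Markdown report and stress-time figure for a classified study."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .damage_classification import StudyDataset
from .threshold_model import PARAM_NAMES, ThresholdModel, compare_thresholds, evaluate_threshold


def render_report(
    dataset: StudyDataset,
    models: dict[str, ThresholdModel],
    references: dict[str, ThresholdModel] | None = None,
) -> str:
    """Markdown summary: baseline, per-sample table, threshold parameters.

    With ``references`` supplied, the parameter table gains delta columns
    (reference minus fitted — positive deltas mean the fitted curve sits
    lower than the reference).
    """
    if not dataset.samples:
        raise ValueError("empty dataset")
    if not models:
        raise ValueError("no fitted models")
    lines = ["# Stress-time cell-death threshold report", ""]
    lines.append(f"Samples: {len(dataset.samples)}  ")
    lines.append(f"Count baseline (lowest localized sample mean): "
                 f"{dataset.baseline:.1f}" if dataset.baseline is not None else "Baseline: n/a")
    excluded = [s for s in dataset.samples if s.excluded]
    if excluded:
        lines.append("")
        lines.append("Excluded samples: " + ", ".join(
            f"{s.sample_id} ({s.exclusion_reason})" for s in excluded))

    lines += ["", "## Samples", "",
              "| sample | t (min) | sigma_int (kPa) | mean count | localized | label |",
              "|---|---|---|---|---|---|"]
    for s in dataset.samples:
        lines.append(
            f"| {s.sample_id} | {s.loading.t:g} | {s.loading.sigma_int:.1f} "
            f"| {s.mean_count:.1f} | {'yes' if s.localized else 'no'} "
            f"| {s.label}{' (excluded)' if s.excluded else ''} |"
        )

    lines += ["", "## Threshold parameters", ""]
    header = "| category | K (kPa) | alpha (1/min) | t0 (min) | C (kPa) | SSE (kPa^2) |"
    sep = "|---|---|---|---|---|---|"
    if references:
        header += " dK | dalpha | dt0 | dC |"
        sep += "---|---|---|---|"
    lines += [header, sep]
    for category, m in models.items():
        row = (f"| {category} | {m.K:.1f} | {m.alpha:.2f} | {m.t0:.1f} | {m.C:.1f} "
               f"| {m.sse:.2f} |" if m.sse is not None else
               f"| {category} | {m.K:.1f} | {m.alpha:.2f} | {m.t0:.1f} | {m.C:.1f} | n/a |")
        if references and category in references:
            deltas = compare_thresholds(models[category], references[category])["b_minus_a"]
            row += "".join(f" {deltas[n]:.1f} |" for n in PARAM_NAMES)
        lines.append(row)
    if references:
        lines += ["", "Deltas are reference minus fitted; a positive dK/dC means "
                      "this study's curve sits below the reference curve."]
    return "\n".join(lines) + "\n"


def plot_thresholds(
    dataset: StudyDataset,
    models: dict[str, ThresholdModel],
    path: str | Path,
) -> Path:
    """Stress-time scatter with the fitted threshold curves."""
    fig, ax = plt.subplots(figsize=(6, 4))
    markers = {"cell_death": ("^", "tab:red"), "no_damage": ("o", "tab:blue")}
    for s in dataset.samples:
        mk, color = markers.get(s.label, ("s", "gray"))
        ax.scatter(s.loading.t, s.loading.sigma_int, marker=mk, c=color,
                   edgecolors="k" if s.excluded else "none",
                   s=60 if s.excluded else 40, zorder=3)
    t = np.linspace(20, 130, 200)
    styles = {"cell_death": ("-", "tab:red"), "no_damage": ("--", "tab:blue")}
    for category, m in models.items():
        ls, color = styles.get(category, ("-", "k"))
        ax.plot(t, evaluate_threshold(m, t), ls, color=color, label=category)
    ax.set_xlabel("loading duration (min)")
    ax.set_ylabel("internal compressive stress (kPa)")
    ax.legend()
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
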