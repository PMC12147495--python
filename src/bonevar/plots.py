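"""Diagnostic figures for a fitted variability ensemble.

Three views: the mean-vs-mean scatter with dispersion rectangles (square
rectangles on the diagonal = good mean and variability prediction), the
per-material paired strip plot of measured vs estimated values, and the
per-material D_JS bar chart.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Rectangle

__all__ = ["mean_scatter_with_rectangles", "paired_strip_plot", "d_js_bar_chart", "save_all_figures"]


def _require(results):
    if not results.evaluation.per_material:
        raise ValueError("empty report: nothing to plot")


def mean_scatter_with_rectangles(results, ax=None, spread_multiplier: float = 2.0):
    """Measured vs predicted means with per-material dispersion rectangles."""
    _require(results)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    rects = results.rectangles(spread_multiplier)
    for _, r in rects.iterrows():
        ax.add_patch(
            Rectangle(
                (r.mean_x - r.width / 2, r.mean_y - r.height / 2),
                r.width,
                r.height,
                fill=False,
                edgecolor="tab:blue",
                linewidth=0.8,
                alpha=0.7,
            )
        )
    ax.scatter(rects.mean_x, rects.mean_y, s=14, color="black", zorder=3)
    lo = min(rects.mean_x.min() - rects.width.max(), rects.mean_y.min() - rects.height.max())
    hi = max(rects.mean_x.max() + rects.width.max(), rects.mean_y.max() + rects.height.max())
    ax.plot([lo, hi], [lo, hi], "k--", linewidth=0.8)
    ax.set_xlabel("measured bone formation rate, mean (%)")
    ax.set_ylabel("predicted bone formation rate, mean (%)")
    ax.set_title(f"Combo {results.evaluation.combo_label}: means and dispersion")
    return ax


def paired_strip_plot(results, ax=None):
    """Measured (black) and estimated (blue) values side by side per material."""
    _require(results)
    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, 0.25 * len(results.evaluation.per_material)), 4))
    dataset = results.model.dataset
    est = results.prediction.estimates
    for i, s in enumerate(dataset.samples):
        ax.scatter(np.full(len(s.measurements), i - 0.15), s.measurements,
                   s=10, color="black", alpha=0.8)
        ax.scatter(np.full(len(est[s.material_id]), i + 0.15), est[s.material_id],
                   s=4, color="tab:blue", alpha=0.3)
    ax.set_xticks(range(len(dataset.samples)))
    ax.set_xticklabels(dataset.material_ids, rotation=90, fontsize=6)
    ax.set_ylabel("bone formation rate (%)")
    ax.set_title("measured (black) vs estimated (blue) values")
    return ax


def d_js_bar_chart(results, ax=None):
    """Per-material Jensen-Shannon divergence bars."""
    _require(results)
    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, 0.2 * len(results.evaluation.per_material)), 3.5))
    d = results.d_js
    ax.bar(range(len(d)), d.values, color="tab:blue")
    ax.set_xticks(range(len(d)))
    ax.set_xticklabels(d.index, rotation=90, fontsize=6)
    ax.set_ylabel("D_JS")
    ax.axhline(np.log(2), color="gray", linewidth=0.8, linestyle=":")
    ax.set_title(f"Combo {results.evaluation.combo_label}: per-material D_JS")
    return ax


def save_all_figures(results, out_dir, prefix: str = "") -> list[str]:
    """Write the three diagnostic figures as PNGs; returns the paths."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, fn in (
        ("mean_scatter", mean_scatter_with_rectangles),
        ("strip_plot", paired_strip_plot),
        ("d_js_bars", d_js_bar_chart),
    ):
        ax = fn(results)
        path = out_dir / f"{prefix}{name}.png"
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
        written.append(str(path))
    return written
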