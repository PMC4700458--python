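"""Report figures: histograms, spatial parameter maps, group maps,
pairwise scatter with SVM boundaries.

Every plotted quantity comes straight from the CSV tables the pipeline
writes (params.csv, labels.csv, overlap.csv), so no figure carries
numbers that cannot be re-derived from shipped files.  Iso-parameter
contours are spaced 10 ms apart for the duration parameters and 0.05 for
fractional repolarization; out-of-mask pixels render blank.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .pipeline_constants import CONTOUR_SPACING, PARAM_COLUMNS

__all__ = ["render_report", "parameter_map", "CONTOUR_SPACING"]


def parameter_map(table: pd.DataFrame, column: str, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a per-site parameter column into an H x W map (NaN off-mask)."""
    grid = np.full(shape, np.nan)
    grid[table["site_row"].to_numpy(int), table["site_col"].to_numpy(int)] = \
        table[column].to_numpy(float)
    return grid


def _plot_map(ax, grid: np.ndarray, title: str, spacing: float | None) -> None:
    im = ax.imshow(grid, origin="upper", interpolation="nearest")
    if spacing and np.isfinite(grid).sum() > 10:
        lo = np.nanmin(grid)
        hi = np.nanmax(grid)
        if hi - lo > spacing:
            levels = np.arange(np.ceil(lo / spacing) * spacing, hi, spacing)
            filled = np.where(np.isnan(grid), lo, grid)
            ax.contour(filled, levels=levels, colors="k", linewidths=0.5)
    ax.set_title(title, fontsize=8)
    ax.set_xticks([])
    ax.set_yticks([])
    plt.colorbar(im, ax=ax, fraction=0.046)


def render_report(out: Path, params: pd.DataFrame, labels: pd.DataFrame,
                  overlap: pd.DataFrame, fits: dict, pres: dict) -> None:
    """Render the figure set for one pipeline run into ``out``/figures."""
    figdir = Path(out) / "figures"
    figdir.mkdir(exist_ok=True)

    # pooled histograms of the four parameters
    fig, axes = plt.subplots(2, 2, figsize=(8, 6))
    for ax, col in zip(axes.ravel(), PARAM_COLUMNS):
        ax.hist(params[col], bins=40, color="steelblue")
        ax.set_xlabel(col, fontsize=8)
        key = "apd80_threshold_k2"
        if col == "apd80_ms" and key in fits and "crossover" in fits[key]:
            ax.axvline(fits[key]["crossover"], ls="--", color="k")
    fig.suptitle("Pooled AP parameter distributions")
    fig.tight_layout()
    fig.savefig(figdir / "pooled_histograms.png", dpi=120)
    plt.close(fig)

    # per-cluster parameter + group maps
    for cid, pre in pres.items():
        sub = params[params.cluster_id == cid]
        if sub.empty:
            continue
        shape = (int(sub.site_row.max()) + 2, int(sub.site_col.max()) + 2)
        fig, axes = plt.subplots(1, len(PARAM_COLUMNS) + 1, figsize=(16, 3))
        for ax, col in zip(axes, PARAM_COLUMNS):
            _plot_map(ax, parameter_map(sub, col, shape), f"{cid} {col}",
                      CONTOUR_SPACING[col])
        lab = labels[(labels.cluster_id == cid) & (labels.method == "waveform_spectral")
                     & (labels.k == 2)]
        if not lab.empty:
            _plot_map(axes[-1], parameter_map(lab, "label", shape), f"{cid} groups", None)
        fig.tight_layout()
        fig.savefig(figdir / f"maps_{cid}.png", dpi=120)
        plt.close(fig)

    # pairwise scatter colored by waveform grouping, with SVM boundaries
    lab2 = labels[(labels.method == "waveform_spectral") & (labels.k == 2)]
    if not lab2.empty and len(lab2) == len(params):
        colors = lab2["label"].to_numpy()
        n_pairs = len(overlap)
        if n_pairs:
            fig, axes = plt.subplots(1, n_pairs, figsize=(3 * n_pairs, 3))
            axes = np.atleast_1d(axes)
            for ax, (_, row) in zip(axes, overlap.iterrows()):
                x = params[row.param_x].to_numpy()
                y = params[row.param_y].to_numpy()
                ax.scatter(x, y, c=colors, s=4, cmap="coolwarm")
                a, b, c = row.coef_x, row.coef_y, row.intercept
                xs = np.linspace(x.min(), x.max(), 50)
                if abs(b) > 1e-12:
                    ax.plot(xs, -(a * xs + c) / b, "k--", lw=1)
                ax.set_xlabel(row.param_x, fontsize=7)
                ax.set_ylabel(row.param_y, fontsize=7)
                ax.set_title(f"overlap {row.overlap_percent:.1f}%", fontsize=8)
            fig.tight_layout()
            fig.savefig(figdir / "pairwise_scatter.png", dpi=120)
            plt.close(fig)
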