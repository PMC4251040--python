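"""Deterministic PNG plotting helpers.

Fixed figure sizes and styling so outputs are reproducible; every plot is
regenerable from the corresponding CSV alone.  Retention times are shown in
minutes throughout.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy.cluster import hierarchy

from .msdata_io import Spectrum, TimeSeries

_FIGSIZE = (8.0, 4.5)
_DPI = 100
_GROUP_COLORS = ("#c0392b", "#2980b9", "#27ae60", "#8e44ad")


def plot_timeseries(series: TimeSeries, path: str, title: str = "") -> str:
    fig, ax = plt.subplots(figsize=_FIGSIZE, dpi=_DPI)
    ax.plot(series.times_min, series.values, lw=0.8, color="#2c3e50")
    ax.set_xlabel("retention time (min)")
    ax.set_ylabel("intensity")
    ax.set_title(title or series.label)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def plot_spectrum(spec: Spectrum, path: str, title: str = "") -> str:
    fig, ax = plt.subplots(figsize=_FIGSIZE, dpi=_DPI)
    ax.vlines(spec.mz, 0, spec.intensity, lw=0.8, color="#2c3e50")
    ax.set_xlabel("m/z")
    ax.set_ylabel("intensity")
    ax.set_title(title or spec.label)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def plot_bin_histogram(bin_vector, path: str, title: str = "") -> str:
    grid = bin_vector.grid
    fig, ax = plt.subplots(figsize=_FIGSIZE, dpi=_DPI)
    ax.bar(grid.edges[:-1], bin_vector.values,
           width=np.diff(grid.edges), align="edge",
           color="#2980b9", edgecolor="none")
    ax.set_xlabel("m/z bin")
    ax.set_ylabel("total intensity")
    ax.set_title(title or f"bin fingerprint ({grid.n_bins} bins of "
                          f"{grid.bin_size:g})")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def plot_pca_scores(pca_result, path: str) -> str:
    fig, ax = plt.subplots(figsize=(6.0, 5.0), dpi=_DPI)
    groups = pca_result.groups or [""] * len(pca_result.scores)
    uniq = list(dict.fromkeys(groups))
    has_pc2 = pca_result.scores.shape[1] > 1
    y = pca_result.scores[:, 1] if has_pc2 else np.zeros(len(pca_result.scores))
    for gi, g in enumerate(uniq):
        mask = np.array(groups) == g
        ax.scatter(pca_result.scores[mask, 0], y[mask],
                   color=_GROUP_COLORS[gi % len(_GROUP_COLORS)],
                   label=str(g), s=36)
    evf = pca_result.explained_variance_fraction
    ax.set_xlabel(f"PC1 ({evf[0] * 100:.1f}%)")
    ax.set_ylabel(f"PC2 ({evf[1] * 100:.1f}%)" if has_pc2 else "")
    if any(uniq):
        ax.legend()
    ax.set_title("PCA scores")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def plot_volcano(volcano_result, path: str) -> str:
    fig, ax = plt.subplots(figsize=(6.0, 5.0), dpi=_DPI)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = volcano_result.log2_fc
        y = -np.log10(np.maximum(volcano_result.p_value, 1e-300))
    ok = np.isfinite(x)
    neither = ok & ~volcano_result.significant
    ax.scatter(x[neither], y[neither], s=10, color="#95a5a6")
    ax.scatter(x[ok & volcano_result.significant_up],
               y[ok & volcano_result.significant_up], s=14, color="#c0392b",
               label=f"up in {volcano_result.numerator}")
    ax.scatter(x[ok & volcano_result.significant_down],
               y[ok & volcano_result.significant_down], s=14, color="#27ae60",
               label=f"down in {volcano_result.numerator}")
    ax.axhline(-np.log10(volcano_result.p_thresh), ls=":", color="#7f8c8d")
    for fc in (volcano_result.fc_thresh, 1 / volcano_result.fc_thresh):
        ax.axvline(np.log2(fc), ls=":", color="#7f8c8d")
    ax.set_xlabel(f"log2 fold change ({volcano_result.numerator}/"
                  f"{volcano_result.denominator})")
    ax.set_ylabel("-log10 p")
    ax.legend()
    ax.set_title("volcano")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def plot_dendrogram(hca_result, path: str) -> str:
    fig, ax = plt.subplots(figsize=_FIGSIZE, dpi=_DPI)
    hierarchy.dendrogram(hca_result._scipy_linkage(),
                         labels=hca_result.items, ax=ax,
                         color_threshold=0.0, above_threshold_color="#2c3e50")
    ax.set_ylabel("merge height (Ward, 1 - r)")
    ax.tick_params(axis="x", labelrotation=90, labelsize=6)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
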