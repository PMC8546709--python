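"""Figure builders: ER scatter plots with confidence ellipses, mean +/- CI
bars, dispersion (PCoA) plots, and top-taxon abundance bars.

Output is deterministic for fixed input and config: the SVG hash salt is
pinned and no timestamps are embedded, so re-rendering the same figure gives
byte-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import diversity
from .exceptions import InvalidInputError
from .stats import confidence_ellipse, mean_ci

__all__ = [
    "PlotConfig",
    "plot_er_scatter",
    "plot_mean_ci",
    "plot_dispersion",
    "plot_top_taxa",
]

log = logging.getLogger(__name__)

matplotlib.rcParams["svg.hashsalt"] = "erdiv"

_SAVEFIG_KW = {"metadata": {"Date": None}}


@dataclass
class PlotConfig:
    """Rendering options shared by all plot functions."""

    path: str | Path | None = None
    fmt: str = "svg"
    level: float = 0.95
    dpi: int = 150
    ellipse_vertices: int = 200

    def __post_init__(self) -> None:
        if not 0.0 < self.level < 1.0:
            raise InvalidInputError("confidence level must be in (0, 1)")
        if self.fmt not in ("svg", "png"):
            raise InvalidInputError(f"unsupported format {self.fmt!r} (svg or png)")


def _finish(fig, config: PlotConfig) -> Path | None:
    if config.path is None:
        return None
    path = Path(config.path)
    path.parent.mkdir(parents=True, exist_ok=True)
    kw = dict(_SAVEFIG_KW) if config.fmt == "svg" else {}
    fig.savefig(path, format=config.fmt, dpi=config.dpi, **kw)
    plt.close(fig)
    return path


def plot_er_scatter(
    coords: pd.DataFrame,
    groups=None,
    config: PlotConfig | None = None,
):
    """Evenness-versus-richness scatter plot with group confidence ellipses.

    Richness is on the x axis and NME on the y axis, so alpha diversity
    increases diagonally toward the top-right corner.  One ellipse is drawn
    per group with at least 3 samples; smaller groups get points only and a
    logged warning.
    """
    config = config or PlotConfig()
    if coords.shape[0] < 1:
        raise InvalidInputError("no samples to plot")
    fig, ax = plt.subplots()
    if groups is None:
        groups = pd.Series(["all"] * len(coords), index=coords.index)
    elif not isinstance(groups, pd.Series):
        groups = pd.Series(np.asarray(groups, dtype=object), index=coords.index)
    for label in pd.unique(groups):
        sub = coords.loc[groups == label, ["richness", "nme"]]
        ax.scatter(sub["richness"], sub["nme"], label=str(label))
        if len(sub) >= 3:
            try:
                spec = confidence_ellipse(sub.to_numpy(), level=config.level)
            except Exception as exc:  # collinear group
                log.warning("no ellipse for group %r: %s", label, exc)
                continue
            poly = spec.polygon(config.ellipse_vertices)
            ax.fill(poly[:, 0], poly[:, 1], alpha=0.2)
        else:
            log.warning("group %r has < 3 samples; ellipse skipped", label)
    ax.set_xlabel("Richness")
    ax.set_ylabel("Normalized-median evenness")
    ax.legend()
    return fig, _finish(fig, config)


def plot_mean_ci(
    values_by_group: dict[str, np.ndarray],
    config: PlotConfig | None = None,
    ylabel: str = "Shannon index",
):
    """Per-group mean with t-based confidence-interval error bars."""
    config = config or PlotConfig()
    labels, means, errs = [], [], []
    for label, values in values_by_group.items():
        m, lo, hi = mean_ci(np.asarray(values, dtype=float), level=config.level)
        labels.append(str(label))
        means.append(m)
        errs.append(m - lo)
    fig, ax = plt.subplots()
    ax.bar(labels, means, yerr=errs, capsize=4)
    ax.set_ylabel(ylabel)
    return fig, _finish(fig, config)


def plot_dispersion(result, config: PlotConfig | None = None):
    """PCoA scatter of a DispersionResult with centroid spokes.

    Each sample is connected to its group centroid by a line segment.  If
    fewer than 2 PCoA axes were retained, falls back to a 1-D strip plot.
    """
    config = config or PlotConfig()
    scores = result.coordinates
    fig, ax = plt.subplots()
    one_d = scores.shape[1] < 2
    if one_d:
        log.warning("fewer than 2 positive PCoA axes; falling back to 1-D strip plot")
    for label in pd.unique(result.groups):
        idx = result.groups == label
        x = scores.loc[idx].iloc[:, 0].to_numpy()
        y = np.zeros_like(x) if one_d else scores.loc[idx].iloc[:, 1].to_numpy()
        cx = result.centroids.loc[label].iloc[0]
        cy = 0.0 if one_d else result.centroids.loc[label].iloc[1]
        for xi, yi in zip(x, y):
            ax.plot([xi, cx], [yi, cy], color="grey", lw=0.7, zorder=1)
        ax.scatter(x, y, label=str(label), zorder=2)
        ax.scatter([cx], [cy], marker="x", s=80, color="black", zorder=3)
    ax.set_xlabel("PCoA 1")
    ax.set_ylabel("PCoA 2" if not one_d else "")
    ax.legend()
    return fig, _finish(fig, config)


def plot_top_taxa(
    matrix: pd.DataFrame,
    groups,
    k: int,
    config: PlotConfig | None = None,
):
    """Mean relative abundance (+/- CI) of the top-k taxa, per group.

    Taxa are ranked by grand-mean relative abundance over all samples; ties
    are broken by taxon label.  ``k`` larger than the taxon count is clamped
    with a warning.
    """
    config = config or PlotConfig()
    if k < 1:
        raise InvalidInputError("k must be >= 1")
    if k > matrix.shape[1]:
        log.warning("k=%d exceeds taxon count %d; clamping", k, matrix.shape[1])
        k = matrix.shape[1]
    rel = matrix.apply(lambda r: diversity.relative_abundances(r.to_numpy()),
                       axis=1, result_type="broadcast")
    # label-ascending pre-sort + stable sort on the mean = lexicographic tie-break
    order = rel.mean(axis=0).sort_index().sort_values(ascending=False, kind="stable")
    top = order.index[:k]
    if not isinstance(groups, pd.Series):
        groups = pd.Series(np.asarray(groups, dtype=object), index=matrix.index)
    labels = list(pd.unique(groups))
    fig, axes = plt.subplots(1, k, figsize=(2.2 * k, 3.2), squeeze=False, sharey=True)
    for j, taxon in enumerate(top):
        ax = axes[0][j]
        means, errs = [], []
        for label in labels:
            vals = rel.loc[groups == label, taxon].to_numpy()
            if len(vals) >= 2:
                m, lo, _ = mean_ci(vals, level=config.level)
                means.append(m)
                errs.append(m - lo)
            else:
                means.append(float(vals.mean()) if len(vals) else 0.0)
                errs.append(0.0)
        ax.bar([str(x) for x in labels], means, yerr=errs, capsize=3)
        ax.set_title(str(taxon), fontsize=9)
        ax.tick_params(axis="x", rotation=90)
    axes[0][0].set_ylabel("Mean relative abundance")
    fig.tight_layout()
    return fig, _finish(fig, config)
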