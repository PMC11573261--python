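"""Manhattan and genetic-path plots."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["render_manhattan", "plot_path"]

_CHROM_COLORS = ("#30578c", "#a6b6cf")


def _chrom_sort_key(chrom: str):
    s = str(chrom)
    return (0, int(s)) if s.isdigit() else (1, s)


def render_manhattan(
    results: pd.DataFrame,
    thresholds: dict[float, float] | None = None,
    path=None,
    y_col: str = "neglog10_p_adj",
    ax=None,
    title: str | None = None,
):
    """Manhattan plot of a scan result table.

    Chromosomes are laid out in numeric order (chromosome "0", holding
    unplaced SNPs, first) with alternating colors; horizontal dashed
    lines mark calibrated significance thresholds keyed by alpha level.
    """
    if results.empty:
        raise ValueError("no results to plot")
    df = results.copy()
    df["chrom"] = df["chrom"].astype(str)
    chroms = sorted(df["chrom"].unique(), key=_chrom_sort_key)
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))
    offset = 0.0
    ticks, tick_labels = [], []
    for ci, chrom in enumerate(chroms):
        sub = df[df["chrom"] == chrom].sort_values("pos")
        x = offset + np.arange(len(sub))
        ax.scatter(
            x,
            sub[y_col],
            s=8,
            color=_CHROM_COLORS[ci % 2],
            linewidths=0,
        )
        ticks.append(offset + len(sub) / 2)
        tick_labels.append(chrom)
        offset += len(sub)
    for alpha, thr in (thresholds or {}).items():
        ax.axhline(
            thr,
            color="red",
            linestyle="--",
            linewidth=0.8,
            label=f"{100 * (1 - alpha):g}% null quantile",
        )
    if thresholds:
        ax.legend(loc="upper right", fontsize=8)
    ax.set_xticks(ticks)
    ax.set_xticklabels(tick_labels, fontsize=7)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10} p$")
    if title:
        ax.set_title(title)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_path(gpath, ensemble=None, path=None, ax=None):
    """Plot one genetic path theta(i), its null line, and Delta-theta.

    Optionally overlays a permutation-null envelope from a
    :class:`~giftmap.nullmodel.NullEnsemble` of the same composition.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    i = np.arange(1, gpath.n + 1)
    ax.plot(i, gpath.theta, color="black", lw=1.0, label=r"$\theta(i)$")
    ax.plot(
        i,
        gpath.theta0_slope * i,
        color="gray",
        lw=0.8,
        ls="--",
        label=r"$\theta_0(i)$",
    )
    ax.plot(i, gpath.delta, color="#b03030", lw=1.0, label=r"$\Delta\theta(i)$")
    if ensemble is not None:
        ax.fill_between(
            i, ensemble.lower, ensemble.upper, color="gray", alpha=0.25,
            label="null envelope",
        )
    ax.set_xlabel("rank position $i$")
    ax.set_ylabel("cumulative microstate sum")
    ax.legend(fontsize=8)
    ax.set_title(gpath.snp_id)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
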