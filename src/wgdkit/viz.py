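"""Plot helpers: Ks histograms, synteny dotplots, MAPS burst profiles."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .ks import KsDistribution, MixtureFit
from .maps import MapsResult
from .synteny import SyntenyBlock


def plot_ks_distribution(
    dist: KsDistribution, fit: MixtureFit | None = None, path=None, bins: int = 60
):
    fig, ax = plt.subplots(figsize=(6, 4))
    ks = dist.values["ks"].to_numpy()
    w = dist.values["weight"].to_numpy()
    ax.hist(ks, bins=bins, weights=w, color="#7fa8c9", edgecolor="white")
    if fit is not None:
        grid = np.linspace(*dist.window, 400)
        lo = np.log(grid)
        dens = np.exp(fit.component_logpdf(lo)).sum(axis=1) / grid
        scale = w.sum() * (dist.window[1] - dist.window[0]) / bins
        ax.plot(grid, dens * scale, color="crimson", lw=1.5)
        for m in fit.medians:
            ax.axvline(m, color="crimson", ls="--", lw=0.8)
    ax.set_xlabel("Ks")
    ax.set_ylabel("weighted duplications")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_dotplot(blocks: list[SyntenyBlock], path=None):
    fig, ax = plt.subplots(figsize=(5, 5))
    for blk in blocks:
        xs = [a.rank_a for a in blk.anchors]
        ys = [a.rank_b for a in blk.anchors]
        ax.plot(xs, ys, ".", ms=2)
    ax.set_xlabel("genome A gene rank")
    ax.set_ylabel("genome B gene rank")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_maps(observed: MapsResult, null: MapsResult | None = None, path=None):
    fig, ax = plt.subplots(figsize=(6, 4))
    nodes = list(observed.table.index)
    x = np.arange(len(nodes))
    ax.plot(x, observed.table["pct"], "o-", label="observed")
    if observed.resample_ci is not None:
        ax.fill_between(
            x,
            observed.resample_ci["pct_lo"],
            observed.resample_ci["pct_hi"],
            alpha=0.25,
        )
    if null is not None:
        ax.plot(x, null.table["pct"], "s--", label="null", color="grey")
    ax.set_xticks(x, nodes)
    ax.set_ylabel("% subtrees with shared duplication")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
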