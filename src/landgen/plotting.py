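"""Minimal figures: RCM support heatmap and diversity-vs-temperature scatter."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .genotypes import SiteTable
from .mantel import RCMResult

__all__ = ["support_heatmap", "diversity_scatter"]


def support_heatmap(rcm: RCMResult, ax=None):
    """Heatmap of the relative-support matrix (winner = positive column)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    vmax = np.abs(rcm.support).max() or 1.0
    im = ax.imshow(rcm.support, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(len(rcm.hypotheses)), rcm.hypotheses, rotation=45,
                  ha="right")
    ax.set_yticks(range(len(rcm.hypotheses)), rcm.hypotheses)
    for i in range(len(rcm.hypotheses)):
        for j in range(len(rcm.hypotheses)):
            ax.text(j, i, f"{rcm.support[i, j]:.2f}", ha="center", va="center",
                    fontsize=8)
    ax.set_title("RCM relative support")
    plt.colorbar(im, ax=ax, shrink=0.8)
    return ax


def diversity_scatter(diversity: pd.DataFrame, sites: SiteTable,
                      response: str = "Ho", variable: str = "tmin", ax=None):
    """Per-population diversity against a site climate variable."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    x = sites.data[variable].reindex(diversity.index)
    y = diversity[response]
    classes = sites.data.get("env_class")
    for marker, cls in (("o", "marginal"), ("^", "optimal")):
        if classes is not None:
            mask = classes.reindex(diversity.index).str.lower() == cls
        else:
            mask = pd.Series(marker == "o", index=diversity.index)
        ax.scatter(x[mask], y[mask], marker=marker, label=cls)
    for pop in diversity.index:
        ax.annotate(pop, (x[pop], y[pop]), fontsize=7,
                    xytext=(2, 2), textcoords="offset points")
    ax.set_xlabel(f"{variable} (deg C)")
    ax.set_ylabel(response)
    if classes is not None:
        ax.legend()
    return ax
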