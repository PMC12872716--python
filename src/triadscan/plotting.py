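"""Plotting helpers: ternary triad scatter and genome hotspot overview."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .triads import ternary_coordinates

_CORNERS = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3.0) / 2.0], [0.0, 0.0]])


def ternary_plot(assignment: pd.DataFrame, ax=None, **scatter_kw):
    """Scatter triads inside the A/B/D simplex, coloured by category."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5.5))
    ax.plot(_CORNERS[:, 0], _CORNERS[:, 1], color="black", lw=1)
    sub = assignment.dropna(subset=["rel_A", "rel_B", "rel_D"])
    xy = ternary_coordinates(sub[["rel_A", "rel_B", "rel_D"]].to_numpy())
    size = scatter_kw.pop("s", 4)
    alpha = scatter_kw.pop("alpha", 0.5)
    for cat in sorted(sub["category"].unique()):
        pts = xy[sub["category"].to_numpy() == cat]
        ax.scatter(pts[:, 0], pts[:, 1], s=size, alpha=alpha, label=str(cat),
                   **scatter_kw)
    for label, (x, y) in zip("ABD", _CORNERS[:3]):
        ax.annotate(label, (x, y), textcoords="offset points",
                    xytext=(0, -12 if y == 0 else 8), ha="center")
    ax.set_aspect("equal")
    ax.axis("off")
    ax.legend(fontsize=7, loc="upper left", bbox_to_anchor=(0.98, 1.0))
    return ax


def genome_plot(table: pd.DataFrame, regions: pd.DataFrame, ax=None):
    """Smoothed log2FC along each chromosome with called regions shaded."""
    import matplotlib.pyplot as plt

    chroms = list(pd.unique(table["chrom"]))
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 0.45 * len(chroms) + 1))
    for i, chrom in enumerate(chroms):
        sub = table[table["chrom"] == chrom]
        scale = sub["smoothed"].abs().max() or 1.0
        ax.plot(sub["pos"] / 1e6, i + 0.4 * sub["smoothed"] / scale,
                lw=0.8, color="grey")
        for row in regions[regions["chrom"] == chrom].itertuples(index=False):
            color = "firebrick" if row.direction == "up" else "steelblue"
            ax.axhspan(i - 0.35, i + 0.35, xmin=0, xmax=1, alpha=0.0)
            ax.fill_betweenx([i - 0.35, i + 0.35], row.start / 1e6, row.end / 1e6,
                             color=color, alpha=0.35, linewidth=0)
    ax.set_yticks(range(len(chroms)), chroms)
    ax.set_xlabel("position (Mbp)")
    return ax
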