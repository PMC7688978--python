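"""Plain heat-map exports for change maps and correlation matrices."""
from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .analytics import CorrelationResult
from .depth import HeightChangeMap


def save_change_heatmap(cmap: HeightChangeMap, path: str | Path,
                        vlim: float | None = None) -> None:
    """Export a signed height-change map as a diverging heat map (PNG)."""
    if vlim is None:
        vlim = float(np.nanmax(np.abs(cmap.grid))) or 1.0
    fig, ax = plt.subplots(figsize=(6, 4.5))
    im = ax.imshow(cmap.grid, cmap="RdBu_r", vmin=-vlim, vmax=vlim)
    fig.colorbar(im, ax=ax, label="height change (cm)")
    ax.set_title(f"{cmap.timescale} change "
                 f"[{cmap.interval[0]:.0f}, {cmap.interval[1]:.0f}] s")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def save_correlation_heatmap(result: CorrelationResult,
                             path: str | Path) -> None:
    """Export a correlation matrix in its UPGMA leaf order (PNG)."""
    order = result.leaf_order
    rmat = result.r.loc[order, order]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(rmat.values, cmap="vlag" if "vlag" in plt.colormaps()
                   else "RdBu_r", vmin=-1, vmax=1)
    ax.set_xticks(range(len(order)), order, rotation=90, fontsize=7)
    ax.set_yticks(range(len(order)), order, fontsize=7)
    fig.colorbar(im, ax=ax, label="Pearson R")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
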