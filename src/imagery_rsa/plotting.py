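"""Basic visualization: RDM heatmaps and violin plots of subject distances."""

from __future__ import annotations

from typing import Optional

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .crossnobis import RDM


def rdm_heatmap(rdm_lh: RDM, rdm_rh: Optional[RDM] = None, ax=None,
                cmap: str = "RdYlBu_r", title: Optional[str] = None):
    """Heatmap of one region's RDM.

    With two hemispheres, the lower triangle shows the left- and the upper
    triangle the right-hemisphere distances; the zero diagonal stays
    blank.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    n = len(rdm_lh.condition_names)
    mat = np.array(rdm_lh.matrix, dtype=float)
    if rdm_rh is not None:
        if rdm_rh.condition_names != rdm_lh.condition_names:
            raise ValueError("hemisphere RDMs must share conditions")
        iu = np.triu_indices(n, 1)
        mat[iu] = rdm_rh.matrix[iu]
    display = np.ma.masked_where(np.eye(n, dtype=bool), mat)
    vmax = np.abs(mat[~np.eye(n, dtype=bool)]).max() or 1.0
    im = ax.imshow(display, cmap=cmap, vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(n))
    ax.set_yticks(range(n))
    ax.set_xticklabels(rdm_lh.condition_names, rotation=90, fontsize=6)
    ax.set_yticklabels(rdm_lh.condition_names, fontsize=6)
    ax.figure.colorbar(im, ax=ax, label="crossnobis distance")
    if title:
        ax.set_title(title)
    return ax


def distance_violins(distances: pd.DataFrame, ax=None,
                     title: Optional[str] = None):
    """Violin plot of per-subject averaged distances, one violin per
    (region, selection); a dashed line marks the meaningful zero."""
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 4))
    groups = distances.dropna(subset=["value"]).groupby(
        ["region", "selection"])["value"]
    labels, data = [], []
    for (region, selection), vals in groups:
        labels.append(f"{region}\n{selection}")
        data.append(vals.to_numpy())
    if not data:
        raise ValueError("no distances to plot")
    ax.violinplot(data, showmeans=True)
    ax.axhline(0.0, color="k", linestyle="--", linewidth=0.8)
    ax.set_xticks(range(1, len(labels) + 1))
    ax.set_xticklabels(labels, fontsize=6, rotation=45, ha="right")
    ax.set_ylabel("mean crossnobis distance")
    if title:
        ax.set_title(title)
    return ax
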