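"""Minimal plotting helpers: clone heatmap and per-group violin summaries.

Aesthetics are not a goal; these render quick-look figures from the
pipeline's tabular outputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cluster import FeatureMatrix


def clone_heatmap(features: FeatureMatrix, assignments: pd.Series | None = None, ax=None):
    """Heatmap of log2 abundance profiles, rows optionally ordered by cluster."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 8))
    X = features.features
    if assignments is not None:
        X = X.loc[assignments.sort_values(kind="stable").index]
    im = ax.imshow(X.to_numpy(), aspect="auto", cmap="viridis", interpolation="nearest")
    ax.set_xticks(range(X.shape[1]))
    ax.set_xticklabels([f"{ct} {tp:g}m" for ct, tp in X.columns], rotation=90, fontsize=7)
    ax.set_ylabel("clones")
    ax.figure.colorbar(im, ax=ax, label="log2 %WBC")
    return ax


def group_violin(per_mouse: pd.DataFrame, ax=None):
    """Violin plot of a per-mouse metric by group (columns group, value)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    groups = sorted(per_mouse["group"].unique())
    data = [per_mouse.loc[per_mouse["group"] == g, "value"].to_numpy() for g in groups]
    ax.violinplot(data, showmeans=True)
    for i, values in enumerate(data, start=1):
        ax.scatter(np.full(len(values), i), values, color="k", s=12, zorder=3)
    ax.set_xticks(range(1, len(groups) + 1))
    ax.set_xticklabels(groups)
    return ax
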