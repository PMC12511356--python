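"""Plot helpers: histogram panels per group with cluster-centroid overlays."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_histogram_panel", "plot_cluster_overlay"]

GROUP_COLORS = {"P": "tab:red", "NP": "tab:blue", "C": "0.5"}


def plot_histogram_panel(histograms, groups, ax=None, title: str = ""):
    """Per-subject strain histograms coloured by group (P red, NP blue, C grey)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    for hist, g in zip(histograms, groups):
        centers = 0.5 * (hist.edges[:-1] + hist.edges[1:])
        ax.plot(centers, hist.values, color=GROUP_COLORS.get(g, "k"), alpha=0.5, lw=1)
    ax.set_xlabel(f"{histograms[0].measure} strain (-)")
    ax.set_ylabel("% of cartilage volume")
    if title:
        ax.set_title(title)
    return ax


def plot_cluster_overlay(features, edges, cluster_result, groups, ax=None, title: str = ""):
    """Subject feature vectors split by cluster, centroids in black."""
    import matplotlib.pyplot as plt

    features = np.asarray(features)
    if ax is None:
        _, axes = plt.subplots(1, 2, figsize=(9, 3.2), sharey=True)
    else:
        axes = ax
    centers = 0.5 * (np.asarray(edges)[:-1] + np.asarray(edges)[1:])
    for k, a in enumerate(axes, start=1):
        for row, g, lab in zip(features, groups, cluster_result.labels):
            if lab == k:
                a.plot(centers, row, color=GROUP_COLORS.get(g, "k"), alpha=0.5, lw=1)
        a.plot(centers, cluster_result.centroids[k - 1], color="k", lw=2)
        a.set_title(f"cluster {k}")
        a.set_xlabel("strain (-)")
    axes[0].set_ylabel("% of cartilage volume")
    if title:
        axes[0].figure.suptitle(title)
    return axes
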