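"""Static cluster-map plots (the tabular outputs are the primary record)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_cluster_map(
    table: pd.DataFrame,
    path: str | Path | None = None,
    title: str = "",
    max_dot: float = 120.0,
):
    """Scatter of 2-D projected peptides, colored by cluster.

    ``table`` needs columns x, y, cluster and optionally count (dot size
    scales with count, the visual emphasis on enriched sequences).
    """
    fig, ax = plt.subplots(figsize=(6, 5))
    clusters = pd.Categorical(table["cluster"])
    if "count" in table.columns:
        counts = table["count"].to_numpy(float)
        sizes = 8.0 + max_dot * counts / counts.max()
    else:
        sizes = np.full(len(table), 12.0)
    sc = ax.scatter(
        table["x"], table["y"], c=clusters.codes, s=sizes,
        cmap="tab20", alpha=0.7, linewidths=0,
    )
    ax.set_xlabel("t-SNE 1 (arbitrary units)")
    ax.set_ylabel("t-SNE 2 (arbitrary units)")
    if title:
        ax.set_title(title)
    fig.colorbar(sc, ax=ax, label="cluster")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
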