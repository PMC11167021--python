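"""End-to-end analyses over a set of selection samples.

Two clustering analyses are provided, sharing the same mixture-fit code
but running on different inputs, as in the study design they emulate:

* global — all unique sequences from every sample pooled into one
  dataset, 20 clusters;
* per-sample / tracking — the naïve library clustered alone (10
  clusters) and round samples assigned to those fixed clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cluster import (
    ClusterModel,
    GLOBAL_K,
    PER_SAMPLE_K,
    assign_clusters,
    fit_gmm,
    project_2d,
    reduce_pca,
)
from .count_table import PeptideCountTable
from .embedding import BUILTIN_EMBEDDER, embed_sequences
from .stats import filter_min_count, sample_summary
from .track import TrackingResult, fit_naive_clusters, track_clusters


@dataclass
class GlobalClustering:
    """Pooled-unique-sequence clustering over all samples."""

    model: ClusterModel
    peptides: list[str]
    labels: np.ndarray
    coords: np.ndarray | None  # (n, 2) t-SNE, None if not projected

    def table(self) -> pd.DataFrame:
        out = pd.DataFrame({"peptide": self.peptides, "cluster": self.labels})
        if self.coords is not None:
            out["x"] = self.coords[:, 0]
            out["y"] = self.coords[:, 1]
        return out


def cluster_global(
    tables: Sequence[PeptideCountTable],
    n_clusters: int = GLOBAL_K,
    seed: int | None = None,
    embedder: str = BUILTIN_EMBEDDER,
    min_count: int = 5,
    target_dim: int = 20,
    project: bool = False,
) -> GlobalClustering:
    """Cluster the union of unique sequences across samples.

    The naïve sample (round label ``naive``) contributes all its unique
    sequences; round samples contribute sequences passing ``min_count``.
    Peptides are deduplicated across samples (unique sequences as one
    dataset, unweighted).
    """
    pooled: dict[str, None] = {}
    for t in tables:
        src = t if t.round_label == "naive" or min_count <= 1 else filter_min_count(t, min_count)
        for p in src.peptides:
            pooled.setdefault(p, None)
    peptides = list(pooled)
    emb = embed_sequences(peptides, embedder)
    reduced, pca = reduce_pca(emb.matrix, target_dim=min(target_dim, emb.dim))
    model = fit_gmm(reduced, n_components=n_clusters, seed=seed, pca=pca)
    labels, _ = assign_clusters(model, reduced)
    coords = project_2d(reduced, seed=seed) if project else None
    return GlobalClustering(model=model, peptides=peptides, labels=labels, coords=coords)


@dataclass
class StudyAnalysis:
    """Summary statistics plus per-arm cluster tracking for one study."""

    summary: pd.DataFrame  # per-sample totals and unique fractions
    tracking: dict[str, TrackingResult]  # per selection arm
    naive_model: ClusterModel


def analyze_study(
    samples: Mapping[str, PeptideCountTable],
    n_clusters: int = PER_SAMPLE_K,
    seed: int | None = None,
    embedder: str = BUILTIN_EMBEDDER,
    min_count: int = 5,
) -> StudyAnalysis:
    """Run the tracking analysis over a naïve + multi-arm sample set.

    ``samples`` maps sample id to table; the naïve sample is identified by
    round label ``naive`` and arms by distinct ``cell_line`` values. The
    naïve clustering is fit once and shared across arms.
    """
    naive = next(
        (t for t in samples.values() if t.round_label == "naive"), None
    )
    if naive is None:
        raise ValueError("no sample with round label 'naive'")
    arms: dict[str, list[PeptideCountTable]] = {}
    for t in samples.values():
        if t.round_label == "naive":
            continue
        arms.setdefault(t.cell_line or "arm", []).append(t)
    for tables in arms.values():
        tables.sort(key=lambda t: t.round_label)
    model, labels, _ = fit_naive_clusters(
        naive, n_clusters=n_clusters, seed=seed, embedder=embedder
    )
    tracking = {
        arm: track_clusters(
            naive,
            tables,
            seed=seed,
            embedder=embedder,
            min_count=min_count,
            model=model,
            naive_labels=labels,
        )
        for arm, tables in arms.items()
    }
    return StudyAnalysis(
        summary=sample_summary(list(samples.values())),
        tracking=tracking,
        naive_model=model,
    )
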