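"""Naïve-cluster trajectory tracking across selection rounds.

Clusters are defined once, on the naïve library (unfiltered unique
sequences), and every round sample's peptides are assigned to those
naïve clusters through the naïve PCA basis and mixture — the clusters
are tracked forward, never refit per round. Round samples pass a
min-count visualization filter (default counts >= 5) before assignment.

Each cluster's aggregate frequency per sample yields an enrichment
ratio rho = final-round frequency / naïve frequency, categorized as:

=========  =========================
Category   Rule
=========  =========================
Eliminated final-round frequency = 0
Minimum    rho < 0.2
Slight     0.2 <= rho < 1
Modest     1 <= rho < 3
High       rho >= 3
=========  =========================

The thresholds are this package's definitions (configurable), not a
published convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cluster import (
    ClusterModel,
    PER_SAMPLE_K,
    assign_clusters,
    fit_gmm,
    reduce_pca,
)
from .count_table import PeptideCountTable
from .embedding import BUILTIN_EMBEDDER, embed_sequences
from .properties import property_summary
from .stats import filter_min_count

#: (lower-exclusive is handled by order) default rho thresholds.
DEFAULT_THRESHOLDS = {"minimum": 0.2, "slight": 1.0, "modest": 3.0}

CATEGORIES = ("Eliminated", "Minimum", "Slight", "Modest", "High")


def categorize_ratio(
    final_frequency: float,
    ratio: float,
    thresholds: dict[str, float] = DEFAULT_THRESHOLDS,
) -> str:
    """Categorical enrichment label from the final-round/naïve ratio."""
    if final_frequency == 0.0:
        return "Eliminated"
    if ratio < thresholds["minimum"]:
        return "Minimum"
    if ratio < thresholds["slight"]:
        return "Slight"
    if ratio < thresholds["modest"]:
        return "Modest"
    return "High"


@dataclass
class ClusterTrajectory:
    """Aggregate frequency of one naïve cluster across selection rounds."""

    cluster: str
    frequencies: dict[str, float]  # sample label -> aggregate frequency
    ratio: float  # final-round / naïve aggregate frequency
    category: str
    n_naive_members: int
    mean_hydropathy: float
    mean_pI: float
    mean_charge: float

    def as_row(self) -> dict:
        return {
            "cluster": self.cluster,
            **{f"freq_{k}": v for k, v in self.frequencies.items()},
            "ratio": self.ratio,
            "category": self.category,
            "n_naive_members": self.n_naive_members,
            "mean_hydropathy": self.mean_hydropathy,
            "mean_pI": self.mean_pI,
            "mean_charge": self.mean_charge,
        }


@dataclass
class TrackingResult:
    """Naïve cluster model plus per-cluster trajectories and assignments."""

    model: ClusterModel
    naive_labels: np.ndarray
    naive_peptides: list[str]
    trajectories: list[ClusterTrajectory]
    assignments: pd.DataFrame  # peptide, sample, cluster, frequency

    def trajectory_table(self) -> pd.DataFrame:
        return pd.DataFrame([t.as_row() for t in self.trajectories])


def fit_naive_clusters(
    naive: PeptideCountTable,
    n_clusters: int = PER_SAMPLE_K,
    seed: int | None = None,
    embedder: str = BUILTIN_EMBEDDER,
    target_dim: int = 20,
) -> tuple[ClusterModel, np.ndarray, list[str]]:
    """Embed + reduce + cluster the naïve library's unique sequences."""
    peptides = naive.peptides
    emb = embed_sequences(peptides, embedder)
    reduced, pca = reduce_pca(emb.matrix, target_dim=min(target_dim, emb.dim))
    model = fit_gmm(reduced, n_components=n_clusters, seed=seed, pca=pca)
    labels, _ = assign_clusters(model, reduced)
    return model, labels, peptides


def _aggregate_frequency(
    table: PeptideCountTable,
    model: ClusterModel,
    embedder: str,
    n_clusters: int,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Sum of table frequencies per naïve cluster, plus assignment rows."""
    emb = embed_sequences(table.peptides, embedder)
    reduced = model.pca.transform(emb.matrix)
    labels, _ = assign_clusters(model, reduced)
    freqs = table.data["frequency"].to_numpy(float)
    agg = np.bincount(labels, weights=freqs, minlength=n_clusters)
    rows = pd.DataFrame(
        {
            "peptide": table.peptides,
            "sample": table.sample_id,
            "cluster": labels,
            "count": table.data["count"].to_numpy(),
            "frequency": freqs,
        }
    )
    return agg, rows


def track_clusters(
    naive: PeptideCountTable,
    rounds: Sequence[PeptideCountTable],
    n_clusters: int = PER_SAMPLE_K,
    seed: int | None = None,
    embedder: str = BUILTIN_EMBEDDER,
    min_count: int = 5,
    thresholds: dict[str, float] = DEFAULT_THRESHOLDS,
    model: ClusterModel | None = None,
    naive_labels: np.ndarray | None = None,
) -> TrackingResult:
    """Track each naïve cluster's aggregate frequency through the rounds.

    The naïve sample is clustered unfiltered; each round table is filtered
    at ``min_count`` (frequencies left un-renormalized) and its peptides
    assigned to the fixed naïve clusters. The ratio uses the last table in
    ``rounds`` as the final round. A prefit naïve ``model`` (with matching
    ``naive_labels``) may be passed to share one clustering across arms.
    """
    if not rounds:
        raise ValueError("need at least one selection round")
    if model is None:
        model, naive_labels, naive_peptides = fit_naive_clusters(
            naive, n_clusters=n_clusters, seed=seed, embedder=embedder
        )
    else:
        if naive_labels is None:
            raise ValueError("naive_labels required with a prefit model")
        naive_peptides = naive.peptides
    n_clusters = model.n_components
    naive_freq = np.bincount(
        naive_labels,
        weights=naive.data["frequency"].to_numpy(float),
        minlength=n_clusters,
    )
    frequencies: dict[str, np.ndarray] = {naive.round_label or "naive": naive_freq}
    assignment_rows = [
        pd.DataFrame(
            {
                "peptide": naive_peptides,
                "sample": naive.sample_id,
                "cluster": naive_labels,
                "count": naive.data["count"].to_numpy(),
                "frequency": naive.data["frequency"].to_numpy(float),
            }
        )
    ]
    for table in rounds:
        filtered = filter_min_count(table, min_count) if min_count > 1 else table
        agg, rows = _aggregate_frequency(filtered, model, embedder, n_clusters)
        frequencies[table.round_label or table.sample_id] = agg
        assignment_rows.append(rows)
    final_label = rounds[-1].round_label or rounds[-1].sample_id
    final = frequencies[final_label]
    trajectories: list[ClusterTrajectory] = []
    for k in range(n_clusters):
        members = [p for p, l in zip(naive_peptides, naive_labels) if l == k]
        if members:
            props = property_summary(members)
            mh, mpi, mc = props.hydropathy, props.pI, props.charge
        else:
            mh = mpi = mc = float("nan")
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = float(final[k] / naive_freq[k]) if naive_freq[k] > 0 else float("nan")
        trajectories.append(
            ClusterTrajectory(
                cluster=str(k),
                frequencies={lab: float(f[k]) for lab, f in frequencies.items()},
                ratio=ratio,
                category=categorize_ratio(float(final[k]), ratio, thresholds),
                n_naive_members=len(members),
                mean_hydropathy=mh,
                mean_pI=mpi,
                mean_charge=mc,
            )
        )
    return TrackingResult(
        model=model,
        naive_labels=np.asarray(naive_labels),
        naive_peptides=list(naive_peptides),
        trajectories=trajectories,
        assignments=pd.concat(assignment_rows, ignore_index=True),
    )


def cluster_feature_fractions(
    peptides: Sequence[str], labels: np.ndarray, n_clusters: int
) -> pd.DataFrame:
    """Composition-signature fractions per cluster: Cys-containing,
    position-1-Met, and multi-cationic (>= 2 K/R) members."""
    rows = []
    labels = np.asarray(labels)
    for k in range(n_clusters):
        members = [p for p, l in zip(peptides, labels) if l == k]
        n = len(members)
        rows.append(
            {
                "cluster": str(k),
                "n_members": n,
                "frac_cys": sum("C" in p for p in members) / n if n else np.nan,
                "frac_nterm_met": sum(p.startswith("M") for p in members) / n
                if n
                else np.nan,
                "frac_multi_cationic": sum(
                    (p.count("K") + p.count("R")) >= 2 for p in members
                )
                / n
                if n
                else np.nan,
            }
        )
    return pd.DataFrame(rows)
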