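"""Per-sample and cross-round enrichment statistics.

Covers the diversity and composition summaries used to read a selection:
unique-sequence fraction (falls as enrichment concentrates the pool),
positional residue frequency matrices, min-count visualization filtering,
and per-peptide frequency trajectories with naïve-referenced fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .codons import AMINO_ACIDS
from .count_table import PeptideCountTable

Weighting = Literal["unique_unweighted", "count_weighted"]


def unique_fraction(table: PeptideCountTable) -> float:
    """Distinct amino-acid sequences / total retained reads, in (0, 1]."""
    if table.total_reads == 0:
        raise ValueError("empty table")
    return table.unique_sequences / table.total_reads


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """L x 20 stochastic matrix of residue usage by peptide position."""

    matrix: pd.DataFrame  # index: position 1..L, columns: 20 residues
    weighting: Weighting
    n_sequences: int

    def validate(self) -> None:
        values = self.matrix.to_numpy()
        assert ((values >= 0) & (values <= 1)).all()
        assert np.allclose(values.sum(axis=1), 1.0, atol=1e-9)


def position_frequency(
    table: PeptideCountTable,
    weighting: Weighting = "count_weighted",
    subsample: int | None = None,
    seed: int | None = None,
) -> PositionFrequencyMatrix:
    """Residue frequency at each position.

    ``unique_unweighted`` counts each distinct sequence once (optionally a
    seeded random subsample of ``subsample`` sequences — the "randomly
    picked sequences" view); ``count_weighted`` weights by read count,
    reflecting pool composition.
    """
    df = table.data
    if weighting == "unique_unweighted":
        peptides = df["peptide"]
        if subsample is not None and subsample < len(peptides):
            rng = np.random.default_rng(seed)
            idx = rng.choice(len(peptides), size=subsample, replace=False)
            peptides = peptides.iloc[np.sort(idx)]
        weights = np.ones(len(peptides))
    elif weighting == "count_weighted":
        peptides = df["peptide"]
        weights = df["count"].to_numpy(float)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    L = len(peptides.iat[0])
    arr = peptides.to_numpy().astype(f"U{L}").view("U1").reshape(len(peptides), L)
    total = weights.sum()
    mat = np.zeros((L, len(AMINO_ACIDS)))
    for j, aa in enumerate(AMINO_ACIDS):
        mat[:, j] = ((arr == aa) * weights[:, None]).sum(axis=0) / total
    out = pd.DataFrame(mat, index=np.arange(1, L + 1), columns=list(AMINO_ACIDS))
    return PositionFrequencyMatrix(
        matrix=out, weighting=weighting, n_sequences=int(len(peptides))
    )


def filter_min_count(table: PeptideCountTable, k: int) -> PeptideCountTable:
    """Keep rows with count >= k; frequencies are NOT renormalized.

    Retained frequencies remain fractions of the full sample; the filter is
    recorded on the returned table's ``min_count``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return table.copy()
    data = table.data[table.data["count"] >= k].reset_index(drop=True)
    if data.empty:
        raise ValueError(f"min-count filter k={k} removed every sequence")
    out = table.copy()
    return replace(out, data=data, min_count=k)


def enrichment_trajectory(
    tables: Sequence[PeptideCountTable],
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Per-peptide frequency series across rounds with fold changes.

    The first table is the reference (naïve). Peptides absent from a round
    get frequency 0. Fold change is round frequency / naïve frequency;
    peptides unseen in the naïve sample are flagged ``newly_observed`` and
    their fold change is NaN unless a positive ``pseudocount`` (added to
    every numerator and denominator count) is supplied.
    """
    if len(tables) < 2:
        raise ValueError("need at least two rounds")
    lengths = {t.peptide_length for t in tables}
    if len(lengths) != 1:
        raise ValueError("inconsistent peptide lengths across rounds")
    labels = [t.round_label or f"round{i}" for i, t in enumerate(tables)]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate round labels")
    series = []
    for t, label in zip(tables, labels):
        s = t.data.set_index("peptide")["frequency"].rename(label)
        series.append(s)
    freq = pd.concat(series, axis=1).fillna(0.0)
    ref_label = labels[0]
    if pseudocount > 0:
        fold = {}
        for t, label in zip(tables[1:], labels[1:]):
            num = freq[label] + pseudocount / t.total_reads
            den = freq[ref_label] + pseudocount / tables[0].total_reads
            fold[f"fold_{label}"] = num / den
        fold_df = pd.DataFrame(fold, index=freq.index)
    else:
        ref = freq[ref_label]
        with np.errstate(divide="ignore", invalid="ignore"):
            fold_df = pd.DataFrame(
                {
                    f"fold_{label}": np.where(ref > 0, freq[label] / ref, np.nan)
                    for label in labels[1:]
                },
                index=freq.index,
            )
    out = pd.concat([freq, fold_df], axis=1)
    out["newly_observed"] = freq[ref_label] == 0
    out.index.name = "peptide"
    return out.reset_index()


def sample_summary(tables: Sequence[PeptideCountTable]) -> pd.DataFrame:
    """One row per sample: totals, unique sequences, unique fraction."""
    rows = [
        {
            "sample_id": t.sample_id,
            "cell_line": t.cell_line,
            "round": t.round_label,
            "total_reads": t.total_reads,
            "unique_sequences": t.unique_sequences,
            "unique_fraction": unique_fraction(t),
        }
        for t in tables
    ]
    return pd.DataFrame(rows)
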