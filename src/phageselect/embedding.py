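"""Peptide embeddings: a built-in physicochemical embedder and an
interface for externally computed embedding matrices.

The built-in embedder maps each fixed-length peptide to a deterministic
numeric vector: five residue descriptors per position (hydropathy,
charge class, side-chain volume, aromaticity, Cys indicator) followed by
the 20 global residue-composition counts — d = 5L + 20 (65 for
9-mers). It is a lightweight, fully deterministic stand-in for protein
language-model embeddings; precomputed external embeddings (e.g. the
1280-dimensional ESM-2 650M vectors) can be supplied as a delimited
numeric table whose first column is the peptide sequence.

Feature scales are balanced deliberately, because downstream PCA + GMM
see raw Euclidean geometry: the rare binary Cys indicator is upweighted
(``CYS_WEIGHT``) so cysteine-containing sequences separate the way they
do under learned embeddings, the N-terminal position is emphasized
(``NTERM_WEIGHT``) because the displayed peptide's free N-terminus is
the most selection-relevant position, and composition counts carry a
moderate weight (``COMPOSITION_WEIGHT``) so overall residue usage
(e.g. multi-cationic content) shapes cluster identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .codons import AMINO_ACIDS
from .properties import KD_HYDROPATHY

BUILTIN_EMBEDDER = "builtin_physchem"

#: Side-chain volumes (A^3, Zamyatnin 1972).
RESIDUE_VOLUME: dict[str, float] = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}

#: Charge class at neutral pH: +1 K/R, +0.5 H, -1 D/E.
RESIDUE_CHARGE_CLASS: dict[str, float] = {
    **{aa: 0.0 for aa in AMINO_ACIDS},
    "K": 1.0, "R": 1.0, "H": 0.5, "D": -1.0, "E": -1.0,
}

AROMATIC = ("F", "W", "Y")

_MAX_VOLUME = max(RESIDUE_VOLUME.values())
_MAX_KD = 4.5

#: Scale of the per-position Cys indicator (not position-weighted).
CYS_WEIGHT = 6.0
#: Multiplier on the position-1 descriptor block (N-terminal emphasis).
NTERM_WEIGHT = 5.0
#: Multiplier on the 20 global residue-composition counts.
COMPOSITION_WEIGHT = 2.0

#: Per-residue descriptor rows [hydropathy, charge, volume, aromatic].
_DESCRIPTORS: dict[str, np.ndarray] = {
    aa: np.array(
        [
            KD_HYDROPATHY[aa] / _MAX_KD,
            RESIDUE_CHARGE_CLASS[aa],
            RESIDUE_VOLUME[aa] / _MAX_VOLUME,
            1.0 if aa in AROMATIC else 0.0,
        ]
    )
    for aa in AMINO_ACIDS
}

N_DESCRIPTORS = 5  # 4 graded descriptors + Cys indicator per position


@dataclass(frozen=True)
class EmbeddingMatrix:
    """Ordered peptides with one embedding row per peptide."""

    peptides: list[str]
    matrix: np.ndarray  # (n, d), float
    embedder: str

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != len(self.peptides):
            raise ValueError("one row per peptide required")
        if np.isnan(self.matrix).any():
            raise ValueError("embedding matrix contains missing values")

    @property
    def n(self) -> int:
        return len(self.peptides)

    @property
    def dim(self) -> int:
        return int(self.matrix.shape[1])


def _builtin_embed(peptides: Sequence[str]) -> np.ndarray:
    lengths = {len(p) for p in peptides}
    if len(lengths) != 1:
        raise ValueError("builtin embedder requires equal-length peptides")
    L = lengths.pop()
    n = len(peptides)
    out = np.zeros((n, N_DESCRIPTORS * L + len(AMINO_ACIDS)))
    aa_index = {aa: j for j, aa in enumerate(AMINO_ACIDS)}
    for i, pep in enumerate(peptides):
        comp = np.zeros(len(AMINO_ACIDS))
        for j, ch in enumerate(pep):
            w = NTERM_WEIGHT if j == 0 else 1.0
            try:
                out[i, j * N_DESCRIPTORS : j * N_DESCRIPTORS + 4] = _DESCRIPTORS[ch] * w
            except KeyError:
                raise ValueError(f"nonstandard residue {ch!r} in {pep!r}") from None
            if ch == "C":
                out[i, j * N_DESCRIPTORS + 4] = CYS_WEIGHT
            comp[aa_index[ch]] += 1
        out[i, N_DESCRIPTORS * L :] = comp * COMPOSITION_WEIGHT
    return out


def load_external_embeddings(
    path: str | Path, peptides: Sequence[str] | None = None
) -> EmbeddingMatrix:
    """Load a delimited numeric table (first column: peptide sequence).

    If ``peptides`` is given, rows are returned in that order and every
    requested peptide must be present (missing ones are listed in the
    error).
    """
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    df.index = df.index.astype(str)
    if peptides is not None:
        missing = sorted(set(peptides) - set(df.index))
        if missing:
            shown = ", ".join(missing[:10])
            more = f" (+{len(missing) - 10} more)" if len(missing) > 10 else ""
            raise ValueError(f"embeddings at {path} missing peptides: {shown}{more}")
        df = df.loc[list(peptides)]
    matrix = df.to_numpy(dtype=float)
    return EmbeddingMatrix(
        peptides=list(df.index), matrix=matrix, embedder=f"external_file:{path}"
    )


def embed_sequences(
    peptides: Sequence[str], embedder: str | Path = BUILTIN_EMBEDDER
) -> EmbeddingMatrix:
    """Embed peptides with the built-in embedder or an external file.

    ``embedder`` is either the string ``"builtin_physchem"`` or a path to a
    delimited embedding table. Identical peptides always receive identical
    rows for a given embedder.
    """
    peptides = list(peptides)
    if not peptides:
        raise ValueError("no peptides to embed")
    if str(embedder) == BUILTIN_EMBEDDER:
        return EmbeddingMatrix(
            peptides=peptides,
            matrix=_builtin_embed(peptides),
            embedder=BUILTIN_EMBEDDER,
        )
    return load_external_embeddings(embedder, peptides)
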