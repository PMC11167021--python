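"""Per-sample peptide count tables — the pipeline's central exchange object."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

FREQ_TOL = 1e-9

#: Columns of the serialized table, in order.
TABLE_COLUMNS = ["sample_id", "cell_line", "round", "peptide", "count", "frequency"]


@dataclass
class PeptideCountTable:
    """Counts and frequencies of amino-acid sequences in one sample.

    Frequencies are fractions of the *retained* reads of the full sample; a
    min-count filter (``min_count`` > 1) removes rows without renormalizing,
    so filtered frequencies still refer to the unfiltered total.
    """

    sample_id: str
    cell_line: str
    round_label: str
    data: pd.DataFrame  # columns: peptide, count, frequency
    rejections: dict[str, int] = field(default_factory=dict)
    min_count: int = 1

    @classmethod
    def from_counts(
        cls,
        counts: Mapping[str, int],
        sample_id: str,
        cell_line: str = "",
        round_label: str = "",
        rejections: Mapping[str, int] | None = None,
    ) -> "PeptideCountTable":
        if not counts:
            raise ValueError(f"sample {sample_id!r}: no retained sequences")
        total = sum(counts.values())
        df = pd.DataFrame(
            {"peptide": list(counts), "count": list(counts.values())}
        )
        df["frequency"] = df["count"] / total
        # deterministic ordering: descending count, ties lexicographic
        df = df.sort_values(
            ["count", "peptide"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
        return cls(
            sample_id=sample_id,
            cell_line=cell_line,
            round_label=round_label,
            data=df,
            rejections=dict(rejections or {}),
        )

    # -- totals ---------------------------------------------------------
    @property
    def total_reads(self) -> int:
        return int(self.data["count"].sum())

    @property
    def unique_sequences(self) -> int:
        return int(len(self.data))

    @property
    def peptides(self) -> list[str]:
        return self.data["peptide"].tolist()

    @property
    def peptide_length(self) -> int:
        return len(self.data["peptide"].iat[0])

    def frequency_of(self, peptide: str) -> float:
        hit = self.data.loc[self.data["peptide"] == peptide, "frequency"]
        return float(hit.iat[0]) if len(hit) else 0.0

    def validate(self) -> None:
        """Check structural invariants; raise AssertionError on violation."""
        df = self.data
        assert (df["count"] >= 1).all(), "counts must be >= 1"
        lengths = df["peptide"].str.len()
        assert lengths.nunique() == 1, "peptides must share one length"
        assert df["peptide"].str.fullmatch(r"[A-Z]+").all(), "non-residue characters"
        if self.min_count <= 1:
            assert abs(df["frequency"].sum() - 1.0) < FREQ_TOL, "frequencies must sum to 1"

    # -- serialization --------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "round", self.round_label)
        out.insert(0, "cell_line", self.cell_line)
        out.insert(0, "sample_id", self.sample_id)
        out.to_csv(path, sep="\t", index=False, float_format="%.12g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PeptideCountTable":
        df = pd.read_csv(path, sep="\t", dtype={"peptide": str})
        missing = set(TABLE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        meta = df.iloc[0]
        return cls(
            sample_id=str(meta["sample_id"]),
            cell_line=str(meta["cell_line"]) if pd.notna(meta["cell_line"]) else "",
            round_label=str(meta["round"]),
            data=df[["peptide", "count", "frequency"]].reset_index(drop=True),
        )

    def copy(self) -> "PeptideCountTable":
        return replace(self, data=self.data.copy(), rejections=dict(self.rejections))


# -- sample sheet -------------------------------------------------------

def write_sample_sheet(
    entries: Iterable[Mapping[str, str]], path: str | Path
) -> None:
    """Write a sample sheet (columns sample_id, cell_line, round, file)."""
    df = pd.DataFrame(list(entries), columns=["sample_id", "cell_line", "round", "file"])
    df.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "cell_line", "round", "file"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: sample sheet missing columns {sorted(missing)}")
    return df
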