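"""Amplicon decoding: flank trimming, NNK translation, counting.

Reads are matched on the forward strand only (single-direction
sequencing of a fixed-structure amplicon) with Hamming-distance flank
location — no indel alignment, which keeps behavior bit-exact and fast
for fixed-length inserts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pysam

from .codons import (
    AmberPolicy,
    Rejection,
    RejectionReason,
    TranslatedPeptide,
    translate_nnk,
)
from .count_table import PeptideCountTable


@dataclass(frozen=True)
class TrimSpec:
    """Flank sequences bracketing the insert and the matching tolerance."""

    flank5: str
    flank3: str
    insert_length: int
    max_mismatches: int = 1

    def __post_init__(self) -> None:
        if not self.flank5 or not self.flank3:
            raise ValueError("flanks must be nonempty")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if self.insert_length < 3:
            raise ValueError("insert_length must be >= 3")


def _find_flank(read: str, flank: str, start: int, max_mm: int) -> int:
    """Leftmost offset >= start where flank matches with <= max_mm Hamming
    mismatches (N always counts as a mismatch); -1 if none."""
    m = len(flank)
    for off in range(start, len(read) - m + 1):
        mm = 0
        for a, b in zip(read[off : off + m], flank):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        if mm <= max_mm:
            return off
    return -1


def trim_read(read: str, spec: TrimSpec) -> str | Rejection:
    """Extract the between-flank insert from one read.

    Locates flank5 first (leftmost acceptable match). flank3 is then tried
    at its expected fixed-amplicon position (``insert_length`` nucleotides
    downstream) before any scan — the amplicon has fixed structure, and an
    insert can legitimately contain flank-like codons (the downstream flank
    encodes a Gly/Ser linker), so scanning first would mis-trim such reads.
    A fallback scan only classifies the failure (wrong_length vs
    flank_not_found).
    """
    if not read:
        raise ValueError("empty read")
    read = read.upper()
    i5 = _find_flank(read, spec.flank5, 0, spec.max_mismatches)
    if i5 < 0:
        return Rejection(RejectionReason.FLANK_NOT_FOUND)
    insert_start = i5 + len(spec.flank5)
    expected = insert_start + spec.insert_length
    if (
        expected + len(spec.flank3) <= len(read)
        and _find_flank(
            read[expected : expected + len(spec.flank3)],
            spec.flank3,
            0,
            spec.max_mismatches,
        )
        == 0
    ):
        i3 = expected
    else:
        i3 = _find_flank(read, spec.flank3, insert_start, spec.max_mismatches)
        if i3 < 0:
            return Rejection(RejectionReason.FLANK_NOT_FOUND)
    insert = read[insert_start:i3]
    if len(insert) != spec.insert_length:
        return Rejection(RejectionReason.WRONG_LENGTH)
    if set(insert) - set("ACGT"):
        return Rejection(RejectionReason.AMBIGUOUS_BASE)
    return insert


def iter_fastq(path: str | Path) -> Iterator[str]:
    """Yield read sequences from a FASTQ file (gzip-transparent)."""
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            yield rec.sequence


def build_count_table(
    reads: Iterable[str],
    trim: TrimSpec,
    sample_id: str,
    cell_line: str = "",
    round_label: str = "",
    amber_policy: AmberPolicy = AmberPolicy.SUPPRESS_TO_Q,
) -> PeptideCountTable:
    """Trim, translate and aggregate a stream of read sequences.

    Retained translations are aggregated by identical amino-acid sequence;
    the table records counts, frequencies and per-reason rejection tallies
    (plus a ``non_nnk_codons`` tally of translated codons with a non-NNK
    third base, which are kept). Raises ValueError if nothing is retained.
    """
    counts: dict[str, int] = {}
    rejections = {reason.value: 0 for reason in RejectionReason}
    rejections["non_nnk_codons"] = 0
    n_total = 0
    for read in reads:
        n_total += 1
        insert = trim_read(read, trim)
        if isinstance(insert, Rejection):
            rejections[insert.reason.value] += 1
            continue
        result = translate_nnk(insert, amber_policy)
        if isinstance(result, Rejection):
            rejections[result.reason.value] += 1
            continue
        assert isinstance(result, TranslatedPeptide)
        rejections["non_nnk_codons"] += result.non_nnk_codons
        counts[result.peptide] = counts.get(result.peptide, 0) + 1
    if not counts:
        raise ValueError(f"sample {sample_id!r}: no reads retained")
    rejections["total_reads_in"] = n_total
    return PeptideCountTable.from_counts(
        counts,
        sample_id=sample_id,
        cell_line=cell_line,
        round_label=round_label,
        rejections=rejections,
    )


def decode_fastq(
    path: str | Path,
    trim: TrimSpec,
    sample_id: str,
    cell_line: str = "",
    round_label: str = "",
    amber_policy: AmberPolicy = AmberPolicy.SUPPRESS_TO_Q,
) -> PeptideCountTable:
    """Decode one FASTQ file into a peptide count table."""
    return build_count_table(
        iter_fastq(path), trim, sample_id, cell_line, round_label, amber_policy
    )
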