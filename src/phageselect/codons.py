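"""NNK degenerate codon table and codon-wise peptide translation.

An NNK codon has any base at positions 1-2 and G or T at position 3
(N = A/C/G/T, K = G/T), giving 32 codons that cover all 20 amino acids.
The only stop codon reachable under NNK is the amber codon TAG; libraries
amplified in amber-suppressor hosts (supE, e.g. XL-1 Blue) read TAG as
glutamine, so both amber policies are supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from Bio.Data import CodonTable as _BioCodonTable

NUCLEOTIDES = "ACGT"
NNK_THIRD_BASES = "GT"
AMBER_CODON = "TAG"
STOP_SYMBOL = "*"

#: Standard genetic code, codon -> one-letter amino acid ('*' for stops).
_table = _BioCodonTable.unambiguous_dna_by_id[1]
STANDARD_CODE: dict[str, str] = dict(_table.forward_table)
STANDARD_CODE.update({c: STOP_SYMBOL for c in _table.stop_codons})

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class AmberPolicy(str, Enum):
    """How the amber stop codon TAG is interpreted.

    SUPPRESS_TO_Q: TAG translated as glutamine (amber-suppressor host).
    DISCARD: any read/clone containing TAG is rejected.
    """

    SUPPRESS_TO_Q = "suppress_to_Q"
    DISCARD = "discard"


class RejectionReason(str, Enum):
    FLANK_NOT_FOUND = "flank_not_found"
    WRONG_LENGTH = "wrong_length"
    AMBIGUOUS_BASE = "ambiguous_base"
    STOP_CODON = "stop_codon"


@dataclass(frozen=True)
class Rejection:
    """Typed rejection of a read or insert, with the failing reason."""

    reason: RejectionReason

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"Rejection({self.reason.value})"


@dataclass(frozen=True)
class TranslatedPeptide:
    """A successfully translated insert.

    ``non_nnk_codons`` counts codons whose third base is A or C — impossible
    in a true NNK library, hence indicative of a sequencing error, but still
    translated (rejecting them would bias against real peptides observed
    through a single error).
    """

    peptide: str
    non_nnk_codons: int = 0


@dataclass(frozen=True)
class NNKCodonTable:
    """The 32 NNK codons, their translations, and per-residue multiplicities.

    ``multiplicity`` includes the amber stop under key '*' and sums to 32.
    """

    codon_to_aa: dict[str, str]
    multiplicity: dict[str, int]

    @property
    def codons(self) -> list[str]:
        return sorted(self.codon_to_aa)

    def amino_acid_probabilities(self, policy: AmberPolicy) -> dict[str, float]:
        """Per-position residue probabilities for an NNK draw.

        Under SUPPRESS_TO_Q the amber codon contributes to Q (20 residues,
        probabilities sum to 1 over 32 codons). Under DISCARD probabilities
        are conditional on the position not being a stop (denominator 31).
        """
        mult = dict(self.multiplicity)
        stop = mult.pop(STOP_SYMBOL, 0)
        if policy is AmberPolicy.SUPPRESS_TO_Q:
            mult["Q"] = mult.get("Q", 0) + stop
            denom = 32
        else:
            denom = 32 - stop
        return {aa: m / denom for aa, m in mult.items()}

    def synonymous_codons(self, aa: str, policy: AmberPolicy) -> list[str]:
        """All NNK codons encoding ``aa`` under the given amber policy."""
        codons = [c for c, a in self.codon_to_aa.items() if a == aa]
        if policy is AmberPolicy.SUPPRESS_TO_Q and aa == "Q":
            codons.append(AMBER_CODON)
        return sorted(codons)


def build_nnk_codon_table() -> NNKCodonTable:
    """Enumerate all 4 x 4 x 2 NNK codons against the standard genetic code."""
    codon_to_aa: dict[str, str] = {}
    multiplicity: dict[str, int] = {}
    for b1 in NUCLEOTIDES:
        for b2 in NUCLEOTIDES:
            for b3 in NNK_THIRD_BASES:
                codon = b1 + b2 + b3
                aa = STANDARD_CODE[codon]
                codon_to_aa[codon] = aa
                multiplicity[aa] = multiplicity.get(aa, 0) + 1
    return NNKCodonTable(codon_to_aa=codon_to_aa, multiplicity=multiplicity)


def translate_nnk(
    insert: str,
    amber_policy: AmberPolicy = AmberPolicy.SUPPRESS_TO_Q,
) -> TranslatedPeptide | Rejection:
    """Codon-wise translation of an NNK insert.

    TAG becomes Q under SUPPRESS_TO_Q and a ``stop_codon`` rejection under
    DISCARD; TAA/TGA are always rejected. Codons with a non-NNK third base
    (A/C) are translated but tallied in ``non_nnk_codons``.
    """
    insert = insert.upper()
    if len(insert) % 3 != 0:
        raise ValueError(f"insert length {len(insert)} not divisible by 3")
    residues: list[str] = []
    non_nnk = 0
    for i in range(0, len(insert), 3):
        codon = insert[i : i + 3]
        if any(b not in NUCLEOTIDES for b in codon):
            return Rejection(RejectionReason.AMBIGUOUS_BASE)
        if codon[2] not in NNK_THIRD_BASES:
            non_nnk += 1
        aa = STANDARD_CODE[codon]
        if aa == STOP_SYMBOL:
            if codon == AMBER_CODON and amber_policy is AmberPolicy.SUPPRESS_TO_Q:
                aa = "Q"
            else:
                return Rejection(RejectionReason.STOP_CODON)
        residues.append(aa)
    return TranslatedPeptide(peptide="".join(residues), non_nnk_codons=non_nnk)
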