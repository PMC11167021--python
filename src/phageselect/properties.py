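"""Peptide physicochemical properties: hydropathy, net charge, pI.

Three named constant sets drive the calculations:

* the Kyte–Doolittle hydropathy scale (mean over residues reported);
* the EMBOSS ``iep`` pKa set, used for isoelectric points;
* the Lehninger textbook pKa set, used for net charge at a given pH.

Net charge is the Henderson–Hasselbalch sum over ionizable groups —
each basic group (N-terminus, K, R, H) contributes ``+1/(1+10^(pH-pKa))``
and each acidic group (C-terminus, D, E, C, Y) ``-1/(1+10^(pKa-pH))`` —
and the pI is the unique pH where that sum vanishes (net charge is
strictly decreasing in pH, and the two termini guarantee a sign change
on (0, 14)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

#: Kyte & Doolittle residue hydropathy constants (original published scale).
KD_HYDROPATHY: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

BASIC_GROUPS = ("nterm", "K", "R", "H")
ACIDIC_GROUPS = ("cterm", "D", "E", "C", "Y")


@dataclass(frozen=True)
class PkaSet:
    """A named, published set of pKa constants for ionizable groups."""

    name: str
    pka: Mapping[str, float]  # keys: nterm, cterm, D, E, C, Y, H, K, R

    def __post_init__(self) -> None:
        for group in BASIC_GROUPS + ACIDIC_GROUPS:
            if group not in self.pka:
                raise ValueError(f"pKa set {self.name!r} missing group {group!r}")
            if not (0.0 < self.pka[group] < 14.0):
                raise ValueError(f"pKa for {group!r} outside (0, 14)")


#: EMBOSS ``iep`` default constants.
EMBOSS_PKA = PkaSet(
    name="EMBOSS",
    pka={
        "nterm": 8.6, "cterm": 3.6,
        "C": 8.5, "D": 3.9, "E": 4.1, "Y": 10.1,
        "H": 6.5, "K": 10.8, "R": 12.5,
    },
)

#: Lehninger (Principles of Biochemistry) free amino-acid table; the
#: glycine alpha-amino/alpha-carboxyl values stand in for the termini.
LEHNINGER_PKA = PkaSet(
    name="Lehninger",
    pka={
        "nterm": 9.69, "cterm": 2.34,
        "C": 8.33, "D": 3.86, "E": 4.25, "Y": 10.07,
        "H": 6.00, "K": 10.53, "R": 12.48,
    },
)

_PKA_SETS = {"EMBOSS": EMBOSS_PKA, "Lehninger": LEHNINGER_PKA}


def get_pka_set(name: str) -> PkaSet:
    try:
        return _PKA_SETS[name]
    except KeyError:
        raise ValueError(
            f"unknown pKa set {name!r}; available: {sorted(_PKA_SETS)}"
        ) from None


def _check_residues(peptide: str) -> None:
    if not peptide:
        raise ValueError("empty peptide")
    for ch in peptide:
        if ch not in KD_HYDROPATHY:
            raise ValueError(f"nonstandard residue {ch!r} in peptide {peptide!r}")


def kd_hydropathy(peptide: str) -> float:
    """Mean Kyte–Doolittle hydropathy over residues."""
    _check_residues(peptide)
    return sum(KD_HYDROPATHY[ch] for ch in peptide) / len(peptide)


def net_charge(peptide: str, pH: float = 7.4, pka: PkaSet = LEHNINGER_PKA) -> float:
    """Henderson–Hasselbalch net charge at ``pH`` (elementary charges)."""
    _check_residues(peptide)
    if not (0.0 < pH < 14.0):
        raise ValueError("pH must be in (0, 14)")
    counts = {"nterm": 1, "cterm": 1}
    for ch in peptide:
        if ch in pka.pka and ch not in ("nterm", "cterm"):
            counts[ch] = counts.get(ch, 0) + 1
    charge = 0.0
    for group, n in counts.items():
        k = pka.pka[group]
        if group in BASIC_GROUPS:
            charge += n / (1.0 + 10.0 ** (pH - k))
        else:
            charge -= n / (1.0 + 10.0 ** (k - pH))
    return charge


def isoelectric_point(
    peptide: str, pka: PkaSet = EMBOSS_PKA, tol: float = 1e-8
) -> float:
    """The pH in (0, 14) at which the net charge is zero (bisection root)."""
    _check_residues(peptide)
    lo, hi = 1e-6, 14.0 - 1e-6
    return float(brentq(lambda p: net_charge(peptide, p, pka), lo, hi, xtol=tol))


# -- vectorized internals (same math as the scalar functions; the scalar
# -- path doubles as their reference implementation in the test suite) ----

_GROUPS = BASIC_GROUPS + ACIDIC_GROUPS


def _group_counts(peptides: Sequence[str]) -> np.ndarray:
    """(n, 9) counts of ionizable groups in _GROUPS order."""
    out = np.empty((len(peptides), len(_GROUPS)))
    for i, p in enumerate(peptides):
        _check_residues(p)
        for j, g in enumerate(_GROUPS):
            out[i, j] = 1.0 if g in ("nterm", "cterm") else p.count(g)
    return out


def _net_charge_vec(counts: np.ndarray, pH: np.ndarray, pka: PkaSet) -> np.ndarray:
    """Net charge for each (peptide row, pH). pH broadcasts against rows."""
    pH = np.asarray(pH, float)
    charge = np.zeros(np.broadcast_shapes(counts.shape[:1], pH.shape))
    for j, g in enumerate(_GROUPS):
        k = pka.pka[g]
        if g in BASIC_GROUPS:
            charge = charge + counts[:, j] / (1.0 + 10.0 ** (pH - k))
        else:
            charge = charge - counts[:, j] / (1.0 + 10.0 ** (k - pH))
    return charge


def _isoelectric_point_vec(
    counts: np.ndarray, pka: PkaSet, iterations: int = 60
) -> np.ndarray:
    """Vectorized bisection for the zero-charge pH of each row."""
    lo = np.full(counts.shape[0], 1e-6)
    hi = np.full(counts.shape[0], 14.0 - 1e-6)
    for _ in range(iterations):
        mid = 0.5 * (lo + hi)
        pos = _net_charge_vec(counts, mid, pka) > 0
        lo = np.where(pos, mid, lo)
        hi = np.where(pos, hi, mid)
    return 0.5 * (lo + hi)


def _hydropathy_vec(peptides: Sequence[str]) -> np.ndarray:
    return np.array(
        [sum(KD_HYDROPATHY[ch] for ch in p) / len(p) for p in peptides]
    )


@dataclass(frozen=True)
class PropertyProfile:
    """The three reported properties of one peptide (or a cluster mean)."""

    peptide: str
    hydropathy: float  # Kyte-Doolittle units
    pI: float  # pH units (EMBOSS pKa set unless stated otherwise)
    charge: float  # elementary charges at charge_pH (Lehninger set)
    charge_pH: float = 7.4


def property_profile(
    peptide: str,
    charge_pH: float = 7.4,
    pi_pka: PkaSet = EMBOSS_PKA,
    charge_pka: PkaSet = LEHNINGER_PKA,
) -> PropertyProfile:
    return PropertyProfile(
        peptide=peptide,
        hydropathy=kd_hydropathy(peptide),
        pI=isoelectric_point(peptide, pi_pka),
        charge=net_charge(peptide, charge_pH, charge_pka),
        charge_pH=charge_pH,
    )


def property_table(
    peptides: Sequence[str],
    charge_pH: float = 7.4,
    pi_pka: PkaSet = EMBOSS_PKA,
    charge_pka: PkaSet = LEHNINGER_PKA,
) -> pd.DataFrame:
    """Per-peptide property table (peptide, hydropathy, pI, charge)."""
    peptides = list(peptides)
    counts = _group_counts(peptides)
    return pd.DataFrame(
        {
            "peptide": peptides,
            "hydropathy": _hydropathy_vec(peptides),
            "pI": _isoelectric_point_vec(counts, pi_pka),
            f"charge_pH{charge_pH:g}": _net_charge_vec(
                counts, np.array(charge_pH), charge_pka
            ),
        }
    )


def property_summary(
    peptides: Sequence[str],
    weights: Sequence[float] | None = None,
    charge_pH: float = 7.4,
    pi_pka: PkaSet = EMBOSS_PKA,
    charge_pka: PkaSet = LEHNINGER_PKA,
) -> PropertyProfile:
    """(Optionally weighted) arithmetic mean profile over member peptides."""
    if not len(peptides):
        raise ValueError("empty peptide set")
    w = np.ones(len(peptides)) if weights is None else np.asarray(weights, float)
    if w.shape != (len(peptides),) or (w < 0).any() or w.sum() <= 0:
        raise ValueError("invalid weights")
    w = w / w.sum()
    counts = _group_counts(peptides)
    hydro = float(w @ _hydropathy_vec(peptides))
    pi = float(w @ _isoelectric_point_vec(counts, pi_pka))
    chg = float(w @ _net_charge_vec(counts, np.array(charge_pH), charge_pka))
    return PropertyProfile(
        peptide="" if len(peptides) > 1 else peptides[0],
        hydropathy=float(hydro),
        pI=float(pi),
        charge=float(chg),
        charge_pH=charge_pH,
    )
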