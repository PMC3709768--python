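"""Theoretical protein properties: average mass, net charge, isoelectric point.

The charge model is the classical Henderson-Hasselbalch sum over ionizable
groups (free N- and C-terminus plus the side chains of Asp, Glu, Cys, Tyr,
His, Lys, Arg), with the Bjellqvist pKa set as shipped default.  The
isoelectric point is the unique root of the net charge, which is strictly
decreasing in pH, found by bisection.

Cysteine is treated as an ionizable free thiol (no disulfide modelling);
masses are average isotopic, not monoisotopic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from functools import cached_property
from typing import Union

import numpy as np

#: average isotopic residue masses (Da), ExPASy convention
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

#: mass of one water molecule (Da), added once per chain
WATER_MASS = 18.01524

_ACIDIC = ("D", "E", "C", "Y")
_BASIC = ("H", "K", "R")


@dataclass(frozen=True)
class PkaSet:
    """Acid dissociation constants (pH units) of the ionizable groups."""

    n_term: float
    c_term: float
    D: float
    E: float
    C: float
    Y: float
    H: float
    K: float
    R: float

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if not 0.0 < value < 14.0:
                raise ValueError(f"pKa {name}={value} outside (0, 14)")

    def side_chain(self, aa: str) -> float:
        return getattr(self, aa)

    @classmethod
    def from_dict(cls, values: dict) -> "PkaSet":
        """Build from a mapping, starting from the Bjellqvist defaults.

        Accepts the field names above; unknown keys raise.
        """
        known = set(BJELLQVIST.__dict__)
        extra = set(values) - known
        if extra:
            raise ValueError(f"unknown pKa keys: {sorted(extra)}")
        return replace(BJELLQVIST, **values)


#: Bjellqvist pKa set (the ExPASy Compute pI/Mw convention, simplified to
#: residue-independent termini)
BJELLQVIST = PkaSet(
    n_term=7.50, c_term=3.55,
    D=4.05, E=4.45, C=9.00, Y=10.00, H=5.98, K=10.00, R=12.00,
)


def _check_protein(protein: str) -> str:
    protein = protein.upper()
    bad = set(protein) - set(AVERAGE_RESIDUE_MASS)
    if bad:
        raise ValueError(f"nonstandard residue letters: {sorted(bad)}")
    return protein


def molecular_weight(protein: str) -> float:
    """Average molecular weight in Da: sum of residue masses plus one water.

    The empty chain therefore weighs one water (18.02 Da).  Display values
    are conventionally rounded to two decimals by the caller.
    """
    protein = _check_protein(protein)
    return sum(AVERAGE_RESIDUE_MASS[aa] for aa in protein) + WATER_MASS


def net_charge(
    protein: str,
    pH: Union[float, np.ndarray],
    pka: PkaSet = BJELLQVIST,
) -> Union[float, np.ndarray]:
    """Net charge (elementary units) at ``pH``; vectorized over pH arrays.

    q = 1/(1+10^(pH-pKa_Nterm)) + sum_basic n_i/(1+10^(pH-pKa_i))
        - 1/(1+10^(pKa_Cterm-pH)) - sum_acidic n_j/(1+10^(pKa_j-pH))
    """
    protein = _check_protein(protein)
    counts = Counter(protein)
    pH = np.asarray(pH, dtype=float)
    q = 1.0 / (1.0 + 10.0 ** (pH - pka.n_term))
    q = q - 1.0 / (1.0 + 10.0 ** (pka.c_term - pH))
    for aa in _BASIC:
        if counts[aa]:
            q = q + counts[aa] / (1.0 + 10.0 ** (pH - pka.side_chain(aa)))
    for aa in _ACIDIC:
        if counts[aa]:
            q = q - counts[aa] / (1.0 + 10.0 ** (pka.side_chain(aa) - pH))
    return float(q) if q.ndim == 0 else q


def isoelectric_point(
    protein: str,
    pka: PkaSet = BJELLQVIST,
    charge_tol: float = 1e-6,
    ph_tol: float = 1e-4,
) -> float:
    """pH at which the net charge vanishes, by bisection on (0, 14).

    The charge is strictly decreasing in pH and positive/negative at the
    interval ends for any chain with free termini, so the root exists and
    is unique.  Iterates until |q| < ``charge_tol`` or the bracket is
    narrower than ``ph_tol``.  The pH bracket is the primary stopping rule:
    for charge-flat chains (few ionizable groups near the pI) a loose
    charge tolerance would stop milli-pH-units away from the root, so the
    charge early-exit is deliberately conservative.
    """
    lo, hi = 0.0, 14.0
    while hi - lo > ph_tol:
        mid = 0.5 * (lo + hi)
        q = net_charge(protein, mid, pka)
        if abs(q) < charge_tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class SubunitProfile:
    """Electrophoretic profile of one subunit variant.

    Bundles the label (e.g. Hf, Hm, Hs for the H-subunit alleles, M for the
    muscle subunit), the protein sequence, and the derived pI, average MW
    and pH-dependent net charge used by the gel-mobility model.
    """

    label: str
    protein: str
    pka: PkaSet = BJELLQVIST

    def __post_init__(self) -> None:
        _check_protein(self.protein)
        if not self.protein:
            raise ValueError("subunit protein must be non-empty")

    @cached_property
    def pI(self) -> float:
        return isoelectric_point(self.protein, self.pka)

    @cached_property
    def mw(self) -> float:
        return molecular_weight(self.protein)

    def net_charge_at(self, pH: float) -> float:
        return net_charge(self.protein, pH, self.pka)

    @classmethod
    def from_protein(cls, label: str, protein: str, pka: PkaSet = BJELLQVIST) -> "SubunitProfile":
        return cls(label=label, protein=protein, pka=pka)
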