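"""Peptide mass arithmetic: monoisotopic residue masses, precursor and
fragment m/z.

These constants are the usual monoisotopic residue masses of the 20
standard amino acids; Cys is the unmodified residue (fixed modifications
enter through the per-position mass deltas carried by a PSM).
"""

from __future__ import annotations

from typing import Iterable, Sequence, Tuple

PROTON = 1.007276466879
WATER = 18.0105646863

#: Monoisotopic residue (i.e. water-free) masses in Da.
MONOISOTOPIC = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

STANDARD_RESIDUES = frozenset(MONOISOTOPIC)

Modification = Tuple[int, float]  # (1-based residue position, mass delta in Da)


def _check_sequence(peptide: str) -> None:
    bad = set(peptide) - STANDARD_RESIDUES
    if bad:
        raise ValueError(f"non-standard residues in {peptide!r}: {sorted(bad)}")


def peptide_mass(peptide: str, modifications: Iterable[Modification] = ()) -> float:
    """Monoisotopic neutral mass of a (possibly modified) peptide in Da."""
    _check_sequence(peptide)
    mass = WATER + sum(MONOISOTOPIC[aa] for aa in peptide)
    return mass + sum(delta for _, delta in modifications)


def precursor_mz(
    peptide: str, charge: int, modifications: Iterable[Modification] = ()
) -> float:
    """Theoretical precursor m/z for the given charge state."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (peptide_mass(peptide, modifications) + charge * PROTON) / charge


def fragment_mz(
    peptide: str,
    series: str,
    ordinal: int,
    fragment_charge: int,
    modifications: Sequence[Modification] = (),
) -> float:
    """m/z of a b- or y-series backbone fragment.

    b_k is the first k residues (neutral mass = residue sum); y_k the last
    k residues plus water. Modification deltas are attributed to the
    fragment that contains the modified residue position.
    """
    _check_sequence(peptide)
    n = len(peptide)
    if not 1 <= ordinal < n:
        raise ValueError(f"ordinal {ordinal} out of range for length {n}")
    if series == "b":
        residues = range(1, ordinal + 1)
        neutral = sum(MONOISOTOPIC[peptide[i - 1]] for i in residues)
    elif series == "y":
        residues = range(n - ordinal + 1, n + 1)
        neutral = WATER + sum(MONOISOTOPIC[peptide[i - 1]] for i in residues)
    else:
        raise ValueError(f"unknown ion series {series!r}")
    pos = set(residues)
    neutral += sum(delta for p, delta in modifications if p in pos)
    return (neutral + fragment_charge * PROTON) / fragment_charge


def ppm_error(measured: float, theoretical: float) -> float:
    """Relative mass error in parts per million."""
    return (measured - theoretical) / theoretical * 1e6
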