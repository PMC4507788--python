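"""Monoisotopic peptide and fragment-ion mass arithmetic.

Only singly/doubly protonated b and y ions are needed downstream; neutral
losses and other ion series are deliberately not modelled.
"""

from __future__ import annotations

# Monoisotopic residue masses (u), standard 20 amino acids.
RESIDUE_MASS: dict[str, float] = {
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

PROTON = 1.007276
WATER = 18.010565


class UnknownResidueError(ValueError):
    """Raised when a sequence contains a residue outside the standard 20."""


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("empty peptide sequence")
    for pos, res in enumerate(sequence, start=1):
        if res not in RESIDUE_MASS:
            raise UnknownResidueError(
                f"unknown residue {res!r} at position {pos} in {sequence!r}"
            )


def neutral_mass(sequence: str) -> float:
    """Monoisotopic neutral (uncharged) peptide mass in u."""
    _check_sequence(sequence)
    return sum(RESIDUE_MASS[r] for r in sequence) + WATER


def precursor_mz(sequence: str, charge: int) -> float:
    """m/z of the [M + charge*H]^charge+ precursor ion."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral_mass(sequence) + charge * PROTON) / charge


def fragment_mz(sequence: str, ion_type: str, ordinal: int, charge: int) -> float:
    """m/z of a b- or y-series fragment ion.

    b_k  : first ``ordinal`` residues, no water.
    y_k  : last ``ordinal`` residues, plus water.

    Parameters
    ----------
    sequence : peptide sequence (standard residues, uppercase).
    ion_type : ``"b"`` or ``"y"``.
    ordinal : fragment length, 1 <= ordinal <= len(sequence) - 1.
    charge : fragment charge, >= 1.
    """
    _check_sequence(sequence)
    if ion_type not in ("b", "y"):
        raise ValueError(f"ion_type must be 'b' or 'y', got {ion_type!r}")
    if not 1 <= ordinal <= len(sequence) - 1:
        raise ValueError(
            f"ordinal must be in [1, {len(sequence) - 1}] for a "
            f"{len(sequence)}-mer, got {ordinal}"
        )
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    if ion_type == "b":
        residues = sequence[:ordinal]
        neutral = sum(RESIDUE_MASS[r] for r in residues)
    else:
        residues = sequence[-ordinal:]
        neutral = sum(RESIDUE_MASS[r] for r in residues) + WATER
    return (neutral + charge * PROTON) / charge
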