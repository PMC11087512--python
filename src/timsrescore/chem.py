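"""Monoisotopic peptide chemistry: residue masses, modifications, peptide mass.

The supported modification chemistry mirrors a standard MaxQuant search of
synthetic-peptide pools: carbamidomethylation of cysteine as a fixed
modification (applied implicitly to every C unless a PSM is flagged as
carrying free cysteine side chains, in which case downstream feature
generation rejects it) and oxidation of methionine as a variable
modification.
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np

# Monoisotopic residue masses (Da), standard 20 amino acids.
RESIDUE_MASSES: dict[str, float] = {
    "G": 57.02146372,
    "A": 71.03711378,
    "S": 87.03202840,
    "P": 97.05276384,
    "V": 99.06841390,
    "T": 101.04767846,
    "C": 103.00918447,
    "L": 113.08406396,
    "I": 113.08406396,
    "N": 114.04292744,
    "D": 115.02694302,
    "Q": 128.05857750,
    "K": 128.09496301,
    "E": 129.04259308,
    "M": 131.04048508,
    "H": 137.05891186,
    "F": 147.06841390,
    "R": 156.10111102,
    "Y": 163.06332852,
    "W": 186.07931294,
}

PROTON = 1.00727646688
WATER = 18.0105646863

#: Modification mass deltas (Da) and the residue each may sit on.
MOD_DELTAS: dict[str, float] = {
    "Carbamidomethyl": 57.02146372,
    "Oxidation": 15.99491462,
}
MOD_TARGETS: dict[str, str] = {
    "Carbamidomethyl": "C",
    "Oxidation": "M",
}

Modifications = Mapping[int, str]  # 1-based position -> modification name


class UnsupportedPeptideError(ValueError):
    """Peptide carries chemistry outside the supported model."""


def validate_sequence(sequence: str) -> None:
    """Raise :class:`UnsupportedPeptideError` naming the first bad position."""
    for i, aa in enumerate(sequence, start=1):
        if aa not in RESIDUE_MASSES:
            raise UnsupportedPeptideError(
                f"unknown residue {aa!r} at position {i} in {sequence!r}"
            )


def _validate_modifications(sequence: str, modifications: Modifications) -> None:
    for pos, name in modifications.items():
        if name not in MOD_DELTAS:
            raise UnsupportedPeptideError(
                f"unsupported modification {name!r} at position {pos}"
            )
        if not 1 <= pos <= len(sequence):
            raise UnsupportedPeptideError(
                f"modification position {pos} outside peptide of length {len(sequence)}"
            )
        if sequence[pos - 1] != MOD_TARGETS[name]:
            raise UnsupportedPeptideError(
                f"modification {name!r} at position {pos} targets "
                f"{MOD_TARGETS[name]!r} but residue is {sequence[pos - 1]!r}"
            )


def residue_mass_array(
    sequence: str, modifications: Optional[Modifications] = None
) -> np.ndarray:
    """Per-residue monoisotopic masses including modification deltas.

    Carbamidomethylation is applied implicitly to every cysteine that does
    not already carry an explicit modification entry (fixed modification).
    """
    validate_sequence(sequence)
    mods = dict(modifications or {})
    _validate_modifications(sequence, mods)
    masses = np.array([RESIDUE_MASSES[aa] for aa in sequence], dtype=np.float64)
    for i, aa in enumerate(sequence, start=1):
        if i in mods:
            masses[i - 1] += MOD_DELTAS[mods[i]]
        elif aa == "C":
            masses[i - 1] += MOD_DELTAS["Carbamidomethyl"]
    return masses


def peptide_mass(sequence: str, modifications: Optional[Modifications] = None) -> float:
    """Neutral monoisotopic peptide mass (Da)."""
    return float(residue_mass_array(sequence, modifications).sum() + WATER)


def precursor_mz(
    sequence: str, charge: int, modifications: Optional[Modifications] = None
) -> float:
    """Theoretical precursor m/z (Th) for a given charge state."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (peptide_mass(sequence, modifications) + charge * PROTON) / charge
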