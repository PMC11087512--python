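"""Theoretical b/y fragment ions and the fixed 174-slot intensity-vector layout.

Fragment intensities for a peptide are stored in a fixed-length vector of
174 entries: 29 cleavage positions x 2 ion series (y before b) x 3 fragment
charges. Slots that cannot exist for a given peptide (cleavage position
beyond the peptide length, or fragment charge above the precursor charge)
carry the sentinel value -1 with a false validity mask. This layout is the
convention shared by fragment-intensity predictors of the Prosit lineage,
which makes observed and predicted spectra directly comparable slot by slot.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .chem import Modifications, PROTON, WATER, residue_mass_array, validate_sequence
from .spectra_io import PSM, Spectrum

__all__ = [
    "LAYOUT_SIZE",
    "MAX_POSITIONS",
    "MAX_VECTOR_CHARGE",
    "FragmentIon",
    "IntensityVector",
    "slot_index",
    "slot_decode",
    "valid_slot_mask",
    "layout_mz",
    "theoretical_ions",
    "annotate_spectrum",
    "match_ion_counts",
]

MAX_POSITIONS = 29          # cleavage positions 1..29 (peptides up to 30 residues)
MAX_VECTOR_CHARGE = 3       # fragment charges 1..3 live in the vector
LAYOUT_SIZE = MAX_POSITIONS * 2 * MAX_VECTOR_CHARGE  # = 174

_ION_OFFSET = {"y": 0, "b": 3}


@dataclass(frozen=True)
class FragmentIon:
    """One theoretical b or y ion."""

    ion_type: str  # "b" or "y"
    index: int     # cleavage index, 1..len-1
    charge: int    # fragment charge >= 1
    mz: float


@dataclass
class IntensityVector:
    """Fixed-layout fragment intensity vector with a validity mask.

    Invalid slots carry -1 in ``values`` and False in ``mask``; valid slots
    are non-negative, base-peak normalized when any entry is positive.
    """

    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != (LAYOUT_SIZE,) or self.mask.shape != (LAYOUT_SIZE,):
            raise ValueError(f"intensity vector must have {LAYOUT_SIZE} entries")


def slot_index(ion_type: str, index: int, charge: int) -> int:
    """Layout slot for a fragment (y before b within each position)."""
    if ion_type not in _ION_OFFSET:
        raise ValueError(f"ion_type must be 'b' or 'y', got {ion_type!r}")
    if not 1 <= index <= MAX_POSITIONS:
        raise ValueError(f"fragment index must be in [1, {MAX_POSITIONS}]")
    if not 1 <= charge <= MAX_VECTOR_CHARGE:
        raise ValueError(f"fragment charge must be in [1, {MAX_VECTOR_CHARGE}]")
    return (index - 1) * 6 + _ION_OFFSET[ion_type] + (charge - 1)


def slot_decode(slot: int) -> tuple[str, int, int]:
    """Inverse of :func:`slot_index`."""
    if not 0 <= slot < LAYOUT_SIZE:
        raise ValueError(f"slot must be in [0, {LAYOUT_SIZE})")
    index = slot // 6 + 1
    rem = slot % 6
    ion_type = "y" if rem < 3 else "b"
    charge = rem % 3 + 1
    return ion_type, index, charge


def valid_slot_mask(
    length: int, precursor_charge: int, max_fragment_charge: int = MAX_VECTOR_CHARGE
) -> np.ndarray:
    """Boolean mask of the slots that exist for a peptide/charge combination."""
    zmax = min(MAX_VECTOR_CHARGE, max_fragment_charge, precursor_charge)
    mask = np.zeros(LAYOUT_SIZE, dtype=bool)
    for index in range(1, min(length - 1, MAX_POSITIONS) + 1):
        for ion_type in ("y", "b"):
            for z in range(1, zmax + 1):
                mask[slot_index(ion_type, index, z)] = True
    return mask


def _series_masses(
    sequence: str, modifications: Optional[Modifications]
) -> tuple[np.ndarray, np.ndarray]:
    """Neutral b/y fragment masses for cleavage indices 1..len-1."""
    residues = residue_mass_array(sequence, modifications)
    prefix = np.cumsum(residues)
    b_neutral = prefix[:-1]                       # first i residues
    suffix = prefix[-1] - prefix[:-1]             # last i residues (reversed order)
    y_neutral = suffix[::-1] + WATER
    return b_neutral, y_neutral


def layout_mz(
    sequence: str,
    modifications: Optional[Modifications] = None,
    precursor_charge: int = MAX_VECTOR_CHARGE,
    max_fragment_charge: int = MAX_VECTOR_CHARGE,
) -> tuple[np.ndarray, np.ndarray]:
    """Theoretical m/z for every layout slot plus the validity mask.

    Invalid slots get m/z -1.
    """
    validate_sequence(sequence)
    mask = valid_slot_mask(len(sequence), precursor_charge, max_fragment_charge)
    mz = np.full(LAYOUT_SIZE, -1.0)
    b_neutral, y_neutral = _series_masses(sequence, modifications)
    zmax = min(MAX_VECTOR_CHARGE, max_fragment_charge, precursor_charge)
    for i in range(1, min(len(sequence) - 1, MAX_POSITIONS) + 1):
        for z in range(1, zmax + 1):
            mz[slot_index("y", i, z)] = (y_neutral[i - 1] + z * PROTON) / z
            mz[slot_index("b", i, z)] = (b_neutral[i - 1] + z * PROTON) / z
    return mz, mask


def theoretical_ions(
    sequence: str,
    modifications: Optional[Modifications] = None,
    max_fragment_charge: int = 1,
) -> list[FragmentIon]:
    """All theoretical b/y ions up to ``max_fragment_charge``.

    b(i, z) = (sum of the first i residue masses + z protons) / z and
    y(i, z) = (sum of the last i residue masses + water + z protons) / z,
    with monoisotopic residue masses including modification deltas.
    """
    if len(sequence) < 2:
        raise ValueError("sequence must have length >= 2")
    if max_fragment_charge < 1:
        raise ValueError("max_fragment_charge must be >= 1")
    b_neutral, y_neutral = _series_masses(sequence, modifications)
    ions: list[FragmentIon] = []
    for i in range(1, len(sequence)):
        for z in range(1, max_fragment_charge + 1):
            ions.append(FragmentIon("b", i, z, (b_neutral[i - 1] + z * PROTON) / z))
            ions.append(FragmentIon("y", i, z, (y_neutral[i - 1] + z * PROTON) / z))
    return ions


def _match_peaks(
    targets: np.ndarray, peak_mz: np.ndarray, peak_int: np.ndarray, tol_ppm: float
) -> np.ndarray:
    """Index of the matched peak for each target m/z, or -1.

    The nearest peak within ``tol_ppm`` of the theoretical m/z wins; an exact
    distance tie between the two flanking peaks is broken toward the higher
    intensity.
    """
    out = np.full(targets.shape, -1, dtype=np.int64)
    if peak_mz.size == 0:
        return out
    pos = np.searchsorted(peak_mz, targets)
    for k, t in enumerate(targets):
        if t <= 0:
            continue
        best = -1
        best_d = np.inf
        best_i = -np.inf
        for j in (pos[k] - 1, pos[k]):
            if 0 <= j < peak_mz.size:
                d = abs(peak_mz[j] - t)
                if d / t * 1e6 <= tol_ppm and (
                    d < best_d or (d == best_d and peak_int[j] > best_i)
                ):
                    best, best_d, best_i = j, d, peak_int[j]
        out[k] = best
    return out


def annotate_spectrum(
    spectrum: Spectrum,
    psm: PSM,
    tol_ppm: float = 40.0,
    max_fragment_charge: int = MAX_VECTOR_CHARGE,
) -> IntensityVector:
    """Map an observed spectrum onto the fragment-intensity layout.

    Each theoretical ion is matched to the nearest observed peak within
    ``tol_ppm``; matched intensities land at their layout slots, unmatched
    valid slots are 0, invalid slots are -1. Valid intensities are divided by
    the maximum matched intensity (base-peak normalization over annotated
    fragments); a spectrum with no matches stays all-zero.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    mz, mask = layout_mz(
        psm.sequence, psm.modifications, psm.precursor_charge, max_fragment_charge
    )
    values = np.where(mask, 0.0, -1.0)
    peak_mz = spectrum.mz_array
    peak_int = spectrum.intensity_array
    matched = _match_peaks(mz, peak_mz, peak_int, tol_ppm)
    hit = (matched >= 0) & mask
    values[hit] = peak_int[matched[hit]]
    peak_max = values[mask].max(initial=0.0)
    if peak_max > 0:
        values[mask] = values[mask] / peak_max
    return IntensityVector(values=values, mask=mask)


def match_ion_counts(
    spectrum: Spectrum,
    psm: PSM,
    tol_ppm: float = 40.0,
    max_fragment_charge: int = 4,
) -> dict[str, float]:
    """Matched b/y ion counts at fragment charges 1..``max_fragment_charge``.

    Charges above the vector's range (3) do not enter the intensity vector
    but are counted here for rescoring features. The fragment charge is
    capped at the precursor charge.
    """
    zmax = max(1, min(max_fragment_charge, psm.precursor_charge))
    ions = theoretical_ions(psm.sequence, psm.modifications, zmax)
    targets = np.array([ion.mz for ion in ions])
    matched = _match_peaks(targets, spectrum.mz_array, spectrum.intensity_array, tol_ppm)
    b_count = sum(1 for ion, m in zip(ions, matched) if m >= 0 and ion.ion_type == "b")
    y_count = sum(1 for ion, m in zip(ions, matched) if m >= 0 and ion.ion_type == "y")
    peak_int = spectrum.intensity_array
    matched_peaks = {int(m) for m in matched if m >= 0}
    matched_intensity = float(sum(peak_int[j] for j in matched_peaks))
    return {
        "matched_b_count": float(b_count),
        "matched_y_count": float(y_count),
        "matched_intensity": matched_intensity,
        "n_theoretical": float(len(ions)),
    }
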