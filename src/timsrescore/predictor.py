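"""Fragment-intensity predictor contract and a synthetic reference predictor.

Downstream stages (CE calibration, rescoring) only need an object with
``predict_intensities(sequence, modifications, precursor_charge, ce)`` and an
optional ``predict_irt(sequence, modifications)``. The synthetic predictor
implements that contract from a seeded ground-truth model in which every
fragment has a basal intensity and a Gaussian collision-energy response:

    intensity(slot, ce) = basal(slot) * exp(-(ce - ce_optimum(slot))^2 / (2 w^2))

Per-fragment basal intensities and CE optima are drawn deterministically
from a hash of (model seed, sequence, modifications, charge), so predictions
are bitwise reproducible, and a spectrum generated from the same model at
the same CE matches its prediction exactly (SA = 1). The per-fragment spread
of the CE optimum is what makes the collision energy identifiable from
fragment intensity ratios: with zero spread all CE settings produce
proportional vectors and SA is constant.
"""

from __future__ import annotations

import hashlib
import json
import urllib.request
from dataclasses import dataclass
from typing import Optional, Protocol, runtime_checkable

import numpy as np

from .annotation import LAYOUT_SIZE, IntensityVector, valid_slot_mask
from .chem import Modifications, validate_sequence

__all__ = [
    "PredictorContract",
    "GroundTruthModel",
    "SyntheticPredictor",
    "synthetic_predict",
    "KoinaPredictor",
]


@runtime_checkable
class PredictorContract(Protocol):
    """What the pipeline requires of any intensity/RT predictor."""

    def predict_intensities(
        self,
        sequence: str,
        modifications: Modifications,
        precursor_charge: int,
        collision_energy: float,
    ) -> IntensityVector: ...

    def predict_irt(
        self, sequence: str, modifications: Modifications
    ) -> Optional[float]: ...


@dataclass(frozen=True)
class GroundTruthModel:
    """Seeded synthetic fragmentation model with a Gaussian CE response.

    ``ce_optimum_center``/``ce_optimum_spread`` (eV) place each fragment's
    optimal collision energy; ``ce_width`` (eV) is the Gaussian width of the
    response; ``noise_sigma`` is the log-scale sigma of multiplicative
    intensity noise applied when *generating* observed spectra (predictions
    are always noise-free).
    """

    seed: int = 0
    ce_optimum_center: float = 30.0
    ce_optimum_spread: float = 8.0
    ce_width: float = 5.0
    noise_sigma: float = 0.0

    def fragment_params(
        self, sequence: str, modifications: Modifications, charge: int
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-slot basal intensities and CE optima, deterministic per peptide."""
        mods_key = ";".join(
            f"{p}:{n}" for p, n in sorted((modifications or {}).items())
        )
        key = f"{self.seed}|{sequence}|{mods_key}|{charge}".encode()
        child = int.from_bytes(hashlib.sha256(key).digest()[:4], "little")
        rng = np.random.default_rng(child)
        basal = rng.lognormal(0.0, 1.0, LAYOUT_SIZE)
        optimum = self.ce_optimum_center + self.ce_optimum_spread * rng.standard_normal(
            LAYOUT_SIZE
        )
        return basal, optimum

    def raw_intensities(
        self,
        sequence: str,
        modifications: Modifications,
        charge: int,
        ce: float,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Un-normalized valid-slot intensities and the validity mask."""
        if ce <= 0:
            raise ValueError("collision energy must be > 0")
        validate_sequence(sequence)
        basal, optimum = self.fragment_params(sequence, modifications, charge)
        mask = valid_slot_mask(len(sequence), charge)
        values = np.zeros(LAYOUT_SIZE)
        values[mask] = basal[mask] * np.exp(
            -((ce - optimum[mask]) ** 2) / (2.0 * self.ce_width**2)
        )
        return values, mask


def synthetic_predict(
    model: GroundTruthModel,
    sequence: str,
    modifications: Modifications,
    charge: int,
    ce: float,
) -> IntensityVector:
    """Predicted intensity vector: Gaussian CE response, base-peak normalized."""
    values, mask = model.raw_intensities(sequence, modifications, charge, ce)
    peak = values[mask].max(initial=0.0)
    if peak > 0:
        values[mask] = values[mask] / peak
    values[~mask] = -1.0
    return IntensityVector(values=values, mask=mask)


# Kyte-Doolittle hydropathy, used for a deterministic synthetic iRT proxy.
_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


class SyntheticPredictor:
    """Reference implementation of :class:`PredictorContract`.

    The iRT proxy is a hydropathy sum: deterministic, monotone in peptide
    hydrophobicity, and on a roughly indexed-retention-time-like scale. It
    stands in for a learned retention-time model in tests and examples.
    """

    def __init__(self, model: Optional[GroundTruthModel] = None):
        self.model = model or GroundTruthModel()

    def predict_intensities(
        self,
        sequence: str,
        modifications: Modifications,
        precursor_charge: int,
        collision_energy: float,
    ) -> IntensityVector:
        return synthetic_predict(
            self.model, sequence, modifications, precursor_charge, collision_energy
        )

    def predict_irt(
        self, sequence: str, modifications: Modifications
    ) -> Optional[float]:
        return float(sum(_KD[aa] for aa in sequence) * 10.0 / len(sequence))


class KoinaPredictor:
    """Optional HTTP adapter for a remotely served intensity model.

    Conforms to the same contract; requires network access and is never
    exercised by the test suite.
    """

    def __init__(
        self,
        model_name: str = "Prosit_2023_intensity_timsTOF",
        url: str = "https://koina.proteomicsdb.org",
        timeout: float = 30.0,
    ):
        self.model_name = model_name
        self.url = url.rstrip("/")
        self.timeout = timeout

    def predict_intensities(
        self,
        sequence: str,
        modifications: Modifications,
        precursor_charge: int,
        collision_energy: float,
    ) -> IntensityVector:
        payload = {
            "id": "0",
            "inputs": [
                {"name": "peptide_sequences", "shape": [1, 1], "datatype": "BYTES",
                 "data": [sequence]},
                {"name": "precursor_charges", "shape": [1, 1], "datatype": "INT32",
                 "data": [precursor_charge]},
                {"name": "collision_energies", "shape": [1, 1], "datatype": "FP32",
                 "data": [collision_energy]},
            ],
        }
        request = urllib.request.Request(
            f"{self.url}/v2/models/{self.model_name}/infer",
            data=json.dumps(payload).encode(),
            headers={"Content-Type": "application/json"},
        )
        with urllib.request.urlopen(request, timeout=self.timeout) as response:
            body = json.loads(response.read())
        intensities = None
        for output in body.get("outputs", []):
            if output.get("name") == "intensities":
                intensities = np.array(output["data"], dtype=np.float64)
        if intensities is None or intensities.size != LAYOUT_SIZE:
            raise RuntimeError("unexpected response from remote predictor")
        mask = intensities >= 0
        return IntensityVector(values=intensities, mask=mask)

    def predict_irt(
        self, sequence: str, modifications: Modifications
    ) -> Optional[float]:
        return None
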