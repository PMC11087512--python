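"""Spectral similarity between observed and predicted intensity vectors.

The primary measure is the normalized spectral contrast angle
SA = 1 - 2*arccos(<u, v>)/pi over L2-normalized non-negative vectors,
computed on the slots valid in *both* vectors (similarity is based on
annotated fragments only). SA is 1 for identical spectra and 0 for
orthogonal ones. Pearson correlation over the same slots is provided as an
auxiliary rescoring feature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .annotation import IntensityVector

__all__ = ["SimilarityScores", "spectral_angle", "pearson_similarity", "similarity_scores"]


@dataclass(frozen=True)
class SimilarityScores:
    spectral_angle: float
    pearson: float
    n_valid: int


def _joint_valid(observed: IntensityVector, predicted: IntensityVector):
    mask = observed.mask & predicted.mask
    a = np.clip(observed.values[mask], 0.0, None)
    b = np.clip(predicted.values[mask], 0.0, None)
    return a, b, mask


def spectral_angle(observed: IntensityVector, predicted: IntensityVector) -> float:
    """Normalized spectral contrast angle in [0, 1].

    Negative entries are clipped to 0 and both vectors are L2-normalized
    over the jointly valid slots. The angle is computed with the numerically
    stable form 2*atan2(|u - v|, |u + v|), which is exact at 0 and pi/2
    where the arccos of a rounded dot product loses precision (this replaces
    the usual clamp of the dot product into the arccos domain). An all-zero
    vector (or an empty joint mask) yields 0: a match with no shared
    fragment evidence scores minimally.
    """
    a, b, mask = _joint_valid(observed, predicted)
    if not mask.any():
        warnings.warn("no jointly valid slots; spectral angle set to 0")
        return 0.0
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    u = a / na
    v = b / nb
    angle = 2.0 * np.arctan2(np.linalg.norm(u - v), np.linalg.norm(u + v))
    return float(1.0 - 2.0 * angle / np.pi)


def pearson_similarity(observed: IntensityVector, predicted: IntensityVector) -> float:
    """Sample Pearson correlation over jointly valid slots; degenerate -> 0."""
    a, b, _ = _joint_valid(observed, predicted)
    if a.size < 2 or np.std(a) == 0.0 or np.std(b) == 0.0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def similarity_scores(
    observed: IntensityVector, predicted: IntensityVector
) -> SimilarityScores:
    _, _, mask = _joint_valid(observed, predicted)
    return SimilarityScores(
        spectral_angle=spectral_angle(observed, predicted),
        pearson=pearson_similarity(observed, predicted),
        n_valid=int(mask.sum()),
    )
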