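"""Collision-energy calibration.

The collision energy an instrument reports is not the energy a predictor
trained on other hardware expects. For each high-scoring PSM the optimal
collision energy is found by grid search: predict the spectrum across a CE
grid (default 5-45 eV in 1 eV steps), score each prediction against the
observed spectrum with the normalized spectral contrast angle, and take the
argmax. The offset reported_ce - optimal_ce is then modeled as a robust
linear function of peptide mass (RANSAC regression), fitted per stratum of
precursor charge x tryptic status with a pooled global fallback, and applied
to align every PSM's collision energy before intensity prediction.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.stats import median_abs_deviation
from sklearn.linear_model import LinearRegression, RANSACRegressor

from .annotation import IntensityVector, annotate_spectrum
from .errors import CalibrationError
from .predictor import PredictorContract
from .similarity import spectral_angle
from .spectra_io import PSM, Spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "GLOBAL_STRATUM",
    "CEObservation",
    "CalibrationModel",
    "ce_grid",
    "is_tryptic",
    "stratum_key",
    "optimal_ce",
    "select_calibration_psms",
    "collect_ce_observations",
    "fit_ce_calibration",
    "apply_calibration",
]

GLOBAL_STRATUM = "global"
DEFAULT_GRID = (5.0, 45.0, 1.0)


def ce_grid(lo: float = 5.0, hi: float = 45.0, step: float = 1.0) -> np.ndarray:
    """Ascending CE grid, inclusive of both endpoints."""
    if not lo < hi or step <= 0:
        raise ValueError("grid requires lo < hi and step > 0")
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


def is_tryptic(sequence: str) -> bool:
    """Tryptic status simplified to a C-terminal K or R."""
    return sequence[-1] in ("K", "R")


def stratum_key(precursor_charge: int, tryptic: bool) -> str:
    return f"z{precursor_charge}_{'tryptic' if tryptic else 'nontryptic'}"


def psm_stratum(psm: PSM) -> str:
    return stratum_key(psm.precursor_charge, is_tryptic(psm.sequence))


@dataclass(frozen=True)
class CEObservation:
    """One calibration data point."""

    peptide_mass: float
    reported_ce: float
    optimal_ce: float
    stratum: str = GLOBAL_STRATUM


@dataclass
class CalibrationModel:
    """Per-stratum linear mapping peptide mass -> CE offset (eV).

    ``strata`` maps stratum keys to (slope eV/Da, intercept eV); a pooled fit
    is stored under :data:`GLOBAL_STRATUM` and used for unmatched strata.
    ``provenance`` optionally records the peptide sequences the model was
    fitted on, enabling the train-split leak guard downstream.
    """

    strata: dict[str, tuple[float, float]]
    grid_lo: float = DEFAULT_GRID[0]
    grid_hi: float = DEFAULT_GRID[1]
    grid_step: float = DEFAULT_GRID[2]
    seed: int = 0
    provenance: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        if not self.grid_lo < self.grid_hi:
            raise ValueError("grid_lo must be < grid_hi")
        for key, (slope, intercept) in self.strata.items():
            if not (np.isfinite(slope) and np.isfinite(intercept)):
                raise ValueError(f"non-finite fit for stratum {key!r}")

    def predict_offset(self, stratum: str, peptide_mass: float) -> float:
        slope, intercept = self.strata.get(stratum, self.strata[GLOBAL_STRATUM])
        return slope * peptide_mass + intercept

    def to_json(self) -> str:
        return json.dumps(
            {
                "strata": {k: list(v) for k, v in self.strata.items()},
                "grid": [self.grid_lo, self.grid_hi, self.grid_step],
                "seed": self.seed,
                "provenance": sorted(self.provenance) if self.provenance else None,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "CalibrationModel":
        data = json.loads(text)
        prov = data.get("provenance")
        return cls(
            strata={k: (float(v[0]), float(v[1])) for k, v in data["strata"].items()},
            grid_lo=float(data["grid"][0]),
            grid_hi=float(data["grid"][1]),
            grid_step=float(data["grid"][2]),
            seed=int(data.get("seed", 0)),
            provenance=frozenset(prov) if prov is not None else None,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationModel":
        return cls.from_json(Path(path).read_text())


def optimal_ce(
    psm: PSM,
    observed: IntensityVector,
    predictor: PredictorContract,
    grid: Sequence[float] | np.ndarray,
) -> float:
    """CE on the grid whose predicted spectrum best matches the observation.

    Ties break toward the lowest collision energy (the grid is ascending and
    the first maximum wins).
    """
    grid = np.asarray(grid, dtype=np.float64)
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be non-empty and strictly ascending")
    best_ce = float(grid[0])
    best_sa = -np.inf
    for ce in grid:
        try:
            predicted = predictor.predict_intensities(
                psm.sequence, psm.modifications, psm.precursor_charge, float(ce)
            )
        except Exception as exc:
            raise CalibrationError(f"predictor failed for PSM {psm.psm_id}") from exc
        sa = spectral_angle(observed, predicted)
        if sa > best_sa:
            best_sa = sa
            best_ce = float(ce)
    return best_ce


def select_calibration_psms(
    psms: Iterable[PSM], k_per_charge: int = 100
) -> list[PSM]:
    """Top-``k_per_charge`` PSMs by search score within each precursor charge.

    Score ties break lexicographically on psm_id for determinism; charges
    with fewer PSMs contribute all of them.
    """
    if k_per_charge < 1:
        raise ValueError("k_per_charge must be >= 1")
    by_charge: dict[int, list[PSM]] = {}
    for psm in psms:
        by_charge.setdefault(psm.precursor_charge, []).append(psm)
    selected: list[PSM] = []
    for charge in sorted(by_charge):
        ranked = sorted(by_charge[charge], key=lambda p: (-p.search_score, p.psm_id))
        selected.extend(ranked[:k_per_charge])
    return selected


def collect_ce_observations(
    psms: Iterable[PSM],
    spectra_by_id: Mapping[str, Spectrum],
    predictor: PredictorContract,
    grid: Sequence[float] | np.ndarray,
    tol_ppm: float = 40.0,
) -> list[CEObservation]:
    """Annotate each PSM's spectrum and grid-search its optimal CE."""
    observations = []
    for psm in psms:
        spectrum = spectra_by_id[psm.spectrum_id]
        observed = annotate_spectrum(spectrum, psm, tol_ppm=tol_ppm)
        reported = psm.reported_ce if psm.reported_ce is not None else spectrum.reported_ce
        if reported is None:
            raise CalibrationError(f"PSM {psm.psm_id} has no reported collision energy")
        observations.append(
            CEObservation(
                peptide_mass=float(psm.peptide_mass),
                reported_ce=float(reported),
                optimal_ce=optimal_ce(psm, observed, predictor, grid),
                stratum=psm_stratum(psm),
            )
        )
    return observations


def _robust_line(
    mass: np.ndarray, delta: np.ndarray, seed: int
) -> tuple[float, float]:
    """RANSAC fit of delta-CE against mass; residual threshold = MAD of delta."""
    threshold = max(float(median_abs_deviation(delta)), 1e-9)
    x = mass.reshape(-1, 1)
    try:
        ransac = RANSACRegressor(
            estimator=LinearRegression(),
            residual_threshold=threshold,
            max_trials=100,
            random_state=seed,
        )
        ransac.fit(x, delta)
        line = ransac.estimator_
    except Exception:  # degenerate inputs: fall back to an ordinary fit
        line = LinearRegression().fit(x, delta)
    return float(line.coef_[0]), float(line.intercept_)


def fit_ce_calibration(
    observations: Iterable[CEObservation],
    grid: tuple[float, float, float] = DEFAULT_GRID,
    seed: int = 0,
    min_stratum_size: int = 10,
    provenance: Optional[Iterable[str]] = None,
) -> CalibrationModel:
    """Fit per-stratum robust linear models of CE offset vs peptide mass.

    Every stratum with at least ``min_stratum_size`` observations gets its
    own fit; smaller strata fall back to the pooled global fit with a
    warning.
    """
    observations = list(observations)
    if len(observations) < 2:
        raise CalibrationError("need at least 2 observations to fit a calibration")
    mass = np.array([o.peptide_mass for o in observations])
    delta = np.array([o.reported_ce - o.optimal_ce for o in observations])
    strata_names = sorted({o.stratum for o in observations})

    fits: dict[str, tuple[float, float]] = {
        GLOBAL_STRATUM: _robust_line(mass, delta, seed)
    }
    for name in strata_names:
        if name == GLOBAL_STRATUM:
            continue
        idx = np.array([o.stratum == name for o in observations])
        if idx.sum() < min_stratum_size:
            warnings.warn(
                f"stratum {name!r} has {int(idx.sum())} < {min_stratum_size} "
                "observations; falling back to the pooled global fit"
            )
            continue
        fits[name] = _robust_line(mass[idx], delta[idx], seed)

    return CalibrationModel(
        strata=fits,
        grid_lo=grid[0],
        grid_hi=grid[1],
        grid_step=grid[2],
        seed=seed,
        provenance=frozenset(provenance) if provenance is not None else None,
    )


def apply_calibration(model: CalibrationModel, psm: PSM) -> float:
    """Aligned CE = reported - predicted offset, clipped to the grid range."""
    if psm.reported_ce is None:
        raise CalibrationError(f"PSM {psm.psm_id} has no reported collision energy")
    offset = model.predict_offset(psm_stratum(psm), float(psm.peptide_mass))
    aligned = psm.reported_ce - offset
    return float(np.clip(aligned, model.grid_lo, model.grid_hi))
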