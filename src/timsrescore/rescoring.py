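"""Rescoring features, Percolator export, target-decoy q-values and comparison.

For every annotatable PSM a feature record is built from the similarity
between its observed spectrum and the intensity prediction at the calibrated
collision energy (spectral angle, Pearson correlation, matched-ion counts and
fractions, precursor mass error, length and charge indicators, optionally a
retention-time difference). Records can be exported in Percolator's PIN
dialect or rescored internally with a semi-supervised linear discriminant:
starting from the search score, confident targets (q <= FDR under the
current score) are contrasted against decoys in cross-validation folds for a
few iterations, and final q-values come from target-decoy competition.
"""

from __future__ import annotations

import logging
import math
import shutil
import subprocess
import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression

from .annotation import annotate_spectrum, match_ion_counts
from .ce_calibration import CalibrationModel, apply_calibration
from .chem import PROTON, UnsupportedPeptideError
from .errors import RescoringError
from .predictor import PredictorContract
from .similarity import pearson_similarity, spectral_angle
from .spectra_io import PSM, Spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureRecord",
    "RescoredPSM",
    "RunComparison",
    "compute_features",
    "compute_feature_table",
    "write_pin",
    "read_pin",
    "qvalues_tdc",
    "rescore",
    "score_baseline",
    "peptide_level_qvalues",
    "peptides_at_fdr",
    "compare_runs",
]


@dataclass
class FeatureRecord:
    """One row of rescoring features in Percolator terms."""

    psm_id: str
    label: int  # +1 target / -1 decoy
    scan_nr: int
    features: dict[str, float]
    peptide: str
    proteins: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.label not in (+1, -1):
            raise ValueError("label must be +1 (target) or -1 (decoy)")
        for name, value in self.features.items():
            if not math.isfinite(value):
                raise ValueError(
                    f"non-finite feature {name!r}={value} for {self.psm_id}"
                )


@dataclass
class RescoredPSM:
    psm_id: str
    peptide: str
    label: int
    score: float
    q_value: float
    pep_estimate: Optional[float] = None


@dataclass
class RunComparison:
    gained: set[str]
    shared: set[str]
    lost: set[str]
    fold_change: Optional[float]


def compute_features(
    psm: PSM,
    spectrum: Spectrum,
    predictor: PredictorContract,
    calibration: Optional[CalibrationModel] = None,
    tol_ppm: float = 40.0,
    scan_nr: int = 0,
) -> FeatureRecord:
    """Build the rescoring feature record for one PSM.

    Raises :class:`UnsupportedPeptideError` (reason "unsupported-residue")
    for peptides the predictor cannot model, e.g. free cysteine side chains.
    """
    if psm.free_cysteine and "C" in psm.sequence:
        raise UnsupportedPeptideError(
            f"unsupported-residue: free cysteine in {psm.psm_id}"
        )
    if calibration is not None:
        ce = apply_calibration(calibration, psm)
    else:
        ce = psm.aligned_ce
        if ce is None:
            ce = psm.reported_ce if psm.reported_ce is not None else spectrum.reported_ce
        if ce is None:
            raise ValueError(f"no collision energy available for PSM {psm.psm_id}")

    observed = annotate_spectrum(spectrum, psm, tol_ppm=tol_ppm)
    predicted = predictor.predict_intensities(
        psm.sequence, psm.modifications, psm.precursor_charge, float(ce)
    )
    counts = match_ion_counts(spectrum, psm, tol_ppm=tol_ppm, max_fragment_charge=4)

    mask = observed.mask
    n_valid = int(mask.sum())
    obs_valid = observed.values[mask]
    matched_frac = float((obs_valid > 0).sum() / n_valid) if n_valid else 0.0

    total_intensity = spectrum.total_intensity()
    intensity_explained = (
        counts["matched_intensity"] / total_intensity if total_intensity > 0 else 0.0
    )

    pred_valid = np.clip(predicted.values[mask & predicted.mask], 0.0, None)
    obs_joint = observed.values[mask & predicted.mask]
    pred_total = float(pred_valid.sum())
    missing_intensity_frac = (
        float(pred_valid[obs_joint <= 0].sum() / pred_total) if pred_total > 0 else 0.0
    )

    theo_mass = float(psm.peptide_mass)
    obs_mass = (spectrum.precursor_mz - PROTON) * spectrum.precursor_charge
    delta_mass_ppm = (obs_mass - theo_mass) / theo_mass * 1e6

    features: dict[str, float] = {
        "search_score": float(psm.search_score),
        "spectral_angle": spectral_angle(observed, predicted),
        "pearson": pearson_similarity(observed, predicted),
        "matched_y_count": counts["matched_y_count"],
        "matched_b_count": counts["matched_b_count"],
        "matched_frac": matched_frac,
        "intensity_explained": float(intensity_explained),
        "delta_mass_ppm": float(delta_mass_ppm),
        "missing_intensity_frac": missing_intensity_frac,
        "peptide_length": float(len(psm.sequence)),
    }
    for z in (1, 2, 3, 4):
        features[f"charge_{z}"] = float(
            psm.precursor_charge == z if z < 4 else psm.precursor_charge >= 4
        )
    if psm.retention_time is not None:
        irt = predictor.predict_irt(psm.sequence, psm.modifications)
        if irt is not None:
            features["abs_rt_diff"] = abs(float(psm.retention_time) - float(irt))

    return FeatureRecord(
        psm_id=psm.psm_id,
        label=-1 if psm.is_decoy else +1,
        scan_nr=scan_nr,
        features=features,
        peptide=psm.sequence,
    )


def compute_feature_table(
    psms: Sequence[PSM],
    spectra_by_id: Mapping[str, Spectrum],
    predictor: PredictorContract,
    calibration: Optional[CalibrationModel] = None,
    tol_ppm: float = 40.0,
) -> tuple[list[FeatureRecord], Counter]:
    """Feature records for all annotatable PSMs plus drop reasons/counts."""
    records: list[FeatureRecord] = []
    dropped: Counter = Counter()
    for i, psm in enumerate(psms):
        try:
            records.append(
                compute_features(
                    psm, spectra_by_id[psm.spectrum_id], predictor,
                    calibration=calibration, tol_ppm=tol_ppm, scan_nr=i,
                )
            )
        except UnsupportedPeptideError as exc:
            reason = str(exc).split(":", 1)[0]
            dropped[reason] += 1
            logger.info("dropped PSM %s: %s", psm.psm_id, exc)
    if dropped:
        logger.info("dropped %d PSMs: %s", sum(dropped.values()), dict(dropped))
    return records, dropped


# ---------------------------------------------------------------------------
# Percolator PIN
# ---------------------------------------------------------------------------

def write_pin(records: Sequence[FeatureRecord], path: str | Path) -> None:
    """Write records as a Percolator input (PIN) file.

    Columns: SpecId, Label, ScanNr, one column per feature (order taken from
    the first record), Peptide in flanked ``X.SEQUENCE.X`` form, Proteins.
    """
    if not records:
        raise ValueError("cannot write an empty PIN file")
    feature_names = list(records[0].features)
    for record in records:
        if list(record.features) != feature_names:
            raise ValueError(
                f"inconsistent feature set for record {record.psm_id!r}: "
                f"{sorted(record.features)} != {sorted(feature_names)}"
            )
    with open(path, "w") as handle:
        handle.write(
            "\t".join(["SpecId", "Label", "ScanNr", *feature_names,
                       "Peptide", "Proteins"]) + "\n"
        )
        for record in records:
            values = [f"{record.features[name]:.6f}" for name in feature_names]
            proteins = ";".join(record.proteins) or "-"
            handle.write(
                "\t".join([record.psm_id, str(record.label), str(record.scan_nr),
                           *values, f"X.{record.peptide}.X", proteins]) + "\n"
            )


def read_pin(path: str | Path) -> list[FeatureRecord]:
    """Read back a PIN file written by :func:`write_pin`."""
    records: list[FeatureRecord] = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        feature_names = header[3:-2]
        for line in handle:
            parts = line.rstrip("\n").split("\t")
            features = {
                name: float(value) for name, value in zip(feature_names, parts[3:-2])
            }
            peptide = parts[-2].split(".")[1]
            proteins = tuple(p for p in parts[-1].split(";") if p != "-")
            records.append(FeatureRecord(
                psm_id=parts[0], label=int(parts[1]), scan_nr=int(parts[2]),
                features=features, peptide=peptide, proteins=proteins,
            ))
    return records


# ---------------------------------------------------------------------------
# Target-decoy q-values
# ---------------------------------------------------------------------------

def qvalues_tdc(scores: Iterable[tuple[float, int]]) -> np.ndarray:
    """q-values by target-decoy competition, in the input order.

    ``scores`` is (score, label) with label +1 target / -1 decoy. At each
    threshold s, FDR(s) = #decoys >= s / max(1, #targets >= s); the q-value
    is the running minimum of FDR from the bottom of the ranking upward, so
    q is non-decreasing as the score decreases. Tied scores share a q.
    """
    pairs = list(scores)
    if not pairs:
        return np.array([])
    score = np.array([p[0] for p in pairs], dtype=np.float64)
    label = np.array([p[1] for p in pairs])
    if not (label == -1).any():
        warnings.warn("no decoys present; all q-values set to 0")
        return np.zeros(len(pairs))

    order = np.argsort(-score, kind="stable")
    s_sorted = score[order]
    d_cum = np.cumsum(label[order] == -1)
    t_cum = np.cumsum(label[order] == +1)

    # close tie groups: counts at the *last* index of each equal-score run
    n = len(pairs)
    fdr = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and s_sorted[j + 1] == s_sorted[i]:
            j += 1
        group_fdr = d_cum[j] / max(1, t_cum[j])
        fdr[i:j + 1] = group_fdr
        i = j + 1

    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty(n)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# Rescoring engines
# ---------------------------------------------------------------------------

def _feature_matrix(
    records: Sequence[FeatureRecord], feature_subset: Optional[Sequence[str]] = None
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    names = list(feature_subset) if feature_subset else list(records[0].features)
    X = np.array([[r.features[n] for n in names] for r in records], dtype=np.float64)
    y = np.array([r.label for r in records])
    return X, y, names


def _standardize(X: np.ndarray) -> np.ndarray:
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    return (X - mean) / std


def _internal_rescore(
    records: Sequence[FeatureRecord],
    fdr: float,
    seed: int,
    n_iterations: int,
    n_folds: int,
    feature_subset: Optional[Sequence[str]],
) -> np.ndarray:
    """Semi-supervised linear-discriminant rescoring; returns final scores."""
    X_raw, y, names = _feature_matrix(records, feature_subset)
    X = _standardize(X_raw)
    if "search_score" in names:
        scores = X_raw[:, names.index("search_score")].copy()
    else:
        scores = X[:, 0].copy()

    n = len(records)
    rng = np.random.default_rng(seed)
    fold = rng.permutation(n) % n_folds

    for _ in range(n_iterations):
        new_scores = scores.copy()
        for k in range(n_folds):
            if n_folds == 1:  # degenerate: fit and score on everything
                train = np.ones(n, dtype=bool)
                test = np.ones(n, dtype=bool)
            else:
                train = fold != k
                test = fold == k
            if not test.any():
                continue
            y_tr = y[train]
            if (y_tr == -1).sum() < 2 or (y_tr == +1).sum() < 2:
                continue
            q_tr = qvalues_tdc(list(zip(scores[train], y_tr)))
            positive = (y_tr == +1) & (q_tr <= fdr)
            if positive.sum() < 10:
                # too few confident targets: seed with the top-scoring ones
                target_idx = np.where(y_tr == +1)[0]
                k_top = min(len(target_idx), max(10, len(target_idx) // 20))
                top = target_idx[np.argsort(-scores[train][target_idx])[:k_top]]
                positive = np.zeros(len(y_tr), dtype=bool)
                positive[top] = True
            negative = y_tr == -1
            X_tr = X[train]
            X_fit = np.vstack([X_tr[positive], X_tr[negative]])
            y_fit = np.concatenate(
                [np.ones(int(positive.sum())), np.zeros(int(negative.sum()))]
            )
            clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
            clf.fit(X_fit, y_fit)
            decision = clf.decision_function(X[test])
            # make fold scores comparable: anchor on the training decoys
            decoy_decision = clf.decision_function(X_tr[negative])
            center = float(np.mean(decoy_decision))
            scale = float(np.std(decoy_decision))
            new_scores[test] = (decision - center) / (scale if scale > 0 else 1.0)
        scores = new_scores
    return scores


def _percolator_rescore(
    records: Sequence[FeatureRecord], fdr: float, seed: int, workdir: Path
) -> list[RescoredPSM]:
    binary = shutil.which("percolator")
    if binary is None:
        raise RescoringError(
            "the 'percolator' binary is not on PATH; install Percolator or use "
            "engine='internal'"
        )
    workdir.mkdir(parents=True, exist_ok=True)
    pin = workdir / "input.pin"
    out_psms = workdir / "percolator.psms.tsv"
    write_pin(records, pin)
    subprocess.run(
        [binary, "--results-psms", str(out_psms), "--seed", str(seed),
         "--testFDR", str(fdr), str(pin)],
        check=True, capture_output=True,
    )
    by_id = {r.psm_id: r for r in records}
    rescored: list[RescoredPSM] = []
    with open(out_psms) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        cols = {name: i for i, name in enumerate(header)}
        for line in handle:
            parts = line.rstrip("\n").split("\t")
            psm_id = parts[cols["PSMId"]]
            record = by_id[psm_id]
            rescored.append(RescoredPSM(
                psm_id=psm_id,
                peptide=record.peptide,
                label=record.label,
                score=float(parts[cols["score"]]),
                q_value=float(parts[cols["q-value"]]),
                pep_estimate=float(parts[cols["posterior_error_prob"]]),
            ))
    return rescored


def _pep_estimates(scores: np.ndarray, y: np.ndarray) -> Optional[np.ndarray]:
    """Posterior error probabilities from a logistic fit on the final score."""
    if len(np.unique(y)) < 2:
        return None
    try:
        clf = LogisticRegression()
        clf.fit(scores.reshape(-1, 1), (y == +1).astype(int))
        return 1.0 - clf.predict_proba(scores.reshape(-1, 1))[:, 1]
    except Exception:
        return None


def rescore(
    records: Sequence[FeatureRecord],
    engine: str = "internal",
    fdr: float = 0.01,
    seed: int = 0,
    n_iterations: int = 3,
    n_folds: int = 3,
    feature_subset: Optional[Sequence[str]] = None,
    workdir: Optional[str | Path] = None,
) -> list[RescoredPSM]:
    """Rescore feature records and assign PSM-level q-values.

    ``engine='internal'`` runs the semi-supervised linear-discriminant
    rescorer; ``engine='percolator'`` writes a PIN file and invokes the
    external binary.
    """
    if not records:
        raise ValueError("no records to rescore")
    if engine == "percolator":
        return _percolator_rescore(
            records, fdr, seed, Path(workdir or "percolator_work")
        )
    if engine != "internal":
        raise ValueError(f"unknown engine {engine!r}")

    scores = _internal_rescore(records, fdr, seed, n_iterations, n_folds,
                               feature_subset)
    y = np.array([r.label for r in records])
    q = qvalues_tdc(list(zip(scores, y)))
    peps = _pep_estimates(scores, y)
    return [
        RescoredPSM(
            psm_id=r.psm_id, peptide=r.peptide, label=r.label,
            score=float(scores[i]), q_value=float(q[i]),
            pep_estimate=float(peps[i]) if peps is not None else None,
        )
        for i, r in enumerate(records)
    ]


def score_baseline(records: Sequence[FeatureRecord]) -> list[RescoredPSM]:
    """q-values from the raw search score alone (no rescoring)."""
    scores = np.array([r.features["search_score"] for r in records])
    y = np.array([r.label for r in records])
    q = qvalues_tdc(list(zip(scores, y)))
    return [
        RescoredPSM(psm_id=r.psm_id, peptide=r.peptide, label=r.label,
                    score=float(scores[i]), q_value=float(q[i]))
        for i, r in enumerate(records)
    ]


def peptide_level_qvalues(rescored: Sequence[RescoredPSM]) -> list[RescoredPSM]:
    """Collapse to the best PSM per peptide sequence, then recompute q-values."""
    best: dict[tuple[str, int], RescoredPSM] = {}
    for psm in rescored:
        key = (psm.peptide, psm.label)
        if key not in best or psm.score > best[key].score:
            best[key] = psm
    peptides = list(best.values())
    q = qvalues_tdc([(p.score, p.label) for p in peptides])
    return [
        RescoredPSM(psm_id=p.psm_id, peptide=p.peptide, label=p.label,
                    score=p.score, q_value=float(q[i]), pep_estimate=p.pep_estimate)
        for i, p in enumerate(peptides)
    ]


def peptides_at_fdr(
    rescored: Sequence[RescoredPSM], fdr: float = 0.01
) -> set[str]:
    """Target peptide sequences accepted at the peptide-level q threshold."""
    return {
        p.peptide
        for p in peptide_level_qvalues(rescored)
        if p.label == +1 and p.q_value <= fdr
    }


def compare_runs(baseline: set[str], rescored: set[str]) -> RunComparison:
    """Gained/shared/lost peptides and the identification fold change."""
    return RunComparison(
        gained=rescored - baseline,
        shared=rescored & baseline,
        lost=baseline - rescored,
        fold_change=(len(rescored) / len(baseline)) if baseline else None,
    )
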