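"""Seeded synthetic datasets: peptides, pools, PSMs and timsTOF-like spectra.

The generator emulates the statistical structure of a pool-based synthetic
peptide measurement on a timsTOF: HLA-I-like peptide lengths (8-15),
precursor charges 1-3, an instrument collision-energy ramp that rises with
peptide mass, a mass-linear offset between the reported CE and the CE the
fragmentation model responds to, multiplicative log-normal intensity noise,
and composite MS/MS spectra split across PASEF frames by multinomial
thinning of integer peak counts (so summing the frames reproduces the
composite exactly). Correct target PSMs carry spectra generated from their
own peptide; incorrect targets and decoys carry spectra of unrelated
peptides, with the precursor m/z still taken from the claimed peptide, as a
search engine only proposes candidates inside the precursor tolerance. The
search score is drawn to correlate with correctness only weakly, so that
intensity-based features carry most of the separating signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .chem import PROTON, peptide_mass
from .dataset_prep import PoolDefinition
from .predictor import GroundTruthModel
from .spectra_io import PSM, Peak, Spectrum

__all__ = [
    "SyntheticDatasetSpec",
    "SyntheticDataset",
    "random_peptides",
    "generate_dataset",
    "generate_pools",
]

_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_INTENSITY_SCALE = 10_000  # counts at the base peak


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Study conditions for one synthetic benchmark dataset.

    ``ce_offset_slope``/``ce_offset_intercept`` plant the reported-minus-true
    CE relation the calibration stage must recover; ``score_separation`` is
    the mean search-score advantage of correct PSMs (in units comparable to
    ``score_sigma``), kept small so the score alone is weakly informative.
    """

    n_peptides: int = 1000
    length_range: tuple[int, int] = (8, 15)
    charge_distribution: tuple[tuple[int, float], ...] = ((1, 0.25), (2, 0.5), (3, 0.25))
    decoy_fraction: float = 0.5
    incorrect_target_fraction: float = 0.3
    ce_offset_slope: float = 0.01     # eV/Da
    ce_offset_intercept: float = -5.0  # eV
    noise_sigma: float = 0.3          # log-scale multiplicative intensity noise
    n_frames_per_spectrum: int = 5
    score_separation: float = 20.0
    score_sigma: float = 8.0
    cterm_kr_bias: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_peptides <= 0 or self.n_frames_per_spectrum <= 0:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.decoy_fraction < 1.0:
            raise ValueError("decoy_fraction must be in [0, 1)")


@dataclass
class SyntheticDataset:
    spectra: list[Spectrum]
    psms: list[PSM]
    truth: dict[str, bool]                     # psm_id -> correct?
    true_ce: dict[str, float]                  # psm_id -> generating CE (correct PSMs)
    frames: dict[str, list[Spectrum]]          # spectrum_id -> frame-level scans
    model: GroundTruthModel


def random_peptides(
    n: int,
    length_range: tuple[int, int] = (8, 15),
    seed: int = 0,
    substring_rate: float = 0.0,
    cterm_kr_bias: float = 0.0,
) -> list[str]:
    """``n`` unique random peptides; a ``substring_rate`` fraction are planted
    N-terminal truncations of other generated peptides (guaranteed substring
    pairs for split testing)."""
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    peptides: list[str] = []
    seen: set[str] = set()
    while len(peptides) < n:
        if peptides and substring_rate > 0 and rng.random() < substring_rate:
            parent = peptides[rng.integers(len(peptides))]
            if len(parent) > lo:
                cut = int(rng.integers(1, len(parent) - lo + 1))
                candidate = parent[cut:]
                if candidate not in seen:
                    peptides.append(candidate)
                    seen.add(candidate)
                continue
        length = int(rng.integers(lo, hi + 1))
        letters = rng.integers(0, len(_ALPHABET), length)
        candidate = "".join(_ALPHABET[i] for i in letters)
        if cterm_kr_bias > 0 and rng.random() < cterm_kr_bias:
            candidate = candidate[:-1] + ("K" if rng.random() < 0.5 else "R")
        if candidate not in seen:
            peptides.append(candidate)
            seen.add(candidate)
    return peptides


def _shuffle_decoy(sequence: str, rng: np.random.Generator) -> str:
    """Shuffle the sequence while fixing the C-terminal residue."""
    interior = list(sequence[:-1])
    for _ in range(10):
        rng.shuffle(interior)
        candidate = "".join(interior) + sequence[-1]
        if candidate != sequence:
            return candidate
    return "".join(interior) + sequence[-1]


def _reported_ce(mass: float) -> float:
    """Instrument-like CE ramp rising with peptide mass, clipped to 20-60 eV."""
    return float(np.clip(20.0 + 0.0125 * mass, 20.0, 60.0))


def _spectrum_counts(
    model: GroundTruthModel,
    sequence: str,
    charge: int,
    ce: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Integer peak counts per layout slot plus their theoretical m/z."""
    from .annotation import layout_mz  # local import to avoid cycles at import time

    values, mask = model.raw_intensities(sequence, {}, charge, ce)
    if model.noise_sigma > 0:
        noise = rng.lognormal(0.0, model.noise_sigma, values.shape)
        values[mask] *= noise[mask]
    peak = values[mask].max(initial=0.0)
    if peak > 0:
        values[mask] /= peak
    counts = np.rint(values * _INTENSITY_SCALE).astype(np.int64)
    counts[~mask] = 0
    mz, _ = layout_mz(sequence, None, charge)
    keep = (counts > 0) & (mz > 0)
    return mz[keep], counts[keep]


def _split_frames(
    counts: np.ndarray, n_frames: int, rng: np.random.Generator
) -> np.ndarray:
    """Multinomial split of each peak's counts across frames (exact total)."""
    out = np.zeros((n_frames, counts.size), dtype=np.int64)
    for j, c in enumerate(counts):
        out[:, j] = rng.multinomial(int(c), np.full(n_frames, 1.0 / n_frames))
    return out


def generate_dataset(spec: SyntheticDatasetSpec) -> SyntheticDataset:
    """Generate a full benchmark dataset, deterministic in ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    model = GroundTruthModel(seed=spec.seed, noise_sigma=spec.noise_sigma)

    n = spec.n_peptides
    n_decoy = int(round(n * spec.decoy_fraction))
    n_target = n - n_decoy
    n_incorrect = int(round(n_target * spec.incorrect_target_fraction))

    lengths = spec.length_range
    targets = random_peptides(
        n_target, lengths, seed=int(rng.integers(2**31)),
        cterm_kr_bias=spec.cterm_kr_bias,
    )
    correct_flags = np.zeros(n_target, dtype=bool)
    correct_flags[: n_target - n_incorrect] = True
    rng.shuffle(correct_flags)

    charges, probs = zip(*spec.charge_distribution)
    charges = np.array(charges)
    probs = np.array(probs) / np.sum(probs)

    # pre-draw unrelated "true but unidentified" source peptides
    n_unrelated = n_incorrect + n_decoy
    unrelated = random_peptides(
        max(n_unrelated, 1), lengths, seed=int(rng.integers(2**31)),
        cterm_kr_bias=spec.cterm_kr_bias,
    )

    spectra: list[Spectrum] = []
    psms: list[PSM] = []
    truth: dict[str, bool] = {}
    true_ce: dict[str, float] = {}
    frames_map: dict[str, list[Spectrum]] = {}

    unrelated_iter = iter(unrelated)

    def _emit(i: int, claimed: str, is_decoy: bool, correct: bool) -> None:
        psm_id = f"psm{i:05d}"
        spectrum_id = f"spec{i:05d}"
        charge = int(rng.choice(charges, p=probs))
        source = claimed if correct else next(unrelated_iter)
        mass_claimed = peptide_mass(claimed)
        mass_source = peptide_mass(source)
        reported = _reported_ce(mass_claimed)
        ce_source = _reported_ce(mass_source) - (
            spec.ce_offset_slope * mass_source + spec.ce_offset_intercept
        )
        mz, counts = _spectrum_counts(model, source, charge, ce_source, rng)
        order = np.argsort(mz)
        mz, counts = mz[order], counts[order]
        # collapse exact m/z coincidences so peaks stay strictly ascending
        uniq_mz, inverse = np.unique(mz, return_inverse=True)
        uniq_counts = np.zeros(uniq_mz.size, dtype=np.int64)
        np.add.at(uniq_counts, inverse, counts)

        frame_counts = _split_frames(uniq_counts, spec.n_frames_per_spectrum, rng)
        precursor = (mass_claimed + charge * PROTON) / charge
        precursor *= 1.0 + rng.normal(0.0, 3e-6)

        composite = Spectrum(
            spectrum_id=spectrum_id,
            peaks=[Peak(float(m), float(c)) for m, c in zip(uniq_mz, uniq_counts)],
            precursor_mz=float(precursor),
            precursor_charge=charge,
            reported_ce=reported,
            source_frames=list(range(spec.n_frames_per_spectrum)),
        )
        frame_specs = [
            Spectrum(
                spectrum_id=f"{spectrum_id}.frame{k}",
                peaks=[
                    Peak(float(m), float(c))
                    for m, c in zip(uniq_mz, frame_counts[k])
                    if c > 0
                ],
                precursor_mz=float(precursor),
                precursor_charge=charge,
                reported_ce=reported,
                source_frames=[k],
            )
            for k in range(spec.n_frames_per_spectrum)
        ]

        score_mean = 50.0 + (spec.score_separation if correct else 0.0)
        score = float(max(0.0, rng.normal(score_mean, spec.score_sigma)))
        pep = float(np.clip(1.0 / (1.0 + np.exp((score - 55.0) / 5.0)), 1e-6, 1.0))

        psm = PSM(
            psm_id=psm_id,
            spectrum_id=spectrum_id,
            sequence=claimed,
            modifications={},
            precursor_charge=charge,
            search_score=score,
            pep=pep,
            is_decoy=is_decoy,
            reported_ce=reported,
        )
        spectra.append(composite)
        psms.append(psm)
        truth[psm_id] = correct
        if correct:
            true_ce[psm_id] = ce_source
        frames_map[spectrum_id] = frame_specs

    for i in range(n_target):
        _emit(i, targets[i], is_decoy=False, correct=bool(correct_flags[i]))
    for k in range(n_decoy):
        base = targets[int(rng.integers(n_target))]
        _emit(n_target + k, _shuffle_decoy(base, rng), is_decoy=True, correct=False)

    return SyntheticDataset(
        spectra=spectra, psms=psms, truth=truth, true_ce=true_ce,
        frames=frames_map, model=model,
    )


def generate_pools(
    n_pools: int,
    peptides_per_pool: int,
    seed: int = 0,
    truncation_rate: float = 0.0,
    length_range: tuple[int, int] = (9, 14),
) -> tuple[list[PoolDefinition], dict[str, list[str]]]:
    """Synthesis pools of unique full-length peptides plus planted truncations.

    Returns the pools and, per pool, a list of N-terminally truncated (suffix)
    variants of ``truncation_rate * peptides_per_pool`` expected peptides;
    the variants are what a curation stage should accept via the suffix rule.
    """
    rng = np.random.default_rng(seed)
    all_peptides = random_peptides(
        n_pools * peptides_per_pool, length_range, seed=int(rng.integers(2**31))
    )
    pools: list[PoolDefinition] = []
    planted: dict[str, list[str]] = {}
    n_truncated = int(round(truncation_rate * peptides_per_pool))
    for p in range(n_pools):
        members = all_peptides[p * peptides_per_pool:(p + 1) * peptides_per_pool]
        pool_id = f"pool{p:03d}"
        pools.append(PoolDefinition(pool_id, frozenset(members)))
        variants: list[str] = []
        for seq in members[:n_truncated]:
            if len(seq) > 7:
                cut = int(rng.integers(1, len(seq) - 7 + 1))
                variants.append(seq[cut:])
        planted[pool_id] = variants
    return pools, planted
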