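"""Ground-truth dataset curation and leak-free train/validation/test splits.

Synthetic-peptide pool searches yield PSM tables that must be reduced to a
trustworthy ground truth: keep only the top PSM per spectrum, PSMs below a
posterior-error-probability ceiling, peptides actually expected in their
pool (full length or N-terminally truncated, i.e. a suffix of an expected
peptide), and search scores above a floor. For model training the peptides
are then split so that no peptide in one partition is a contiguous
subsequence of a peptide in another — otherwise shared b/y fragment ladders
would leak information between train and test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .ce_calibration import CalibrationModel, apply_calibration
from .errors import LeakGuardError
from .spectra_io import PSM

logger = logging.getLogger(__name__)

__all__ = [
    "PARTITIONS",
    "PoolDefinition",
    "SplitAssignment",
    "curate_psms",
    "leakfree_split",
    "assign_training_ce",
]

PARTITIONS = ("train", "validation", "test")


@dataclass(frozen=True)
class PoolDefinition:
    """A synthesis pool: the peptides expected in its pool-specific search."""

    pool_id: str
    expected_peptides: frozenset[str]

    def __post_init__(self) -> None:
        if not self.expected_peptides:
            raise ValueError(f"pool {self.pool_id!r} has no expected peptides")


@dataclass
class SplitAssignment:
    """Peptide -> partition mapping with the requested fractions and seed."""

    assignment: dict[str, str]
    fractions: tuple[float, float, float]
    seed: int
    n_groups: int = 0

    def partition(self, name: str) -> set[str]:
        return {seq for seq, part in self.assignment.items() if part == name}

    def realized_fractions(self) -> dict[str, float]:
        total = len(self.assignment)
        return {
            name: len(self.partition(name)) / total if total else 0.0
            for name in PARTITIONS
        }


def curate_psms(
    psms: Sequence[PSM],
    pools: Mapping[str, PoolDefinition],
    min_length: int = 7,
    max_pep: float = 0.01,
    min_score: float = 70.0,
) -> list[PSM]:
    """Filter pool-search PSMs down to ground-truth quality.

    Keeps, in order: (1) the highest-scoring PSM per spectrum; (2) PSMs with
    PEP below ``max_pep``; (3) sequences equal to an expected pool peptide or
    an N-terminal truncation of one (a suffix), at least ``min_length``
    residues; (4) search score at or above ``min_score``. Duplicate
    identifications of the same peptide across spectra are retained.
    """
    # (1) top PSM per spectrum (score ties break on psm_id)
    best: dict[str, PSM] = {}
    for psm in psms:
        if psm.pool_id is None or psm.pool_id not in pools:
            raise KeyError(f"PSM {psm.psm_id} references unknown pool {psm.pool_id!r}")
        current = best.get(psm.spectrum_id)
        if (
            current is None
            or psm.search_score > current.search_score
            or (psm.search_score == current.search_score and psm.psm_id < current.psm_id)
        ):
            best[psm.spectrum_id] = psm

    curated: list[PSM] = []
    for psm in best.values():
        if not psm.pep < max_pep:  # (2)
            continue
        if len(psm.sequence) < min_length:  # (3) length floor
            continue
        expected = pools[psm.pool_id].expected_peptides
        if not any(full.endswith(psm.sequence) for full in expected):  # (3)
            continue
        if psm.search_score < min_score:  # (4)
            continue
        curated.append(psm)
    curated.sort(key=lambda p: p.psm_id)
    return curated


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _containment_groups(sequences: Sequence[str]) -> list[list[int]]:
    """Connected components under contiguous-substring containment.

    Every substring of each sequence (down to the shortest sequence length
    present) is looked up against the full set, so any containment pair is
    found without an all-pairs scan.
    """
    index = {seq: i for i, seq in enumerate(sequences)}
    min_len = min(len(s) for s in sequences)
    uf = _UnionFind(len(sequences))
    for i, seq in enumerate(sequences):
        for sub_len in range(min_len, len(seq)):
            for start in range(len(seq) - sub_len + 1):
                j = index.get(seq[start:start + sub_len])
                if j is not None:
                    uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(len(sequences)):
        groups.setdefault(uf.find(i), []).append(i)
    return list(groups.values())


def leakfree_split(
    sequences: Iterable[str],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitAssignment:
    """Split peptides into train/validation/test with no cross-partition
    substring containment.

    Sequences connected by contiguous-substring containment (transitively)
    form groups; groups are shuffled with the seed and assigned greedily to
    the partition currently furthest below its target count, so every
    co-containing family lands in a single partition and the realized
    fractions track the requested ones.
    """
    sequences = list(dict.fromkeys(sequences))  # dedupe, keep order
    if not sequences:
        return SplitAssignment({}, fractions, seed, 0)
    if any(f <= 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be positive and sum to 1")

    groups = _containment_groups(sequences)
    groups.sort(key=lambda g: min(g))  # deterministic order before shuffling
    rng = np.random.default_rng(seed)
    rng.shuffle(groups)

    n = len(sequences)
    targets = [f * n for f in fractions]
    assigned = [0, 0, 0]
    assignment: dict[str, str] = {}
    for group in groups:
        deficits = [targets[k] - assigned[k] for k in range(3)]
        k = int(np.argmax(deficits))  # ties break toward train
        for i in group:
            assignment[sequences[i]] = PARTITIONS[k]
        assigned[k] += len(group)
    return SplitAssignment(assignment, fractions, seed, len(groups))


def assign_training_ce(
    psms: Sequence[PSM],
    calibration: CalibrationModel,
    split: SplitAssignment,
) -> list[PSM]:
    """Annotate every PSM with its aligned collision energy.

    Leak guard: the calibration model must record its fitting provenance and
    every peptide it was fitted on must sit in the training partition;
    otherwise information from validation/test peptides would leak into the
    calibration applied to them.
    """
    if calibration.provenance is None:
        raise LeakGuardError(
            "calibration model has no provenance; fit it with provenance= the "
            "training peptide sequences"
        )
    for seq in calibration.provenance:
        if split.assignment.get(seq) != "train":
            raise LeakGuardError(
                f"calibration model was fitted on {seq!r}, which is in partition "
                f"{split.assignment.get(seq)!r}, not 'train'"
            )
    return [psm.with_aligned_ce(apply_calibration(calibration, psm)) for psm in psms]
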