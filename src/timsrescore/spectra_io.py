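"""Spectrum and PSM I/O plus PASEF frame-level scan summation.

Readers cover the formats the pipeline touches in practice: MGF peak lists
(the deposited format for timsTOF synthetic-peptide runs), centroided mzML,
and the MaxQuant output tables ``msms.txt`` / ``accumulatedMsmsScans.txt`` /
``pasefMsmsScans.txt`` that link a PSM to the PASEF frames its spectrum was
accumulated from. A composite MS/MS spectrum is built by summing the
frame-level scans, merging peaks that agree within a ppm tolerance.
"""

from __future__ import annotations

import logging
import math
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf
from pyteomics import mzml as _mzml

from .chem import Modifications, peptide_mass
from .errors import MGFParseError, MissingColumnError

logger = logging.getLogger(__name__)

__all__ = [
    "Peak",
    "Spectrum",
    "PSM",
    "read_mgf",
    "write_mgf",
    "read_mzml",
    "read_maxquant_tables",
    "sum_frame_scans",
    "read_psm_table",
    "write_psm_table",
]


@dataclass(frozen=True)
class Peak:
    """A single centroided peak: m/z in Th, intensity in arbitrary units."""

    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be >= 0, got {self.intensity}")


@dataclass
class Spectrum:
    """One composite MS/MS peak list with precursor metadata.

    Peaks are sorted ascending by m/z at construction. ``source_frames``
    carries the PASEF frame identifiers the spectrum was summed from, when
    known.
    """

    spectrum_id: str
    peaks: list[Peak]
    precursor_mz: float
    precursor_charge: int
    reported_ce: Optional[float] = None
    source_frames: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.precursor_charge < 1:
            raise ValueError("precursor_charge must be >= 1")
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks], dtype=np.float64)

    @property
    def intensity_array(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks], dtype=np.float64)

    def total_intensity(self) -> float:
        return math.fsum(p.intensity for p in self.peaks)


@dataclass
class PSM:
    """A peptide-spectrum match in MaxQuant-like terms.

    ``search_score`` is an Andromeda-like score, ``pep`` the posterior error
    probability. ``peptide_mass`` is the neutral monoisotopic mass; when not
    given it is computed from sequence and modifications, and when given it
    must agree with the computed value within 1e-4 Da.
    """

    psm_id: str
    spectrum_id: str
    sequence: str
    modifications: Modifications
    precursor_charge: int
    search_score: float
    pep: float
    is_decoy: bool
    peptide_mass: Optional[float] = None
    reported_ce: Optional[float] = None
    pool_id: Optional[str] = None
    free_cysteine: bool = False
    retention_time: Optional[float] = None
    aligned_ce: Optional[float] = None

    def __post_init__(self) -> None:
        if not 7 <= len(self.sequence) <= 30:
            raise ValueError(
                f"peptide length must be in [7, 30], got {len(self.sequence)} "
                f"for {self.sequence!r}"
            )
        if not 0.0 <= self.pep <= 1.0:
            raise ValueError(f"PEP must be in [0, 1], got {self.pep}")
        computed = peptide_mass(self.sequence, self.modifications)
        if self.peptide_mass is None:
            self.peptide_mass = computed
        elif abs(self.peptide_mass - computed) > 1e-4:
            raise ValueError(
                f"peptide_mass {self.peptide_mass} inconsistent with "
                f"sequence+modifications ({computed:.5f}) for {self.psm_id}"
            )

    def with_aligned_ce(self, ce: float) -> "PSM":
        return replace(self, aligned_ce=ce)


# ---------------------------------------------------------------------------
# MGF
# ---------------------------------------------------------------------------

def _first_charge(charge_param) -> Optional[int]:
    try:
        seq = list(charge_param)
    except TypeError:
        seq = [charge_param]
    if not seq:
        return None
    return abs(int(seq[0]))


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read an MGF file into :class:`Spectrum` records.

    One spectrum per BEGIN IONS block; TITLE becomes the spectrum id,
    PEPMASS the precursor m/z, CHARGE the precursor charge. Blocks without a
    CHARGE entry are skipped with a warning; a malformed block raises
    :class:`MGFParseError` naming the block index (0-based).
    """
    spectra: list[Spectrum] = []
    index = 0
    with _mgf.MGF(str(path), convert_arrays=1) as reader:
        iterator = iter(reader)
        while True:
            try:
                entry = next(iterator)
            except StopIteration:
                break
            except Exception as exc:  # pyteomics raises assorted ValueErrors
                raise MGFParseError(f"malformed MGF block {index}: {exc}") from exc
            try:
                spectra.append(_entry_to_spectrum(entry, index))
            except _SkipSpectrum as skip:
                warnings.warn(str(skip), stacklevel=2)
            index += 1
    return spectra


class _SkipSpectrum(Exception):
    pass


def _entry_to_spectrum(entry: dict, index: int) -> Spectrum:
    params = entry.get("params", {})
    title = str(params.get("title", f"index={index}"))
    if "charge" not in params:
        raise _SkipSpectrum(f"MGF block {index} ({title!r}) has no CHARGE; skipped")
    charge = _first_charge(params["charge"])
    if charge is None:
        raise _SkipSpectrum(f"MGF block {index} ({title!r}) has empty CHARGE; skipped")
    try:
        pepmass = float(np.atleast_1d(params["pepmass"])[0])
    except (KeyError, TypeError, ValueError) as exc:
        raise MGFParseError(f"malformed MGF block {index}: bad PEPMASS") from exc
    ce = params.get("collision_energy")
    reported_ce = float(ce) if ce is not None else None
    frames_raw = params.get("source_frames")
    frames = (
        [int(x) for x in str(frames_raw).split(";") if x != ""]
        if frames_raw is not None
        else []
    )
    mzs = np.asarray(entry.get("m/z array", []), dtype=np.float64)
    ints = np.asarray(entry.get("intensity array", []), dtype=np.float64)
    peaks = [Peak(float(m), float(i)) for m, i in zip(mzs, ints)]
    return Spectrum(
        spectrum_id=title,
        peaks=peaks,
        precursor_mz=pepmass,
        precursor_charge=charge,
        reported_ce=reported_ce,
        source_frames=frames,
    )


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra in this package's MGF dialect.

    Fixed formatting (m/z and intensity with 6 decimals) so that
    write -> read -> write is byte-stable.
    """
    with open(path, "w") as handle:
        for spec in spectra:
            handle.write("BEGIN IONS\n")
            handle.write(f"TITLE={spec.spectrum_id}\n")
            handle.write(f"PEPMASS={spec.precursor_mz:.6f}\n")
            handle.write(f"CHARGE={spec.precursor_charge}+\n")
            if spec.reported_ce is not None:
                handle.write(f"COLLISION_ENERGY={spec.reported_ce:.6f}\n")
            if spec.source_frames:
                frames = ";".join(str(f) for f in spec.source_frames)
                handle.write(f"SOURCE_FRAMES={frames}\n")
            for peak in spec.peaks:
                handle.write(f"{peak.mz:.6f} {peak.intensity:.6f}\n")
            handle.write("END IONS\n")


def read_mzml(path: str | Path) -> list[Spectrum]:
    """Read centroided MS2 spectra from an mzML file (read-only).

    MS1 scans are ignored; MS2 scans without a precursor charge are skipped
    with a warning.
    """
    spectra: list[Spectrum] = []
    with _mzml.MzML(str(path)) as reader:
        for entry in reader:
            if entry.get("ms level") != 2:
                continue
            sid = str(entry.get("id", len(spectra)))
            try:
                precursor = entry["precursorList"]["precursor"][0]
                ion = precursor["selectedIonList"]["selectedIon"][0]
                pmz = float(ion["selected ion m/z"])
                charge = int(ion["charge state"])
            except (KeyError, IndexError, TypeError, ValueError):
                warnings.warn(f"mzML spectrum {sid!r} lacks precursor charge; skipped")
                continue
            mzs = np.asarray(entry.get("m/z array", []), dtype=np.float64)
            ints = np.asarray(entry.get("intensity array", []), dtype=np.float64)
            peaks = [Peak(float(m), float(i)) for m, i in zip(mzs, ints) if m > 0]
            spectra.append(
                Spectrum(spectrum_id=sid, peaks=peaks, precursor_mz=pmz,
                         precursor_charge=charge)
            )
    return spectra


# ---------------------------------------------------------------------------
# MaxQuant tables
# ---------------------------------------------------------------------------

_MSMS_REQUIRED = ["Sequence", "Modifications", "Charge", "Score", "PEP",
                  "Reverse", "Scan number"]

# "(Oxidation (M))" or "(ox)" after a residue in a MaxQuant modified sequence
_MODSEQ_TOKEN = re.compile(r"([A-Z])(\((?:[^()]|\([^()]*\))*\))?")


def _require_columns(df: pd.DataFrame, required: Sequence[str], table: str) -> None:
    for col in required:
        if col not in df.columns:
            raise MissingColumnError(col, table)


def _parse_modified_sequence(modseq: str, sequence: str) -> dict[int, str]:
    """Positions of variable modifications from a MaxQuant modified sequence."""
    core = modseq.strip("_")
    mods: dict[int, str] = {}
    pos = 0
    for match in _MODSEQ_TOKEN.finditer(core):
        pos += 1
        tag = match.group(2)
        if tag:
            lowered = tag.lower()
            if "ox" in lowered:
                mods[pos] = "Oxidation"
            elif "ca" in lowered:  # carbamidomethyl: implicit fixed mod, skip
                pass
            else:
                raise MGFParseError(
                    f"unsupported modification tag {tag!r} in {modseq!r}"
                )
    if pos != len(sequence):
        raise MGFParseError(
            f"modified sequence {modseq!r} inconsistent with sequence {sequence!r}"
        )
    return mods


def read_maxquant_tables(
    msms_path: str | Path,
    accumulated_path: str | Path,
    pasef_path: str | Path,
) -> tuple[list[PSM], dict[str, list[int]]]:
    """Read MaxQuant msms/accumulatedMsmsScans/pasefMsmsScans tables.

    Returns one PSM per msms row (keyed by raw file + scan number) and a
    mapping psm_id -> PASEF frame identifiers, joined via the PASEF precursor
    ids in ``accumulatedMsmsScans.txt`` and the Precursor/Frame columns in
    ``pasefMsmsScans.txt``. A PSM whose join finds no frames is retained with
    an empty frame list and a warning.
    """
    msms = pd.read_csv(msms_path, sep="\t", dtype=str)
    accumulated = pd.read_csv(accumulated_path, sep="\t", dtype=str)
    pasef = pd.read_csv(pasef_path, sep="\t", dtype=str)

    _require_columns(msms, _MSMS_REQUIRED, "msms.txt")
    _require_columns(accumulated, ["Scan number", "PASEF precursor IDs"],
                     "accumulatedMsmsScans.txt")
    _require_columns(pasef, ["Precursor", "Frame"], "pasefMsmsScans.txt")

    # precursor id -> frames
    precursor_frames: dict[str, list[int]] = {}
    for _, row in pasef.iterrows():
        precursor_frames.setdefault(str(row["Precursor"]), []).append(
            int(float(row["Frame"]))
        )

    # (raw file, scan number) -> precursor ids
    def _raw(df: pd.DataFrame, i) -> str:
        return str(df["Raw file"].iloc[i]) if "Raw file" in df.columns else "run"

    scan_precursors: dict[tuple[str, str], list[str]] = {}
    for i in range(len(accumulated)):
        key = (_raw(accumulated, i), str(accumulated["Scan number"].iloc[i]))
        ids = str(accumulated["PASEF precursor IDs"].iloc[i])
        scan_precursors[key] = [p for p in ids.split(";") if p not in ("", "nan")]

    psms: list[PSM] = []
    frame_map: dict[str, list[int]] = {}
    for i in range(len(msms)):
        row = msms.iloc[i]
        raw = _raw(msms, i)
        scan = str(row["Scan number"])
        psm_id = f"{raw}.{scan}"
        sequence = str(row["Sequence"])
        if "Modified sequence" in msms.columns and isinstance(
            row.get("Modified sequence"), str
        ):
            mods = _parse_modified_sequence(row["Modified sequence"], sequence)
        elif str(row["Modifications"]) in ("Unmodified", "nan", ""):
            mods = {}
        else:
            raise MGFParseError(
                f"cannot place modifications {row['Modifications']!r} without a "
                "'Modified sequence' column"
            )
        ce = None
        if "Collision energy" in msms.columns:
            try:
                ce = float(row["Collision energy"])
            except (TypeError, ValueError):
                ce = None
        psm = PSM(
            psm_id=psm_id,
            spectrum_id=psm_id,
            sequence=sequence,
            modifications=mods,
            precursor_charge=int(float(row["Charge"])),
            search_score=float(row["Score"]),
            pep=float(row["PEP"]),
            is_decoy=str(row["Reverse"]).strip() == "+",
            reported_ce=ce,
        )
        frames: list[int] = []
        for pid in scan_precursors.get((raw, scan), []):
            frames.extend(precursor_frames.get(pid, []))
        if not frames:
            warnings.warn(f"no PASEF frames found for PSM {psm_id}")
        psms.append(psm)
        frame_map[psm_id] = sorted(set(frames))
    return psms, frame_map


# ---------------------------------------------------------------------------
# Frame summation
# ---------------------------------------------------------------------------

def sum_frame_scans(
    frame_spectra: Sequence[Spectrum], merge_tol_ppm: float = 40.0
) -> Spectrum:
    """Sum PASEF frame-level scans into one composite spectrum.

    Peaks pooled across frames are merged greedily over the m/z-sorted list:
    adjacent peaks whose m/z differ by at most ``merge_tol_ppm`` (relative to
    the lower m/z) join the same cluster, chains closing transitively. Each
    cluster becomes one peak with the intensity sum and the
    intensity-weighted mean m/z. Total intensity is conserved and the result
    is permutation-invariant in the input list.
    """
    if not frame_spectra:
        raise ValueError("sum_frame_scans requires at least one frame spectrum")
    if merge_tol_ppm <= 0:
        raise ValueError("merge_tol_ppm must be > 0")
    first = frame_spectra[0]
    for spec in frame_spectra[1:]:
        if spec.precursor_charge != first.precursor_charge:
            raise ValueError(
                "inconsistent precursor charge across frames: "
                f"{spec.precursor_charge} != {first.precursor_charge}"
            )

    pooled = sorted(
        (p for spec in frame_spectra for p in spec.peaks), key=lambda p: (p.mz, p.intensity)
    )
    frames = sorted({f for spec in frame_spectra for f in spec.source_frames})

    merged: list[Peak] = []
    cluster: list[Peak] = []

    def _flush() -> None:
        if not cluster:
            return
        if len(cluster) == 1:
            merged.append(cluster[0])
            return
        total = math.fsum(p.intensity for p in cluster)
        if total > 0:
            mz = math.fsum(p.mz * p.intensity for p in cluster) / total
        else:
            mz = math.fsum(p.mz for p in cluster) / len(cluster)
        # guard the weighted mean against last-ulp rounding outside the cluster
        mz = min(max(mz, cluster[0].mz), cluster[-1].mz)
        merged.append(Peak(mz, total))

    for peak in pooled:
        if cluster and (peak.mz - cluster[-1].mz) / cluster[-1].mz * 1e6 <= merge_tol_ppm:
            cluster.append(peak)
        else:
            _flush()
            cluster = [peak]
    _flush()

    return Spectrum(
        spectrum_id=first.spectrum_id,
        peaks=merged,
        precursor_mz=first.precursor_mz,
        precursor_charge=first.precursor_charge,
        reported_ce=first.reported_ce,
        source_frames=frames,
    )


# ---------------------------------------------------------------------------
# PSM table (this package's TSV dialect)
# ---------------------------------------------------------------------------

_PSM_COLUMNS = [
    "psm_id", "spectrum_id", "sequence", "modifications", "charge",
    "search_score", "pep", "is_decoy", "peptide_mass", "reported_ce", "pool_id",
]


def _format_mods(mods: Modifications) -> str:
    return ";".join(f"{pos}:{name}" for pos, name in sorted(mods.items()))


def _parse_mods(text: str) -> dict[int, str]:
    if not text or text == "-":
        return {}
    out: dict[int, str] = {}
    for token in text.split(";"):
        pos, name = token.split(":", 1)
        out[int(pos)] = name
    return out


def write_psm_table(psms: Iterable[PSM], path: str | Path) -> None:
    rows = []
    for p in psms:
        rows.append({
            "psm_id": p.psm_id,
            "spectrum_id": p.spectrum_id,
            "sequence": p.sequence,
            "modifications": _format_mods(p.modifications) or "-",
            "charge": p.precursor_charge,
            "search_score": p.search_score,
            "pep": p.pep,
            "is_decoy": int(p.is_decoy),
            "peptide_mass": p.peptide_mass,
            "reported_ce": "" if p.reported_ce is None else p.reported_ce,
            "pool_id": p.pool_id or "",
        })
    pd.DataFrame(rows, columns=_PSM_COLUMNS).to_csv(path, sep="\t", index=False)


def read_psm_table(path: str | Path) -> list[PSM]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, _PSM_COLUMNS[:-1], str(path))
    psms = []
    for _, row in df.iterrows():
        psms.append(PSM(
            psm_id=row["psm_id"],
            spectrum_id=row["spectrum_id"],
            sequence=row["sequence"],
            modifications=_parse_mods(row["modifications"]),
            precursor_charge=int(row["charge"]),
            search_score=float(row["search_score"]),
            pep=float(row["pep"]),
            is_decoy=bool(int(row["is_decoy"])),
            peptide_mass=float(row["peptide_mass"]),
            reported_ce=float(row["reported_ce"]) if row["reported_ce"] else None,
            pool_id=row.get("pool_id") or None,
        ))
    return psms
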