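import math

import numpy as np
import pytest

from timsrescore import PSM, Peak, Spectrum, read_mgf, sum_frame_scans, write_mgf
from timsrescore.errors import MGFParseError, MissingColumnError
from timsrescore.spectra_io import (
    read_maxquant_tables,
    read_psm_table,
    write_psm_table,
)


def _spectrum(peaks, sid="s1", charge=2, mz=500.25, ce=None, frames=()):
    return Spectrum(
        spectrum_id=sid,
        peaks=[Peak(m, i) for m, i in peaks],
        precursor_mz=mz,
        precursor_charge=charge,
        reported_ce=ce,
        source_frames=list(frames),
    )


class TestMGF:
    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.mgf"
        path.write_text("")
        assert read_mgf(path) == []

    def test_roundtrip_three_blocks(self, tmp_path):
        spectra = [
            _spectrum([(100.123456, 10.0), (200.5, 20.0)], sid=f"spec{i}",
                      charge=i + 1, ce=30.5, frames=[1, 2])
            for i in range(3)
        ]
        path = tmp_path / "rt.mgf"
        write_mgf(spectra, path)
        back = read_mgf(path)
        assert len(back) == 3
        for orig, readback in zip(spectra, back):
            assert readback.spectrum_id == orig.spectrum_id
            assert readback.precursor_charge == orig.precursor_charge
            assert readback.reported_ce == pytest.approx(30.5)
            assert readback.source_frames == [1, 2]
            for p, q in zip(orig.peaks, readback.peaks):
                assert q.mz == pytest.approx(p.mz, abs=1e-6)
                assert q.intensity == pytest.approx(p.intensity, abs=1e-6)

    def test_write_read_write_is_byte_stable(self, tmp_path):
        spectra = [_spectrum([(100.1, 1.0), (300.333333, 5.5)], ce=25.0)]
        p1, p2 = tmp_path / "a.mgf", tmp_path / "b.mgf"
        write_mgf(spectra, p1)
        write_mgf(read_mgf(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_unsorted_peaks_are_sorted(self):
        spec = _spectrum([(300.0, 1.0), (100.0, 2.0), (200.0, 3.0)])
        assert [p.mz for p in spec.peaks] == [100.0, 200.0, 300.0]

    def test_malformed_block_names_index(self, tmp_path):
        path = tmp_path / "bad.mgf"
        path.write_text(
            "BEGIN IONS\nTITLE=ok\nPEPMASS=500.0\nCHARGE=2+\n100.0 1.0\nEND IONS\n"
            "BEGIN IONS\nTITLE=bad\nPEPMASS=not_a_number\nCHARGE=2+\n"
            "100.0 1.0\nEND IONS\n"
        )
        with pytest.raises(MGFParseError, match="block 1"):
            read_mgf(path)

    def test_missing_charge_skips_with_warning(self, tmp_path):
        path = tmp_path / "nocharge.mgf"
        path.write_text(
            "BEGIN IONS\nTITLE=nocharge\nPEPMASS=500.0\n100.0 1.0\nEND IONS\n"
            "BEGIN IONS\nTITLE=ok\nPEPMASS=400.0\nCHARGE=2+\n100.0 1.0\nEND IONS\n"
        )
        with pytest.warns(UserWarning, match="no CHARGE"):
            spectra = read_mgf(path)
        assert [s.spectrum_id for s in spectra] == ["ok"]


class TestMaxQuantTables:
    @staticmethod
    def _write_tables(tmp_path, msms_rows, drop_column=None):
        msms_header = ["Raw file", "Scan number", "Sequence", "Modifications",
                       "Charge", "Score", "PEP", "Reverse"]
        if drop_column:
            msms_header = [c for c in msms_header if c != drop_column]
        lines = ["\t".join(msms_header)]
        for row in msms_rows:
            lines.append("\t".join(str(row[c]) for c in msms_header))
        (tmp_path / "msms.txt").write_text("\n".join(lines) + "\n")
        (tmp_path / "accumulatedMsmsScans.txt").write_text(
            "Raw file\tScan number\tPASEF precursor IDs\n"
            "run1\t10\t101;102\n"
            "run1\t11\t103\n"
        )
        (tmp_path / "pasefMsmsScans.txt").write_text(
            "Precursor\tFrame\n101\t7\n101\t8\n102\t9\n103\t12\n"
        )
        return (tmp_path / "msms.txt", tmp_path / "accumulatedMsmsScans.txt",
                tmp_path / "pasefMsmsScans.txt")

    _ROWS = [
        {"Raw file": "run1", "Scan number": 10, "Sequence": "PEPTIDEK",
         "Modifications": "Unmodified", "Charge": 2, "Score": 95.2,
         "PEP": 0.001, "Reverse": ""},
        {"Raw file": "run1", "Scan number": 11, "Sequence": "EDITPEPK",
         "Modifications": "Unmodified", "Charge": 2, "Score": 42.0,
         "PEP": 0.2, "Reverse": "+"},
    ]

    def test_two_rows_one_decoy(self, tmp_path):
        paths = self._write_tables(tmp_path, self._ROWS)
        psms, _ = read_maxquant_tables(*paths)
        assert len(psms) == 2
        assert sum(p.is_decoy for p in psms) == 1
        assert psms[0].search_score == pytest.approx(95.2)

    def test_missing_scan_number_column_is_named(self, tmp_path):
        paths = self._write_tables(tmp_path, self._ROWS, drop_column="Scan number")
        with pytest.raises(MissingColumnError, match="Scan number"):
            read_maxquant_tables(*paths)

    def test_frame_join(self, tmp_path):
        paths = self._write_tables(tmp_path, self._ROWS)
        psms, frame_map = read_maxquant_tables(*paths)
        assert frame_map["run1.10"] == [7, 8, 9]
        assert frame_map["run1.11"] == [12]


class TestSumFrameScans:
    def test_single_frame_identity(self):
        spec = _spectrum([(100.0, 1.0), (200.0, 2.0)])
        out = sum_frame_scans([spec])
        assert [(p.mz, p.intensity) for p in out.peaks] == [(100.0, 1.0), (200.0, 2.0)]

    def test_two_identical_frames_double_intensity(self):
        spec = _spectrum([(100.0, 1.0), (200.0, 2.0)])
        out = sum_frame_scans([spec, spec])
        assert [p.mz for p in out.peaks] == [100.0, 200.0]
        assert [p.intensity for p in out.peaks] == [2.0, 4.0]

    def test_weighted_mean_merge(self):
        a = _spectrum([(1000.000, 100.0)])
        b = _spectrum([(1000.010, 300.0)])
        out = sum_frame_scans([a, b], merge_tol_ppm=15.0)
        assert len(out.peaks) == 1
        assert out.peaks[0].mz == pytest.approx(1000.0075, abs=1e-9)
        assert out.peaks[0].intensity == pytest.approx(400.0)

    def test_gap_above_tolerance_not_merged(self):
        a = _spectrum([(1000.000, 100.0)])
        b = _spectrum([(1000.050, 300.0)])  # 50 ppm apart
        out = sum_frame_scans([a, b], merge_tol_ppm=15.0)
        assert len(out.peaks) == 2

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            sum_frame_scans([])

    def test_inconsistent_charge_raises(self):
        with pytest.raises(ValueError, match="charge"):
            sum_frame_scans([_spectrum([(100.0, 1.0)], charge=2),
                             _spectrum([(100.0, 1.0)], charge=3)])

    @pytest.mark.parametrize("seed", range(10))
    def test_conservation_bounds_and_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        frames = []
        for _ in range(rng.integers(2, 6)):
            n = int(rng.integers(1, 30))
            mz = np.sort(rng.uniform(100, 1500, n))
            inten = rng.integers(1, 10_000, n).astype(float)
            frames.append(_spectrum(list(zip(mz, inten))))
        out = sum_frame_scans(frames, merge_tol_ppm=40.0)

        total_in = math.fsum(p.intensity for f in frames for p in f.peaks)
        assert out.total_intensity() == total_in  # exact for integer counts

        all_mz = [p.mz for f in frames for p in f.peaks]
        for p in out.peaks:
            assert min(all_mz) <= p.mz <= max(all_mz)

        perm = list(frames)
        rng.shuffle(perm)
        out2 = sum_frame_scans(perm, merge_tol_ppm=40.0)
        assert [(p.mz, p.intensity) for p in out.peaks] == [
            (p.mz, p.intensity) for p in out2.peaks
        ]


class TestPSM:
    def _psm(self, **kwargs):
        defaults = dict(
            psm_id="p1", spectrum_id="s1", sequence="PEPTIDEK", modifications={},
            precursor_charge=2, search_score=80.0, pep=0.005, is_decoy=False,
        )
        defaults.update(kwargs)
        return PSM(**defaults)

    def test_mass_computed_from_sequence(self):
        psm = self._psm()
        assert psm.peptide_mass == pytest.approx(927.4549, abs=1e-3)

    def test_inconsistent_mass_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            self._psm(peptide_mass=900.0)

    def test_length_bounds_enforced(self):
        with pytest.raises(ValueError, match="length"):
            self._psm(sequence="PEPTID")  # 6 residues

    def test_psm_table_roundtrip(self, tmp_path):
        psms = [self._psm(), self._psm(psm_id="p2", sequence="MPEPTIDE",
                                       modifications={1: "Oxidation"},
                                       is_decoy=True, reported_ce=32.5)]
        path = tmp_path / "psms.tsv"
        write_psm_table(psms, path)
        back = read_psm_table(path)
        assert len(back) == 2
        assert back[1].modifications == {1: "Oxidation"}
        assert back[1].is_decoy
        assert back[1].reported_ce == pytest.approx(32.5)
        assert back[0].reported_ce is None
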