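import numpy as np
import pytest

from timsrescore import (
    FeatureRecord,
    compare_runs,
    compute_feature_table,
    compute_features,
    peptides_at_fdr,
    qvalues_tdc,
    read_pin,
    rescore,
    score_baseline,
    write_pin,
)
from timsrescore.chem import UnsupportedPeptideError
from timsrescore.errors import RescoringError
from timsrescore.synthetic import SyntheticDatasetSpec, generate_dataset


def brute_force_qvalues(pairs):
    """O(n^2) oracle: q_i = min FDR over all thresholds at or below score_i."""
    out = []
    for score_i, _ in pairs:
        best = np.inf
        for threshold, _ in pairs:
            if threshold <= score_i:
                decoys = sum(1 for s, l in pairs if s >= threshold and l == -1)
                targets = sum(1 for s, l in pairs if s >= threshold and l == +1)
                best = min(best, decoys / max(1, targets))
        out.append(best)
    return np.array(out)


class TestQValues:
    def test_simple_example(self):
        pairs = [(3.0, 1), (2.0, 1), (1.0, -1)]
        q = qvalues_tdc(pairs)
        assert q[0] == 0.0
        assert q[1] == 0.0
        assert q[2] == pytest.approx(0.5)

    def test_all_targets_above_all_decoys(self):
        pairs = [(10.0, 1), (9.0, 1), (8.0, 1), (2.0, -1), (1.0, -1)]
        q = qvalues_tdc(pairs)
        assert np.all(q[:3] == 0.0)

    def test_interleaved_equal_counts_bottom_q_is_one(self):
        pairs = [(8.0, 1), (7.0, -1), (6.0, 1), (5.0, -1), (4.0, 1), (3.0, -1)]
        q = qvalues_tdc(pairs)
        assert q[-1] == pytest.approx(1.0)

    def test_ties_share_q(self):
        pairs = [(5.0, 1), (5.0, 1), (5.0, -1), (1.0, -1)]
        q = qvalues_tdc(pairs)
        assert q[0] == q[1] == q[2]

    def test_no_decoys_warns_zero(self):
        with pytest.warns(UserWarning, match="no decoys"):
            q = qvalues_tdc([(3.0, 1), (2.0, 1)])
        assert np.all(q == 0.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        scores = np.round(rng.uniform(0, 5, n), 1)  # induce occasional ties
        labels = rng.choice([-1, 1], n)
        if not (labels == -1).any():
            labels[0] = -1
        pairs = list(zip(scores, labels))
        assert np.allclose(qvalues_tdc(pairs), brute_force_qvalues(pairs))

    def test_monotone_nonincreasing_in_score(self):
        rng = np.random.default_rng(7)
        pairs = list(zip(rng.uniform(0, 10, 500), rng.choice([-1, 1], 500)))
        q = qvalues_tdc(pairs)
        order = np.argsort([-s for s, _ in pairs])
        assert np.all(np.diff(q[order]) >= -1e-12)


def _record(psm_id, label, features, peptide="PEPTIDEK", scan=0):
    return FeatureRecord(psm_id=psm_id, label=label, scan_nr=scan,
                         features=features, peptide=peptide)


class TestPin:
    def test_shape_and_roundtrip(self, tmp_path):
        records = [
            _record("a", 1, {"search_score": 10.0, "spectral_angle": 0.9}),
            _record("b", -1, {"search_score": 3.123456, "spectral_angle": 0.1},
                    peptide="KEDITPEP", scan=1),
        ]
        path = tmp_path / "out.pin"
        write_pin(records, path)
        lines = path.read_text().splitlines()
        assert len(lines) == 3
        assert lines[0].split("\t") == ["SpecId", "Label", "ScanNr", "search_score",
                                        "spectral_angle", "Peptide", "Proteins"]
        assert "X.KEDITPEP.X" in lines[2]
        back = read_pin(path)
        assert [r.label for r in back] == [1, -1]
        for orig, rb in zip(records, back):
            for name, value in orig.features.items():
                assert rb.features[name] == pytest.approx(value, abs=1e-6)

    def test_inconsistent_features_rejected(self, tmp_path):
        records = [_record("a", 1, {"x": 1.0}), _record("b", 1, {"y": 1.0})]
        with pytest.raises(ValueError, match="b"):
            write_pin(records, tmp_path / "bad.pin")

    def test_nan_feature_rejected_at_construction(self):
        with pytest.raises(ValueError, match="non-finite"):
            _record("a", 1, {"x": float("nan")})


class TestComputeFeatures:
    def test_self_match_features(self, tiny_dataset, tiny_predictor,
                                 tiny_spectra_by_id):
        ds = tiny_dataset
        psm = next(p for p in ds.psms if ds.truth[p.psm_id])
        psm = psm.with_aligned_ce(ds.true_ce[psm.psm_id])
        record = compute_features(psm, tiny_spectra_by_id[psm.spectrum_id],
                                  tiny_predictor)
        assert record.label == 1
        assert record.features["spectral_angle"] > 0.7
        assert record.features["matched_frac"] > 0.5
        assert record.features["peptide_length"] == len(psm.sequence)
        assert abs(record.features["delta_mass_ppm"]) < 15.0

    def test_zero_noise_self_match_is_near_perfect(self):
        """Observed == predicted (zero noise): SA and Pearson sit at 1 up to
        count quantization and rare coincident-fragment m/z merges."""
        ds = generate_dataset(SyntheticDatasetSpec(
            n_peptides=20, seed=5, noise_sigma=0.0, n_frames_per_spectrum=1,
            decoy_fraction=0.0, incorrect_target_fraction=0.0,
            ce_offset_slope=0.0, ce_offset_intercept=0.0,
        ))
        from timsrescore import SyntheticPredictor
        predictor = SyntheticPredictor(ds.model)
        spectra = {s.spectrum_id: s for s in ds.spectra}
        sas, pearsons = [], []
        for psm in ds.psms:
            record = compute_features(psm, spectra[psm.spectrum_id], predictor)
            sas.append(record.features["spectral_angle"])
            pearsons.append(record.features["pearson"])
        assert np.median(sas) == pytest.approx(1.0, abs=1e-3)
        assert np.median(pearsons) == pytest.approx(1.0, abs=1e-3)
        assert min(sas) > 0.95

    def test_decoy_against_unrelated_spectrum_scores_low(
        self, tiny_dataset, tiny_predictor, tiny_spectra_by_id
    ):
        ds = tiny_dataset
        sas = []
        for psm in ds.psms:
            if psm.is_decoy:
                record = compute_features(
                    psm, tiny_spectra_by_id[psm.spectrum_id], tiny_predictor
                )
                sas.append(record.features["spectral_angle"])
        assert np.median(sas) < 0.3

    def test_free_cysteine_dropped_with_reason(self, tiny_predictor):
        ds = generate_dataset(SyntheticDatasetSpec(n_peptides=10, seed=2))
        from dataclasses import replace
        psm = replace(ds.psms[0], sequence="PCPTIDEK", free_cysteine=True,
                      peptide_mass=None)
        spectra = {s.spectrum_id: s for s in ds.spectra}
        with pytest.raises(UnsupportedPeptideError, match="unsupported-residue"):
            compute_features(psm, spectra[psm.spectrum_id], tiny_predictor)
        from timsrescore import SyntheticPredictor
        records, dropped = compute_feature_table(
            [psm], spectra, SyntheticPredictor(ds.model)
        )
        assert records == []
        assert dropped["unsupported-residue"] == 1


class TestRescore:
    def test_internal_beats_score_baseline(self, tiny_dataset, tiny_predictor,
                                           tiny_spectra_by_id):
        records, _ = compute_feature_table(
            tiny_dataset.psms, tiny_spectra_by_id, tiny_predictor
        )
        rescored = rescore(records, seed=1)
        baseline = score_baseline(records)
        n_rescored = sum(1 for r in rescored if r.label == 1 and r.q_value <= 0.01)
        n_baseline = sum(1 for r in baseline if r.label == 1 and r.q_value <= 0.01)
        assert n_rescored > n_baseline

    def test_pure_noise_features_identify_nothing(self):
        rng = np.random.default_rng(0)
        records = [
            _record(f"p{i}", int(rng.choice([-1, 1])),
                    {"search_score": float(rng.normal()),
                     "spectral_angle": float(rng.uniform()),
                     "pearson": float(rng.uniform(-1, 1))},
                    peptide=f"PEPTID{i:04d}"[:10])
            for i in range(1000)
        ]
        rescored = rescore(records, seed=0)
        n_accept = sum(1 for r in rescored if r.label == 1 and r.q_value <= 0.01)
        assert n_accept <= 10  # 0 within binomial noise

    def test_single_feature_preserves_score_ranking(self):
        rng = np.random.default_rng(3)
        records = []
        for i in range(200):
            label = 1 if i < 120 else -1
            score = float(rng.normal(60 if label == 1 else 40, 5))
            records.append(_record(f"p{i}", label, {"search_score": score},
                                   peptide=f"AAAAAAA{i:03d}"[:10]))
        rescored = rescore(records, seed=0, n_iterations=1, n_folds=1,
                           feature_subset=["search_score"])
        raw = np.array([r.features["search_score"] for r in records])
        new = np.array([r.score for r in rescored])
        assert np.array_equal(np.argsort(-raw, kind="stable"),
                              np.argsort(-new, kind="stable"))

    def test_percolator_engine_missing_binary_is_actionable(self, tmp_path,
                                                            monkeypatch):
        monkeypatch.setenv("PATH", str(tmp_path))  # no percolator here
        records = [_record("a", 1, {"search_score": 1.0}),
                   _record("b", -1, {"search_score": 0.5})]
        with pytest.raises(RescoringError, match="internal"):
            rescore(records, engine="percolator", workdir=tmp_path)


class TestCompareRuns:
    def test_identical_sets(self):
        result = compare_runs({"A", "B"}, {"A", "B"})
        assert result.gained == set() and result.lost == set()
        assert result.fold_change == 1.0

    def test_superset_fold_change(self):
        baseline = {f"pep{i}" for i in range(10)}
        rescored = baseline | {f"new{i}" for i in range(17)}
        result = compare_runs(baseline, rescored)
        assert result.lost == set()
        assert result.fold_change == pytest.approx(2.7)

    def test_disjoint_sets(self):
        result = compare_runs({"A"}, {"B", "C"})
        assert result.shared == set()
        assert result.fold_change == 2.0

    def test_empty_baseline_fold_absent(self):
        assert compare_runs(set(), {"A"}).fold_change is None

    def test_partition_property(self):
        rng = np.random.default_rng(1)
        universe = [f"pep{i}" for i in range(100)]
        baseline = {p for p in universe if rng.random() < 0.5}
        rescored = {p for p in universe if rng.random() < 0.6}
        result = compare_runs(baseline, rescored)
        assert len(result.gained) + len(result.shared) == len(rescored)
        assert len(result.lost) + len(result.shared) == len(baseline)


def test_peptides_at_fdr_uses_best_psm_per_peptide():
    records = [
        _record("a1", 1, {"search_score": 10.0}, peptide="AAAAAAAK"),
        _record("a2", 1, {"search_score": 90.0}, peptide="AAAAAAAK"),
        _record("b", 1, {"search_score": 80.0}, peptide="CCCCCCCK"),
        _record("d", -1, {"search_score": 20.0}, peptide="DDDDDDDK"),
    ]
    accepted = peptides_at_fdr(score_baseline(records), fdr=0.01)
    assert accepted == {"AAAAAAAK", "CCCCCCCK"}
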