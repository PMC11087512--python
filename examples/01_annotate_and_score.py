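"""Annotate a peptide's MS/MS spectrum and score it against a prediction.

Builds a small synthetic spectrum for one peptide, maps it onto the fixed
174-slot b/y intensity layout at 40 ppm tolerance, and compares it to the
synthetic predictor's intensity vector with the normalized spectral
contrast angle (1 = identical fragment pattern, 0 = no shared signal).
"""

from timsrescore import (
    PSM,
    GroundTruthModel,
    Peak,
    Spectrum,
    SyntheticPredictor,
    annotate_spectrum,
    similarity_scores,
    theoretical_ions,
)
from timsrescore.annotation import layout_mz

SEQUENCE = "VEDPVTVEY"  # an HLA-I-like non-tryptic peptide
CHARGE = 1

model = GroundTruthModel(seed=7)
predictor = SyntheticPredictor(model)

# pretend measurement: peaks at the theoretical m/z with the model's
# CE-dependent intensities at 28 eV
predicted = predictor.predict_intensities(SEQUENCE, {}, CHARGE, collision_energy=28.0)
mz, mask = layout_mz(SEQUENCE, None, CHARGE)
peaks = [Peak(float(m), float(v) * 1e4)
         for m, v in zip(mz[mask], predicted.values[mask]) if v > 0]
spectrum = Spectrum(spectrum_id="demo", peaks=peaks,
                    precursor_mz=1034.5, precursor_charge=CHARGE)

psm = PSM(psm_id="demo", spectrum_id="demo", sequence=SEQUENCE,
          modifications={}, precursor_charge=CHARGE, search_score=90.0,
          pep=0.001, is_decoy=False)

observed = annotate_spectrum(spectrum, psm, tol_ppm=40.0)
scores = similarity_scores(observed, predicted)

ions = theoretical_ions(SEQUENCE, max_fragment_charge=1)
print(f"peptide {SEQUENCE}/{CHARGE}: {len(ions)} theoretical b/y ions at charge 1")
print(f"annotated slots: {int(observed.mask.sum())} valid, "
      f"{int((observed.values[observed.mask] > 0).sum())} matched")
print(f"spectral angle = {scores.spectral_angle:.3f}, "
      f"pearson = {scores.pearson:.3f} over {scores.n_valid} joint slots")
print("(SA = 1.0 here because the spectrum was built from the same model "
      "and collision energy as the prediction)")

# shift the prediction's collision energy and watch the similarity drop
for ce in (28.0, 32.0, 38.0):
    other = predictor.predict_intensities(SEQUENCE, {}, CHARGE, ce)
    from timsrescore import spectral_angle
    print(f"  prediction at {ce:4.1f} eV -> SA {spectral_angle(observed, other):.3f}")
print("the decay away from 28 eV is what collision-energy calibration exploits")
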