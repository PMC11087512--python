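# Methods

This note documents the models, parameter choices and numerical decisions
behind `timsrescore`, and what the synthetic benchmarks do and do not show
about real data.

## Spectra and frame summation

A timsTOF acquires each precursor's MS/MS signal across several PASEF
frames. `sum_frame_scans` pools the frame-level peak lists, sorts by m/z and
merges greedily: adjacent peaks whose m/z differ by at most `merge_tol_ppm`
(default 40 ppm, the same tolerance used for fragment matching) join one
cluster, chains closing transitively; each cluster becomes a peak with the
intensity sum and the intensity-weighted mean m/z. Sorting first makes the
result independent of frame order. Intensities are treated as detector
counts: for integer-valued inputs the summation is exact, and cluster sums
use compensated summation (`math.fsum`) so float inputs are conserved to the
last ulp. A single-peak cluster keeps its m/z bit-for-bit, and a merged m/z
is clamped into its cluster's m/z range to guard against last-ulp rounding.

MGF and mzML parsing is delegated to pyteomics; the package's own MGF writer
uses fixed 6-decimal formatting so write → read → write is byte-stable. The
MaxQuant join follows the tables' structure: `msms.txt` rows keyed by raw
file + scan number, linked to PASEF precursor ids via
`accumulatedMsmsScans.txt` and to frame numbers via `pasefMsmsScans.txt`.

## Fragment annotation

Theoretical b/y ions use monoisotopic residue masses (full precision, 8
decimals; proton 1.00727646688 Da, water 18.0105646863 Da) with
carbamidomethyl-cysteine (+57.02146372 Da) applied implicitly as a fixed
modification and methionine oxidation (+15.99491462 Da) as the supported
variable modification. Peptides with chemistry outside this model (unknown
residues, unsupported modifications, flagged free cysteines) are rejected,
because an intensity predictor trained without that chemistry cannot score
them.

Observed spectra are mapped onto a fixed vector of 174 slots — 29 cleavage
positions × 2 ion series (y before b) × fragment charges 1–3 — the layout
convention of Prosit-lineage intensity predictors. Slots that cannot exist
for a peptide (position ≥ length, fragment charge > precursor charge) carry
the sentinel −1 and a false mask. Matching takes the nearest peak within the
ppm tolerance (an exact distance tie goes to the higher intensity); several
theoretical ions may claim the same peak (no exclusivity — deterministic and
the common annotator behavior). Matched intensities are base-peak normalized
over the annotated fragments only; whether to normalize over the whole
spectrum instead is an open choice, and annotated-fragments normalization
was picked because the downstream similarity is likewise restricted to
annotated fragments. Fragment charge 4, used during rescoring annotation,
does not fit the vector and feeds separate count features instead.

## Spectral contrast angle

Similarity between observed and predicted vectors is the normalized
spectral contrast angle over the slots valid in both vectors: negatives are
clipped to zero, both vectors are L2-normalized, and
`SA = 1 − 2θ/π` with `θ` the angle between them. The angle is computed as
`θ = 2·atan2(‖û − v̂‖, ‖û + v̂‖)` rather than `arccos` of the dot product:
the arccos form loses ~8 digits near θ = 0 (its derivative diverges), while
the atan2 form is exact at both θ = 0 and θ = π/2. All-zero vectors (and
empty joint masks) score 0 by convention so that matches with no shared
fragment evidence rank minimally. Zero-zero slot pairs are kept; they do not
affect the angle.

## Synthetic ground-truth model

The reference predictor is a seeded generative model: per (sequence,
modifications, charge), each layout slot receives a basal intensity
(log-normal, σ = 1) and a collision-energy optimum drawn around a center,
both from a SHA-256-keyed RNG, so predictions are bitwise deterministic.
Intensity follows a Gaussian CE response,

    I(slot, ce) = basal(slot) · exp(−(ce − opt(slot))² / (2 w²)),

base-peak normalized. Defaults: center 30 eV, per-fragment spread 8 eV,
width w = 5 eV. The spread is essential: with a shared optimum every CE
yields a proportional vector and the spectral angle is constant, making CE
unidentifiable; with spread > 0 the SA between spectra generated at two CEs
is maximal exactly at equality (Cauchy–Schwarz), so grid search has a
recoverable truth.

The dataset generator emulates a pool-based timsTOF measurement: unique
peptides of length 8–15 (HLA-I-like), precursor charges 1–3 with
probabilities 0.25/0.5/0.25, an instrument CE ramp
`reported = 20 + 0.0125·mass` eV clipped to [20, 60] (instrument
acquisitions span roughly 20–70 eV), and a planted mass-linear offset
`ΔCE = 0.01·mass − 5` eV between reported and effective CE. Observed
intensities get multiplicative log-normal noise (σ = 0.3), are quantized to
integer counts (base peak = 10,000) and split across 5 PASEF frames by a
multinomial draw — Poisson thinning conditioned on the total, chosen over
independent Poisson draws so that frame summation conserves intensity
exactly. Incorrect targets (30% of targets) and decoys (half of all PSMs;
sequences shuffled with the C-terminal residue fixed) carry spectra of
unrelated peptides, but their precursor m/z still derives from the claimed
peptide (±3 ppm): a search engine only proposes candidates inside the
precursor tolerance, so the precursor mass error must not trivially separate
correct from incorrect. Search scores are normal with an 8-point spread and
a 20-point mean shift for correct PSMs — enough that a score-only baseline
accepts roughly a quarter to a third of the correct PSMs at 1% FDR, leaving
the intensity features to carry most of the signal, as they do in practice.

What the generator does not emulate: chimeric spectra, isotope envelopes,
neutral losses and internal fragments, ion-mobility information, retention
time structure, and real search-engine score distributions. Passing tests
therefore demonstrate the pipeline's correctness and its qualitative
gain mechanism, not quantitative performance on real instrument data. One
physical artifact it does share with real data: fragment ions whose m/z
coincide (e.g. b1⁺ vs b2²⁺ after a repeated residue) produce a single merged
peak, which caps the closed-loop spectral angle slightly below 1 for the
affected peptide.

## Collision-energy calibration

For each PSM selected for calibration (top 100 by search score per
precursor charge by default), the optimal CE is the grid argmax (5–45 eV,
1 eV steps; the grid endpoints follow the calibration range above, the step
is this package's choice) of the spectral angle between the annotated
spectrum and the prediction; ties break toward the lowest CE. The offset
`reported − optimal` is regressed on peptide mass with RANSAC (scikit-learn;
residual threshold = the median absolute deviation of the offsets, 100
trials, seeded), per stratum of precursor charge × tryptic status — tryptic
meaning a C-terminal K or R — with a pooled global fit as fallback for
strata under 10 observations. Applying the model subtracts the predicted
offset from the reported CE and clips into the grid range (the predictor's
supported domain). The fitted model can record the peptide sequences it was
trained on; the split-aware application path refuses a model whose
provenance contains any non-training peptide.

## Rescoring

Feature records carry the search score, spectral angle, Pearson
correlation, matched b/y counts (fragment charges 1–4), matched-slot
fraction, fraction of total spectrum intensity explained, precursor mass
error in ppm, fraction of predicted intensity missing from the observation,
peptide length, charge indicators, and — when the predictor provides
retention times and the PSM has one — the absolute retention-time
difference. The set is configurable; records serialize to Percolator's PIN
dialect and an installed Percolator binary can be invoked directly.

The internal engine is a semi-supervised linear rescorer in the Percolator
mold, with a regularized linear discriminant (LDA, lsqr solver, automatic
shrinkage) in place of an SVM — dependency-light and deterministic under a
seed. Scores start at the search score; for 3 iterations, each of 3
cross-validation folds trains on the other folds' decoys versus confident
targets (q ≤ the target FDR under the current scores; if fewer than 10, the
top-scoring targets seed the positive set) and scores the held-out fold.
Fold scores are anchored on the training decoys (mean/std) so they are
comparable when pooled. Final q-values come from target-decoy competition:
`FDR(s) = #decoys ≥ s / max(1, #targets ≥ s)`, monotonized from the bottom
of the ranking, ties sharing a q. Peptide-level q-values collapse to the
best PSM per sequence first. A logistic fit of label on the final score
provides optional posterior error probabilities.

On the default benchmark the empirical false-discovery proportion at
q ≤ 0.01 stays below the nominal level because decoys and incorrect targets
are exchangeable by construction; the same TDC estimate on real data
inherits the usual assumptions (decoy adequacy, one competition per
spectrum).

## Curation and splitting

Ground-truth curation keeps, in order: the top PSM per spectrum, PSMs with
PEP < 0.01, sequences expected in their pool — equality or an N-terminal
truncation, i.e. a suffix, of an expected peptide, at least 7 residues —
and Andromeda-like scores ≥ 70. After the top-per-spectrum step the
remaining filters commute.

The train/validation/test split (default 0.8/0.1/0.1) treats "subsequence"
as contiguous substring: substring-containment pairs (found by indexing all
substrings down to the shortest sequence length, not by an all-pairs scan)
are closed transitively with union–find, and the resulting groups are
shuffled by seed and assigned greedily to the partition furthest below its
target count. Fractions target peptide counts; realized PSM fractions can be
computed from the assignment. The greedy largest-deficit rule keeps realized
fractions within a fraction of a percent of the targets for group sizes
small relative to the dataset.

## Problem sizes in tests and the acceptance script

The bundled benchmarks run at desk scale as the package's own choice of
test conditions: 5,000 PSMs for FDR control, 5 × 1,000 PSMs for the
rescoring-gain property, 600 PSMs for end-to-end CE calibration (so enough
correct PSMs remain outside the top-k calibration set to measure held-out
error), 10,000 peptides for the split check, and 500 points with 20%
uniform outliers for the robust-fit recovery. All randomness is seeded; the
acceptance script derives sub-seeds from its `--seed` argument.

## Known limitations

- Only canonical b/y ions; no neutral losses, internal or immonium ions.
- Modification support is carbamidomethyl-C and oxidation-M; other PTMs are
  rejected rather than mispredicted.
- The synthetic predictor's Gaussian CE response is a modeling convenience;
  real fragment CE curves are asymmetric.
- The internal rescorer demonstrates the pipeline's gain property; it is not
  a drop-in replacement for Percolator's SVM on real data.
- Raw Bruker .d/TDF reading is out of scope; the package consumes extracted
  peak lists (MGF/mzML) and MaxQuant tables.
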