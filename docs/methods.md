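# Methods

This note documents the models, numerical choices and known limitations of
`dcfmri`, in the spirit of a methods appendix: everything stated here is
computed by the package's tests, analysis scripts or `scripts/acceptance.py`.

## Synthetic BOLD cohort

The generator emulates a two-group resting-state case-control study at desk
scale. Each subject's scan is

  y_v(t) = λ_{g, k(v)} · n_k(t) + ε_v(t)

where each planted network *k* has a latent signal n_k — unit-variance
Gaussian noise ideally band-limited to 0.01–0.08 Hz, drawn fresh per
subject — applied with a group-specific loading λ to the voxels of its
spherical ROI, and ε is AR(1) noise (marginal sd σ), spatially smoothed and
re-standardised per voxel. Two in-ROI voxels with loading λ therefore have
expected correlation λ²/(λ² + σ²) before spatial noise correlation, which
is the handle by which degree effects are planted on either side of the
r > 0.25 threshold.

Defaults and why:

- **Grid 24×24×18 at 3 mm, TR 2 s, 150 volumes, 20 + 20 subjects.** The
  structure (ellipsoidal brain of ~4 000 voxels, band-pass-feasible TR,
  QC-able motion series) mirrors a full-size study; the size is chosen so a
  complete run takes seconds per subject. All of it is configurable.
- **Loadings 0.9 (affected group) vs 0.2 (other group), ROI radius 6 mm.**
  After band-passing, broadband noise loses roughly the fraction of its
  power outside 0.01–0.08 Hz while the band-limited network signal keeps
  all of it, so the effective within-ROI correlation is ≈ 0.7 at λ = 0.9
  and ≈ 0.1 at λ = 0.2 — comfortably on opposite sides of the 0.25 degree
  threshold. Two networks are planted by default, one elevated and one
  depreciated in patients, giving both contrast directions.
- **Noise AR(1) ρ = 0.3, spatial smoothing 3 mm FWHM.** Mild temporal
  autocorrelation and intrinsic spatial correlation of the right order for
  BOLD. Smoothing the noise *field* much more than the voxel size (e.g. at
  the 6 mm used for DC maps) makes local neighbourhood correlations
  dominate every voxel's degree and simultaneously dilutes them inside the
  ROI (the added shared signal lowers correlations with non-ROI
  neighbours), nearly cancelling the planted hub contrast — so the default
  keeps the intrinsic noise smoothness at one voxel and leaves the 6 mm
  smoothing to the DC maps where the published convention applies it.
- **Phenotypes.** Ages and education are truncated normals matched to
  typical case-control summaries (28.0 ± 7.4 vs 27.9 ± 6.5 years;
  12.1 ± 3.3 vs 12.6 ± 2.9 years), sex is Bernoulli with per-group male
  fractions (102/198, 130/234), HRSD-17 severity is a rounded truncated
  normal 23.63 ± 2.55 on [17, 52] for patients, and illness duration is
  log-normal with median ≈ 20 months. HRSD/duration are missing-coded "NA"
  for controls.
- **Motion** is a bounded (reflected) random walk within ±1.5 mm/°, so QC
  at ±2 passes by default; `n_motion_violators` injects a 2.6 mm excursion
  into the first k subjects to exercise the exclusion path.

What the generator does *not* emulate: scanner drift beyond linear,
spikes, physiological aliasing, EPI distortion, anatomy/atlases, or any
coupling between DC and the clinical scores. Passing tests therefore
demonstrate correctness and calibration of the *methods* under a known
generative model, not performance on real scans.

## Preprocessing

Discard 5 volumes → motion QC (inclusive at exactly 2.0, since "±2" is
conventionally a closed bound) → per-voxel linear detrend (least squares)
→ ideal FFT band-pass (bins outside [0.01, 0.08] Hz zeroed, DC bin always
zeroed; no padding or tapering — a documented limitation for short series,
accepted to match the ideal-filter convention and to make pass/stop-band
behaviour exactly testable) → OLS nuisance regression (intercept + 6
motion + WM + CSF; all-zero confound columns are dropped so a motionless
subject degrades to demeaning; rank deficiency raises an error naming the
collinear columns) → a final re-detrend (default on). Realignment,
slice-timing and spatial normalisation are out of scope: inputs are assumed
pre-aligned on a common grid with motion parameters given.

## Degree centrality

Binary degree (count of r > 0.25, strict inequality — ties are a
measure-zero event and excluding them keeps the map deterministic) is the
default; a weighted mode (sum of suprathreshold positive r) is available.
Correlations and the mask are both restricted to the provided gray-matter
mask. The pairwise pass is chunked ((chunk × V) correlation blocks) so
memory is O(chunk·V); results are chunk-size invariant (bit-identical in
binary mode), verified against an O(n²) brute-force oracle. Z-scoring uses
the population (divisor-n) sd and precedes smoothing, matching the
published order; smoothing is mask-renormalised separable Gaussian
convolution (per-axis σ = FWHM/(voxel·√(8 ln 2)), kernel truncated at 6σ),
which preserves constants and lets nothing bleed in from outside the mask —
important for small synthetic brains where zero-padding would attenuate
edges.

## Group statistics

The voxelwise GLM is OLS with t = c·β̂ / √(σ̂² c(XᵀX)⁻¹cᵀ), df = n − rank(X);
with no covariates this reduces exactly to the pooled two-sample t (tested
to 1e-10). Residual smoothness: each subject's residual field is
standardised to unit variance over the mask and the mean squared forward
difference along each axis gives FWHM_a = √(4 ln 2 / λ_a) voxels; the resel
count is V/∏FWHM. On noise smoothed with a known 6 mm kernel the estimator
is biased high by ~9% (finite-difference derivatives on a lattice), within
the 15% band we require.

Cluster inference forms 26-connected components above the per-tail
t-quantile matching Gaussian height u = Φ⁻¹(1 − 0.001) (the t field is
Gaussianised through its p-values, adequate at the df > 30 used here), and
assigns each cluster the RFT extent p described in the README. Two design
choices deserve note:

- **Two-sidedness.** Both tails are thresholded at voxel p < 0.001 and the
  Poisson combination uses the expected cluster count summed over both
  tails, so "any surviving cluster of either sign" is controlled at the
  nominal cluster p. Under 500 null simulations the realised familywise
  rate is ~0.01–0.02 — conservative, as expected for cluster RFT at ~2
  voxel FWHM where lattice clusters are smaller than the continuum
  approximation assumes. The permutation oracle is the arbiter where the
  analytic approximation is doubtful: on simulated datasets the two methods
  agree on every cluster whose corrected p is clearly away from the
  decision boundary (outside (0.01, 0.2)).
- **Freedman–Lane permutations.** The reduced model (design minus the group
  column) is fitted, its residuals are permuted and added back to the
  reduced fit, and the full-model maximum suprathreshold extent over both
  tails forms the null; corrected p = (1 + #{max ≥ k})/(1 + n_perm), with
  the usual 1/(n_perm+1) floor.

Demographics: Pearson chi-square on the 2×2 sex table **without continuity
correction** (the convention that reproduces the published p = 0.401 on the
102/96 vs 130/104 table; Yates' correction would not), pooled-variance
two-sample t for age and education, and a descriptive summary for HRSD-17
(present in one group only).

## Classification

RBF C-SVC with patient fixed as the positive class. The published analyses
of this kind rarely state their cross-validation scheme, so the default is
defensible modern practice: stratified 10-fold outer CV, inner 5-fold grid
search (C ∈ 2^{−5..15}, γ ∈ 2^{−15..3}), standardisation fit on training
folds only, confusion counts pooled over held-out predictions, everything
seeded. A `paper_style` flag instead runs one grid search on the full
sample and cross-validates at those fixed hyperparameters — the optimistic
LIBSVM-default workflow — for comparison. Reported best_C/best_gamma under
the nested scheme are the modal inner choice (reporting only; predictions
are fully nested). If all feature rows are identical the classifier is
degenerate and the majority-class baseline is reported with a warning.
Label permutation of separable clouds yields mean held-out accuracy
0.497 ± — i.e. chance — confirming no information leaks through
standardisation or the grid search.

Clinical correlations are two-sided Pearson tests per (ROI, variable) over
patients, uncorrected for multiplicity (the output column says so).

## Numerical conventions and degenerate inputs

Voxel indices are 0-based internally; world coordinates only ever come from
the affine, and reported peaks are in mm. Constant voxel series (exact
ptp = 0) are rejected with their coordinates listed; constant DC maps
cannot be z-scored; empty suprathreshold sets yield an empty cluster list,
not an error; permutation runs with n_perm < 100 log a warning but proceed.
NIfTI data are stored float32 (round-trip within float32 eps), masks uint8,
affines exact. All cohort outputs are byte-identical across runs with the
same config and seed.

## Problem sizes used in the validation suites

Null calibration and RFT/permutation concordance simulate subject-level
maps directly (smoothed unit-variance fields, 24×24×18 grid, 20+20
subjects, 500 null datasets / 20 concordance datasets × 500 permutations):
for these questions the BOLD-to-DC stages contribute nothing but runtime.
The effect-recovery experiment, which must exercise the whole chain, runs
the full simulate → preprocess → DC → GLM → RFT pipeline 50 times on a
reduced cohort (18×18×12 grid, 125 volumes, 12 subjects per group) with
the **default** planted loadings; at that size recovery of the elevated hub
with the correct sign is essentially certain (50/50 in the shipped run).

## Known limitations

- The ideal FFT band-pass assumes circularity; very short or strongly
  trending series can ring. The final re-detrend mitigates the latter.
- The Gaussianised-t RFT approximation degrades below df ≈ 10 (guarded by
  an error) and the extent approximation is conservative at smoothness
  near the voxel size; permutation inference is provided precisely for
  those regimes.
- Binary degree at a fixed r threshold ignores connection strength above
  threshold; the weighted mode is provided but the binary convention is
  the default because it is the one the thresholded-degree literature
  standardised on.
- The simulator's group effect enters only through network loadings; it
  cannot, by construction, validate claims about clinical correlates.
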