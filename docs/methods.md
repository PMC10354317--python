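# Methods

This note records the models, parameter choices and numerical decisions
behind `ramantriage`, and what the synthetic experiments do and do not
demonstrate.

## The study design the package implements

The analysis chain mirrors a two-cohort diagnostic evaluation of a serum
Raman test for colorectal cancer:

1. a **retrospective training cohort** of known cancers and controls,
   age- and sex-matched 1:1 by propensity score into a 50:50 training set
   (300 patients by default);
2. a **prospective referral cohort** (532 patients at ~5% CRC prevalence by
   default) evaluated blind: spectra are preprocessed and scored without
   any access to diagnoses, each patient's per-spectrum cancer
   probabilities are averaged, and the fixed threshold ≥ 0.5 classifies
   CRC;
3. **patient-flow rules** before evaluation: patients verified only by
   flexible sigmoidoscopy are excluded, as are patients with no reference
   test or no final diagnosis; results are reported per reference standard
   (colonoscopy alone as gold standard, and colonoscopy plus CT
   colonography), with exact binomial confidence intervals and a
   stage-stratified sensitivity table.

Blinding is structural, not procedural: `model.predict_patients` takes a
model artifact and processed spectra only — there is no argument through
which an outcome could reach the classifier, and a test exercises this by
scrambling every diagnosis on disk and asserting bit-identical predictions.

## Synthetic spectra

No public serum Raman dataset accompanies this design (clinical serum
spectra are not deposited), so the simulator is a first-class module and
the package's experiments run entirely on synthetic cohorts with known
ground truth.

A spectrum is a sum of bands on a fluorescence background plus noise,
sampled on 601 points across the 600–1800 cm⁻¹ fingerprint region:

- **Band library** (defaults): 11 Gaussian bands at serum-typical shifts —
  phenylalanine 621/1004, tyrosine 643/852, tryptophan 757, carotenoids
  1157/1518, amide III 1246, nucleic acids/CH 1336, CH₂ 1450, amide I
  1655 cm⁻¹ — with amplitudes of tens to low hundreds of counts. The
  library is a documented, configurable stand-in: no published numerical
  description of serum spectra underlies it.
- **Between-patient biology**: a lognormal overall serum scale
  (sd 0.08) and independent lognormal per-band amplitude jitter (sd 0.20)
  per patient. Replicates share the patient's amplitudes.
- **Disease effect**: cases multiply selected band amplitudes by fixed
  factors — carotenoid depletion (1157 × 0.855, 1518 × 0.840), raised
  nucleic-acid and amide III signal (1336 × 1.123, 1246 × 1.083), reduced
  tyrosine (852 × 0.914). The directions follow what is generally reported
  for cancer sera; the magnitudes were calibrated once so that the default
  pipeline operates at a held-out patient-level AUC of roughly 0.8–0.85 on
  a 300-patient 50:50 cohort, the regime a pilot-stage spectral classifier
  plausibly occupies. `scaled_effect_map` scales every factor's
  log-distance from 1, giving a clean knob for effect-size sweeps.
- **Background and noise**: a random nonnegative cubic polynomial
  (scale 400 counts, decaying toward high wavenumber) emulates
  fluorescence, with lognormal per-replicate scale jitter (sd 0.10);
  additive Gaussian detector noise (sd 4 counts by default) and an
  optional Poisson-like shot-noise term. Cosmic-ray spikes are isolated
  single-point positive excursions with Poisson-distributed count;
  miscalibration is an affine axis map `axis' = gain·axis + offset`.
- **Cohort structure**: prevalence is fixed (`round(n·prevalence)` cases)
  by default for reproducibility, or binomial on request. Stage
  probabilities default to 4/29, 10/29, 12/29, 3/29 over UICC I–IV.
  Reference tests are apportioned by largest remainder from a default mix
  (248/532 colonoscopy, 157/532 CT colonography, 64/532 flexible
  sigmoidoscopy, 63/532 none) with cancers always assigned a definitive
  reference, so the default 532-patient cohort reproduces the flow
  532 → 405 retained with a 248-patient colonoscopy stratum exactly.
  Cases are on average older and more often male than controls, which
  gives the propensity matching real work to do.

What the simulator does **not** model: instrument response and substrate
signal, wavelength-dependent detector efficiency, serum batch effects,
inter-instrument transfer, non-CRC pathology with its own spectral
signature, and correlation between bands beyond the shared patient scale.
Passing tests therefore demonstrate that the pipeline recovers the truth
of this generative model at realistic sizes and noise levels — not that
the clinical test performs at any particular level on real sera.

## Preprocessing

Operator order is fixed: wavenumber calibration → binning → smoothing →
background subtraction → normalisation (optional despiking first). Each
step appends a provenance record with its parameters.

- **Calibration** detects reference bands (defaults 852, 1004, 1157,
  1518 cm⁻¹ — spanning the axis, avoiding overlapped doublets and the very
  broad amide I band) by fitting a Gaussian plus straight line in a
  ±20 cm⁻¹ window of a lightly smoothed copy, then regresses expected on
  detected positions. Two refinements matter numerically: the search
  windows are re-centred once using the first-pass fit (bands truncated at
  a window edge otherwise bias the centre under large perturbations), and
  the gain is kept only when it differs from 1 beyond four standard
  errors — estimating a gain that is truly 1 inflates the offset variance
  about fourfold, because the intercept extrapolates to 0 cm⁻¹. Mean
  absolute offset-recovery error over injected offsets in [−3, +3] cm⁻¹ is
  ≈ 0.15 cm⁻¹ at 2-count noise. Fewer than two detectable bands is an
  error (the affine map is underdetermined); residuals above 2 cm⁻¹ flag
  the spectrum without failing it.
- **Binning** averages intensities into half-open bins [edge, edge+step)
  on a 610–1790 cm⁻¹ grid with 4 cm⁻¹ steps (295 features); empty bins are
  linearly interpolated and counted in provenance.
- **Smoothing** is Savitzky–Golay, window 11, order 3, endpoint handling
  by polynomial fit on the truncated window. Signals that are polynomials
  of degree ≤ order pass through exactly, which is the operator's test
  surface.
- **Background subtraction** defaults to asymmetric least squares (Eilers
  & Boelens: second-difference penalty λ = 1e5, asymmetry p = 0.01,
  iterated to a weight fixed point, max 50 iterations — exceeding the cap
  raises an error carrying the iteration count). An iterative-polynomial
  alternative (fit, clip, refit; order 5) is available. No clipping of
  negative residuals afterwards: clipping would destroy the linearity that
  the recovery tests rely on, and downstream normalisation does not
  require positivity.
- **Normalisation** is vector L2 by default (‖values‖₂ = 1 to 1e-12),
  total-area (trapezoidal integral = 1) as option. All-zero input is an
  error, not a silent pass-through. The invariant is asserted for every
  spectrum of every run.

Nothing in the module is stochastic; reruns are bit-identical.

## Matching, model, evaluation

- **Propensity matching**: logistic regression of case status on age and
  sex (effectively unpenalised), greedy 1:1 nearest-neighbour on the logit
  in descending case-score order with ties broken by patient id, caliper
  0.2 × SD(logit), controls used at most once. Everything is deterministic
  without a seed. Complete covariate separation raises an error only when
  no caliper is active: with a caliper, degenerate scores fall outside it
  and matching correctly returns zero pairs.
- **Random forest**: 500 trees, √p features per split, unlimited depth by
  default (smaller forests are used in tests and the acceptance script,
  where 200 trees give indistinguishable AUCs at half the cost). Rows are
  spectra; the patient is the unit of inference everywhere else.
- **Cross-validation** is stratified by class and grouped by patient —
  all of a patient's replicates stay in one fold, since splitting them
  would leak within-patient correlation into the held-out estimate. Fold
  metrics (sensitivity and specificity at the 0.5 patient threshold, AUC)
  are computed after per-patient aggregation; the "typical fold" is the
  fold at the median AUC (lower median for even counts).
- **Aggregation** is the arithmetic mean of per-spectrum probabilities;
  the boundary 0.5 classifies as CRC. The mean (rather than, say, a
  geometric pooling) keeps the boundary behaviour simple and matches the
  plain reading of "average probability".

## Diagnostic statistics

Clopper–Pearson intervals come from beta quantiles; an independent
bisection on binomial tail sums reproduces them to 1e-6 for all x ≤ n ≤ 30
in the test suite, and a Monte-Carlo check confirms ≥ 95% coverage (exact
intervals are conservative). AUC uses midranks, making it exactly the
pairwise concordance probability — verified against exhaustive pair
counting on hundreds of small tied instances. The Buderer sample size uses
floor truncation: 1.96² · 0.09 / 0.01 / 0.05 = 691.49 truncates to the
conventional 691; a ceiling rule would print 692. Reported percentages use
half-up rounding to one decimal.

One reporting subtlety is documented rather than hidden: for 26 of 29
detected cancers, the exact Clopper–Pearson lower bound is 0.726485, which
rounds to 72.6% at one decimal; clinical reports sometimes print 72.7% for
this quantity via double rounding (0.7265 → 72.7). The package computes
and asserts the exact value. Likewise, a specificity interval of
"69.3 (63.8–76.1)" on 225 non-diseased patients is not reproducible as
Clopper–Pearson for the unique consistent count 156/225 (CP gives
62.9–75.3); the package applies Clopper–Pearson uniformly and makes no
attempt to reverse-engineer a different interval.

## Problem sizes and seeds

The acceptance script and the heavier tests use 300-patient, 3-replicate
cohorts (900 spectra, 295 features) with 5×5 patient-grouped CV and
200-tree forests — sizes at which the null band (AUC 0.40–0.60 with zero
effect) and the calibrated default band (0.75–0.90) are stable across
seeds while a full run stays in the minutes range. A single top-level seed
fans out deterministically to simulation, fold shuffling and forest
construction; identical configs reproduce byte-identical reports.

## Known limitations

- The simulator's band-amplitude model is additive and lognormal; real
  serum spectra have correlated band structure and matrix effects the
  generator does not attempt.
- Calibration assumes at least two well-separated reference bands with
  roughly Gaussian tops; heavily overlapped or saturated bands would need
  a different localiser.
- The propensity model uses two covariates (age, sex) as the design
  specifies; the machinery generalises but no other covariates are wired.
- Threshold 0.5 is fixed by design, not tuned; no decision-curve or
  predictive-value analysis is included.
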