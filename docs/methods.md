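# Methods

## Problem and pipeline

`physioattn` detects a binary attention state (engaged vs. disengaged) from
single-channel physiological recordings. Two modalities are supported, each
with its own decomposition:

* **ECG** (128 Hz): smooth → remove baseline wander → split by annotation →
  10 s windows → discrete Stockwell transform (S-transform) → 27 statistics
  per window.
* **EEG** (1000 Hz): Butterworth band split (Delta 0.2–4, Theta 4–8,
  Alpha 8–13, Beta 13–30, Gamma 30–55 Hz) → split by annotation → 10 s
  windows per band → 5-level DWT with band-specific mother wavelets →
  7 statistics × 6 coefficient vectors × 5 bands = 210 per window.

Feature tables are evaluated under leave-one-subject-out (LOSO)
cross-validation with three tree classifiers: an entropy-split decision tree
(C4.5 family), classification-via-regression (per-class indicator regression
trees, argmax), and a 100-tree random forest. Reported metrics per
classifier are unweighted across-fold means of accuracy, specificity and
sensitivity, with "attention" as the positive class.

## ECG preprocessing

Savitzky-Golay smoothing uses a 15-sample cubic frame by default — at 128 Hz
a ~0.12 s frame that suppresses wideband noise while leaving QRS complexes
essentially intact (the filter reproduces cubic segments exactly). Both
parameters are configurable.

Baseline wander is removed by subtracting, from every consecutive window of
`round(rate)` samples (one second), the ordinary least-squares line fitted to
that window:

    m = (n Σxy − Σx Σy) / (n Σx² − (Σx)²),    b = (Σy − m Σx) / n.

Because each fit has an intercept, per-window residuals sum to zero exactly
and the operation is idempotent. Boundary policy: a trailing partial window
of ≥ 2 samples gets its own fit; a single trailing sample passes through.
Per-window subtraction leaves small step discontinuities at window joins;
no blending is applied. Annotated segments are cut out *after* cleaning,
as half-open sample ranges `[floor(start·rate), floor(end·rate))`.

## Discrete S-transform

For a length-N window with normalized spectrum
`H[n] = (1/N) Σ_k h[k] e^{−2πink/N}`, each retained voice n > 0 is

    S[j, n] = Σ_{m=0}^{N−1} H[(m+n) mod N] · e^{−2π²m²/n²} · e^{2πimj/N},

one output column per input sample. Three conventions deserve note:

* **Gaussian sign.** The transform is only convergent with a negative
  exponent in the Gaussian factor; the implementation uses
  `exp(−2π²m²/n²)` (the original Stockwell form).
* **DFT sign pairing.** The forward DFT uses the standard `e^{−2πink/N}`
  kernel; the voice sum uses `e^{+2πimj/N}`. The two must be opposite for
  the time-marginal identity `mean_j S[j,n] = H[n]` to hold — that identity
  is asserted in tests to 1e−12 and is the strongest single correctness
  check of the implementation.
* **One-sided Gaussian.** The Gaussian factor is evaluated literally on
  `m = 0..N−1` (the spectral shift index does wrap modulo N). Common
  S-transform codes instead use a symmetric wrapped Gaussian; the one-sided
  form is retained here and the FFT-per-voice fast path is verified
  element-wise against a naive O(N²) evaluation of the same sum.

Voices are stepped at 1 Hz (a 10 s window has 0.1 Hz native resolution, so
every 10th voice is computed — neighbouring voices are not averaged) up to
Nyquist; the 0 Hz row is defined as the window mean and included in feature
reduction by default (a flag excludes it).

## ECG features (27)

On the magnitude matrix |ST|: per time column — mean, sum, product,
population standard deviation, range across frequencies (5 series); per
series — mean, sum, mean of the autocovariance sequence, sum of the
autocorrelation sequence, log2 of variance (25 values); plus the mean over
time of per-column maxima and the grand mean absolute deviation (2 values).

Statistic conventions (fixed package-wide): population variance (divide by
n); biased autocovariance over all non-negative lags
`c(l) = (1/n) Σ_t (x_t−x̄)(x_{t+l}−x̄)`; autocorrelation `r(l) = c(l)/c(0)`.
Magnitudes (not real parts or powers) are used because products, ranges and
maxima are not meaningful on complex values. The per-column product
multiplies ~65 values typically far below one, which underflows a naive
product; it is computed as `exp(Σ log)` with factors clamped at the smallest
positive normal float. Undefined values — log of zero variance,
autocorrelation of a constant series — become an `NA` sentinel, never a
silent zero.

## EEG features (210)

Mother wavelets per band: `db4` (Delta, Theta, Alpha), `coif3` (Beta),
`bior3.9` (Gamma); 5 cascade levels; symmetric (half-sample) boundary
extension. D1..D5 and A5 are retained. The seven statistics per coefficient
vector:

1. **rms** — `sqrt((1/n) Σ x²)`, implemented exactly as the defining formula
   (which is labelled a standard deviation but contains no mean-centering);
   a `centered` flag switches to the conventional population SD.
2. **entropy** — Shannon entropy in bits of the normalized equal-width
   histogram. Bin count defaults to a Rice-style `2⌈n^{1/3}⌉` and is
   configurable; empty bins are skipped.
3. **log2 of variance** (population).
4. **fourier_mean** — mean of the unnormalized DFT magnitudes (a complex
   mean would largely cancel and duplicate the signal mean).
5. **hist_var** — population variance of the normalized histogram vector,
   i.e. of the empirical probability distribution itself (the alternative
   reading — variance of the data — would duplicate statistic 3's argument
   and was rejected as redundant).
6. **autocorr_sum**, 7. **autocov_mean** — same conventions as the ECG side.

Energy is conserved through the cascade for the orthogonal wavelets (db4,
coif3, asserted in tests with 5% slack for boundary coefficients) but *not*
for the biorthogonal bior3.9, where no such assertion is made.

## Classification details

NA sentinels are imputed with training-fold medians only. The
classification-via-regression construction fits one
`DecisionTreeRegressor` per class on 0/1 indicator targets and predicts the
argmax; for two classes this reduces to thresholding a single indicator tree
at 0.5 when the trees agree. Random forest size (100), tree depth (none) and
seeds are config-exposed. A fold whose test subject lacks positives reports
NaN sensitivity and is excluded from the average with a warning.

## Synthetic cohorts

No recordings ship with the package; the generator emulates the acquisition
design (two ~20-minute stimulus conditions per subject; 21-subject ECG and
12-subject EEG cohorts) so the pipeline is testable end to end.

* **ECG**: a train of Gaussian-bump PQRST complexes. Per subject, a resting
  RR interval is drawn lognormally around 0.85 s (≈ 71 bpm, subject SD 5%)
  with RR variability 6% of RR. During attention the mean RR is multiplied
  by `exp(−0.08·effect_size)` and the RR SD by `exp(−0.40·effect_size)` —
  arousal shortens and regularizes the beat interval; the direction is a
  modelling choice, not an empirical claim. Additive slow sinusoidal
  baseline wander (two components at 0.12–0.40 Hz, default amplitude 0.3 of
  the R peak) and white noise (default SD 0.05) give the preprocessing
  stages something real to remove.
* **EEG**: a sum of five band-limited noise processes (white noise filtered
  into each canonical band), with resting RMS amplitudes 2.0 / 1.2 / 0.9 /
  0.55 / 0.35 (Delta…Gamma) and 10% lognormal subject offsets. Attention
  multiplies Beta and Gamma amplitude by `exp(+0.3·effect_size)` and Theta
  and Alpha by `exp(−0.3·effect_size)`; Delta is state-independent.

Randomness is counter-based: every (seed, subject, modality) triple owns an
independent `SeedSequence`-derived stream, so cohorts are bit-reproducible
element-wise and the wander/noise amplitude settings do not perturb the beat
train. At `effect_size = 0` the two conditions are draws from identical
distributions; windows are then exchangeable across labels, which the
chance-level acceptance check relies on.

What the generator deliberately does not model: true PQRST morphology
dynamics, respiratory sinus arrhythmia coupling, EEG artifacts (blinks,
EMG), 1/f broadband background, or any within-condition drift. Passing
tests therefore demonstrate that the pipeline recovers rhythm- and
band-power-coded state differences through its full chain — not that these
accuracies transfer to human recordings.

## Problem sizes and evaluation conditions

The recovery check runs 21-subject ECG cohorts at the full 20-minute
condition length (240 windows/subject, 5040 windows/cohort) over a 5-seed
grid, at `effect_size = 2.0` ("high contrast") and at 0. The EEG evaluation
in the acceptance script uses one 12-subject cohort at the same durations.
The monotonicity property test uses a reduced cohort (4 subjects, 60 s
conditions) purely to keep the property cheap to evaluate repeatedly.

## Known limitations

* The one-sided Gaussian voice window slightly leaks wrapped spectral
  content (e.g. a constant signal leaves ~1e−11 in the highest voice); this
  is a property of the literal transform definition, preserved by design.
* Whether the original feature set computed statistics on magnitudes, real
  parts or powers of the S-transform is not determinable from its
  description; magnitude was chosen and documented.
* The log-domain product feature deliberately avoids the underflow a naive
  product would suffer; a degenerate (all-underflow) product feature cannot
  be reproduced here.
* Baseline removal assumes an integer-ish sampling rate ("one-second"
  windows of `round(rate)` samples); heavily non-integer rates shift window
  boundaries off exact seconds.
* EDF import is not provided; recordings enter through the plain-text
  dialect described in the I/O module.
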