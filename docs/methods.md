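# Methods notes

This note records the modeling choices behind tremorkit, the reasoning
where the design was genuinely open, and what the synthetic experiments do
and do not establish.

## Signal model and preprocessing

Wrist acceleration is treated as a sum of gravity (quasi-static, below
0.3 Hz), voluntary movement (activities of daily living, ADL; energy
concentrated below 3 Hz), PD tremor (a narrowband oscillation with base
frequency f₀ in 3–9 Hz plus harmonics at 2f₀ and 3f₀), and broadband
sensor/body noise.  All stages work at 50 Hz; information above 25 Hz is
negligible for these signals.

* **Resampling.** Polyphase anti-aliased resampling; the common 100 Hz
  input is decimated by 2 with a zero-phase filter.
* **Gravity removal.** Third-order Butterworth high-pass at 0.3 Hz,
  applied forward-backward.  Zero-phase filtering was chosen because the
  analysis is offline; a causal filter would delay events by the group
  delay and misalign them with interval annotations.
* **Windows.** 150 samples (3 s) with a 50-sample hop; the trailing
  partial window is dropped, and the first window starts at the first
  sample.  A window is tremor iff its overlap with annotated events
  exceeds 1.5 s strictly; exactly 50 % counts as non-tremor.
* **Spectral grid.** One grid for everything: the Hamming-tapered window
  is zero-padded to 256 points and the first 128 one-sided amplitude bins
  (0–24.8 Hz, step ≈ 0.195 Hz) are kept.  PSD features, the tremor
  factorization and the spectral CNN inputs all share this grid.

## Non-negative tremor factorization

Each axis of each window is factorized independently:
Ŝ = (wᵗT) ∘ (wʰH) + wᵃA, with all weights non-negative.

* **Tremor dictionary T.** 60 rows, base frequencies every 0.1 Hz on the
  half-open interval [3, 9) — the half-open grid honors the row count of
  60 (an inclusive grid would give 61).  Each row is
  Σₖ aₖ·|sinc((f − k·f₀)/Δ)| with Δ = 1/3 Hz (the spectral resolution of
  a 3-s window) and harmonic amplitudes a = (1, ½, ¼), a typical harmonic
  roll-off.  A final all-ones row models "no movement"; its fitted weight
  is used as a threshold below which all other source weights are zeroed.
* **Shape/non-tremor dictionaries H, A.** 63 Hann bumps of width 5 grid
  points centered at even grid indices 2..126 (50 % overlap); A = H.
* **Optimization.** Multiplicative updates in the order source, shape,
  non-tremor, recomputing the reconstruction after every update;
  denominators are floored at 1e-12 and weights are initialized to ones
  (deterministic, no seed).  Each block update is the Lee–Seung rule for
  a model linear in that block, so the Euclidean objective is
  non-increasing; 100 iterations are used throughout.
* **Personalization.** The subject's average power spectrum (mean of
  squared amplitude spectra over all their windows and axes,
  max-normalized) multiplies the 60 tremor rows; f₀ is the highest local
  maximum of the average spectrum within 4–8 Hz; after fitting and
  thresholding, only the three largest source weights within ±1 Hz of f₀
  are kept (ties break toward lower frequency; applied once, after the
  final iteration — imposing the support earlier would freeze it under
  multiplicative updates).  Degenerate average spectra (all-zero, or no
  peak in band) leave the dictionary unpersonalized with a warning.
* **Identifiability, and what NTF is for.** The non-tremor dictionary can
  express narrow bumps, so for a pure synthetic comb whose teeth happen to
  align with Hann-basis centers the tremor/non-tremor energy split is
  ambiguous and the update dynamics, not the objective, decide it.  NTF is
  therefore used as a *feature extractor* (inputs to MFCC-T/NT and the
  spectral CNN, and an unsupervised energy ranking for MIL
  initialization), not as an exact source separator.  For the same reason
  raw source weights are not comparable across rows (source and shape are
  identified only up to a shared scale); the base-frequency estimator
  `estimate_base_frequency` weights each surviving row by the energy it
  actually contributes to the tremor spectrum, ‖wᵢ·tᵢ ∘ S_shape‖².

## Feature sets

Dimensions are fixed contracts: energy 1, PSD 3×128, baseline 356, MFCC
36, MFCC-T/NT 108.  Choices the baseline set needed but that are not
uniquely determined by convention: ECDF(4) = signal quantiles at levels
0.2/0.4/0.6/0.8; IQR(2) = the 25th and 75th percentiles; entropy = Shannon
entropy of the 16-bin histogram of |x| (time domain) or of the normalized
spectrum (frequency domain); AR(2) by Yule–Walker; dominant frequency =
spectral argmax; average frequency = spectral centroid; six equal-width
band energies over 0–25 Hz; jerk = first difference × sample rate;
correlations of constant channels defined as 0.

The cepstral pipeline uses 26 triangular mel-spaced filters over
0.3–25 Hz (the mel band rescaled from the speech convention to the
accelerometer bandwidth), a log with floor 1e-10, and an orthonormal
DCT-II keeping c1–c12; excluding c0 makes the coefficients invariant to
overall amplitude scaling.  MFCC-T/NT applies the same filterbank/log/DCT
stack to the total, tremor and non-tremor spectra of each axis (the FFT
stage is skipped because the spectra are already on the shared grid).

## Classifiers

No deep-learning framework is required: `tremorkit.nn` is a small numpy
engine (dense and "same"-padded convolution layers, ReLU/sigmoid,
inverted dropout, RMSProp, binary cross-entropy, early stopping) whose
runs are bitwise reproducible for a fixed seed.

* **RF** — 100 trees (scikit-learn); scores are tremor vote fractions.
* **MLP** — 128/32/1, dropout 0.2 after hidden layers, batch 50, RMSProp
  at the 1e-3 default rate, epochs selected by early stopping (patience 5)
  on a 20 % validation split; inputs are z-scored with training-split
  statistics.  For frozen CNN feature maps the z-scoring is disabled
  (per-dimension rescaling of sparse ReLU activations amplifies inactive
  units and destroys the feature ordering).
* **CNN (raw)** — 16 length-25 kernels applied per axis with "same"
  padding, max-pool 4, dense 128/64/32/1.  **CNN (spectral)** — 32 kernels
  3×9 then 16 kernels 3×5 on the 9×128 spectra stack; the second
  convolution's output is the learned feature map, then dense 128/32/1.
  Kernel counts and dense widths were sized to keep parameters well below
  the synthetic-data size.  Convolution kernels are initialized from a
  3-layer patch autoencoder (10 epochs, MSE, RMSProp) and then rescaled to
  unit pre-activation variance on the sampled patches — without the
  rescaling the autoencoder init saturates downstream layers and training
  collapses.  Remaining layers are Glorot-uniform.

## Weak supervision (MIL)

Diary entries rate 5-minute intervals on three levels.  Each iteration
scores all windows, sorts each interval's windows, and selects: bottom
50 % (label 0) for *almost none*, top 50 % (label 1) for *almost always*,
bottom 25 % + top 25 % for *half the time*; counts use floor with a
minimum of 1, sorting is stable so ties fall back to window order, and
intervals with fewer than 4 windows are skipped.  The first ranking uses
the NTF tremor-energy score, since no classifier exists yet.  Retraining
uses only the latest selections (the loop re-selects every iteration).
Stopping: 20 % of subjects' entries are held out; the validation metric is
the Spearman correlation between predicted interval labels (fraction of
windows scoring above 0.5, mapped through the percentage thresholds) and
the reported labels; training stops after 3 iterations without improvement
or at the iteration cap, and the best-validation model is returned.

## Evaluation

Aggregate performance is the mean of per-subject AUCs (not pooled
windows) under LOSO.  FPR at 0.90 TPR is linearly interpolated between
ROC points (a step function would overstate it).  AUC differences can be
tested with the Hanley–McNeil standard error and an independent two-sided
z-test.  Percentage of tremor time is the fraction of tremor-classified
windows per consecutive period; the diary mapping uses <33 → *almost
none*, [33, 66] → *half the time* (boundaries inclusive), >66 → *almost
always*, with inverse midpoints 16.6 / 50 / 83.3 %.  Hands are evaluated
independently.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes:
100 Hz recordings (so the 2:1 resampling path is exercised) containing
gravity with slow orientation drift, low-passed (<3 Hz) Gaussian ADL
motion, broadband 3–9 Hz confounder bursts without harmonic structure
(≈5 % of time — vigorous movements that fool plain band energy), tremor
bursts with Hann on/off envelopes whose off periods are exponential so
expected coverage matches the subject's prevalence, and a 0.01 g white
noise floor.  Tremor is not a pure sinusoid: the instantaneous frequency
wanders ≈±0.3 Hz and harmonic amplitudes fluctuate slowly, as
physiological tremor does — this broadens the spectral lines and is what
makes cepstral features transfer across subjects.  Default cohort: 30 min
per hand, one diary entry per 5 minutes with 10 % label noise, f₀ drawn
from 4.3–7.5 Hz, tremor amplitude 0.12–0.25 g, ADL RMS 0.03–0.08 g, and a
prevalence spread that always includes a ≤5 % and a ≥60 % subject.

What passing tests on this cohort show: the pipeline's stages compose
correctly, the factorized-spectrum features separate tremor from
confounded backgrounds where plain band energy cannot, weak supervision
converges in a handful of iterations without degrading, and the
percentage-of-tremor metric concentrates with averaging period.  What
they do not show: performance on real PD data — real tremor is
non-stationary in ways the generator does not model (dyskinesia,
medication cycles, posture changes), real ADL is far richer, and diary
noise is not independent across entries.

Problem sizes in the test suite are scaled to desk hardware: the
discrimination checks run on the default 6-subject cohort, the MIL
cross-validation check on a 4-subject, 10-minute cohort, and the CNN
ordering check on a 3-subject, 4-minute cohort with a single train/test
split.

## Known limitations

* **Cross-subject transfer of cepstral features needs cohort coverage of
  the tremor-frequency range.**  An MLP trained on subjects whose f₀ all
  lie away from the test subject's can misrank that subject's windows
  badly (the mel-cepstral encoding of a shifted peak is not linearly
  transferable), while RF and the unsupervised energy ranking degrade
  gracefully.  Small cohorts drawn with an isolated-f₀ subject show this;
  larger cohorts wash it out.
* The tremor/non-tremor energy split of NTF is not identifiable for
  spectra that the non-tremor dictionary can express equally well (see
  above); downstream stages do not rely on the split being exact.
* Severity (amplitude) calibration, on-line operation and device formats
  beyond plain CSV are out of scope.
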