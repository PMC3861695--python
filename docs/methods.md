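# Methods

## Overview

`nirstate` implements an end-to-end analysis for decoding task engagement
from functional near-infrared spectroscopy (fNIRS), together with a
forward simulator that generates the raw two-wavelength recordings the
analysis consumes. The measurement model is a block-design selective
attention experiment (the multi-source interference task, MSIT) recorded
from two cortical regions with opposite task responses: the right
dorsolateral prefrontal cortex (DLPFC, task-positive — its activity rises
during task blocks) and the anterior medial frontal gyrus (MFG,
task-negative — its activity falls during task blocks, as part of the
default-mode network). The analysis recovers hemoglobin concentration
changes from raw intensities, removes superficial physiology with
short-separation channels, selects the best task-responding traces by GLM
fit, decodes task vs. rest per time point with an RBF-kernel SVM under
leave-one-run-out cross-validation, and summarizes the network structure
with within-/across-network correlations.

## Experimental design

Each run is 400 s at 6.25 Hz (2500 samples): a 16 s initial rest block
followed by 12 alternations of 16 s task (8 MSIT trials) and 16 s rest.
MSIT stimuli are four-digit strings in which a target digit differs from
three distracters; congruent stimuli are 1111/2222/3333/4444 and
incongruent stimuli are 2111/2122/3343/4443, with the digit family
({1,2} vs {3,4}) alternating between consecutive trials. Truth labels for
classification map task samples to +1 and rest to −1 and are delayed by
4 s (25 samples) to account for hemodynamic lag; samples before the first
shifted label are filled with −1, since every run opens with rest. The
labels are delayed, not wrapped: any samples shifted past the run end are
dropped (with the default design the last task block ends 16 s before the
run end, so no task samples are lost).

## Forward model (synthetic data)

Per region, the neural response is `amplitude × (boxcar ⊛ HRF)`,
peak-normalized so the amplitude parameter is the peak hemoglobin
excursion in µM. The HRF is the canonical double-gamma (response peak
6 s, undershoot 16 s, undershoot ratio 1/6) — no specific HRF is implied
by the measurement model, so the standard choice is used and is
configurable. Deoxygenated hemoglobin (HbR) responses are the negated HbO
responses scaled by `hbr_ratio`.

Per detector, a superficial physiology trace is the sum of sinusoids at
cardiac (1.1 Hz), respiratory (0.25 Hz) and Mayer-wave (0.1 Hz)
frequencies with random phases, plus a random-walk drift. Deep (3 cm)
channels receive the regional neural signal scaled by a per-channel gain,
plus `coupling ×` the superficial trace, plus a spontaneous hemodynamic
background shared by all deep channels of the region, plus independent
white noise and a small instrumental drift. Shallow (1 cm) channels
receive the superficial trace plus independent noise only. Raw
intensities at 690 and 830 nm are produced by the modified Beer-Lambert
law (MBLL) run forward: ΔOD(λ,t) = (ε_HbO(λ)ΔHbO + ε_HbR(λ)ΔHbR)·d·DPF(λ)
and I = I₀·10^(−ΔOD), with the standard compiled extinction spectra
(ε in mM⁻¹cm⁻¹: 0.2764/2.0516 at 690 nm, 1.0585/0.7811 at 830 nm for
HbO/HbR), DPF = 6.0 at both wavelengths, and I₀ = 5000 ADC counts. The
10^(−ΔOD) form guarantees strictly positive intensities.

### Default parameters and calibration

| parameter | default | rationale |
| --- | --- | --- |
| DLPFC amplitude | +0.40 µM | peak activation excursion |
| MFG amplitude | −0.30 µM | task-negative deactivation, somewhat weaker than the activation |
| `hbr_ratio` | 0.4 | HbR excursions are smaller in magnitude than HbO; also makes HbO traces the systematically best-fitting species so trace selection is sign-stable |
| DLPFC channel gains | 1.0 … 0.3 | probes differ in cortical sampling; low-numbered channels best |
| `coupling` | 0.8 | superficial contamination of deep channels |
| `noise_sd` | 0.8 µM | independent white measurement noise per sample |
| `shared_noise_sd` | 1.2 µM | per-region spontaneous background common to deep channels |
| drift steps | 0.01 / 0.03 µM | superficial and per-channel random walks |
| I₀ | 5000 counts | comfortably above the 500-count QC threshold |

No amplitude scale for the hemoglobin changes is available from real
recordings, so the noise levels were calibrated once so that the
preprocessed signal-to-noise ratio places leave-one-run-out
classification accuracy in the mid-60s to low-70s percent and the
within-network correlation well above the across-network one — the regime
the method is designed for. At these defaults (8 probe seeds, fixed
c = 1, g = 0.01) the simulator yields within-network accuracy ≈ 0.70,
across-network accuracy ≈ 0.73, within-network r ≈ 0.6, across-network
r ≈ −0.16, and a 20-run fixed-effects group correlation ≈ −0.5, negative
in every replicate. This calibration describes the synthetic test-bed,
not a claim about any real cohort.

The shared regional background is what makes neighboring deep channels
correlate beyond their common task response (high within-network r) and
also what limits the benefit of a second DLPFC feature for
classification, so the across-network pair — whose second feature carries
statistically independent information — tends to classify slightly
better, mirroring the trend the method is meant to exploit.

### What the generator does not emulate

Motion artifacts, scalp-coupling and photomultiplier gain variation
(beyond a constant baseline and an optional low-intensity "bad channel"
mode), photon-transport physics (the forward model is exactly the MBLL
the inversion assumes, so the roundtrip is exact by construction),
heterogeneous DPF or partial-volume errors, serially correlated
measurement noise, and behavioral/neural coupling. Passing recovery tests
therefore demonstrates internal consistency of the pipeline and its
statistical behavior at realistic SNR — not robustness to the model
mismatch present in real recordings.

## Preprocessing

Processing order: band-pass filter the raw intensities, then MBLL
inversion, then per-run normalization.

- **Band-pass 0.008–0.08 Hz**: 4th-order Butterworth applied forward and
  backward (zero phase, so filtering never shifts features relative to
  the truth labels). The band keeps sustained task-frequency activity
  (the 32 s block cycle is at 0.031 Hz) while rejecting slow drift,
  respiration and cardiac oscillations. Padding spans about three corner
  periods to keep the long edge transients of the 0.008 Hz corner small.
  The filter operates on intensity fluctuations about the run mean; the
  mean is restored before the logarithm so the MBLL baseline is
  preserved.
- **MBLL inversion**: ΔOD(λ,t) = −log₁₀(I/I₀̂) with I₀̂ the run-mean
  intensity (the baseline convention is not dictated by the measurement;
  run-mean is the natural choice for normalized block designs), solved
  per sample as a 2×2 linear system for (ΔHbO, ΔHbR). Because the
  baseline is the run mean rather than the true resting intensity,
  concentration changes are recovered up to an additive constant per
  species; all downstream steps (normalization, GLM with intercept,
  correlation) are invariant to that constant.
- **Normalization**: per-run z-scoring by default. The alternative
  reading of trace normalization as baseline-relative scaling is exposed
  as `normalize: mean_subtract`; the default keeps all traces on a common
  scale for the SVM.

## Nuisance regression and trace selection

The shallow channel of each detector is smoothed with a trailing 6-point
moving average (causal, hence usable in a real-time monitoring loop) and
its task-like component is removed by regressing it on the expected task
response — otherwise using it as a nuisance regressor would subtract
genuine task activity from the deep channels. The expected response is
the normalized boxcar ⊛ HRF for HbO and its exact negation for HbR.

Each deep trace is fit by ordinary least squares on [expected response,
cleaned shallow regressor, intercept], always within species (shallow HbO
cleans deep HbO, likewise HbR). No prewhitening or extra drift regressors
are used — the model is deliberately plain linear regression. The
functional task signal is the measured trace minus the fitted nuisance
component and intercept. The task beta quantifies model fit and drives
selection.

Selection scores each (deep channel, species) by its mean task beta
across the participant's runs (a "min" aggregate is available; whether
the original betas were aggregated per run or computed on concatenated
runs is not determinable, so per-run mean was chosen and both are
exposed). The score is multiplied by the region's expected polarity: +1
for DLPFC, −1 for MFG. For a task-negative region every trace fits the
activation model with a negative beta, so a raw signed argmax would
perversely reward the *weakest* (anti-task) trace; the polarity-aware
rule selects the strongest task-locked deactivation instead, which is
what makes the across-network pair anti-correlated. Signed (not absolute)
beta is used within a region so anti-task fits are never rewarded. Ties
break to the lower channel id, then HbO. The two best DLPFC traces must
come from distinct channels (the within-network pair); the best DLPFC
trace with the best MFG trace forms the across-network pair. Selections
are fixed across a participant's runs. Channels whose run-mean intensity
falls below 500 ADC counts at either wavelength (exactly 500 passes) are
barred from selection but retained in the data.

## Classification

Every time point is one sample with a 2-feature vector (the selected
pair's functional task signals); accuracy is the fraction of the held-out
run's 2500 time points whose prediction matches the shifted truth label.
The classifier is a soft-margin SVC with RBF kernel; features are
standardized with training-fold statistics only. Cost c ∈ {0.1, 1, 10}
and kernel width g ∈ {0.001, 0.01, 0.1} are searched over the nine-cell
grid under the constraint that a single (c, g) serves all of a
participant's folds; a 9×9 grid matching the wider sweep used for
coarser co-registered imaging traces is also provided. The default
protocol reports the grid cell with the highest mean fold accuracy
computed on the same folds that are reported — an intentionally
optimistic "best achievable accuracy" protocol; a nested variant that
optimizes (c, g) by inner cross-validation within each training set is
available via `protocol="nested"`. Grid winners are invariant to grid
ordering (ties break to the smallest (c, g)).

Permutation nulls (labels permuted uniformly at random within each run
before training and testing) are evaluated at the grid's central cell
(c = 1, g = 0.01): under permuted labels every cell is chance-level, and
a full grid search would multiply the cost ninefold without changing the
expectation. Note that the chance level equals 50% only for balanced
classes; the default design has 1200 task and 1300 rest samples, so a
majority-collapsed classifier scores up to 52%. The permutation suite in
the test battery therefore uses a class-balanced design variant, while
the acceptance script reports the null on the default design.

## Network statistics

Within-network correlation is the Pearson r between the two selected
DLPFC functional task signals of a run; across-network correlation
relates the selected DLPFC and MFG signals. Correlations are averaged
hierarchically — runs within participant, then participants — so every
participant contributes equally. All tests are one-tailed with
comparisons paired by participant (accuracy > 50%, within-r > 0,
across-r < 0, within-r > across-r); p-values are reported at full
precision. Deoxygenated traces are inverted only for the fixed-effects
group average (where all runs' traces are averaged per region per time
point and the group r is the correlation of the two region means); the
participant-level pair correlations use the signals as-is. An optional
trailing 10 s pre-smoothing of both traces before correlation supports
coarser, noisier ROI-averaged traces from co-registered imaging.

## Numerical choices and degenerate inputs

- Seconds-to-samples conversion rounds half away from zero; at 6.25 Hz
  all default durations are exactly sample-aligned.
- Zero-variance traces cannot be z-scored or correlated: preprocessing
  flags such channels (carried as NaN and excluded from fitting), and
  correlation raises an explicit error.
- A degenerate all-zero expected response (no task blocks) makes
  shallow cleaning return the mean-centered trace with a warning.
- Collinear GLM regressors (|corr| > 0.999) raise an error naming the
  pair rather than returning an unstable fit.
- Single-run participants cannot be cross-validated; the pipeline aborts
  in the classify stage with an explicit error.
- All randomness flows through `numpy.random.default_rng` seeded from a
  single master seed; identical seeds give bit-identical outputs.

## Problem sizes in the test battery

The statistical suites are sized to run comfortably on one CPU: GLM
recovery uses 100 noise seeds on the full 2500-sample design; selection
recovery uses 100 simulated participants of 4 full runs; the permutation
null uses 100 replicates of a class-balanced 1000-sample design; group
anti-correlation recovery uses 20 replicate cohorts of 5 participants ×
2 full runs plus one full 5 × 4 cohort for the paired within-vs-across
test; classifier-heavy structural tests use a shortened 3-alternation
design. These sizes are the package's own choices for a fast default
test run; all of them can be scaled up through the same interfaces.

## Known limitations

- The optimistic grid protocol reuses reported folds for model
  selection; accuracies under it are upper bounds, which is why the
  nested protocol exists.
- The MBLL constants (extinction spectra, DPF) are configurable but the
  pipeline's accuracy is only invariant to them insofar as forward and
  inverse use the same values; no partial-volume or pathlength
  calibration is attempted.
- Motion correction and adaptive physiological filtering are out of
  scope; the shallow-channel regression is the only nuisance control.
- The behavioral module simulates reaction times and error rates from
  condition summaries (truncated-normal RTs with a 0.15 s floor); it is
  a stand-in for real response data, not a psychophysical model.
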