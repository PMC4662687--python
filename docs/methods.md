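# Methods

## The recognition problem and the fusion-link design

The package classifies short EEG segments into two emotional-stress states,
calm-neutral and negatively excited, induced by affective pictures. The
central methodological idea is that stimulus identity is an unreliable
label: a participant may not respond to a picture block. The labeling
stage therefore treats the autonomic (peripheral) signals as a tutor — a
trial's EEG epochs are labeled with the intended class only when
self-assessment and the peripheral signals confirm that the state was
actually realized — and the EEG classifier is trained on the surviving
epochs only.

## Synthetic study conditions

No recordings ship with the package; the generator produces the cohort the
analysis assumes (defaults in parentheses, all configurable):

* **Protocol**: 15 subjects × 8 trials; 10 s fixation + 4 pictures × 3 s =
  12 s block; class balance 0.5; negative trials draw valence ∈ [1.5, 3.5]
  and arousal ∈ [6, 8], calm trials valence ∈ [4, 6] and arousal ∈
  [1.5, 3.5] (a stand-in selection rule on the 1–9 scales); self ratings =
  true ratings + uniform(±0.7).
* **EEG** (256 Hz, 5 channels, ~20 µV RMS): a variance-matched mixture of
  white noise and its 9-sample moving average. The mixing weight rises from
  0.25 by `eeg_complexity_shift` (0.35) during negative blocks, lowering
  the sign-change rate and binary pattern diversity — i.e. Petrosian
  fractal dimension and Lempel-Ziv complexity — without changing amplitude.
  This induces the intended complexity reduction directly rather than
  asserting a physiological mechanism. Blink-like 150 µV bursts are
  injected into FP1/FP2 at 1/min against the 100 µV rejection threshold.
* **SC** (2048 Hz, baseline 2 µS): slow drift + event-related rise of
  `sc_level_shift` (2 µS, ~2.5 s time constant) during negative blocks +
  spontaneous nonspecific SCRs at 2/min with exponential amplitudes (mean
  0.15 µS), which real resting electrodermal activity always shows and
  which keep the qualitative screen from being a deterministic gate.
* **BVP** (2048 Hz): two-harmonic pulse waveform; instantaneous HR =
  70 bpm + 0.1 Hz LF modulation (±2.5 bpm) + smoothed jitter + `hr_shift`
  (8 bpm) during negative blocks.
* **Respiration** (256 Hz): ~0.25 Hz oscillation, 0.32 Hz and added
  frequency irregularity during negative blocks.
* **Non-responders**: with probability `nonresponse_p` (0.1 in the default
  experiment) a trial's physiology and self ratings follow the opposite
  class while the intended label is kept. This is the label noise the
  fusion link exists to catch.

These effect sizes are physiologically moderate (an 8 bpm HR rise and a
2 µS SCR are typical stress responses; the complexity shift produces a few
percent PFD change) and were fixed once as the package's study conditions.

What the generator does **not** emulate: volume conduction and channel
correlation, 1/f spectral structure, realistic blink/EMG morphology,
movement artifacts in peripherals, inter-subject variability in baselines
beyond seeding, habituation across trials. Passing tests therefore
demonstrate that the pipeline recovers the encoded class structure under
controlled conditions — not that comparable accuracy is reachable on real
recordings, where the published accuracies of such systems are far from
ceiling.

## Signal processing choices

* **Band-pass**: 4th-order Butterworth 0.5–40 Hz applied forward-backward
  (zero phase, so epoch boundaries are not delayed). The 0.5 Hz corner
  rings for seconds; measurements near edges must trim accordingly.
* **Moving average**: centered, shrinking windows at the edges (even
  windows take the extra sample from the left); default 0.25 s for SC and
  respiration, 0.05 s for BVP so systolic peaks survive.
* **Decimation**: FIR anti-aliasing (`scipy.signal.decimate`), BVP/SC
  2048 → 256 Hz.
* **Artifact rejection**: per-epoch absolute-amplitude threshold (100 µV),
  a reproducible stand-in for manual segment removal. A slot is dropped for
  all channels if any channel's epoch is rejected, keeping rows complete.
* **PFD**: zero first-differences inherit the previous sign (leading zeros
  the first nonzero sign); constant/monotone epochs give exactly 1.
* **LZ76**: exhaustive-history parsing with the final, possibly
  non-innovative word counted — the dominant convention in EEG complexity
  work. Binarization threshold is the median (mean available).
* **DWT**: db4, 5 levels, periodization boundary mode so the transform is
  orthonormal and sub-band energies sum to signal energy (tested to 1e-6);
  D1/D2 (> 32 Hz) are treated as noise and discarded.
* **Normalization**: per-feature min-max affine to [−1, 1] fitted on
  training rows only; constant features map to 0; held-out values may
  exceed the interval.
* **Kurtosis** is non-excess (normal ⇒ 3) throughout.
* **HRV spectrum**: the beat-to-beat HR series is cubic-spline resampled
  at 4 Hz before a Hann periodogram; LF = 0.05–0.15 Hz, total = 0.05–1 Hz.

## Labeling stages

Stage 1 passes a trial when both self-rating discrepancies are ≤ 2 points
(inclusive). Stage 2 codifies the qualitative narrative as baseline-
relative rules using the trial's own 10 s fixation: negative trials need an
SC rise ≥ 0.1 µS **or** an HR rise ≥ 1 bpm; calm trials must show neither
an SC rise > 1 µS nor a >2.5× increase in respiratory irregularity (SD of
the first differences). Stage 3 is leave-one-trial-out classification of
the 40 peripheral features with the one-vs-all RBF SVM (C = 1); a trial is
accepted iff the held-out prediction matches the intended class.
Rejection is at trial granularity. Loosening stage-2 thresholds can only
grow the accepted set.

A note on leave-one-out behavior: with uninformative features the SVM
degenerates toward majority vote, and removing the held-out trial makes its
class the training minority, so null rejection rates sit *above* 1/2 —
the relevant null property is absence of skill, not a 50% rate.

## Selection and classification

The GA uses bitmask genomes over the 70 features: population 100, per-bit
mutation 0.01, one-point crossover 0.4, roulette selection on min-max-
scaled fitness, elitism of one, 50 generations with early stop after 15
generations without best-ever improvement. Fitness is 3-fold
trial-grouped, stratified cross-validated accuracy on the training
partition (a `resubstitution` mode reproduces the literal whole-dataset
variant, which invites overfitting and is not the default). Empty genomes
are repaired by activating one random bit. For two classes the one-vs-all
pair is exactly complementary — flipping the labels negates the decision
function — so the GA's inner loop scores a single binary SVM per fold;
the persisted model still carries both machines explicitly.

The final classifier trains one SVM per class (RBF, C = 1, γ = 1/number of
selected features) on the GA-selected, normalized features. The decision
logic takes the class with the largest decision value, returns *reject*
when no machine claims the sample, and breaks ties toward calm-neutral.
Splits are grouped by trial (epochs of one trial never straddle
partitions) and stratified by class, 75/15/10, with largest-remainder
rounding; an `epoch` split mode exists for the literal per-epoch variant,
which leaks trial identity and is not the default. Accuracy is the sum of
diagonal confusion-matrix row percentages weighted by class priors
(empirical priors by default, which makes it the plain fraction correct
when nothing is rejected).

## Degenerate inputs and numerical notes

Constant epochs: PFD = 1, binarization all zeros, c(n) = 2. Flat BVP:
empty beat series with a warning. Too few beats (< 3 for BVP features,
< 8 for HRV) raise `ValueError`, as do band edges beyond Nyquist,
non-integer decimation factors and starved split partitions. Stage-3
results and GA runs are deterministic given their seeds; every pipeline
stage derives its seed from the experiment's `global_seed`.

## Problem sizes

The default experiment simulates 15 subjects × 8 trials (176 s each,
~2.6 M samples per subject across channels), yielding ~670 retained
60-epoch-per-subject EEG feature rows; the GA evaluates ≤ 100 × 51 masks
with 3-fold fitness. The zero-effect control replicates the experiment
three times with all class shifts at 0 and the labeling gate off — with
truly absent effects the gate (correctly) confirms almost no negative
trial, so the gated null run terminates with the starved-partition error
by design; the ungated control is the configuration that measures
classifier-path leakage, and its mean test accuracy must sit at chance.

## Known limitations

* The synthetic classes are close to separable at the default effect
  sizes; headline accuracies near 100% on synthetic test data say nothing
  about field performance.
* The qualitative stage-2 thresholds are heuristics; on real data they
  would need per-subject calibration.
* The peripheral "variability" series (trough/peak/amplitude/beat-mean/
  baseline) are per-beat descriptors; other conventions exist.
* Only two classes are supported; no probability calibration; no
  alternative feature selectors.
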