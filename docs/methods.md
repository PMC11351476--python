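# Methods

This note documents the models, simulation conditions, and numerical
choices behind `erosdecode`, in the order the pipeline runs.

## 1. Synthetic EROS data

### What is emulated

Event-related optical signals are fast, spatially localized changes in
near-infrared light scattering. The generator emulates the statistical
structure the decoding analysis relies on, at the *voxel* level:

- **Geometry.** A two-hemisphere motor-cortex region of interest flattened
  to C = 42 voxels (a 3 × 7 grid per hemisphere). The flattened index is
  `hemisphere * 21 + row * 7 + col`.
- **Task.** Blocks of trials (default 20 blocks × 24 trials, half of them
  manual responses → 240 labeled trials per montage), with left/right
  labels balanced within each block.
- **Effect.** A response-locked template: two Gaussian bumps (σ = 50 ms) at
  179 ms and 410 ms after the response, centered on a "hand" voxel in the
  right hemisphere (grid position row 1, col 3), with a Gaussian spatial
  falloff (σ = 0.75 voxels). The template's sign flips with the responding
  hand (right-hand responses positive), and the right-hemisphere amplitude
  is 1.5× the left-hemisphere mirror — in right-handed subjects the left
  hemisphere activates for both hands, so the right hemisphere carries the
  more hand-specific signal.
- **Noise.** An equal-power mixture of white noise and spectrally shaped
  1/f noise (exponent 1), scaled per voxel by 1/√k for k channels averaged
  into that voxel, plus a sinusoidal cardiac pulse artifact (≈1.2 Hz,
  random phase per block, shared across voxels).
- **Montage quality.** Each montage draws a voxel dropout fraction from
  [0.10, 0.35] and integer channels-per-voxel counts from [1, 6] —
  mirroring the observed range where roughly 60–85% of ROI voxels receive
  1.6–5.4 channels on average. Non-viable voxels carry pure noise. An
  optional per-montage latency jitter models imperfect inter-montage
  alignment (default 0 ms).
- **Modalities.** Phase delay and DC intensity are co-recorded: they share
  event times and labels but have independent noise. Intensity carries 1.5×
  the noise (weighted further toward low frequencies) and a 0.6× effect
  amplitude, reflecting its susceptibility to low-frequency contamination.

Default amplitudes are `effect_amplitude = 0.5` against `noise_sd = 1.0` —
a deliberately low single-trial SNR at which the default pipeline reaches
roughly 60% held-out accuracy, the regime this class of experiment
operates in. These defaults are fixed once; validation studies that need a
clearly learnable signal (e.g., effect recovery) raise the amplitude to 3×
the noise SD explicitly.

### What is *not* emulated

Photon transport and diffusion-path reconstruction, realistic cardiac
waveforms, instrument physics (110/300 MHz modulation), head geometry, and
co-registration. Consequently, passing tests demonstrate that the
*analysis* behaves correctly under the assumed signal structure — they say
nothing about optical physics, and real recordings may contain artifact
families (motion, optode decoupling) the simulator does not produce.

### Determinism

Every random draw descends from `numpy.random.SeedSequence` keyed on
`(seed, subject, montage, modality)`, so identical configurations produce
bitwise-identical datasets, and montage/modality streams are independent.

## 2. Preprocessing

Pipeline order for each continuous block: (optional) pulse regression →
per-voxel mean centering over the block → zero-phase band-pass →
segmentation at each response event → per-voxel subtraction of the
pre-response baseline mean → crop. Numerical choices:

- **Filter.** 4th-order Butterworth applied forward–backward
  (`sosfiltfilt`), i.e. zero-phase, with band edges (0.1, 12) Hz by default
  and (4, 7), (8, 13), (13, 20) Hz as the narrow-band options. Only the
  band edges are prescribed; the order and zero-phase application are this
  package's choices, made so that epoch timing is not skewed by filter
  delay.
- **Epoching.** 716 ms either side of the response at 39.0625 Hz gives
  `round(0.716 × 39.0625) = 28` samples per side — a 56-sample epoch with
  the response at index 28. The baseline window is
  `round(0.998 × 39.0625) = 39` samples immediately preceding the response.
- **Channel QC boundaries.** Distance bounds inclusive (2 ≤ d ≤ 7 cm),
  phase SD strictly < 200, mean AC strictly > 100 mV, following the
  wording "less than" / "over". The phase-SD threshold's units are not
  standardized; it is a plain configurable number.
- **Voxel projection.** Unweighted mean of all channel series mapping to a
  voxel. This is a declared simplification of diffusion-path-weighted
  reconstruction, which requires optode geometry and a light-propagation
  model that are out of scope.
- **Scaling.** Each trial is divided by its own global max-|value| across
  all voxels and time points, so the largest entry becomes ±1. Per-trial
  (rather than per-dataset) scope was chosen so test-time scaling needs no
  training-set statistics; an all-zero epoch passes through unchanged.
- **Phase unwrapping** uses the period-generalized unwrap (jumps larger
  than half the modulation period are removed by integer multiples of the
  period); **pulse regression** projects out a pulse reference and its
  Hilbert quadrature by least squares.

## 3. Network and numerics

The classifier is a depthwise-separable spatiotemporal CNN (layer table in
the README). It is implemented directly in numpy (`erosdecode.nn`) with
reverse-mode gradients — there is no framework dependency — and gradient
correctness is enforced by finite-difference tests rather than assumed.

- **Same-padding parity.** The even temporal kernels (length 20) pad
  asymmetrically: 9 samples left, 10 right. Fixed so results reproduce.
- **Batch-norm.** Momentum 0.1, ε = 1e-5 (common framework defaults,
  recorded in `ModelConfig`); batch statistics use the biased variance and
  running statistics track the same quantity.
- **Max-norm constraints.** After every optimizer step, each depthwise
  spatial filter is projected onto the L2 ball of radius 1 and each dense
  row onto radius 0.25. The projection is idempotent and non-expansive.
- **Dense bias** is included; convolutions are bias-free.
- **Initialization.** Glorot-uniform for all convolution and dense weights,
  seeded per network.
- **Default (F1, D, F2) = (8, 2, 16)** as the center of the search space
  {4, 8, 16} × {1, 2, 4} × {8, 16, 32}.
- **Decision rule.** `p > 0.5 → right`; exactly 0.5 classifies as left
  ("exceeds" is strict).

## 4. Training protocol

- 20% held-out test split stratified by label (jointly by label × montage
  for pooled runs), then 5 stratified CV folds over the remaining 80%; the
  "4 of 5 blocks" train/validation structure refers to these CV partitions,
  not recording blocks.
- Binary cross-entropy on logits, up to 300 epochs, batch size 32,
  early stopping with patience 50 and best-weight restoration. Patience and
  batch size are this package's choices (unstated in the protocol being
  followed); both are configurable.
- Random search samples 50 configurations × 3 initializations by default
  (architecture triplet, optimizer ∈ {Adam, SGD+momentum 0.9}, learning
  rate log-uniform [1e-4, 1e-2], weight decay log-uniform [1e-6, 1e-3],
  early-stop metric ∈ {val accuracy, val AUROC, val loss}); selection is by
  mean validation accuracy across initializations, ties to the lower config
  index. Search ranges are package defaults, overridable via
  `SearchSpace`.
- **Paradigms.** Montage-specific reporting selects the montage with the
  highest mean validation accuracy — never test performance. Pre-training
  fits on the pooled non-target montages (montage-stratified split) and
  then fine-tunes *all* weights on the target montage's training split;
  layer freezing is not applied (configurable in principle via a smaller
  fine-tuning schedule).

## 5. Evaluation statistics

- Reported test metrics are means over the five fold models; 95% CIs are
  `mean ± t₀.₉₇₅,df=4 · SE` across the five fold values.
- Above-chance accuracy: one-sided exact binomial test on the pooled
  held-out predictions against 0.5 (the specific test is this package's
  documented choice). Above-chance AUROC: one-sided Mann–Whitney U on the
  pooled scores.
- AUROC itself is the Mann–Whitney probability (mid-ranks; ties count ½),
  cross-checked in tests against an O(n²) pairwise count and
  scikit-learn.
- Data-quality analyses fit `accuracy ~ quality + C(subject)` by OLS with
  Type-II (order-invariant) sums of squares for montage-specific quality
  measures and Type-I (sequential) for the cross-montage predictors.
  Post-hoc pairwise comparisons use the studentized-range (Tukey HSD)
  procedure from statsmodels; exact replication of any particular
  statistics package's output is not promised.

## 6. Attribution

DeepLIFT with the Rescale rule, propagated from the sigmoid output to the
input grid. Linear layers (convolutions, batch-norm in inference mode,
pooling, dense) propagate multipliers through their exact transpose;
ELU and sigmoid use Δoutput/Δinput with a gradient fallback when
|Δinput| < 1e-7. This construction satisfies summation-to-delta to
machine precision (tested < 1e-3, observed ~1e-16).

- **Reference input:** all zeros — the natural rest point of a
  baseline-corrected, max-abs-scaled trial.
- **Sign convention:** relevance is with respect to the right-response
  direction of the output (positive supports "right"), fixed regardless of
  the predicted class.
- **Confidence groups:** high when p < 0.20 or p > 0.80; the boundary
  values 0.20/0.80 belong to the low-confidence group ("between" read
  inclusively). Empty groups yield an explicit empty result, not a NaN map.
- Spatial slices use nearest-sample lookup: at 39.0625 Hz, 179 ms after the
  response is sample 28 + 7 = 35, and 410 ms is sample 44.

## 7. Validation scales

The test suite and `scripts/acceptance.py` run the heavier checks at sizes
chosen to finish in minutes on a single CPU core, as the package's own
standard validation settings: effect-recovery and permutation-null fits use
a (F1, D, F2) = (4, 2, 8) network with 40/25 epoch budgets and patiences
10/8; attribution localization uses 20-epoch fits over 5 seeds; ANOVA
calibration uses 200 simulated 8-subject × 4-montage tables. Full-scale
runs (300 epochs, 50-configuration searches) use exactly the same code
paths through the public configuration objects.

## 8. Known limitations

- The simulator's pulse artifact is a pure sinusoid; real cardiac artifacts
  are broadband and amplitude-modulated, so pulse-regression performance on
  real data will be worse than in tests.
- The channel→voxel stage is an unweighted average; diffusion-weighted
  reconstruction may change montage-quality statistics in ways the ANOVA
  analyses would inherit.
- Whether the 42-voxel input covers one hemisphere or two is ambiguous in
  the source protocol; the generator fixes a 21 + 21 split but exposes the
  grid shape in `SimConfig`.
- The dual-input (phase + intensity) network shares the training loop but
  attribution is implemented for single-input networks only.
- With montage counts ≤ 4 per subject, the quality ANOVAs have low power at
  realistic effect sizes; the calibration studies use 8 synthetic subjects.
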