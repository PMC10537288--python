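# Methods

This note records the models implemented in `icpulse`, the defaults and why
they were chosen, the numerical decisions, and what the synthetic
validation does and does not establish.

## Signal model of the synthetic generator

A record is a concatenation of heartbeat-induced pulses on a constant
baseline (default 10 mmHg), plus additive components:

- **Beat morphology.** Each beat of duration T is a sum of up to three
  Gaussian bumps (subpeaks P1, P2, P3) with positions and widths expressed
  as fractions of T, plus a rectified-sine diastolic filling term
  `diastolic_amp·|sin(πt/T)|` (default 1 mmHg). The filling term gives
  every beat a distinct V-shaped trough at its boundary — the feature the
  onset detector keys on in real ICP — without adding any in-band
  oscillatory content of its own.
- **Ground truth.** Subpeak labels are re-derived from the local maxima of
  the rendered noiseless beat nearest each configured position, not read
  off the template: overlapping Gaussians shift apexes, and labels must
  match what a perfect detector could recover. The true P2/P1 ratio is the
  quotient of the min–max-normalized beat at those apex samples, hence
  exact by construction.
- **Respiration** — additive sinusoid, default 0.25 Hz; **drift** — a
  random walk low-passed below 0.1 Hz; **noise** — white Gaussian. All
  three lie (respiration, drift) outside or (noise) across the 0.3–20 Hz
  analysis band, so the preprocessing filter can be validated against
  them. **Degradation** replaces a configurable fraction of beats with
  artifact shapes (movement spikes, flat saturation, damped electronic
  noise) or with morphologies lacking a distinct P1 or P2; those beats are
  flagged non-calculable and carry the (0, 0) label sentinel.
- **Per-beat period jitter** is a truncated-Gaussian coefficient of
  variation on the beat period (default 0.03 where noise is wanted).

For training the learned stages directly in the 180-point frame,
`generate_pulse_dataset` renders individual beats at random lengths
(70–130 samples, i.e. 46–86 bpm at 100 Hz), corrupts them with
**band-limited** noise (low-passed at 20 Hz) and normalizes them. The
band-limiting matters: pulses that reach the neural stages of the real
pipeline have passed the 0.3–20 Hz filter, so white corruption would
misrepresent them. Calculable templates draw subpeak widths from
U(0.04, 0.07)·T and P1–P2 spacing from U(0.18, 0.30)·T — subpeaks that a
human labeller would call distinctly visible. Merged-subpeak shapes are
generated, but as members of the non-calculable class, which mirrors the
labeling convention (a pulse whose subpeaks cannot be told apart has no
calculable ratio).

**What the generator does not emulate:** inter-patient morphology
differences, slow physiological trends (Lundberg waves), sensor drift
physics, coupling between heart rate and pulse shape, and the full
diversity of clinical artifacts. Passing tests on this data demonstrates
that the pipeline's machinery is correct and that the learned stages can
recover known structure; it does not predict clinical performance.

## Preprocessing

- Band-pass: Butterworth of design order 4 with edges 0.3 and 20 Hz,
  applied forward–backward (`sosfiltfilt`) for zero phase. Zero phase is
  deliberate: subpeak appearance time is a headline metric and phase
  distortion would bias it. Records shorter than three time constants of
  the slow edge (≈1.6 s at 100 Hz) are rejected.
- Onset detection: bounded-scale multiscale minima counting. For scales
  k = 1..L (L = 500 ms by default, capped at half the record), sample i is
  marked at scale k iff x_i < x_{i−k} and x_i < x_{i+k}; the scale λ with
  the most marks wins (smallest λ on ties — the finest consistent scale),
  and onsets are the samples marked at every scale ≤ λ. The algorithm is
  comparison-only, hence invariant to amplitude scaling, and needs no
  thresholds.
- Segmentation keeps beats between 0.25 s and 2 s (30–240 bpm), permissive
  around the 60–80 bpm range of interest; the tail after the last onset is
  discarded.
- Normalization maps each beat affinely to [0, 1] and resamples it to 180
  points with a cubic spline through all samples (a single global cubic
  could not represent three subpeaks). Resampling a 180-point beat onto
  itself is the identity, and the operation is idempotent.

## Curvature candidates

κ(x) = x″/(1+x′²)^{3/2} with central differences on the index grid. Before
differentiation the pulse is smoothed with a width-5 moving average
(second differences amplify interpolation noise; 5 samples is well below
subpeak spacing). Candidates are strict local maxima of κ(−p) — plateaus
contribute their left edge — restricted to samples where the smoothed p″
is negative, with a concavity tolerance proportional to the pulse range so
float dust on straight segments cannot fake concavity, and excluding the
half-window margin where the smoother's edge padding distorts derivatives.
On noiseless three-subpeak pulses the true apexes lie within ±2 samples of
a candidate in ≥ 99 % of random templates; 2 % band-limited noise widens
that to roughly ±5 — which is why candidates are *scored by a network*
rather than ranked by curvature alone.

## Learned stages

All networks run on the package's numpy engine (float32, Adam, manual
backpropagation validated against finite differences; a single
`numpy.random.Generator` drives initialization, dropout and shuffling, so
every run is bit-reproducible from its seed).

**Selector.** Input is the 180-point pulse; output one logit.
- `cnn`: three blocks of (conv k=7 → batch-norm → ReLU → max-pool 2) with
  channels (32, 64, 128), dropout 0.2 after the encoder, dense 128 → ReLU
  → dropout → dense 1.
- `lstm` (default): one bidirectional LSTM cell, hidden 64, final hidden
  states concatenated (128) → dropout → dense 64 → ReLU → dropout →
  dense 1.
- `lstm_fcn`: the CNN encoder and the biLSTM cell run in parallel on the
  same pulse; their outputs are concatenated into the two dense layers.
  Dropout probability is fixed at 0.2 throughout.

Training: binary cross-entropy on logits, Adam, lr 10⁻³, batch 256, last
10 % of a seeded shuffle as validation, fixed epoch count (no early
stopping). With the realistic 10 % non-calculable minority, the recurrent
selector collapses onto the base rate (a constant-logit plateau of the
unweighted objective) for tens of epochs; the `pos_weight="balanced"`
option weights the positive class by n_neg/n_pos, removing the plateau.
The convolutional selector does not need it. The LSTM forget-gate bias is
initialized to 1 to ease gradient flow across the 180 steps.

**Designator.** Input the pulse, output a 180-point score vector trained
with MSE against ½·(exp(−(t−p1)²/2σ²)+exp(−(t−p2)²/2σ²)).
- `lstm` (default): biLSTM hidden 180 → dense (360, 360) → ReLU → dropout
  → dense (360, 180).
- `unet`: three-level 1-D U-Net (180 → 90 → 45 → 90 → 180), encoder
  channels (16, 32, 64), kernel 7, nearest-neighbour upsampling, skip
  concatenation, dropout 0.2 per convolution block, 1×1 output projection.

The canonical target width is σ = 1 sample (`target_vector`'s default);
training uses σ = 2 (standard practice in landmark heatmap regression —
unit-width targets are so sparse that the MSE signal is dominated by the
background). Designation modes: `curvature` (default) scores each
curvature candidate by the network output exactly at the candidate index
and keeps the two highest (ties keep the earlier index); `nn_output` takes
the two highest local maxima of the score vector. In both, the earlier
index is P1. Fewer than two candidates/maxima marks the pulse
non-calculable rather than raising. A non-learned baseline
(`designate_curvature_baseline`) takes the two earliest candidates.

The P2/P1 ratio is computed on the [0, 1]-normalized pulse,
`values[i2] / values[i1]` — amplitudes relative to the pulse minimum,
invariant to the raw signal's scale and offset.

## Postprocessing

Trailing window of 100 pulses, step 1 (causal — the displayed series lags
by up to the window length, about a minute at 70 bpm). Per window: if
fewer than 50 values are non-missing, display missing; otherwise compute
mean and sample standard deviation (ddof 1) of the raw non-missing values,
discard values outside mean ± z·sd (z = 1.96 at the default 95 % level,
one pass, no iteration — the ≥ 50 check precedes exclusion), and display
the mean of the rest. With fewer than two valid values no exclusion is
attempted. An all-equal window displays that value at any confidence
level.

## Evaluation

TPR = tp/(tp+fn), FPR = fp/(fp+tn), dataset fractions fp/total and
fn/total (all reported in percent, half-up rounding in report tables only);
appearance-time MAE as a percentage of the 180-sample pulse duration,
separately for P1 and P2; ratio MAE; and ratio>1 detection accuracy, with
a ratio of exactly 1 assigned to the "≤1" class. Designation metrics are
computed only on pulses that are calculable in truth and passed selection.

## Problem sizes and measured behaviour

Training runs in the test suite and acceptance script are sized for a
single CPU: selector 2 500 train / 800 held-out pulses, 20 epochs;
designator 1 500 / 400 pulses, 30 epochs. Convergence studies behind these
choices: the balanced-weight LSTM selector reaches held-out AUC 0.995 by
epoch 10 and 1.000 by epoch 20; the LSTM designator in curvature mode
reaches appearance MAE ≈1.3 % (P1) / 2.8 % (P2) of pulse duration and
ratio MAE ≈0.06 by epoch 25-30. These figures are re-measured, not
asserted, by `scripts/acceptance.py`.

## Known limitations

- Validation is entirely synthetic; no claim transfers to patient data.
- The onset detector localizes the trough to about ±2 samples on noiseless
  records and degrades with heavy in-band noise; end-to-end appearance
  errors on full records therefore exceed the pulse-frame errors.
- The curvature candidate set on noisy pulses can miss an apex by a few
  samples; `nn_output` mode is free of that quantization but needs a
  sharper heatmap to match it.
- The numpy engine is single-threaded and unsuited to training at clinical
  dataset scale; it exists to make the pipeline self-contained and
  reproducible.
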