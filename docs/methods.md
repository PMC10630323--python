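# Methods

This note records the scientific and numerical choices behind `ppgvitals`:
what each stage assumes, which parameters matter, what the synthetic
generator does and does not emulate, and where the design was genuinely
open.

## Signal model

A camera PPG is modelled as a per-channel intensity
`x_c(t) = DC_c + AC_c · p(t) · m(t) + d(t) + ε(t)` where `p(t)` is the
pulse waveform (systolic wave plus a smaller dicrotic wave per beat),
`m(t)` an amplitude modulation at the respiratory frequency, `d(t)` a
baseline drift at the same frequency and `ε` sensor noise. The single-lead
ECG shares the beat sequence; its R-peak precedes the PPG pulse peak by the
pulse-transit time (PTT). These are the features the pipeline exploits:
periodicity for HR, the respiratory components for RR, the red/green AC/DC
ratio for SpO2, and the per-beat morphological correspondence for ECG
synthesis.

## Synthetic generator (`siggen`)

Stands in for paired clinical recordings that cannot be redistributed.

* **ECG**: per beat, five Gaussian bumps at fixed angular positions
  (P, Q, R, S, T ≈ −70°, −15°, 0°, 15°, 100°; amplitudes 1.2, −5, 30, −7.5,
  0.75 scaled to a unit R-peak; widths 0.25, 0.1, 0.1, 0.1, 0.4 rad) — the
  classical sum-of-Gaussians parameterization. The beat period is
  `round(fs·60/hr)` samples, optionally modulated at the breathing rate
  (`rsa_amp`, default 0 so that fixed-rate examples have exactly equal R-R
  intervals).
* **PPG**: systolic Gaussian delayed from each R-peak by the PTT
  (default 200 ms), dicrotic wave at +0.30 of the beat at 0.35 amplitude.
  Channel DC levels 180/120/60 (8-bit scale); the green pulsatile
  perfusion is 5% of DC and the red AC is set by inverting
  `SpO2 = 110 − 25·R` (ratio-of-ratios, red over green) — an arbitrary but
  fixed, documented convention, since real calibrations are
  device-specific. `noise_sd` and `drift_amp` are expressed relative to
  each signal's AC amplitude so one number means the same SNR for ECG and
  every colour channel; the respiratory amplitude-modulation depth is tied
  to `drift_amp` (0.2×) so a single knob controls respiratory effects and
  `drift_amp = 0` yields strictly stationary beats.
* **Frames**: every pixel holds the channel value plus zero-mean spatial
  noise, clamped and quantized to 8 bits; the ROI mean recovers the PPG up
  to quantization (≤ 0.5) plus the central-limit term `3·σ/√N_pixels`.

What it does **not** emulate: motion artifacts, fingertip pressure changes,
camera auto-exposure/white-balance drift, beat-morphology pathology. Tests
passing on this generator demonstrate that the algorithms recover what the
model encodes; they are not evidence of clinical accuracy.

## Preprocessing

* **Wavelet rule**: `db4`, 5-level decomposition (symmetric extension);
  the approximation band and detail levels 1–2 are zeroed and the signal
  reconstructed. The family is a package choice (the selection rule, not
  the family, is prescribed in this literature); it is configurable. Note
  the approximation band at 125 Hz spans 0–2 Hz, so at clinical sampling
  rates this rule removes the cardiac fundamental while retaining its
  harmonics; peak detection and detrending for ECG synthesis therefore
  operate on the raw (or separately detrended) signal, and the wavelet
  stage is primarily useful at camera frame rates (≈ 30 Hz) where the
  approximation band stops at ≈ 0.5 Hz.
* **Detrending**: natural cubic splines through (index, value) of peaks
  (upper envelope) and valleys (lower); `y = (x − lower)/(upper − lower) −
  0.5`. Envelopes are clamped to the nearest fiducial value outside the
  outermost fiducials (extrapolating a cubic is unstable). Spline
  overshoot beyond ±0.05 raises a warning. Degenerate envelopes (upper ≤
  lower) raise an error naming the first offending sample.
* **Segmentation**: windows of `w_s` seconds every 1 s; the label of a
  window is the mean of the per-second labels it spans; `w_s·fs` must be
  integral. Defaults: 10 s for HR and SpO2, 30 s for RR (RR needs several
  breathing cycles per window).

## Peak detection (TERMA)

The squared positive part of the mean-removed signal is smoothed with two
centered moving averages — event-scale (ECG 97 ms / PPG 111 ms) and
beat-scale (611 / 667 ms). Blocks where the event average exceeds
`cycle_average·(1+β) + β·mean(energy)` are blocks of interest; blocks
shorter than the event window are rejected; the signal argmax of each block
is the peak (earliest sample on ties). The additive global term suppresses
T/P-wave bumps between widely spaced beats at low heart rates; because
every term scales with the square of the input, detection is invariant to
positive affine rescaling. β defaults to 0.08 (ECG) / 0.02 (PPG) and is
the knob to adjust manually on difficult recordings. Exact window values
in the source literature are unstated; these defaults follow the published
algorithm family and are configurable.

## Vitals networks

All three architectures take standardized segments `(N, w_s·fs, ch)` and
train with the batch-mean absolute error `L = (1/|B|)Σ|y − ŷ|` (robust to
oximeter label outliers), Adam at 1e-3, batch 128, up to 1000 epochs with
early stopping (patience 20 on validation MAE, best weights restored) and
a reduce-on-plateau learning-rate decay (factor 0.1). Vital-specific
training uses one output and raw labels; joint training stacks the three
vitals and z-scales each (documented choice — the loss would otherwise be
dominated by HR's numeric range). Default conv stacks (16/32/64 filters,
kernel 5, pool 2; 8/16/32 in the fast benchmark profile) keep the models
in the tens-of-kilobytes range; the base architectures in the source
literature are not fully printed, so all layer sizes are configurable.
LESSO evaluation holds out `k = 5` whole subjects and reports the mean and
population-std of per-subject MAEs.

Since no deep-learning framework is assumed, the networks run on the
package's own NumPy reverse-mode autodiff core (`ppgvitals.nn`): broadcast
aware elementwise ops, im2col convolutions, batch/layer norm, multi-head
attention, Adam, and finite-difference-verified gradients (see
`tests/test_nn.py`).

## Contrastive caption model

Captions are templated as `"HR is 72 beats/min, SpO2 is 97 %, RR is 16
breaths/min."` (optionally with SBP/DBP fields, which HR/SpO2/RR parsing
ignores); parsing is by unit-anchored patterns, and the template
round-trips exactly. The PPG encoder follows the printed output-shape
column of its architecture table (channels 8, 8, 16, 32; kernels 10, 5, 3,
3; two max-pools; flatten 9728 at input length 1250), topped by a
projection head (dense → gelu → dense → dropout 0.2 → add → layer-norm,
L2-normalized 256-dim output). The default text encoder is fully
trainable and offline: digit-level tokens plus learned positional
embeddings, a two-layer convolution over the token axis (so multi-digit
numbers are composed in place — mean-pooling alone cannot read numbers),
flatten, and the same projection head. A pretrained language-model encoder
can be plugged in via the `text_encoder` hook.

Pretraining is the symmetric in-batch contrastive objective with a
learnable temperature (init 1/0.07, clamped at 100). Two measures keep the
small-corpus regime honest: fresh Gaussian noise is added to each segment
batch (the encoder cannot memorize the noise pattern of individual
segments), and early stopping monitors the validation *retrieval* HR error
— the quantity querying mode cares about — rather than the contrastive
loss, which keeps improving while retrieval degrades. Querying embeds the
segment, ranks the caption bank by dot product, parses the top-k captions
and averages each vital over the captions that contain it.

## PPG → ECG translation

Training cuts both detrended signals into per-beat cycles at the PPG pulse
peaks (ECG cut points shifted by the median matched R-to-pulse lag),
resamples each to `L = 300` samples (comfortable headroom above the longest
beat at 125 Hz; the source only fixes the coefficient counts), and keeps
the first `L_P = L_E = 150` orthonormal type-II DCT coefficients — enough
for < 2% reconstruction error on a smooth cycle. Cut points are backed off
40 ms before the reference peak: one-sample detection jitter would
otherwise flip the R spike between the two ends of the resampled cycle and
make the regression target bimodal across recordings (this mattered in
practice; see `pair_cycles`). Test-time cycle splitting uses the same
guard, and needs only PPG pulse peaks.

Two regression configurations map `c_P → ĉ_E`:

* **ridge** — closed-form multi-output penalized least squares
  `(XᵀX + λI)⁻¹XᵀY` on centered data, λ = 1e-3 by default;
* **ffnn** — 150 → 175 → 175 → 150 with selu activations (tanh
  selectable; both appear in the source, the conflict is recorded),
  batch-norm after each hidden layer, L1 1e-5 on hidden weights, Xavier
  init, Adam at 1e-3 with a staircase exponential decay (factor
  `exp(−0.1)` every 100 epochs — the printed rate `exp(0.1)` would grow
  the learning rate, so the package reads it as a decay), batch 100, up to
  1000 epochs, early stopping with best-weights restore. The default
  widths give ≈ 84 K parameters, matching the printed model budget.

Reconstruction inverse-transforms `ĉ_E`, then inverse-resamples each cycle
to its native beat length so the synthetic ECG keeps the subject's rhythm.

## Metrics

`P_corr` is the centered cosine; the Dirichlet distance is
`max_i |x_i − y_i|` (the printed outer min over the single index set is
vacuous and implemented as identity); MAE/SAE use the population (ddof 0)
std, as does the LESSO σ. Fiducial amplitude errors are taken at the
*reference* cycle's P/Q/R/S/T indices (re-detection on the reconstruction
is a configurable alternative); fiducial search windows are Q/S within
80 ms of R, P in (−250, −80) ms, T in (+80, +400) ms, evaluated at the
effective sampling rate of the resampled cycle.

## Problem sizes used in the shipped benchmarks

The in-repo benchmarks are sized for a single CPU: the translation
benchmark trains on 1,500 cycle pairs (~50 synthetic sessions of 30 s) and
scores 300 held-out cycles; the HR-recovery benchmark uses ~1,900 segments
of 10 s at a 25 Hz frame rate (camera-realistic) across 60 synthetic
subjects; the retrieval benchmark pretrains on a 2,000-pair corpus and
queries 200 fresh segments. All are fixed, seeded study conditions, not
tuning targets.

## Known limitations

* The generator's beat-to-beat regularity makes cycle pairing easier than
  on arrhythmic or motion-corrupted recordings; the manual TERMA threshold
  exists for exactly those cases.
* SpO2 recovery is only as meaningful as the generator's fixed
  ratio-of-ratios convention; real devices need per-device calibration.
* The reconstructed ECG timeline is anchored to the PPG pulse peaks; the
  absolute lag to the true ECG is the training-set median PTT and is not
  re-estimated per subject at test time.
* The ViT and CLIP models are deliberately minimal; they demonstrate the
  training and querying protocols rather than a tuned architecture.
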