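# Methods

`dusqa` (Doppler Ultrasound Signal Quality Assessment) classifies short
windows of 1-D Doppler ultrasound audio from low-cost fetal monitors
into five signal-quality classes: **Good, Poor, Interference, Talking,
Silent**. This document records the model, its assumptions, every tunable
parameter, and the reasoning behind the numerical choices.

## 1. Problem model

A hand-held Doppler transducer produces an audio stream in which fetal
heartbeats appear as paired amplitude bursts. Recording quality in the
field is highly variable: probe movement and poor contact produce noisy
("Poor") signal, the device's own handset produces a harmonic buzz
("Interference"), conversation near the microphone leaks in ("Talking"),
and an idle probe yields near-silence ("Silent"). Quality must be judged
continuously and cheaply enough to run on the phone driving the probe,
so the user can be prompted to reposition in real time.

### Assumptions

- Audio is mono. Multichannel input is reduced to its first channel.
- The analysis rate is 4 kHz; higher-rate input is decimated with a
  polyphase anti-aliasing filter. Upsampling is refused — a recording
  below 4 kHz has already lost the band the features live in.
- Quality is quasi-stationary over 0.75 s; labels are per-0.75 s
  segment, and a classified window is 5 consecutive same-class segments
  (3.75 s = 15 000 samples).
- Human labels are noisy: three annotators label each segment, and a
  consensus rule decides the training label (Section 3).

## 2. Signal representation: scalogram

Each 3.75 s window is transformed with a continuous wavelet transform
(Morlet mother wavelet, scales 1–40) and reduced to a 250 × 40
time-frequency image.

| Parameter | Default | Why |
|---|---|---|
| analysis rate | 4000 Hz | Doppler audio content is < 2 kHz; keeps the CWT cheap |
| mother wavelet | `morl` | Symmetric oscillatory kernel suited to burst-like audio |
| centre frequency | 0.8125 | The conventional discrete FFT-peak measurement of the Morlet spectrum (13/16 cycles over its 16-unit support) |
| scales | 1 … 40 | Pseudo-frequencies 3250 Hz down to 81.25 Hz via f = 0.8125·4000/scale |
| time columns | 250 | Block-mean over 60-sample blocks: 15 000 → 250, i.e. 15 ms resolution |
| normalization | per-window min–max to [0, 1] | Removes gain differences between probes/recordings |

Numerical choices:

- `pywt.cwt(..., method="fft")` computes each window in ≈50 ms; the
  default time-domain convolution is ~20× slower with identical output
  to floating-point tolerance.
- **Magnitude, not power**: |coefficients| keeps weak late-scale energy
  visible after min–max scaling; squaring would compress it toward 0.
- Block-mean temporal reduction (rather than decimation) is an
  anti-aliasing average and is exactly invertible in expectation for
  block-constant signals; it requires 15 000 to be divisible by the
  column count, which 250 satisfies.
- A constant window min–max-normalizes to all zeros rather than
  dividing by zero.

## 3. Annotation and consensus

Labels per 0.75 s segment come from three annotators. Classes split into
two consensus regimes:

- **Good / Poor / Silent** require 3/3 unanimity — these classes grade a
  continuum and disagreement signals genuine ambiguity.
- **Interference / Talking** require ≥ 2/3 — these are event classes a
  rater can miss; one dissent (including "Unsure") does not veto.
- **Unsure** never becomes a consensus label; segments without consensus
  are dropped, and windows never span them.

Windows are built at maximal overlap: every index where 5 consecutive
segments agree starts a window, so a run of L segments yields L − 4
windows (stride 0.75 s).

Agreement is quantified with Fleiss' kappa (3 raters, segment level) and
Cohen's kappa (2 raters, window level), both via established library
implementations (`statsmodels`, `scikit-learn`). Kappa is undefined when
only one category occurs; the package raises a specific error rather
than returning a misleading number.

## 4. Network

Input: 250 × 40 scalogram (time × scale). Default architecture
(`CNN_GRU_ATT`):

1. Three convolution blocks: 3×3 same-padding conv → ReLU → batch norm →
   max-pool → 25 % dropout, with 32/64/128 filters and pool shapes
   (2,2), (1,2), (1,2). Time is halved once (250 → 125) while frequency
   collapses 40 → 5, preserving temporal resolution for the recurrence.
2. Flatten frequency×channels: 125 timesteps × 640 features.
3. GRU, 50 units, full output sequence.
4. Time-distributed dense (50, ReLU).
5. Context-vector attention: u_t = tanh(W h_t + b), α = softmax(u_tᵀu),
   pooled vector v = Σ α_t h_t. The α's are exposed for inspection.
6. Dense softmax over the 5 classes.

Total: 202 175 parameters. Ablation variants: `CNN_ATT` (no GRU) and
`GRU_ATT` (no convolution; raw scalogram rows feed the GRU).

The network and its backpropagation are implemented in NumPy
(`dusqa/layers.py`) because no deep-learning framework is available in
the target environment; all gradients were verified against central
finite differences (worst relative error ≈ 1e-7).

Batch-norm inference statistics are **bias-corrected** exponential
running averages (accumulators start at zero and are divided by
1 − momentum^t after t updates). Without the correction the averages
stay anchored to their 0/1 initialisation for the first ~1/(1−momentum)
batches; when an epoch is only a few batches long, early stopping then
judges validation loss with meaningless inference statistics and aborts
training at chance level.

`desk_scale_config` shrinks the conv widths (4/8/16) and computes in
float32 — the desk-scale step is memory-bandwidth-bound, so halving the
element size gives a ~2.3× speedup — letting end-to-end cross-validation
run on a single CPU in minutes. Architecture, recurrence and attention
widths are unchanged, and the default full-size model stays float64.

## 5. Training

| Parameter | Default | Why |
|---|---|---|
| batch size | 128 | Balanced-batch design below |
| optimizer | SGD, lr 0.01, momentum 0.9 | Small model, stable with batch norm |
| max epochs | 100 | Upper bound; early stopping decides |
| patience | 10 | Stop after 10 epochs without validation improvement |

- **Balanced batches.** 128 is not divisible by 5, so per-class quotas
  rotate through (26,26,26,25,25); every class takes turns getting the
  extra item. The majority class cycles a seeded shuffle without
  replacement; minority classes are oversampled with replacement. One
  epoch is ceil(majority·5/128) batches.
- **Recording-disjoint folds.** Recordings (not windows) are dealt into
  k folds: grouped by modal class, shuffled within group with the seed,
  and dealt round-robin with the cursor carrying across groups so fold
  sizes stay balanced for any class counts.
- **Early stopping** uses a held-out validation fold, fold (f+1) mod k
  when testing fold f; the test fold influences nothing during training.
  Weights from the best validation epoch are restored.
- All stochastic components (init, dropout, batch composition, fold
  deals) are driven by explicit seeds; two runs with the same seed are
  bit-identical.

## 6. Evaluation

Per-class precision/recall/F1 are computed from a 5×5 confusion matrix
(rows actual, columns estimated) and reported in percent. A class absent
from the test data has undefined recall/F1 (NaN), and macro F1 averages
only the defined classes — reporting 0 instead would invent a failure on
data that does not exist. Micro F1 equals accuracy when every item is
classified; this identity is property-tested. Cross-fold aggregation
reports mean ± sample standard deviation (ddof = 1). Display rounding is
half-up at 2 decimals, matching conventional reporting.

## 7. Streaming

Real-time use evaluates the newest 3.75 s of audio every `hop_s` seconds
(default 1 s): a signal of duration T yields evaluations at
t = 3.75 + k·hop for t ≤ T (+1e-9 float guard), e.g. 34 evaluations for
37.5 s. A ring buffer holds exactly one window; chunk boundaries are
aligned to evaluation times internally so streaming output is
*bit-identical* to offline classification regardless of chunk size. A
whole-signal summary averages the per-evaluation probability vectors and
reports the argmax (ties to the lowest class index).

## 8. Synthetic study conditions

Real labelled fetal Doppler recordings cannot be shipped with the
package, so `dusqa/synthetic.py` generates surrogate audio whose
*class structure* mirrors the field conditions:

- **Good** — paired Hann-window bursts (systolic/diastolic) at a fetal
  heart rate drawn from 110–160 bpm, carried on 150–900 Hz bandpass
  noise, 20 dB SNR.
- **Poor** — the same beat train with timing jitter (σ = 0.18 of the
  period), 35 % beat dropout, amplitude drift, at −3 dB SNR.
- **Interference** — a harmonic complex (fundamental ≈ 217.4 Hz, 8
  harmonics) gated at the handset frame period, gate locked to the
  period so energy stays on the harmonics.
- **Talking** — noise shaped by two formant resonators (500 and 1500 Hz,
  Q = 8) under a ~5 Hz syllabic envelope with pauses.
- **Silent** — near-zero noise (RMS 3·10⁻⁴).

Annotator tracks are simulated by flipping each segment label with
probability 0.05 and substituting "Unsure" with probability 0.02 per
annotator.

**What the generator does *not* emulate:** real fetal physiology
(accelerations/decelerations, movement artefacts), maternal vessel
sounds, device AGC, room acoustics, or correlated annotator biases.
Results on synthetic data demonstrate that the pipeline can learn the
intended class distinctions — they are not clinical performance claims.

### Discriminability guard

A fixed bank of four acoustic statistics — RMS, harmonic "buzz" power
share (±6 Hz around the fundamental's harmonics), 1300–1700 Hz band
share, and envelope autocorrelation peak within heartbeat lags
(60/180 s … 60/95 s) — classifies generated windows by thresholds
(RMS < 0.005 → Silent; buzz > 0.5 → Interference; high band > 0.15 →
Talking; periodicity > 0.5 → Good; else Poor). It achieves 100 % on 300
held-out windows (the acceptance floor is 99 %). The periodicity
threshold 0.5 was placed in the centre of the observed Good/Poor gap
(0.39 vs 0.72) during design. This guard guarantees the classes are
separable from the audio alone, so the network-learnability check
measures the model and training code, not generator noise.

## 9. Reproducibility

Every script and API accepts explicit seeds; `scripts/acceptance.py`
recomputes the wavelet frequency endpoints (3250 Hz and 81.25 Hz) from
the centre-frequency relation and validates them against an FFT
measurement of the mother wavelet at three resolutions.
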