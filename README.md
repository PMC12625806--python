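# dusqa — Doppler Ultrasound Signal Quality Assessment

`dusqa` classifies short windows of 1-D Doppler ultrasound audio from
low-cost fetal monitors into five signal-quality classes — **Good,
Poor, Interference, Talking, Silent** — in real time, so that an
untrained operator can be prompted to reposition the probe while a
recording is still in progress.

## The problem

Hand-held Doppler devices make fetal heart monitoring affordable in
low-resource settings, but the recordings they produce are only useful
when the probe is well placed: bursts of reflected ultrasound from the
moving heart must dominate the audio. In the field, recordings are
degraded by probe movement and poor contact (*Poor*), buzz from the
device's own handset (*Interference*), nearby conversation (*Talking*),
or an idle probe (*Silent*). Automatic quality grading closes the loop:
the audio is transformed into a wavelet scalogram and classified by a
small convolutional-recurrent network with attention, light enough for a
phone CPU.

## Pipeline

1. **Audio** — mono, decimated to a 4 kHz analysis rate.
2. **Labels** — three annotators label each 0.75 s segment; unanimity
   (Good/Poor/Silent) or 2-of-3 (Interference/Talking) consensus decides
   the truth; 5 consecutive same-class segments form a 3.75 s window.
3. **Scalogram** — continuous wavelet transform (Morlet, scales 1–40,
   pseudo-frequencies 3250 Hz down to 81.25 Hz), block-averaged to a
   250 × 40 image, min–max normalized.
4. **Network** — three 3×3 conv blocks (32/64/128 filters, batch norm,
   max-pool, dropout) → GRU(50) → time-distributed dense → context-
   vector attention → softmax over 5 classes (202 175 parameters).
   Implemented, with full backpropagation, in pure NumPy.
5. **Training** — class-balanced batches of 128, SGD with momentum,
   early stopping on a held-out validation fold, recording-disjoint
   k-fold cross-validation.
6. **Streaming** — the newest 3.75 s window is re-evaluated every
   second through a ring buffer; output is bit-identical to offline
   classification.

See `docs/methods.md` for parameters and rationale.

## Worked example

Generate synthetic study conditions, train a reduced-width model by
cross-validation, and stream-classify a recording:

```sh
# 25 recordings (5 per class), 25 segments each, with 3 simulated annotators
dusqa synth --n-recordings 25 --segments 25 --seed 1 --out scratch/data

# consensus labels -> 3.75 s windows -> 250x40 scalograms
dusqa preprocess --data scratch/data --out scratch/prep

# train once with a held-out validation fifth, save a checkpoint
dusqa train --prep scratch/prep --epochs 10 --seed 1 --out scratch/model

# metrics + confusion matrix of the checkpoint on prepared data
dusqa eval --prep scratch/prep --model scratch/model --out scratch/eval

# continuous quality trace for one WAV file
dusqa stream --wav scratch/data/synth-good-000.wav --model scratch/model --out scratch/trace.csv

# full 5-fold recording-disjoint cross-validation (desk-scale model)
dusqa cv --prep scratch/prep --epochs 12 --seed 1 --out scratch/cv
```

The `preprocess` step keeps 329 of the 525 possible windows (simulated
annotator disagreement breaks consensus runs, mostly in the unanimity
classes), and the cross-validation finishes in a few minutes on one CPU
with micro F1 94.4 ± 8.8 % and macro F1 95.3 ± 5.0 % across folds for
this seed.

The same pipeline via the Python API:

```python
import numpy as np
from dusqa.synthetic import SynthConfig, gen_good
from dusqa.scalogram import scalogram_pipeline, scale_to_frequency
from dusqa.network import desk_scale_config, build_model, predict_window

# frequency axis of the scalogram
print(scale_to_frequency(1))   # 3250.0  (Hz, finest scale)
print(scale_to_frequency(40))  # 81.25   (Hz, coarsest scale)

rec = gen_good(3.75, fhr_bpm=140.0, seed=0)     # one Good window of audio
sg = scalogram_pipeline(rec.samples)            # (250, 40) in [0, 1]
model = build_model(desk_scale_config(seed=1))
print(predict_window(sg.values, model))         # 5 class probabilities
```

On the default synthetic dataset (10 recordings per class, 210 windows
per class, seed 1), 5-fold cross-validation of the desk-scale model
reaches a pooled macro F1 above 90 % — see `tests/test_acceptance.py`
(criterion 4g), which performs exactly this run.

## Reproduction

Quantitative targets are recomputed from scratch by:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which re-derives the scalogram frequency endpoints (`t11`: scale 1 →
3250 Hz, `t12`: scale 40 → 81.25 Hz) from the Morlet centre-frequency
relation and cross-checks them against an independent FFT measurement of
the mother wavelet at three resolutions. The full test suite
(`python -m pytest -q tests/`) additionally reproduces published
external-test-set metrics from their confusion matrix, the real-time
evaluation schedule (34 evaluations for a 37.5 s signal), and the
end-to-end learnability and generator-discriminability checks.

## Layout

- `src/dusqa/audio_io.py` — WAV I/O, decimation, window/segment cutting
- `src/dusqa/annotation.py` — consensus rules, windows, agreement kappas
- `src/dusqa/scalogram.py` — CWT scalogram pipeline
- `src/dusqa/layers.py`, `network.py` — NumPy layers and model assembly
- `src/dusqa/training.py` — balanced batches, folds, early stopping, CV
- `src/dusqa/evaluation.py` — confusion matrices and F1 reporting
- `src/dusqa/streaming.py` — ring buffer, real-time evaluation schedule
- `src/dusqa/synthetic.py` — synthetic study conditions + statistic bank
- `src/dusqa/cli.py` — `dusqa` command-line interface
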