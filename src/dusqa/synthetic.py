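"""Doppler-like audio simulators for the five quality classes.

Real 1D Doppler ultrasound of the fetal heart sounds like a train of paired
"whoosh" bursts (valve/wall motion) whose carrier energy sits in the low
audio band.  The generators here caricature the five annotation classes
with simple, fully parameterised acoustics:

* Good - paired band-limited noise bursts repeating at the fetal heart
  rate over a weak noise floor (high SNR, strong envelope periodicity).
* Poor - the same burst machinery degraded by timing jitter, amplitude
  drift, beat dropouts and sub-0 dB SNR, destroying the periodicity.
* Interference - a gated harmonic buzz (fundamental ~217 Hz with
  harmonics, the familiar GSM/TDMA 4.6 ms frame structure) that dominates
  total power.
* Talking - formant-like filtered noise (resonances near 500 and 1500 Hz)
  amplitude-modulated at syllabic rates with pauses.
* Silent - a near-zero noise floor.

Every generator is a pure function of its arguments and seed.  A fixed
bank of acoustic statistics (RMS, buzz-band share, envelope periodicity,
high-band formant share) separates the classes by construction, which is
what makes learnability experiments on this data a test of the classifier
rather than of the generator.  No claim of physiological realism is made.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, iirpeak, lfilter, periodogram, sosfilt

from .annotation import MODEL_CLASSES, AnnotatorTrack, QualityClass
from .audio_io import ANALYSIS_RATE, AudioRecording

SEGMENT_SAMPLES = 3000  # 0.75 s at 4 kHz


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the synthetic acoustics and of the simulated annotators.

    ``snr_db`` maps class name to burst-to-floor SNR where applicable.
    ``annotator_flip`` is the per-segment probability that a simulated
    annotator replaces the true label with a random other class;
    ``annotator_unsure`` the probability of an Unsure vote.
    """

    rate: int = ANALYSIS_RATE
    fhr_bpm: tuple[float, float] = (110.0, 160.0)
    carrier_band_hz: tuple[float, float] = (150.0, 900.0)
    good_snr_db: float = 20.0
    poor_snr_db: float = -3.0
    buzz_fundamental_hz: float = 1000.0 / 4.6  # 4.6 ms TDMA frame
    buzz_harmonics: int = 8
    formants_hz: tuple[float, float] = (500.0, 1500.0)
    syllable_rate_hz: float = 5.0
    silent_rms: float = 3e-4
    annotator_flip: float = 0.05
    annotator_unsure: float = 0.02
    n_annotators: int = 3


def _bandpass_noise(rng, n, band, rate):
    sos = butter(4, band, btype="bandpass", fs=rate, output="sos")
    return sosfilt(sos, rng.standard_normal(n))


def _burst_envelope(n, rate, beat_times, widths, amps):
    """Sum of Hann bumps centred at beat_times (seconds)."""
    env = np.zeros(n)
    for t0, width, amp in zip(beat_times, widths, amps):
        half = int(width * rate / 2)
        c = int(t0 * rate)
        lo, hi = max(0, c - half), min(n, c + half)
        if hi <= lo:
            continue
        idx = np.arange(lo, hi) - (c - half)
        env[lo:hi] += amp * np.hanning(2 * half)[idx]
    return env

def _beat_train(rng, n, rate, fhr_bpm, jitter_frac, drop_prob, drift):
    """Burst envelope of paired (systolic/diastolic-like) heart bursts."""
    period = 60.0 / fhr_bpm
    times, widths, amps = [], [], []
    t = 0.05
    while t < n / rate:
        jitter = rng.normal(0.0, jitter_frac * period)
        gain = 1.0
        if drift:
            gain = 0.3 + 0.7 * 0.5 * (1 + np.sin(2 * np.pi * 0.15 * t + rng.uniform(0, 2 * np.pi)))
        if rng.random() >= drop_prob:
            times += [t + jitter, t + jitter + 0.42 * period]
            widths += [0.07, 0.05]
            amps += [gain, 0.6 * gain]
        t += period
    return _burst_envelope(n, rate, times, widths, amps)


def _mix_to_snr(signal, noise, snr_db):
    ps = np.mean(signal**2)
    pn = np.mean(noise**2)
    if pn == 0 or ps == 0:
        return signal + noise
    scale = np.sqrt(ps / (pn * 10 ** (snr_db / 10)))
    return signal + scale * noise


def _normalize(x, peak=0.8):
    m = np.max(np.abs(x))
    return x * (peak / m) if m > 0 else x


def gen_good(
    duration_s: float,
    fhr_bpm: float | None = None,
    cfg: SynthConfig | None = None,
    seed: int = 0,
) -> AudioRecording:
    """Clear heartbeat audio: periodic paired bursts at high SNR."""
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(seed)
    if fhr_bpm is None:
        fhr_bpm = rng.uniform(*cfg.fhr_bpm)
    n = int(round(duration_s * cfg.rate))
    env = _beat_train(rng, n, cfg.rate, fhr_bpm, jitter_frac=0.01, drop_prob=0.0, drift=False)
    carrier = _bandpass_noise(rng, n, cfg.carrier_band_hz, cfg.rate)
    signal = env * carrier
    noise = rng.standard_normal(n) * 1.0
    x = _mix_to_snr(signal, noise, cfg.good_snr_db)
    return AudioRecording(_normalize(x), cfg.rate, f"good-{seed}")


def gen_poor(
    duration_s: float, cfg: SynthConfig | None = None, seed: int = 0
) -> AudioRecording:
    """Degraded heartbeat audio: jittered, drifting, dropout-ridden, noisy."""
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(seed)
    fhr_bpm = rng.uniform(*cfg.fhr_bpm)
    n = int(round(duration_s * cfg.rate))
    env = _beat_train(rng, n, cfg.rate, fhr_bpm, jitter_frac=0.18, drop_prob=0.35, drift=True)
    carrier = _bandpass_noise(rng, n, cfg.carrier_band_hz, cfg.rate)
    signal = env * carrier
    noise = _bandpass_noise(rng, n, (50.0, 1500.0), cfg.rate)
    x = _mix_to_snr(signal, noise, cfg.poor_snr_db)
    return AudioRecording(_normalize(x, 0.5), cfg.rate, f"poor-{seed}")


def gen_interference(
    duration_s: float, cfg: SynthConfig | None = None, seed: int = 0
) -> AudioRecording:
    """Radio-frequency buzz: gated harmonic complex dominating total power."""
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * cfg.rate))
    t = np.arange(n) / cfg.rate
    f0 = cfg.buzz_fundamental_hz
    tone = np.zeros(n)
    for k in range(1, cfg.buzz_harmonics + 1):
        if k * f0 >= cfg.rate / 2:
            break
        tone += np.sin(2 * np.pi * k * f0 * t + rng.uniform(0, 2 * np.pi)) / k
    # on/off gating locked to the frame period keeps energy on the harmonics
    gate = ((t * f0) % 1.0) < 0.5
    signal = tone * gate
    noise = rng.standard_normal(n)
    x = _mix_to_snr(signal, noise, 25.0)
    return AudioRecording(_normalize(x, 0.7), cfg.rate, f"interference-{seed}")


def gen_talking(
    duration_s: float, cfg: SynthConfig | None = None, seed: int = 0
) -> AudioRecording:
    """Speech-like audio: formant-filtered noise with syllabic modulation."""
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * cfg.rate))
    noise = rng.standard_normal(n)
    voiced = np.zeros(n)
    for f, gain in zip(cfg.formants_hz, (1.0, 0.8)):
        b, a = iirpeak(f, Q=8.0, fs=cfg.rate)
        voiced += gain * lfilter(b, a, noise)
    # syllable bumps at ~cfg.syllable_rate_hz with pauses between utterances
    times, widths, amps = [], [], []
    t = 0.05
    while t < duration_s:
        if rng.random() < 0.15:  # inter-utterance pause
            t += rng.uniform(0.3, 0.7)
            continue
        times.append(t)
        widths.append(rng.uniform(0.10, 0.16))
        amps.append(rng.uniform(0.6, 1.0))
        t += rng.uniform(0.8, 1.2) / cfg.syllable_rate_hz
    env = _burst_envelope(n, cfg.rate, times, widths, amps)
    signal = env * voiced
    floor = rng.standard_normal(n)
    x = _mix_to_snr(signal, floor, 18.0)
    return AudioRecording(_normalize(x, 0.7), cfg.rate, f"talking-{seed}")


def gen_silent(
    duration_s: float, cfg: SynthConfig | None = None, seed: int = 0
) -> AudioRecording:
    """Near-zero floor: RMS at most 1e-3 of full scale."""
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * cfg.rate))
    x = np.clip(rng.standard_normal(n) * cfg.silent_rms, -0.009, 0.009)
    return AudioRecording(x, cfg.rate, f"silent-{seed}")


_GENERATORS = {
    QualityClass.GOOD: lambda d, cfg, seed: gen_good(d, None, cfg, seed),
    QualityClass.POOR: lambda d, cfg, seed: gen_poor(d, cfg, seed),
    QualityClass.INTERFERENCE: lambda d, cfg, seed: gen_interference(d, cfg, seed),
    QualityClass.TALKING: lambda d, cfg, seed: gen_talking(d, cfg, seed),
    QualityClass.SILENT: lambda d, cfg, seed: gen_silent(d, cfg, seed),
}


@dataclass(frozen=True)
class GeneratedRecording:
    """A synthetic recording with its ground truth and simulated annotations."""

    recording: AudioRecording
    truth: tuple[QualityClass, ...]  # one 5-class label per 0.75 s segment
    tracks: tuple[AnnotatorTrack, ...]


def gen_labeled_recording(
    blocks: list[tuple[QualityClass, int]],
    cfg: SynthConfig | None = None,
    seed: int = 0,
    recording_id: str | None = None,
) -> GeneratedRecording:
    """Compose a recording from (class, n_segments) blocks on the 0.75 s grid.

    Each block's audio is generated in one piece so within-block beat phase
    is continuous; simulated annotator tracks apply per-segment symmetric
    label confusion plus occasional Unsure votes to the ground truth.
    """
    cfg = cfg or SynthConfig()
    ss = np.random.SeedSequence(seed)
    block_seeds = ss.spawn(len(blocks) + 1)
    pieces, truth = [], []
    for (label, n_seg), bs in zip(blocks, block_seeds[:-1]):
        if label not in MODEL_CLASSES:
            raise ValueError("blocks must use the five model-facing classes")
        dur = n_seg * SEGMENT_SAMPLES / cfg.rate
        rec = _GENERATORS[label](dur, cfg, int(bs.generate_state(1)[0] % 2**31))
        pieces.append(rec.samples[: n_seg * SEGMENT_SAMPLES])
        truth += [label] * n_seg
    samples = np.concatenate(pieces)
    rid = recording_id or f"synth-{seed}"
    recording = AudioRecording(samples, cfg.rate, rid)

    ann_rng = np.random.default_rng(block_seeds[-1])
    tracks = []
    others = {c: [o for o in MODEL_CLASSES if o != c] for c in MODEL_CLASSES}
    for a in range(cfg.n_annotators):
        labels = []
        for true_label in truth:
            u = ann_rng.random()
            if u < cfg.annotator_unsure:
                labels.append(QualityClass.UNSURE)
            elif u < cfg.annotator_unsure + cfg.annotator_flip:
                labels.append(ann_rng.choice(others[true_label]))
            else:
                labels.append(true_label)
        tracks.append(AnnotatorTrack(rid, f"annotator-{a}", tuple(labels)))
    return GeneratedRecording(recording, tuple(truth), tuple(tracks))


def gen_dataset(
    n_recordings: int,
    class_mix: list[QualityClass] | None = None,
    cfg: SynthConfig | None = None,
    seed: int = 0,
    segments_per_recording: int = 25,
) -> list[GeneratedRecording]:
    """Single-class recordings cycled over ``class_mix`` (default: all five).

    With 25 segments each recording yields 21 maximally-overlapping 3.75 s
    windows of its class.
    """
    cfg = cfg or SynthConfig()
    mix = list(class_mix) if class_mix else list(MODEL_CLASSES)
    if not set(MODEL_CLASSES) <= set(mix):
        raise ValueError("class_mix must cover all five classes")
    ss = np.random.SeedSequence([seed, 7])
    out = []
    for i, child in enumerate(ss.spawn(n_recordings)):
        label = mix[i % len(mix)]
        out.append(
            gen_labeled_recording(
                [(label, segments_per_recording)],
                cfg,
                int(child.generate_state(1)[0] % 2**31),
                recording_id=f"synth-{label.name.lower()}-{i:03d}",
            )
        )
    return out


# --------------------------------------------------------------------------
# fixed acoustic-statistic bank: separates the generated classes without any
# learned model, so learnability experiments test the classifier, not the data
# --------------------------------------------------------------------------

def acoustic_features(samples: np.ndarray, cfg: SynthConfig | None = None) -> dict:
    """RMS, buzz share, envelope periodicity and high-band share of a window."""
    cfg = cfg or SynthConfig()
    x = np.asarray(samples, dtype=np.float64)
    rate = cfg.rate
    rms = float(np.sqrt(np.mean(x**2)))

    f, pxx = periodogram(x, fs=rate)
    total = pxx.sum() + 1e-30
    buzz = 0.0
    f0 = cfg.buzz_fundamental_hz
    for k in range(1, cfg.buzz_harmonics + 1):
        sel = np.abs(f - k * f0) < 6.0
        buzz += pxx[sel].sum()
    high = pxx[(f >= 1300) & (f <= 1700)].sum()

    # envelope periodicity: autocorrelation peak in the heartbeat lag range
    sos = butter(2, 20.0, btype="lowpass", fs=rate, output="sos")
    env = sosfilt(sos, np.abs(x))
    env = env - env.mean()
    denom = float(np.dot(env, env)) + 1e-30
    lags = np.arange(int(60 / 180 * rate), int(60 / 95 * rate))
    ac = np.array([np.dot(env[:-lag], env[lag:]) for lag in lags]) / denom
    periodicity = float(ac.max()) if len(ac) else 0.0

    return {
        "rms": rms,
        "buzz_share": float(buzz / total),
        "high_band_share": float(high / total),
        "periodicity": periodicity,
    }


def classify_by_statistics(samples: np.ndarray, cfg: SynthConfig | None = None) -> QualityClass:
    """Rule-based class decision from the fixed statistic bank."""
    ft = acoustic_features(samples, cfg)
    if ft["rms"] < 0.005:
        return QualityClass.SILENT
    if ft["buzz_share"] > 0.5:
        return QualityClass.INTERFERENCE
    if ft["high_band_share"] > 0.15:
        return QualityClass.TALKING
    if ft["periodicity"] > 0.5:
        return QualityClass.GOOD
    return QualityClass.POOR
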