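"""WAV input/output, decimation to the 4 kHz analysis rate, and window cutting.

Field recordings of 1D Doppler ultrasound arrive as 16-bit PCM WAV at
44.1 kHz; every downstream stage (annotation grids, scalograms, the
classifier) operates at 4 kHz.  The 44100 -> 4000 Hz conversion is the
rational ratio 40/441 and is performed with polyphase resampling and a
low-pass anti-alias filter cutting at the 2 kHz output Nyquist.

Time is discretised on a 0.75 s grid: at 4 kHz a grid segment is exactly
3000 samples and the 3.75 s classification window exactly 15000.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

logger = logging.getLogger(__name__)

#: analysis sampling rate in Hz used throughout the pipeline
ANALYSIS_RATE = 4000
#: annotation grid step in seconds
SEGMENT_S = 0.75
#: classification window length in seconds (5 consecutive grid segments)
WINDOW_S = 3.75

_PCM16_SCALE = 32768.0


@dataclass(frozen=True)
class AudioRecording:
    """A mono waveform with its sampling rate and an opaque identifier.

    ``samples`` are float amplitudes in [-1, 1] (16-bit full scale maps to
    -1.0 exactly at -32768).
    """

    samples: np.ndarray
    rate: int
    recording_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("AudioRecording requires a 1-D sample array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate


@dataclass(frozen=True)
class SampleSpan:
    """Half-open sample interval [start_sample, end_sample) at a given rate."""

    start_sample: int
    end_sample: int
    rate: int = ANALYSIS_RATE

    def __post_init__(self) -> None:
        if not (0 <= self.start_sample < self.end_sample):
            raise ValueError(
                f"invalid span [{self.start_sample}, {self.end_sample})"
            )

    @property
    def n_samples(self) -> int:
        return self.end_sample - self.start_sample

    def slice(self, samples: np.ndarray) -> np.ndarray:
        return samples[self.start_sample : self.end_sample]


def read_wav(path, recording_id: str | None = None) -> AudioRecording:
    """Read a 16-bit PCM WAV file into an :class:`AudioRecording`.

    Integer PCM is scaled by 1/32768 so full-scale negative maps to -1.0.
    Multi-channel files are reduced to channel 0 with a warning; float WAVs
    are accepted as already normalised.
    """
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        warnings.warn(
            f"{path}: {data.shape[1]}-channel WAV, keeping channel 0",
            stacklevel=2,
        )
        data = data[:, 0]
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / _PCM16_SCALE
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"{path}: unsupported WAV sample format {data.dtype}")
    rid = recording_id if recording_id is not None else str(path)
    return AudioRecording(samples=samples, rate=int(rate), recording_id=rid)


def write_wav(path, rec: AudioRecording) -> None:
    """Write a recording as 16-bit PCM, clipping to full scale."""
    clipped = np.clip(rec.samples, -1.0, 32767.0 / _PCM16_SCALE)
    pcm = np.round(clipped * _PCM16_SCALE).astype(np.int16)
    wavfile.write(path, rec.rate, pcm)


def decimate_to_analysis_rate(
    rec: AudioRecording, target_rate: int = ANALYSIS_RATE
) -> AudioRecording:
    """Resample a recording down to ``target_rate`` with anti-alias filtering.

    Polyphase rational resampling (e.g. 40/441 for 44.1 kHz input); the
    built-in Kaiser-windowed low-pass cuts at the output Nyquist.  A
    recording already at the target rate is returned unchanged; upsampling
    is refused.
    """
    if rec.rate == target_rate:
        return rec
    if rec.rate < target_rate:
        raise ValueError(
            f"refusing to upsample {rec.rate} Hz -> {target_rate} Hz"
        )
    g = np.gcd(rec.rate, target_rate)
    up, down = target_rate // g, rec.rate // g
    out = resample_poly(rec.samples, up, down)
    return AudioRecording(
        samples=out, rate=target_rate, recording_id=rec.recording_id
    )


def cut_windows(
    rec: AudioRecording,
    window_s: float = WINDOW_S,
    hop_s: float = SEGMENT_S,
) -> list[SampleSpan]:
    """All ``window_s`` spans starting every ``hop_s`` within the recording.

    Span *k* is ``[k*hop*rate, k*hop*rate + window*rate)`` for
    ``k = 0 .. floor((duration - window)/hop)``; a recording shorter than one
    window yields an empty list.
    """
    if hop_s <= 0:
        raise ValueError("hop_s must be positive")
    win = int(round(window_s * rec.rate))
    n = len(rec.samples)
    spans = []
    k = 0
    while True:
        start = int(round(k * hop_s * rec.rate))
        if start + win > n:
            break
        spans.append(SampleSpan(start, start + win, rec.rate))
        k += 1
    return spans


def cut_segments(rec: AudioRecording, segment_s: float = SEGMENT_S) -> list[SampleSpan]:
    """Non-overlapping annotation-grid segments (0.75 s each by default)."""
    seg = int(round(segment_s * rec.rate))
    n_full = len(rec.samples) // seg
    return [SampleSpan(i * seg, (i + 1) * seg, rec.rate) for i in range(n_full)]


def spans_to_frame(recording_id: str, spans: list[SampleSpan]) -> pd.DataFrame:
    """Tabulate spans as (recording_id, start_sample, end_sample) rows."""
    return pd.DataFrame(
        {
            "recording_id": recording_id,
            "start_sample": [s.start_sample for s in spans],
            "end_sample": [s.end_sample for s in spans],
        }
    )
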