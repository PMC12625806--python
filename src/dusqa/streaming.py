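"""Ring-buffer streaming classification of live 4 kHz Doppler audio.

A fixed 15000-sample (3.75 s) ring buffer holds the most recent audio; once
it first fills, the buffered window is scalogram-transformed and classified
at every hop (1 s by default, matching an on-device once-per-second
feedback loop; 0.75 s reproduces a dense probability trace).  Streamed
results are bitwise identical to classifying the same sample spans offline.
A whole recording is summarised by the elementwise mean of its per-window
probability vectors, decided by argmax (lowest class index on ties).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import CLASS_NAMES, QualityClass
from .audio_io import ANALYSIS_RATE
from .network import QualityModel, predict_window
from .scalogram import WINDOW_SAMPLES, WaveletConfig, scalogram_pipeline


class RingBuffer:
    """Circular store of the most recent ``capacity`` samples."""

    def __init__(self, capacity: int = WINDOW_SAMPLES):
        self.capacity = capacity
        self._buf = np.zeros(capacity)
        self._pos = 0
        self._count = 0

    @property
    def filled(self) -> bool:
        return self._count >= self.capacity

    def write(self, samples: np.ndarray) -> None:
        samples = np.asarray(samples, dtype=np.float64)
        if len(samples) >= self.capacity:
            self._buf[:] = samples[-self.capacity :]
            self._pos = 0
        else:
            end = self._pos + len(samples)
            if end <= self.capacity:
                self._buf[self._pos : end] = samples
            else:
                k = self.capacity - self._pos
                self._buf[self._pos :] = samples[:k]
                self._buf[: end - self.capacity] = samples[k:]
            self._pos = end % self.capacity
        self._count += len(samples)

    def read(self) -> np.ndarray:
        """The buffered samples in time order (oldest first)."""
        if not self.filled:
            return np.concatenate(
                [self._buf[: self._pos]]
            )  # partial content, time-ordered by construction
        return np.concatenate([self._buf[self._pos :], self._buf[: self._pos]])


@dataclass(frozen=True)
class ProbabilityTrace:
    """Per-evaluation class probabilities along a recording."""

    times: np.ndarray  # seconds at the right edge of each evaluated window
    probs: np.ndarray  # (n_eval, 5)
    latency_s: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=np.float64)
        p = np.asarray(self.probs, dtype=np.float64)
        if len(t) != len(p) or (len(t) and p.shape[1] != 5):
            raise ValueError("times and (n, 5) probs must align")
        if len(t) and (np.diff(t) <= 0).any():
            raise ValueError("evaluation times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "probs", p)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.probs, columns=[f"p_{c.lower()}" for c in CLASS_NAMES]
        )
        df.insert(0, "time_s", self.times)
        df["decision"] = [
            CLASS_NAMES[i] for i in self.probs.argmax(axis=1)
        ]
        return df


def evaluation_times(
    duration_s: float, window_s: float = 3.75, hop_s: float = 1.0
) -> np.ndarray:
    """Seconds at which a streaming evaluation fires.

    The first evaluation happens when the buffer first holds a full window,
    then every hop: window + k*hop for k = 0 .. floor((duration-window)/hop).
    """
    if hop_s <= 0:
        raise ValueError("hop_s must be positive")
    if duration_s < window_s:
        return np.array([])
    n = int(np.floor((duration_s - window_s) / hop_s + 1e-9)) + 1
    return window_s + hop_s * np.arange(n)


def stream_classify(
    samples: np.ndarray,
    model: QualityModel,
    hop_s: float = 1.0,
    wavelet_cfg: WaveletConfig | None = None,
    chunk_samples: int = 400,
    record_latency: bool = False,
) -> ProbabilityTrace:
    """Feed a 4 kHz sample stream through the ring buffer and classify.

    The stream is consumed in chunks (100 ms by default); at every hop past
    the initial fill, the buffer content is transformed and classified.  A
    trailing partial window is never evaluated.
    """
    cfg = wavelet_cfg or WaveletConfig()
    samples = np.asarray(samples, dtype=np.float64)
    rate = cfg.analysis_rate
    hop = int(round(hop_s * rate))
    buf = RingBuffer(WINDOW_SAMPLES)
    times, probs, latencies = [], [], []
    next_eval = WINDOW_SAMPLES
    consumed = 0
    while consumed < len(samples):
        # never write past the next evaluation boundary in one go, so the
        # buffer is read exactly when the schedule dictates
        take = min(chunk_samples, len(samples) - consumed, next_eval - consumed)
        buf.write(samples[consumed : consumed + take])
        consumed += take
        if buf.filled and consumed == next_eval:
            t0 = time.perf_counter()
            p = predict_window(scalogram_pipeline(buf.read(), cfg), model)
            if record_latency:
                latencies.append(time.perf_counter() - t0)
            times.append(next_eval / rate)
            probs.append(p)
            next_eval += hop
    return ProbabilityTrace(
        np.array(times),
        np.array(probs).reshape(len(times), 5),
        tuple(latencies),
    )


def summarize_signal(trace: ProbabilityTrace) -> tuple[np.ndarray, QualityClass]:
    """Average the trace probabilities and decide the recording's class."""
    if len(trace.times) == 0:
        raise ValueError("cannot summarise an empty trace")
    mean = trace.probs.mean(axis=0)
    total = mean.sum()
    if abs(total - 1.0) > 1e-9:
        mean = mean / total
    return mean, QualityClass(int(mean.argmax()))
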