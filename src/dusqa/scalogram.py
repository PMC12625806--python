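"""Morlet scalograms: the 250 x 40 time-frequency images the classifier eats.

A 3.75 s window at 4 kHz (15000 samples) is transformed with the continuous
wavelet transform at integer scales 1..40 of the real Morlet mother wavelet
(center frequency 0.8125 cycles/sample, the classic MATLAB ``morl``
convention), giving per-scale center frequencies 3250 Hz down to 81.25 Hz.
Coefficient magnitudes are averaged over non-overlapping blocks of 60 time
samples to 250 time columns and min-max normalised to [0, 1].

The magnitude (not power) convention, block-mean temporal reduction and
zero-padded CWT edges are package choices, recorded in the config so a
stored scalogram can be traced to the exact transform that produced it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pywt

from .audio_io import ANALYSIS_RATE

#: samples in one analysis window at 4 kHz
WINDOW_SAMPLES = 15000


@dataclass(frozen=True)
class WaveletConfig:
    """Parameters of the scalogram transform.

    ``center_frequency`` is in cycles per sample of the mother wavelet; the
    default 0.8125 is what makes scales 1..40 at 4 kHz span 3250 down to
    81.25 Hz.
    """

    scales: tuple[int, ...] = tuple(range(1, 41))
    mother: str = "morl"
    center_frequency: float = 0.8125
    analysis_rate: int = ANALYSIS_RATE
    time_columns: int = 250

    def __post_init__(self) -> None:
        sc = tuple(int(s) for s in self.scales)
        if any(s <= 0 for s in sc) or any(
            b <= a for a, b in zip(sc, sc[1:])
        ):
            raise ValueError("scales must be strictly increasing positive integers")
        object.__setattr__(self, "scales", sc)

    @property
    def n_scales(self) -> int:
        return len(self.scales)

    def to_json(self) -> str:
        return json.dumps(
            {
                "scales": list(self.scales),
                "mother": self.mother,
                "center_frequency": self.center_frequency,
                "analysis_rate": self.analysis_rate,
                "time_columns": self.time_columns,
            }
        )


@dataclass(frozen=True)
class Scalogram:
    """Normalised scalogram: rows = time (early to late), columns = scale 1..40."""

    values: np.ndarray
    config: WaveletConfig = field(default_factory=WaveletConfig)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        expected = (self.config.time_columns, self.config.n_scales)
        if v.shape != expected:
            raise ValueError(f"scalogram shape {v.shape}, expected {expected}")
        if not np.all(np.isfinite(v)):
            raise ValueError("scalogram values must be finite")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("scalogram values must lie in [0, 1]")
        object.__setattr__(self, "values", v)


def scale_to_frequency(scale: int, cfg: WaveletConfig | None = None) -> float:
    """Center frequency in Hz of the wavelet at the given integer scale.

    f(scale) = center_frequency * analysis_rate / scale; scale 1 maps to
    3250 Hz and scale 40 to 81.25 Hz under the defaults.
    """
    if cfg is None:
        cfg = WaveletConfig()
    if scale <= 0:
        raise ValueError("scale must be a positive integer")
    return cfg.center_frequency * cfg.analysis_rate / scale


def cwt_magnitude(window: np.ndarray, cfg: WaveletConfig | None = None) -> np.ndarray:
    """|CWT| of a 15000-sample window: a (time x scales) magnitude matrix."""
    if cfg is None:
        cfg = WaveletConfig()
    window = np.asarray(window, dtype=np.float64)
    if window.shape != (WINDOW_SAMPLES,):
        raise ValueError(
            f"window must have exactly {WINDOW_SAMPLES} samples, got {window.shape}"
        )
    coeffs, _ = pywt.cwt(
        window, np.asarray(cfg.scales, dtype=float), cfg.mother, method="fft"
    )
    return np.abs(coeffs).T  # (time, scales)


def temporal_reduce(matrix: np.ndarray, time_columns: int = 250) -> np.ndarray:
    """Average non-overlapping time blocks down to ``time_columns`` rows."""
    matrix = np.asarray(matrix, dtype=np.float64)
    n_time, n_scales = matrix.shape
    if n_time % time_columns != 0:
        raise ValueError(
            f"time length {n_time} not divisible by {time_columns} columns"
        )
    block = n_time // time_columns
    return matrix.reshape(time_columns, block, n_scales).mean(axis=1)


def minmax_normalize(matrix: np.ndarray) -> np.ndarray:
    """Affine rescale to [0, 1]; a constant matrix maps to all zeros."""
    matrix = np.asarray(matrix, dtype=np.float64)
    if not np.all(np.isfinite(matrix)):
        raise ValueError("matrix must be finite")
    lo, hi = matrix.min(), matrix.max()
    if hi == lo:
        return np.zeros_like(matrix)
    return (matrix - lo) / (hi - lo)


def scalogram_pipeline(
    window: np.ndarray, cfg: WaveletConfig | None = None
) -> Scalogram:
    """Full transform: |CWT| -> block-mean to 250 columns -> min-max to [0,1]."""
    if cfg is None:
        cfg = WaveletConfig()
    mag = cwt_magnitude(window, cfg)
    reduced = temporal_reduce(mag, cfg.time_columns)
    return Scalogram(values=minmax_normalize(reduced), config=cfg)


def save_scalograms(
    path, values: np.ndarray, cfg: WaveletConfig, meta: dict | None = None
) -> None:
    """Persist a stack of scalograms as .npy with a JSON sidecar."""
    path = Path(path)
    np.save(path, np.asarray(values, dtype=np.float32))
    sidecar = {"shape": list(np.shape(values)), "config": json.loads(cfg.to_json())}
    if meta:
        sidecar.update(meta)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_scalograms(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    values = np.load(path.with_suffix(".npy"))
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return values, sidecar
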