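"""Glue from labelled recordings to a trainable scalogram dataset."""

from __future__ import annotations

import numpy as np

from .annotation import ConsensusSegment, build_windows, consensus_track
from .scalogram import WaveletConfig, scalogram_pipeline
from .synthetic import GeneratedRecording
from .training import Dataset


def windows_from_recording(rec: GeneratedRecording, use_truth: bool = False):
    """Consensus 3.75 s windows of one recording (or ground-truth windows)."""
    if use_truth:
        segments = [
            ConsensusSegment(rec.recording.recording_id, i, lab)
            for i, lab in enumerate(rec.truth)
        ]
    else:
        segments = consensus_track(list(rec.tracks))
    return build_windows(segments, rec.recording.rate)


def build_dataset(
    recordings: list[GeneratedRecording],
    wavelet_cfg: WaveletConfig | None = None,
    use_truth: bool = False,
) -> Dataset:
    """Scalogram-transform every consensus window of every recording."""
    cfg = wavelet_cfg or WaveletConfig()
    scalos, labels, rids = [], [], []
    for rec in recordings:
        for win in windows_from_recording(rec, use_truth):
            window_samples = win.span.slice(rec.recording.samples)
            scalos.append(scalogram_pipeline(window_samples, cfg).values)
            labels.append(int(win.label))
            rids.append(win.recording_id)
    if not scalos:
        raise ValueError("no consensus windows survive; nothing to train on")
    return Dataset(np.stack(scalos), np.array(labels), tuple(rids))
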