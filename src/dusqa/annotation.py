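"""Quality labels, annotator consensus, window building and rater agreement.

Annotators grade 0.75 s segments of Doppler audio into six categories
(Good, Poor, Interference, Talking, Silent, Unsure).  Consensus rules turn
three independent tracks into a single labelled track: the well-populated
classes (Good, Poor, Silent) require unanimity, the scarce ones
(Interference, Talking) accept a 2-of-3 majority, and Unsure segments are
discarded.  Five consecutive consensus segments of one class form a 3.75 s
classification window; windows are emitted at every admissible start so
runs overlap maximally.

Agreement statistics (Fleiss' kappa for three raters on segments, Cohen's
kappa for two raters on windows) are delegated to statsmodels and
scikit-learn respectively, with explicit handling of the degenerate
single-category case.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score
from statsmodels.stats.inter_rater import aggregate_raters
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss

from .audio_io import ANALYSIS_RATE, SampleSpan

#: segments per classification window (5 x 0.75 s = 3.75 s)
SEGMENTS_PER_WINDOW = 5


class QualityClass(IntEnum):
    """Six-way annotation label; model-facing code sees only the first five."""

    GOOD = 0
    POOR = 1
    INTERFERENCE = 2
    TALKING = 3
    SILENT = 4
    UNSURE = 5


#: the five model-facing classes in canonical order
MODEL_CLASSES: tuple[QualityClass, ...] = (
    QualityClass.GOOD,
    QualityClass.POOR,
    QualityClass.INTERFERENCE,
    QualityClass.TALKING,
    QualityClass.SILENT,
)

CLASS_NAMES = ("Good", "Poor", "Interference", "Talking", "Silent")

#: classes that require unanimous agreement of all three annotators
_UNANIMOUS = {QualityClass.GOOD, QualityClass.POOR, QualityClass.SILENT}
#: scarce classes accepted on a two-of-three majority
_MAJORITY = {QualityClass.INTERFERENCE, QualityClass.TALKING}

#: sentinel for a segment with no consensus label
ABSENT = None


@dataclass(frozen=True)
class AnnotatorTrack:
    """One annotator's labels for a recording, one per 0.75 s segment."""

    recording_id: str
    annotator_id: str
    labels: tuple[QualityClass, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "labels", tuple(QualityClass(v) for v in self.labels)
        )


@dataclass(frozen=True)
class ConsensusSegment:
    """A 0.75 s segment after consensus; label is None when consensus failed."""

    recording_id: str
    segment_index: int
    label: QualityClass | None

    def __post_init__(self) -> None:
        if self.label is not None and self.label == QualityClass.UNSURE:
            raise ValueError("consensus segments never carry UNSURE")


@dataclass(frozen=True)
class QualityWindow:
    """A 3.75 s window of five consecutive same-class consensus segments."""

    recording_id: str
    start_segment_index: int
    label: QualityClass
    span: SampleSpan

    def __post_init__(self) -> None:
        if self.label not in MODEL_CLASSES:
            raise ValueError("window label must be one of the five model classes")


class DegenerateAgreementError(ValueError):
    """Raised when a kappa statistic is undefined (single observed category)."""


def consensus_3(labels) -> QualityClass | None:
    """Consensus label from three annotator votes on one segment.

    Good/Poor/Silent need 3/3 agreement; Interference/Talking need at least
    2/3 (a dissenting third vote, including Unsure, does not block the
    majority).  Unsure can never be a consensus outcome.  Returns ``None``
    when no rule fires.
    """
    labels = tuple(QualityClass(v) for v in labels)
    if len(labels) != 3:
        raise ValueError(f"consensus_3 expects exactly 3 labels, got {len(labels)}")
    if labels[0] in _UNANIMOUS and labels[0] == labels[1] == labels[2]:
        return labels[0]
    for cls in _MAJORITY:
        if sum(lab == cls for lab in labels) >= 2:
            return cls
    return ABSENT


def consensus_2(labels) -> QualityClass | None:
    """Two-rater consensus for directly-labelled 3.75 s windows.

    The label stands iff both raters agree on a non-Unsure class.
    """
    labels = tuple(QualityClass(v) for v in labels)
    if len(labels) != 2:
        raise ValueError(f"consensus_2 expects exactly 2 labels, got {len(labels)}")
    if labels[0] == labels[1] and labels[0] != QualityClass.UNSURE:
        return labels[0]
    return ABSENT


def consensus_track(tracks: list[AnnotatorTrack]) -> list[ConsensusSegment]:
    """Apply :func:`consensus_3` segment-wise to three aligned tracks."""
    if len(tracks) != 3:
        raise ValueError("consensus_track expects exactly 3 annotator tracks")
    lengths = {len(t.labels) for t in tracks}
    if len(lengths) != 1:
        raise ValueError("annotator tracks differ in length")
    rid = tracks[0].recording_id
    return [
        ConsensusSegment(rid, i, consensus_3([t.labels[i] for t in tracks]))
        for i in range(lengths.pop())
    ]


def build_windows(
    segments: list[ConsensusSegment], rate: int = ANALYSIS_RATE
) -> list[QualityWindow]:
    """All maximally-overlapping 3.75 s windows over one recording's segments.

    A window starts at every index *i* where segments ``i .. i+4`` carry the
    same non-absent label; a run of L same-class segments therefore yields
    L - 4 windows.  Runs break at any absent segment.
    """
    seg_samples = int(round(0.75 * rate))
    windows = []
    for i in range(len(segments) - SEGMENTS_PER_WINDOW + 1):
        group = segments[i : i + SEGMENTS_PER_WINDOW]
        label = group[0].label
        if label is None:
            continue
        if all(s.label == label for s in group[1:]):
            span = SampleSpan(
                i * seg_samples, (i + SEGMENTS_PER_WINDOW) * seg_samples, rate
            )
            windows.append(
                QualityWindow(segments[0].recording_id, i, label, span)
            )
    return windows


def fleiss_kappa(label_matrix) -> float:
    """Fleiss' kappa for a (segments x annotators) categorical label matrix.

    Raises :class:`DegenerateAgreementError` when only one category occurs,
    where chance-corrected agreement is undefined (0/0).
    """
    arr = np.asarray(label_matrix)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need >= 2 segments and >= 2 annotators")
    counts, _ = aggregate_raters(arr)
    if np.count_nonzero(counts.sum(axis=0)) < 2:
        raise DegenerateAgreementError(
            "Fleiss' kappa undefined: all labels fall in one category"
        )
    return float(_sm_fleiss(counts, method="fleiss"))


def cohen_kappa(labels_a, labels_b) -> float:
    """Cohen's kappa between two equal-length label sequences."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length sequences of length >= 2")
    if len(np.unique(np.concatenate([a, b]))) < 2:
        raise DegenerateAgreementError(
            "Cohen's kappa undefined: all labels fall in one category"
        )
    return float(cohen_kappa_score(a, b))


def tracks_to_frame(tracks: list[AnnotatorTrack]) -> pd.DataFrame:
    """Annotator tracks as long-format rows for CSV export."""
    rows = [
        (t.recording_id, t.annotator_id, i, lab.name)
        for t in tracks
        for i, lab in enumerate(t.labels)
    ]
    return pd.DataFrame(
        rows, columns=["recording_id", "annotator_id", "segment_index", "label"]
    )


def frame_to_tracks(df: pd.DataFrame) -> list[AnnotatorTrack]:
    """Inverse of :func:`tracks_to_frame`."""
    tracks = []
    for (rid, aid), grp in df.groupby(["recording_id", "annotator_id"], sort=True):
        grp = grp.sort_values("segment_index")
        labels = tuple(QualityClass[name] for name in grp["label"])
        tracks.append(AnnotatorTrack(str(rid), str(aid), labels))
    return tracks
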