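"""Preictal/interictal sampling from a gap-aware timeline.

Sampling follows the leading-seizure convention: seizures cluster, and
only the first seizure of each cluster — one preceded by at least the
seizure-free time T of quiet — contributes positive (preictal) samples.
The preictal segment of a leading seizure is the SOP-long stretch ending
SPH before onset, ``[onset - SPH - SOP, onset - SPH)``, clipped to
recording coverage and purged of any earlier ictal span.  Interictal
(negative) time is everything at least a guard distance (default 2 h)
away from every seizure, leading or not.  Segments are tiled into
fixed-length moving windows (default 5 s, no overlap); partial windows
at segment ends are dropped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import intervals as iv
from .annotations_io import SeizureEvent, SubjectTimeline, common_channels, read_signal

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SamplingParams:
    """All durations in seconds.

    Defaults are the benchmark regime: SPH 5 min, SOP 30 min, seizure-free
    time T 4 h, interictal guard 2 h, 5-s windows with no overlap.
    """

    sph: float = 300.0
    sop: float = 1800.0
    t_free: float = 14400.0
    interictal_guard: float = 7200.0
    window_len: float = 5.0
    window_overlap: float = 0.0

    def __post_init__(self):
        for name in ("sph", "sop", "t_free", "interictal_guard",
                     "window_len", "window_overlap"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sop <= 0:
            raise ValueError("sop must be > 0")
        if self.window_len <= self.window_overlap:
            raise ValueError("window_len must exceed window_overlap")


@dataclass(frozen=True)
class LabeledSegment:
    """A maximal preictal or interictal stretch, before window tiling."""

    segment_id: int
    interval: Tuple[float, float]
    label: int  # 1 = preictal, 0 = interictal
    source_seizure: Optional[int] = None

    def __post_init__(self):
        if self.label == 1 and self.source_seizure is None:
            raise ValueError("preictal segment needs a source seizure")
        if self.label == 0 and self.source_seizure is not None:
            raise ValueError("interictal segment must not carry a seizure")

    @property
    def duration(self) -> float:
        return self.interval[1] - self.interval[0]


@dataclass
class WindowSample:
    """One fixed-length labeled window cut from a segment."""

    data: np.ndarray  # (n_channels, window_len * rate)
    label: int
    segment_id: int
    t_start: float
    t_end: float
    channels: Tuple[str, ...]
    source_seizure: Optional[int] = None


class EmptyPreictalWarning(UserWarning):
    """A leading seizure yielded no preictal windows (missing data)."""


def find_leading_seizures(
    seizures: Sequence[SeizureEvent], t_free: float
) -> List[SeizureEvent]:
    """Cluster-initial seizures: first overall, or preceded by >= t_free quiet.

    The gap is measured from the previous seizure's offset to the current
    onset, regardless of whether the previous seizure was itself leading.
    """
    for prev, cur in zip(seizures, seizures[1:]):
        if cur.onset_global < prev.onset_global:
            raise ValueError("seizures must be sorted by onset")
    leading: List[SeizureEvent] = []
    for i, s in enumerate(seizures):
        if i == 0 or s.onset_global - seizures[i - 1].offset_global >= t_free:
            leading.append(s)
    return leading


def preictal_intervals(
    seizure: SeizureEvent,
    params: SamplingParams,
    timeline: SubjectTimeline,
) -> iv.IntervalSet:
    """Coverage-clipped preictal span of one seizure; may be empty.

    Nominal span is ``[onset - sph - sop, onset - sph)``; recording gaps
    and any earlier seizure's ictal span are subtracted.  An empty result
    (data missing) is valid output, not an error.
    """
    onset = seizure.onset_global
    nominal = [(onset - params.sph - params.sop, onset - params.sph)]
    clipped = iv.intersect(nominal, timeline.coverage)
    return iv.subtract(clipped, timeline.ictal_spans)


def interictal_intervals(
    timeline: SubjectTimeline, params: SamplingParams
) -> iv.IntervalSet:
    """Coverage minus a guard-padded neighbourhood of EVERY seizure."""
    excluded = [
        (s.onset_global - params.interictal_guard,
         s.offset_global + params.interictal_guard)
        for s in timeline.seizures
    ]
    return iv.subtract(timeline.coverage, excluded)


def tile_windows(
    intervals: Sequence[Tuple[float, float]], params: SamplingParams
) -> List[Tuple[float, float]]:
    """Tile each interval with windows anchored at its start.

    Successive windows advance by ``window_len - window_overlap``; a
    window overhanging the interval end is dropped.
    """
    step = params.window_len - params.window_overlap
    out: List[Tuple[float, float]] = []
    for a, b in iv.normalize(intervals):
        n = int(np.floor((b - a - params.window_len) / step)) + 1
        for k in range(max(n, 0)):
            out.append((a + k * step, a + k * step + params.window_len))
    return out


@dataclass
class SampleSet:
    """Window samples plus the provenance records behind them."""

    windows: List[WindowSample]
    segments: List[LabeledSegment]
    leading_seizures: List[SeizureEvent]
    channels: Tuple[str, ...]

    @property
    def n_preictal(self) -> int:
        return sum(1 for w in self.windows if w.label == 1)

    @property
    def n_interictal(self) -> int:
        return sum(1 for w in self.windows if w.label == 0)

    def manifest(self) -> str:
        """Delimited-text window manifest for inspection and auditing."""
        lines = ["window_id\tsegment_id\tlabel\tt_start\tt_end\tsource_seizure"]
        for i, w in enumerate(self.windows):
            src = "" if w.source_seizure is None else str(w.source_seizure)
            lines.append(
                f"{i}\t{w.segment_id}\t{w.label}\t{w.t_start:g}\t{w.t_end:g}\t{src}"
            )
        return "\n".join(lines) + "\n"

    def segments_bed(self) -> str:
        """Segments as BED-like 0-based half-open records (seconds)."""
        lines = []
        for s in self.segments:
            name = "preictal" if s.label == 1 else "interictal"
            lines.append(f"{name}\t{s.interval[0]:g}\t{s.interval[1]:g}\t{s.segment_id}")
        return "\n".join(lines) + "\n"


def segment_timeline(
    timeline: SubjectTimeline, params: SamplingParams
) -> Tuple[List[LabeledSegment], List[SeizureEvent]]:
    """Labeled preictal/interictal segments with provenance, no signal IO."""
    leading = find_leading_seizures(timeline.seizures, params.t_free)
    segments: List[LabeledSegment] = []
    sid = 0
    for s in leading:
        spans = preictal_intervals(s, params, timeline)
        if not spans:
            warnings.warn(
                f"leading seizure {s.seizure_id} of {timeline.subject_id} "
                f"yielded no preictal interval (missing data)",
                EmptyPreictalWarning,
                stacklevel=2,
            )
        for span in spans:
            segments.append(LabeledSegment(sid, span, 1, s.seizure_id))
            sid += 1
    for span in interictal_intervals(timeline, params):
        segments.append(LabeledSegment(sid, span, 0, None))
        sid += 1
    return segments, leading


def build_sample_set(
    timeline: SubjectTimeline,
    params: SamplingParams,
    channels: Optional[Sequence[str]] = None,
    load_signal: bool = True,
) -> SampleSet:
    """Cut labeled windows from the timeline.

    Preictal windows come from leading seizures only; interictal windows
    from guard-cleared time.  When ``load_signal`` is false the window
    ``data`` arrays are empty placeholders (interval bookkeeping only).
    A leading seizure with zero preictal windows triggers
    :class:`EmptyPreictalWarning`; wall-to-wall seizures leaving no
    interictal time trigger a plain warning.
    """
    montage = tuple(channels) if channels is not None else common_channels(timeline)
    segments, leading = segment_timeline(timeline, params)
    windows: List[WindowSample] = []
    for seg in segments:
        for (a, b) in tile_windows([seg.interval], params):
            if load_signal and timeline.signal_store is not None:
                data = read_signal(timeline, (a, b), montage)
            else:
                data = np.empty((len(montage), 0), dtype=np.float32)
            windows.append(
                WindowSample(
                    data=data,
                    label=seg.label,
                    segment_id=seg.segment_id,
                    t_start=a,
                    t_end=b,
                    channels=montage,
                    source_seizure=seg.source_seizure,
                )
            )
    for s in leading:
        if not any(w.label == 1 and w.source_seizure == s.seizure_id for w in windows):
            warnings.warn(
                f"leading seizure {s.seizure_id} of {timeline.subject_id} "
                f"produced no preictal windows",
                EmptyPreictalWarning,
                stacklevel=2,
            )
    if not any(w.label == 0 for w in windows):
        warnings.warn(
            f"{timeline.subject_id}: no interictal windows (no guard-cleared time)",
            UserWarning,
            stacklevel=2,
        )
    return SampleSet(windows=windows, segments=segments,
                     leading_seizures=leading, channels=montage)
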