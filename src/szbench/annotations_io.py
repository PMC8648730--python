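"""Per-subject recording timelines from CHB-MIT-style annotation summaries.

A subject's long-term EEG is stored as many EDF files with clock-time
stamps and, frequently, gaps between files.  Everything downstream
(preictal/interictal sampling, leakage-free cross-validation) works on a
single gap-aware global time axis: float seconds, origin at the start of
the first file, all intervals half-open ``[start, end)``.

The summary dialect parsed here is the plain-text one that ships with the
CHB-MIT scalp EEG database::

    File Name: chb01_03.edf
    File Start Time: 13:43:04
    File End Time: 14:43:04
    Number of Seizures in File: 1
    Seizure Start Time: 2996 seconds
    Seizure End Time: 3036 seconds

Clock times carry no date, so a file whose start clock precedes the
previous file's start clock is taken to have crossed midnight (+24 h).
Hours greater than 23 (which the database itself uses, and which
:func:`write_summary` emits) are accepted and disambiguate multi-day gaps.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Protocol, Sequence, Tuple

import numpy as np

from . import intervals as iv


class SummaryParseError(ValueError):
    """Malformed summary text; message names the offending line."""


class TimelineValidationError(ValueError):
    """Timeline violates an invariant (overlap, bad seizure span, ...)."""


class CoverageError(ValueError):
    """Requested interval touches a gap in the recording coverage."""


class ChannelError(ValueError):
    """Requested channel missing, or no common montage exists."""


@dataclass(frozen=True)
class RecordingFile:
    """One EDF file placed on the subject's global time axis."""

    file_id: str
    start_global: float
    duration: float
    sampling_rate: float
    channel_names: Tuple[str, ...]

    def __post_init__(self):
        if self.duration <= 0:
            raise TimelineValidationError(f"{self.file_id}: duration must be > 0")
        if self.sampling_rate <= 0:
            raise TimelineValidationError(f"{self.file_id}: sampling rate must be > 0")
        if self.start_global < 0:
            raise TimelineValidationError(f"{self.file_id}: negative start")
        if not self.channel_names:
            raise TimelineValidationError(f"{self.file_id}: empty channel list")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise TimelineValidationError(f"{self.file_id}: duplicate channel names")

    @property
    def end_global(self) -> float:
        return self.start_global + self.duration

    @property
    def span(self) -> Tuple[float, float]:
        return (self.start_global, self.end_global)


@dataclass(frozen=True)
class SeizureEvent:
    """An annotated ictal span in global seconds."""

    seizure_id: int
    onset_global: float
    offset_global: float

    def __post_init__(self):
        if self.offset_global <= self.onset_global:
            raise TimelineValidationError(
                f"seizure {self.seizure_id}: offset {self.offset_global} "
                f"<= onset {self.onset_global}"
            )

    @property
    def span(self) -> Tuple[float, float]:
        return (self.onset_global, self.offset_global)


class SignalStore(Protocol):
    """Sample access for one subject's recording files."""

    def read(
        self, file_id: str, channels: Sequence[str], start_sample: int, n_samples: int
    ) -> np.ndarray:  # (len(channels), n_samples)
        ...


@dataclass
class SubjectTimeline:
    """Validated, gap-aware global time axis for one subject.

    ``coverage`` is the union of file spans; every seizure must lie inside
    it.  ``signal_store`` is optional — interval algebra and fold
    construction never touch samples, only :func:`read_signal` does.
    """

    subject_id: str
    files: List[RecordingFile]
    seizures: List[SeizureEvent]
    signal_store: Optional[SignalStore] = None
    clock_base: float = 0.0  # seconds past midnight of first file start

    def __post_init__(self):
        self.files = sorted(self.files, key=lambda f: f.start_global)
        for prev, cur in zip(self.files, self.files[1:]):
            if cur.start_global < prev.end_global:
                raise TimelineValidationError(
                    f"{self.subject_id}: files {prev.file_id!r} and "
                    f"{cur.file_id!r} have overlapping spans"
                )
        self.seizures = sorted(self.seizures, key=lambda s: s.onset_global)
        cov = self.coverage
        for s in self.seizures:
            if not iv.contains(cov, s.onset_global, s.offset_global):
                raise TimelineValidationError(
                    f"{self.subject_id}: seizure {s.seizure_id} "
                    f"[{s.onset_global}, {s.offset_global}) outside coverage"
                )

    @property
    def coverage(self) -> iv.IntervalSet:
        return iv.normalize(f.span for f in self.files)

    @property
    def ictal_spans(self) -> iv.IntervalSet:
        return iv.normalize(s.span for s in self.seizures)


# ---------------------------------------------------------------------------
# summary-dialect parsing

_CLOCK_RE = re.compile(r"^(\d+):([0-5]?\d):([0-5]?\d)$")

# channels that CHB-MIT uses as placeholders in changed-montage blocks
_DUMMY_CHANNELS = {"-", ".", ""}


def _parse_clock(text: str, lineno: int) -> float:
    m = _CLOCK_RE.match(text.strip())
    if not m:
        raise SummaryParseError(f"line {lineno}: bad clock time {text!r}")
    h, mi, s = (int(g) for g in m.groups())
    return h * 3600.0 + mi * 60.0 + s


def _dedupe_channels(names: List[str]) -> Tuple[str, ...]:
    seen, out = set(), []
    for n in names:
        n = n.strip()
        if n in _DUMMY_CHANNELS or n in seen:
            continue
        seen.add(n)
        out.append(n)
    return tuple(out)


def parse_summary(
    summary_text: str,
    subject_id: str = "subject",
    sampling_rate: Optional[float] = None,
    signal_store: Optional[SignalStore] = None,
) -> SubjectTimeline:
    """Parse a CHB-MIT-style summary into a :class:`SubjectTimeline`.

    Global offsets are computed from clock times; 24 h is added whenever a
    file's start clock steps backwards past the previous file's start
    clock (midnight rollover).  A start clock falling strictly inside the
    previous file's clock span is an overlap and raises
    :class:`TimelineValidationError`.
    """
    rate = sampling_rate
    channels: Tuple[str, ...] = ()
    files: List[RecordingFile] = []
    seizures: List[SeizureEvent] = []
    clock_base = 0.0

    pending_channels: List[str] = []
    # per-file parse state
    cur: Dict[str, object] = {}
    prev_start_raw: Optional[float] = None
    prev_end_unwrapped: Optional[float] = None
    first_start: Optional[float] = None
    day_offset = 0.0
    seiz_starts: List[float] = []
    seiz_ends: List[float] = []

    def flush(lineno: int):
        nonlocal prev_start_raw, prev_end_unwrapped, first_start, day_offset
        nonlocal clock_base
        if not cur:
            return
        for key in ("name", "start", "end"):
            if key not in cur:
                raise SummaryParseError(
                    f"line {lineno}: file block {cur.get('name', '?')!r} "
                    f"missing {key}"
                )
        if len(seiz_starts) != len(seiz_ends):
            raise SummaryParseError(
                f"line {lineno}: unpaired seizure start/end in {cur['name']!r}"
            )
        start_raw = float(cur["start"])  # seconds past some midnight
        end_raw = float(cur["end"])
        if prev_start_raw is not None:
            prev_file = files[-1]
            if start_raw < prev_start_raw:
                day_offset += 86400.0
            start_unwrapped = start_raw + day_offset
            if start_unwrapped < prev_end_unwrapped:
                raise TimelineValidationError(
                    f"files {prev_file.file_id!r} and {cur['name']!r} "
                    f"have overlapping clock spans"
                )
        else:
            start_unwrapped = start_raw
            first_start = start_raw
            clock_base = start_raw % 86400.0
        duration = end_raw - start_raw
        if duration < 0:  # file itself crosses midnight
            duration += 86400.0
        if duration <= 0:
            raise SummaryParseError(
                f"line {lineno}: file {cur['name']!r} has non-positive duration"
            )
        start_global = start_unwrapped - first_start
        if rate is None:
            raise SummaryParseError(
                "no 'Data Sampling Rate' header and no sampling_rate argument"
            )
        if not channels:
            raise SummaryParseError(
                f"file {cur['name']!r}: no channel list seen before file block"
            )
        files.append(
            RecordingFile(
                file_id=str(cur["name"]),
                start_global=start_global,
                duration=duration,
                sampling_rate=rate,
                channel_names=channels,
            )
        )
        for s, e in zip(seiz_starts, seiz_ends):
            if e <= s:
                raise TimelineValidationError(
                    f"file {cur['name']!r}: seizure end {e} <= start {s}"
                )
            seizures.append(
                SeizureEvent(
                    seizure_id=len(seizures),
                    onset_global=start_global + s,
                    offset_global=start_global + e,
                )
            )
        prev_start_raw = start_raw
        prev_end_unwrapped = start_unwrapped + duration
        cur.clear()
        seiz_starts.clear()
        seiz_ends.clear()

    for lineno, raw in enumerate(summary_text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        m = re.match(r"Data Sampling Rate:\s*([\d.]+)\s*Hz", line, re.I)
        if m:
            rate = float(m.group(1))
            continue
        m = re.match(r"Channel\s+\d+:\s*(.*)$", line, re.I)
        if m:
            pending_channels.append(m.group(1))
            continue
        m = re.match(r"File Name:\s*(\S+)", line, re.I)
        if m:
            flush(lineno)
            if pending_channels:
                channels = _dedupe_channels(pending_channels)
                if not channels:
                    raise SummaryParseError(
                        f"line {lineno}: channel block contains only dummies"
                    )
                pending_channels = []
            cur["name"] = re.sub(r"\.edf$", "", m.group(1), flags=re.I)
            continue
        m = re.match(r"File Start Time:\s*(\S+)", line, re.I)
        if m:
            cur["start"] = _parse_clock(m.group(1), lineno)
            continue
        m = re.match(r"File End Time:\s*(\S+)", line, re.I)
        if m:
            cur["end"] = _parse_clock(m.group(1), lineno)
            continue
        m = re.match(r"Number of Seizures in File:\s*(\d+)", line, re.I)
        if m:
            cur["n_seizures"] = int(m.group(1))
            continue
        m = re.match(r"Seizure(?:\s+\d+)? Start Time:\s*([\d.]+)\s*sec", line, re.I)
        if m:
            seiz_starts.append(float(m.group(1)))
            continue
        m = re.match(r"Seizure(?:\s+\d+)? End Time:\s*([\d.]+)\s*sec", line, re.I)
        if m:
            seiz_ends.append(float(m.group(1)))
            continue
        if re.match(r"(\*+|Channels in EDF Files:|File Channel|Channels changed)", line, re.I):
            continue
        if cur or pending_channels or files:
            raise SummaryParseError(f"line {lineno}: unrecognised line {line!r}")
    flush(-1)
    if not files:
        raise SummaryParseError("summary contains no file blocks")
    return SubjectTimeline(
        subject_id=subject_id,
        files=files,
        seizures=seizures,
        signal_store=signal_store,
        clock_base=clock_base,
    )


def _fmt_clock(seconds: float) -> str:
    s = int(round(seconds))
    return f"{s // 3600:02d}:{s % 3600 // 60:02d}:{s % 60:02d}"


def write_summary(timeline: SubjectTimeline) -> str:
    """Emit summary text that re-parses to an identical timeline.

    Hours are written unwrapped (25:10:00 for 01:10 next day), matching
    the convention some CHB-MIT subjects use, so multi-day gaps survive
    the round trip.
    """
    lines: List[str] = []
    rate = timeline.files[0].sampling_rate
    lines.append(f"Data Sampling Rate: {rate:g} Hz")
    lines.append("")
    prev_channels: Tuple[str, ...] = ()
    for f in timeline.files:
        if f.channel_names != prev_channels:
            lines.append("Channels in EDF Files:")
            for i, ch in enumerate(f.channel_names, start=1):
                lines.append(f"Channel {i}: {ch}")
            lines.append("")
            prev_channels = f.channel_names
        start = timeline.clock_base + f.start_global
        end = start + f.duration
        in_file = [
            s for s in timeline.seizures
            if f.start_global <= s.onset_global < f.end_global
        ]
        lines.append(f"File Name: {f.file_id}.edf")
        lines.append(f"File Start Time: {_fmt_clock(start)}")
        lines.append(f"File End Time: {_fmt_clock(end)}")
        lines.append(f"Number of Seizures in File: {len(in_file)}")
        for s in in_file:
            lines.append(
                f"Seizure Start Time: {s.onset_global - f.start_global:g} seconds"
            )
            lines.append(
                f"Seizure End Time: {s.offset_global - f.start_global:g} seconds"
            )
        lines.append("")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# signal access

def common_channels(timeline: SubjectTimeline) -> Tuple[str, ...]:
    """Channels present in every file, in first-file order (the montage)."""
    if not timeline.files:
        raise ChannelError(f"{timeline.subject_id}: timeline has no files")
    common = set(timeline.files[0].channel_names)
    for f in timeline.files[1:]:
        common &= set(f.channel_names)
    ordered = tuple(c for c in timeline.files[0].channel_names if c in common)
    if not ordered:
        raise ChannelError(f"{timeline.subject_id}: no channel common to all files")
    return ordered


def read_signal(
    timeline: SubjectTimeline,
    interval: Tuple[float, float],
    channels: Sequence[str],
) -> np.ndarray:
    """Read ``[start, end)`` across file boundaries as a C x L matrix.

    L = round(rate * length).  Concatenation across abutting files is
    sample-exact; an interval touching a coverage gap raises
    :class:`CoverageError`.
    """
    start, end = float(interval[0]), float(interval[1])
    if timeline.signal_store is None:
        raise ValueError(f"{timeline.subject_id}: timeline has no signal store")
    if end < start:
        raise ValueError(f"inverted interval [{start}, {end})")
    if end == start:
        return np.empty((len(channels), 0), dtype=np.float32)
    if not iv.contains(timeline.coverage, start, end):
        raise CoverageError(
            f"{timeline.subject_id}: [{start}, {end}) not fully covered"
        )
    spanned = [f for f in timeline.files if f.start_global < end and f.end_global > start]
    rates = {f.sampling_rate for f in spanned}
    if len(rates) != 1:
        raise ValueError(f"interval spans files with mixed rates {rates}")
    rate = rates.pop()
    for f in spanned:
        missing = [c for c in channels if c not in f.channel_names]
        if missing:
            raise ChannelError(f"{f.file_id}: missing channels {missing}")
    total = int(round(rate * (end - start)))
    pieces: List[np.ndarray] = []
    got = 0
    for f in spanned:
        a = max(start, f.start_global)
        b = min(end, f.end_global)
        i0 = int(round((a - f.start_global) * rate))
        n = int(round((b - a) * rate))
        n = min(n, total - got)
        pieces.append(timeline.signal_store.read(f.file_id, channels, i0, n))
        got += n
    out = np.concatenate(pieces, axis=1) if pieces else np.empty((len(channels), 0))
    if out.shape[1] != total:
        raise CoverageError(
            f"{timeline.subject_id}: expected {total} samples, got {out.shape[1]}"
        )
    return out


class ArraySignalStore:
    """In-memory signal store: file_id -> (channel names, C x L array).

    The portable on-disk form is a directory of ``<file_id>.npy`` arrays
    plus an ``index.tsv`` manifest mapping file_id to its channel list.
    """

    def __init__(self):
        self._files: Dict[str, Tuple[Tuple[str, ...], np.ndarray]] = {}

    def add(self, file_id: str, channel_names: Sequence[str], data: np.ndarray):
        data = np.asarray(data)
        if data.ndim != 2 or data.shape[0] != len(channel_names):
            raise ValueError(f"{file_id}: data must be (n_channels, n_samples)")
        self._files[file_id] = (tuple(channel_names), data)

    def read(self, file_id, channels, start_sample, n_samples):
        if file_id not in self._files:
            raise KeyError(f"no signal for file {file_id!r}")
        names, data = self._files[file_id]
        try:
            rows = [names.index(c) for c in channels]
        except ValueError as e:
            raise ChannelError(f"{file_id}: {e}") from None
        if start_sample < 0 or start_sample + n_samples > data.shape[1]:
            raise CoverageError(
                f"{file_id}: samples [{start_sample}, {start_sample + n_samples}) "
                f"out of range"
            )
        return data[rows, start_sample:start_sample + n_samples].astype(
            np.float32, copy=False
        )

    def save(self, directory):
        import os
        os.makedirs(directory, exist_ok=True)
        with open(os.path.join(directory, "index.tsv"), "w") as fh:
            fh.write("file_id\tchannels\n")
            for fid, (names, data) in self._files.items():
                np.save(os.path.join(directory, f"{fid}.npy"), data)
                fh.write(f"{fid}\t{','.join(names)}\n")

    @classmethod
    def load(cls, directory):
        import os
        store = cls()
        with open(os.path.join(directory, "index.tsv")) as fh:
            next(fh)
            for line in fh:
                fid, chans = line.rstrip("\n").split("\t")
                data = np.load(os.path.join(directory, f"{fid}.npy"))
                store.add(fid, chans.split(","), data)
        return store


class EdfSignalStore:
    """Signal store over a directory of EDF files (requires ``mne``)."""

    def __init__(self, directory):
        self.directory = directory
        self._cache: Dict[str, object] = {}

    def _raw(self, file_id: str):
        if file_id not in self._cache:
            import os
            import mne
            path = os.path.join(self.directory, f"{file_id}.edf")
            self._cache[file_id] = mne.io.read_raw_edf(
                path, preload=False, verbose="error"
            )
        return self._cache[file_id]

    def read(self, file_id, channels, start_sample, n_samples):
        raw = self._raw(file_id)
        picks = [raw.ch_names.index(c) for c in channels]
        data, _ = raw[picks, start_sample:start_sample + n_samples]
        return (data * 1e6).astype(np.float32)  # volts -> microvolts


def write_timeline_manifest(timeline: SubjectTimeline) -> str:
    """Normalized delimited-text manifest (one row per file)."""
    lines = ["file_id\tstart_global\tduration\tsampling_rate"]
    for f in timeline.files:
        lines.append(
            f"{f.file_id}\t{f.start_global:g}\t{f.duration:g}\t{f.sampling_rate:g}"
        )
    return "\n".join(lines) + "\n"


def write_seizure_table(timeline: SubjectTimeline) -> str:
    lines = ["seizure_id\tonset_global\toffset_global"]
    for s in timeline.seizures:
        lines.append(f"{s.seizure_id}\t{s.onset_global:g}\t{s.offset_global:g}")
    return "\n".join(lines) + "\n"
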