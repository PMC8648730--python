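"""Synthetic multi-file EEG recordings with planted seizure annotations.

The generator emulates the regime of a scalp-EEG archive — multi-file
recordings with gaps, clock-stamped files, per-file seizure annotations,
23 channels at 256 Hz by default — so the whole pipeline is testable
without downloading anything.  Background activity is order-2
autoregressive noise per channel (EEG-like short-range correlation,
microvolt scale).  During the nominal preictal span of every planted
seizure, ``[onset - onset_lead, onset - sph)`` with
``onset_lead = sph + sop``, a band-limited oscillation is added at a
configurable amplitude gain, so the generative ground truth coincides
exactly with the SPH/SOP labeling rule; ictal spans get a high-amplitude
burst.  Gain is the separability dial: 0 means preictal and interictal
windows are drawn from the same distribution.

No claim of biophysical realism is made — no seizure morphology, montage
physics, or artifacts.  Rates below 256 Hz (64 or 32 Hz) keep fixtures
small; nothing downstream hard-codes the rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import lfilter

from .annotations_io import (
    ArraySignalStore,
    RecordingFile,
    SeizureEvent,
    SubjectTimeline,
    TimelineValidationError,
    write_summary,
)
from .sampling import SamplingParams
from . import intervals as iv


@dataclass(frozen=True)
class PreictalSignature:
    """Additive band-limited oscillation marking the preictal state."""

    band_center: float = 20.0  # Hz
    bandwidth: float = 5.0  # Hz (jitter range of the per-channel tone)
    gain: float = 3.0  # amplitude in units of the noise scale
    onset_lead: float = 2100.0  # seconds before onset it switches on (sph+sop)
    sph: float = 300.0  # seconds before onset it switches off

    def __post_init__(self):
        if self.onset_lead < 0 or self.sph < 0 or self.onset_lead < self.sph:
            raise ValueError("need onset_lead >= sph >= 0")


@dataclass(frozen=True)
class NoiseModel:
    """AR background: x[t] = a1 x[t-1] + a2 x[t-2] + scale * e[t].

    ``drift_scale``/``drift_tau`` add a slow per-channel baseline
    (std in microvolts): a stationary AR(1) with correlation time
    ``drift_tau`` seconds, or a constant per-file level when
    ``drift_tau`` is None. This baseline is the within-recording
    "identical feature" (electrode and session state) that windows from
    one recording share: shuffled train/test splits can exploit it
    because same-recording windows land on both sides, while honest
    leave-one-out folds cannot — held-out recordings carry their own
    baseline.
    """

    ar: Tuple[float, ...] = (0.5, -0.1)
    scale: float = 20.0  # innovation std, microvolts
    drift_scale: float = 20.0  # slow-baseline std, microvolts
    drift_tau: Optional[float] = 15.0  # correlation time (s); None = per-file constant


@dataclass(frozen=True)
class SynthParams:
    n_channels: int = 23
    rate: float = 256.0
    file_plan: Tuple[Tuple[float, float], ...] = ()  # (duration, gap_after)
    seizure_plan: Tuple[Tuple[float, float], ...] = ()  # (onset_global, duration)
    signature: PreictalSignature = field(default_factory=PreictalSignature)
    noise: NoiseModel = field(default_factory=NoiseModel)
    ictal_gain: float = 6.0
    seed: int = 0
    subject_id: str = "synth"

    def __post_init__(self):
        if self.rate <= 0 or self.n_channels < 1:
            raise ValueError("rate and n_channels must be positive")


def _file_spans(params: SynthParams) -> List[Tuple[float, float]]:
    spans, t = [], 0.0
    for duration, gap_after in params.file_plan:
        spans.append((t, t + duration))
        t += duration + gap_after
    return spans


def generate_subject(params: SynthParams) -> Tuple[SubjectTimeline, str]:
    """Materialize a subject: timeline + in-memory signals + summary text.

    Deterministic: identical params and seed give bit-identical signals
    and summary text.  The returned summary round-trips through the
    annotation parser to the same timeline.
    """
    spans = _file_spans(params)
    if not spans:
        raise ValueError("empty file plan")
    coverage = iv.normalize(spans)
    for onset, duration in params.seizure_plan:
        if not iv.contains(coverage, onset, onset + duration):
            raise TimelineValidationError(
                f"planted seizure at {onset} (+{duration}s) outside coverage"
            )
    channels = tuple(f"EEG{i + 1:02d}" for i in range(params.n_channels))
    store = ArraySignalStore()
    files, seizures = [], []
    sig = params.signature
    # per-channel tone frequency and phase, fixed for the whole subject
    rng_sig = np.random.default_rng(np.random.SeedSequence([params.seed, 7919]))
    freqs = params.signature.band_center + rng_sig.uniform(
        -sig.bandwidth / 2, sig.bandwidth / 2, size=params.n_channels
    )
    phases = rng_sig.uniform(0, 2 * np.pi, size=params.n_channels)
    for fidx, (start, end) in enumerate(spans):
        file_id = f"{params.subject_id}_{fidx + 1:02d}"
        n = int(round((end - start) * params.rate))
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, fidx]))
        e = rng.standard_normal((params.n_channels, n)) * params.noise.scale
        a = np.concatenate([[1.0], -np.asarray(params.noise.ar)])
        data = lfilter([1.0], a, e, axis=1)
        if params.noise.drift_scale > 0:
            if params.noise.drift_tau is None:
                data += params.noise.drift_scale * rng.standard_normal(
                    (params.n_channels, 1)
                )
            else:
                # stationary AR(1); burn-in removes the start transient
                rho = float(np.exp(-1.0 / (params.noise.drift_tau * params.rate)))
                burn = int(5 * params.noise.drift_tau * params.rate)
                w = rng.standard_normal((params.n_channels, n + burn))
                w *= params.noise.drift_scale * np.sqrt(1.0 - rho ** 2)
                data += lfilter([1.0], [1.0, -rho], w, axis=1)[:, burn:]
        t = start + np.arange(n) / params.rate
        for onset, dur in params.seizure_plan:
            pre_mask = (t >= onset - sig.onset_lead) & (t < onset - sig.sph)
            if sig.gain > 0 and pre_mask.any():
                tone = np.sin(
                    2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]
                )
                data += (sig.gain * params.noise.scale) * tone * pre_mask[None, :]
            ict_mask = (t >= onset) & (t < onset + dur)
            if ict_mask.any():
                burst = np.sin(2 * np.pi * 3.0 * t[None, :] + phases[:, None])
                data += (params.ictal_gain * params.noise.scale) * burst * ict_mask[None, :]
        store.add(file_id, channels, data.astype(np.float32))
        files.append(
            RecordingFile(
                file_id=file_id,
                start_global=start,
                duration=end - start,
                sampling_rate=params.rate,
                channel_names=channels,
            )
        )
    for i, (onset, dur) in enumerate(sorted(params.seizure_plan)):
        seizures.append(SeizureEvent(i, onset, onset + dur))
    timeline = SubjectTimeline(
        subject_id=params.subject_id,
        files=files,
        seizures=seizures,
        signal_store=store,
    )
    return timeline, write_summary(timeline)


# ---------------------------------------------------------------------------
# canned fixtures

def _benchmark_plan(preictal_margin: float = 2400.0):
    """File/seizure layout with 3 well-separated leading seizures.

    Seizure onsets at 20000/40000/60000 s (gaps > 4 h of quiet), each
    preceded by a file covering its whole 30-min preictal span, plus
    three 1-h interictal files clear of the 2-h guard.
    """
    onsets = (20000.0, 40000.0, 60000.0)
    spans = [(0.0, 3600.0)]
    for o in onsets:
        spans.append((o - preictal_margin, o + 120.0))
    spans.extend([(28000.0, 31600.0), (48000.0, 51600.0)])
    spans.sort()
    file_plan = []
    for (a, b), nxt in zip(spans, spans[1:] + [None]):
        gap = (nxt[0] - b) if nxt else 0.0
        file_plan.append((b - a, gap))
    seizure_plan = tuple((o, 60.0) for o in onsets)
    return tuple(file_plan), seizure_plan


def make_fixture_suite(
    seed: int, rate: float = 64.0, n_channels: int = 4
) -> Dict[str, Tuple[SubjectTimeline, str]]:
    """Small canned subjects exercising the sampling edge cases.

    Keys: ``eligible`` (3 leading seizures, full preictal coverage),
    ``ineligible`` (2 leading seizures), ``gapped`` (a recording gap
    inside one preictal interval), ``clustered`` (a follow-up seizure
    within the seizure-free time T that must not yield positives).
    All use the benchmark sampling geometry (SPH 5 min / SOP 30 min /
    T 4 h / guard 2 h) at a reduced rate and channel count.
    """
    out: Dict[str, Tuple[SubjectTimeline, str]] = {}
    base = dict(n_channels=n_channels, rate=rate)

    file_plan, seizure_plan = _benchmark_plan()
    out["eligible"] = generate_subject(
        SynthParams(file_plan=file_plan, seizure_plan=seizure_plan,
                    seed=seed, subject_id="synth_a", **base)
    )

    spans = [(0.0, 3600.0), (17600.0, 20120.0), (37600.0, 40120.0)]
    fp = tuple(
        (b - a, (spans[i + 1][0] - b) if i + 1 < len(spans) else 0.0)
        for i, (a, b) in enumerate(spans)
    )
    out["ineligible"] = generate_subject(
        SynthParams(file_plan=fp, seizure_plan=((20000.0, 60.0), (40000.0, 60.0)),
                    seed=seed + 1, subject_id="synth_b", **base)
    )

    # gap eats [onset-2100, onset-1500) of the second seizure's preictal span
    file_plan_g, seizure_plan_g = _benchmark_plan()
    spans = [(0.0, 3600.0), (17600.0, 20120.0), (38500.0, 40120.0),
             (28000.0, 31600.0), (48000.0, 51600.0), (57600.0, 60120.0)]
    spans.sort()
    fp = tuple(
        (b - a, (spans[i + 1][0] - b) if i + 1 < len(spans) else 0.0)
        for i, (a, b) in enumerate(spans)
    )
    out["gapped"] = generate_subject(
        SynthParams(file_plan=fp, seizure_plan=seizure_plan_g,
                    seed=seed + 2, subject_id="synth_c", **base)
    )

    # follow-up seizure 2000 s after the first: inside T, excluded
    spans = [(0.0, 3600.0), (17600.0, 22120.0), (28000.0, 31600.0),
             (37600.0, 40120.0), (48000.0, 51600.0), (57600.0, 60120.0)]
    fp = tuple(
        (b - a, (spans[i + 1][0] - b) if i + 1 < len(spans) else 0.0)
        for i, (a, b) in enumerate(spans)
    )
    out["clustered"] = generate_subject(
        SynthParams(
            file_plan=fp,
            seizure_plan=((20000.0, 60.0), (22000.0, 60.0),
                          (40000.0, 60.0), (60000.0, 60.0)),
            seed=seed + 3, subject_id="synth_d", **base)
    )
    return out


# ---------------------------------------------------------------------------
# compact separability subject for end-to-end training experiments

def separability_sampling_params() -> SamplingParams:
    """Scaled-down sampling geometry for training experiments.

    SPH 20 s / SOP 100 s / T 600 s / guard 300 s with 5-s windows keeps a
    full leave-one-out run to a few hundred window samples so repeated
    seeded replicates stay cheap; the labeling rules are identical to the
    benchmark geometry.
    """
    return SamplingParams(sph=20.0, sop=100.0, t_free=600.0,
                          interictal_guard=300.0, window_len=5.0)


def make_separability_subject(
    seed: int, gain: float, rate: float = 32.0, n_channels: int = 3
) -> Tuple[SubjectTimeline, SamplingParams]:
    """Three leading seizures under the scaled-down geometry.

    Yields 20 preictal windows per seizure and three 32-window interictal
    segments.  ``gain`` is the preictal signature amplitude (in noise-scale
    units): 0 gives chance-level separability by construction.
    """
    sp = separability_sampling_params()
    onsets = (2000.0, 4000.0, 6000.0)
    spans = [(0.0, 160.0), (3000.0, 3160.0), (5000.0, 5160.0)]
    spans += [(o - 140.0, o + 30.0) for o in onsets]
    spans.sort()
    fp = tuple(
        (b - a, (spans[i + 1][0] - b) if i + 1 < len(spans) else 0.0)
        for i, (a, b) in enumerate(spans)
    )
    sig = PreictalSignature(
        band_center=8.0, bandwidth=2.0, gain=gain,
        onset_lead=sp.sph + sp.sop, sph=sp.sph,
    )
    params = SynthParams(
        n_channels=n_channels,
        rate=rate,
        file_plan=fp,
        seizure_plan=tuple((o, 20.0) for o in onsets),
        signature=sig,
        seed=seed,
        subject_id=f"sep_g{gain:g}",
    )
    timeline, _ = generate_subject(params)
    return timeline, sp
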