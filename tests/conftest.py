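"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's interval algebra: the
per-second labeler walks every integer second through a brute-force
state machine, and the leading-seizure scan checks raw event overlap, so
they can arbitrate the fast implementations.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np
import pytest

from szbench.annotations_io import RecordingFile, SeizureEvent, SubjectTimeline
from szbench.sampling import SamplingParams
from szbench.synthgen import make_fixture_suite


def toy_timeline(
    cov_spans: Sequence[Tuple[float, float]],
    seizures: Sequence[Tuple[float, float]],
    rate: float = 64.0,
    n_channels: int = 2,
    subject_id: str = "toy",
) -> SubjectTimeline:
    """Timeline without signal: one file per coverage span."""
    channels = tuple(f"EEG{i + 1:02d}" for i in range(n_channels))
    files = [
        RecordingFile(
            file_id=f"{subject_id}_{i + 1:02d}",
            start_global=a,
            duration=b - a,
            sampling_rate=rate,
            channel_names=channels,
        )
        for i, (a, b) in enumerate(cov_spans)
    ]
    events = [SeizureEvent(i, on, off) for i, (on, off) in enumerate(seizures)]
    return SubjectTimeline(subject_id=subject_id, files=files, seizures=events)


def brute_force_leading(
    events: Sequence[Tuple[float, float]], t_free: float
) -> List[int]:
    """Event i is leading iff no event intersects (onset_i - t_free, onset_i)."""
    out = []
    for i, (on_i, off_i) in enumerate(events):
        lo, hi = on_i - t_free, on_i
        clear = all(
            off_j <= lo or on_j >= hi
            for j, (on_j, off_j) in enumerate(events)
            if j != i
        )
        if i == 0 or clear:
            out.append(i)
    return out


def per_second_state(
    t: float,
    cov_spans: Sequence[Tuple[float, float]],
    seizures: Sequence[Tuple[float, float]],
    params: SamplingParams,
) -> str:
    """Brute-force state at time t: ictal/preictal/interictal/excluded."""
    covered = any(a <= t < b for a, b in cov_spans)
    if not covered:
        return "excluded"
    if any(on <= t < off for on, off in seizures):
        return "ictal"
    leading = brute_force_leading(seizures, params.t_free)
    for i in leading:
        on = seizures[i][0]
        if on - params.sph - params.sop <= t < on - params.sph:
            return "preictal"
    near = any(
        on - params.interictal_guard <= t < off + params.interictal_guard
        for on, off in seizures
    )
    if not near:
        return "interictal"
    return "excluded"


def random_toy_layout(rng: np.random.Generator):
    """Random gappy coverage + seizures for oracle-equivalence checks.

    Integer endpoints so the per-second oracle is exact at every second.
    """
    n_files = rng.integers(1, 5)
    t = 0
    cov = []
    for _ in range(n_files):
        t += int(rng.integers(0, 200))
        dur = int(rng.integers(50, 800))
        cov.append((float(t), float(t + dur)))
        t += dur
    seizures = []
    for _ in range(int(rng.integers(0, 4))):
        a, b = cov[rng.integers(len(cov))]
        if b - a < 12:
            continue
        on = int(rng.integers(int(a), int(b) - 10))
        off = on + int(rng.integers(5, min(40, int(b) - on)))
        if any(not (off <= o or on >= f) for o, f in seizures):
            continue
        seizures.append((float(on), float(off)))
    seizures.sort()
    sph = float(rng.integers(0, 40))
    sop = float(rng.integers(20, 300))
    # the guard must dominate sph+sop (as 2 h dominates 35 min in the
    # benchmark geometry) or the preictal and interictal states overlap
    params = SamplingParams(
        sph=sph,
        sop=sop,
        t_free=float(rng.integers(50, 500)),
        interictal_guard=sph + sop + float(rng.integers(0, 200)),
        window_len=5.0,
    )
    return cov, seizures, params


@pytest.fixture(scope="session")
def fixture_suite():
    return make_fixture_suite(seed=0, rate=64.0, n_channels=4)
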