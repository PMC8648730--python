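"""Leakage-free evaluation of the single-channel classifier.

Training and inference are channel-wise: every C x L window is split into
C single-channel vectors that inherit the window's label.  At inference
each vector is classified independently and the window's decision is a
vote — positive when the number of positive channels strictly exceeds a
threshold (N/2 by default).

Evaluation is leave-one-out over leading seizures: each fold holds out
one seizure's preictal windows plus one chronologically contiguous block
of interictal segments, and trains on the rest.  Windows from one
segment never appear on both sides of a fold — the audit asserting this
runs on every fold.  For contrast (the optimistic-bias failure mode of
shuffled splits on time-series data), the module can also emulate
shuffled K-fold and 8:1:1 partitions of the same window pool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.utils.validation import check_is_fitted

from .annotations_io import ChannelError, SubjectTimeline
from .network import CnnBiLstmClassifier, NetworkConfig
from .sampling import (
    LabeledSegment,
    SampleSet,
    SamplingParams,
    WindowSample,
    build_sample_set,
)


class EligibilityError(ValueError):
    """Subject has too few leading seizures for leave-one-out CV."""


class LeakageError(AssertionError):
    """Train/test provenance overlap detected by the audit."""


@dataclass(frozen=True)
class VectorSample:
    """One channel's slice of a window, carrying full provenance."""

    data: np.ndarray  # (L,)
    label: int
    segment_id: int
    channel: str
    t_start: float
    source_seizure: Optional[int] = None


def split_into_vectors(sample: WindowSample) -> List[VectorSample]:
    """C x L window -> C labeled 1 x L vectors (row order preserved)."""
    return [
        VectorSample(
            data=sample.data[c],
            label=sample.label,
            segment_id=sample.segment_id,
            channel=sample.channels[c],
            t_start=sample.t_start,
            source_seizure=sample.source_seizure,
        )
        for c in range(len(sample.channels))
    ]


def vote(channel_labels: Sequence[int], threshold: float) -> int:
    """1 iff the count of positive channels strictly exceeds ``threshold``."""
    if len(channel_labels) == 0:
        raise ValueError("vote needs at least one channel label")
    if not (0 <= threshold <= len(channel_labels)):
        raise ValueError(f"threshold {threshold} outside [0, {len(channel_labels)}]")
    return int(sum(1 for v in channel_labels if v == 1) > threshold)


@dataclass(frozen=True)
class Metrics:
    """Window-level confusion counts and derived rates.

    A rate whose denominator is zero is reported as ``None`` (absent),
    never as 0.
    """

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def accuracy(self) -> Optional[float]:
        n = self.tp + self.tn + self.fp + self.fn
        return (self.tp + self.tn) / n if n else None

    @property
    def sensitivity(self) -> Optional[float]:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def specificity(self) -> Optional[float]:
        d = self.tn + self.fp
        return self.tn / d if d else None

    @staticmethod
    def from_predictions(y_true: Sequence[int], y_pred: Sequence[int]) -> "Metrics":
        yt, yp = np.asarray(y_true), np.asarray(y_pred)
        return Metrics(
            tp=int(((yt == 1) & (yp == 1)).sum()),
            tn=int(((yt == 0) & (yp == 0)).sum()),
            fp=int(((yt == 0) & (yp == 1)).sum()),
            fn=int(((yt == 1) & (yp == 0)).sum()),
        )


@dataclass(frozen=True)
class Fold:
    fold_id: int
    test_seizure: int
    train_seizures: Tuple[int, ...]
    test_interictal_blocks: Tuple[int, ...]  # segment ids
    train_interictal_blocks: Tuple[int, ...]

    def __post_init__(self):
        if self.test_seizure in self.train_seizures:
            raise LeakageError(f"fold {self.fold_id}: test seizure in training set")
        if set(self.test_interictal_blocks) & set(self.train_interictal_blocks):
            raise LeakageError(f"fold {self.fold_id}: interictal blocks overlap")


def _contiguous_blocks(durations: Sequence[float], n_blocks: int) -> List[List[int]]:
    """Partition indices 0..m-1 into n contiguous groups of ~equal duration."""
    m = len(durations)
    blocks: List[List[int]] = [[] for _ in range(n_blocks)]
    if m == 0:
        return blocks
    total = float(sum(durations))
    cum = 0.0
    b = 0
    for i, d in enumerate(durations):
        remaining_items = m - i
        remaining_blocks = n_blocks - b
        # never leave a later block without items if we can help it
        must_advance = remaining_items == remaining_blocks and blocks[b]
        target = total * (b + 1) / n_blocks
        if blocks[b] and b < n_blocks - 1 and (must_advance or cum + d / 2 > target):
            b += 1
        blocks[b].append(i)
        cum += d
    return blocks


def make_loocv_folds(
    leading_seizures: Sequence[int],
    interictal_segments: Sequence[LabeledSegment],
    seed: int = 0,
    subject_id: str = "subject",
) -> List[Fold]:
    """One fold per leading seizure (chronological order).

    Interictal segments are partitioned chronologically into as many
    contiguous blocks as folds, balanced by duration; block k is held
    out together with seizure k so interictal test time is also unseen
    during training.  Requires at least three leading seizures.
    """
    seizure_ids = list(leading_seizures)
    if len(seizure_ids) < 3:
        raise EligibilityError(
            f"{subject_id}: {len(seizure_ids)} leading seizure(s); "
            f"leave-one-out cross-validation requires at least three"
        )
    segs = sorted(
        (s for s in interictal_segments if s.label == 0),
        key=lambda s: s.interval[0],
    )
    blocks = _contiguous_blocks([s.duration for s in segs], len(seizure_ids))
    folds = []
    for k, sz in enumerate(seizure_ids):
        test_block = tuple(segs[i].segment_id for i in blocks[k])
        train_block = tuple(
            segs[i].segment_id
            for j, blk in enumerate(blocks) if j != k for i in blk
        )
        folds.append(
            Fold(
                fold_id=k,
                test_seizure=sz,
                train_seizures=tuple(s for s in seizure_ids if s != sz),
                test_interictal_blocks=test_block,
                train_interictal_blocks=train_block,
            )
        )
    return folds


@dataclass(frozen=True)
class TrainParams:
    """Training schedule for one fold (the seed drives everything)."""

    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 1e-3
    balance: bool = True
    seed: int = 0

    def fold_seed(self, fold_id: int) -> int:
        """Documented fan-out: independent per-fold streams from one seed."""
        return int(np.random.SeedSequence([self.seed, fold_id]).generate_state(1)[0]
                   % (2 ** 31))


class ChannelVoteClassifier(BaseEstimator, ClassifierMixin):
    """Window classifier: per-channel base model + strict-majority vote.

    ``X`` is (n_windows, n_channels, window_len).  ``fit`` trains one
    shared single-channel base estimator on all channel vectors;
    ``predict`` classifies each channel independently and returns 1 when
    the positive-channel count strictly exceeds ``threshold`` (default
    n_channels / 2).
    """

    def __init__(
        self,
        base: Optional[CnnBiLstmClassifier] = None,
        threshold: Optional[float] = None,
    ):
        self.base = base
        self.threshold = threshold

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 3:
            raise ValueError("X must be (n_windows, n_channels, window_len)")
        n, c, L = X.shape
        base = clone(self.base) if self.base is not None else CnnBiLstmClassifier()
        vec_X = X.reshape(n * c, L)
        vec_y = np.repeat(y, c)
        self.base_ = base.fit(vec_X, vec_y)
        self.n_channels_ = c
        self.classes_ = self.base_.classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "base_")
        X = np.asarray(X, dtype=float)
        n, c, L = X.shape
        if c != self.n_channels_:
            raise ChannelError(
                f"model trained on {self.n_channels_} channels, got {c}"
            )
        thr = self.threshold if self.threshold is not None else c / 2
        channel_pred = self.base_.predict(X.reshape(n * c, L)).reshape(n, c)
        return np.array([vote(row, thr) for row in channel_pred])

    def positive_fraction(self, X):
        """Per-window fraction of positive channels (soft score)."""
        check_is_fitted(self, "base_")
        X = np.asarray(X, dtype=float)
        n, c, L = X.shape
        pred = self.base_.predict(X.reshape(n * c, L)).reshape(n, c)
        return pred.mean(axis=1)


def train_model(
    train_vectors: Sequence[VectorSample],
    config: Optional[NetworkConfig],
    train_params: TrainParams,
) -> CnnBiLstmClassifier:
    """Fit the single-channel classifier on labeled vector samples."""
    X = np.stack([v.data for v in train_vectors]).astype(float)
    y = np.array([v.label for v in train_vectors])
    clf = CnnBiLstmClassifier(
        config=config,
        epochs=train_params.epochs,
        batch_size=train_params.batch_size,
        learning_rate=train_params.learning_rate,
        balance=train_params.balance,
        random_state=train_params.seed,
    )
    return clf.fit(X, y)


def evaluate_fold(
    model: ChannelVoteClassifier,
    test_windows: Sequence[WindowSample],
) -> Metrics:
    """Window-level metrics of voted decisions on held-out windows.

    The vote threshold lives on the model (set at construction); test
    windows must share one montage matching the training montage.
    """
    if not test_windows:
        return Metrics(0, 0, 0, 0)
    montages = {w.channels for w in test_windows}
    if len(montages) != 1:
        raise ChannelError("test windows carry mixed channel montages")
    X = np.stack([w.data for w in test_windows]).astype(float)
    y_true = np.array([w.label for w in test_windows])
    y_pred = model.predict(X)
    return Metrics.from_predictions(y_true, y_pred)


@dataclass
class EvalReport:
    """Per-fold and averaged metrics plus the leakage-audit outcome."""

    folds: List[Fold]
    fold_metrics: List[Metrics]
    audit_passed: bool

    def _mean(self, attr: str) -> Optional[float]:
        vals = [getattr(m, attr) for m in self.fold_metrics]
        vals = [v for v in vals if v is not None]
        return float(np.mean(vals)) if vals else None

    @property
    def accuracy(self) -> Optional[float]:
        return self._mean("accuracy")

    @property
    def sensitivity(self) -> Optional[float]:
        return self._mean("sensitivity")

    @property
    def specificity(self) -> Optional[float]:
        return self._mean("specificity")

    def to_text(self) -> str:
        def fmt(v):
            return "-" if v is None else f"{v:.3f}"

        lines = ["fold\ttest_seizure\tACC\tTPR\tTNR"]
        for f, m in zip(self.folds, self.fold_metrics):
            lines.append(
                f"{f.fold_id}\t{f.test_seizure}\t{fmt(m.accuracy)}"
                f"\t{fmt(m.sensitivity)}\t{fmt(m.specificity)}"
            )
        lines.append(
            f"average\t-\t{fmt(self.accuracy)}\t{fmt(self.sensitivity)}"
            f"\t{fmt(self.specificity)}"
        )
        return "\n".join(lines) + "\n"


def audit_fold(fold: Fold, train: Sequence[WindowSample],
               test: Sequence[WindowSample]) -> None:
    """Assert empty train/test provenance intersection; raise on leakage."""
    train_segs = {w.segment_id for w in train}
    test_segs = {w.segment_id for w in test}
    if train_segs & test_segs:
        raise LeakageError(
            f"fold {fold.fold_id}: segments {sorted(train_segs & test_segs)} "
            f"in both train and test"
        )
    train_sz = {w.source_seizure for w in train if w.source_seizure is not None}
    test_sz = {w.source_seizure for w in test if w.source_seizure is not None}
    if train_sz & test_sz:
        raise LeakageError(
            f"fold {fold.fold_id}: seizures {sorted(train_sz & test_sz)} "
            f"in both train and test"
        )


def _fold_windows(
    sample_set: SampleSet, fold: Fold
) -> Tuple[List[WindowSample], List[WindowSample]]:
    train, test = [], []
    test_blocks = set(fold.test_interictal_blocks)
    train_blocks = set(fold.train_interictal_blocks)
    for w in sample_set.windows:
        if w.label == 1:
            if w.source_seizure == fold.test_seizure:
                test.append(w)
            elif w.source_seizure in fold.train_seizures:
                train.append(w)
        else:
            if w.segment_id in test_blocks:
                test.append(w)
            elif w.segment_id in train_blocks:
                train.append(w)
    return train, test


def run_loocv(
    timeline: SubjectTimeline,
    sampling_params: Optional[SamplingParams] = None,
    net_config: Optional[NetworkConfig] = None,
    train_params: Optional[TrainParams] = None,
    threshold: Optional[float] = None,
    sample_set: Optional[SampleSet] = None,
) -> EvalReport:
    """Full leave-one-out evaluation of one subject.

    Every fold trains a fresh channel-vote classifier on the other
    seizures' preictal windows plus the training interictal blocks, and
    scores the held-out seizure and interictal block at window level.
    The leakage audit runs on every fold and any overlap raises.
    """
    sampling_params = sampling_params or SamplingParams()
    train_params = train_params or TrainParams()
    if sample_set is None:
        sample_set = build_sample_set(timeline, sampling_params)
    folds = make_loocv_folds(
        [s.seizure_id for s in sample_set.leading_seizures],
        sample_set.segments,
        seed=train_params.seed,
        subject_id=timeline.subject_id,
    )
    fold_metrics = []
    for fold in folds:
        train, test = _fold_windows(sample_set, fold)
        audit_fold(fold, train, test)
        model = ChannelVoteClassifier(
            base=CnnBiLstmClassifier(
                config=net_config,
                epochs=train_params.epochs,
                batch_size=train_params.batch_size,
                learning_rate=train_params.learning_rate,
                balance=train_params.balance,
                random_state=train_params.fold_seed(fold.fold_id),
            ),
            threshold=threshold,
        )
        X_train = np.stack([w.data for w in train]).astype(float)
        y_train = np.array([w.label for w in train])
        model.fit(X_train, y_train)
        fold_metrics.append(evaluate_fold(model, test))
    return EvalReport(folds=folds, fold_metrics=fold_metrics, audit_passed=True)


# ---------------------------------------------------------------------------
# contrast partitions (the splits the benchmark protocol rejects)

def shuffled_kfold_accuracy(
    sample_set: SampleSet,
    k: int,
    net_config: Optional[NetworkConfig] = None,
    train_params: Optional[TrainParams] = None,
    threshold: Optional[float] = None,
) -> float:
    """Mean window accuracy under a shuffled K-fold split of all windows.

    Deliberately ignores segment/seizure provenance, so windows from one
    preictal segment can sit on both sides of a fold — the optimistic
    partition this benchmark exists to rule out.  Returned for contrast
    with :func:`run_loocv`, never as an endorsed protocol.
    """
    train_params = train_params or TrainParams()
    rng = np.random.default_rng(train_params.seed)
    windows = list(sample_set.windows)
    order = rng.permutation(len(windows))
    fold_assign = np.array_split(order, k)
    accs = []
    for fid, test_idx in enumerate(fold_assign):
        test_set = set(int(i) for i in test_idx)
        train_w = [w for i, w in enumerate(windows) if i not in test_set]
        test_w = [windows[i] for i in sorted(test_set)]
        if not test_w or len({w.label for w in train_w}) < 2:
            continue
        model = ChannelVoteClassifier(
            base=CnnBiLstmClassifier(
                config=net_config,
                epochs=train_params.epochs,
                batch_size=train_params.batch_size,
                learning_rate=train_params.learning_rate,
                balance=train_params.balance,
                random_state=train_params.fold_seed(fid),
            ),
            threshold=threshold,
        )
        model.fit(
            np.stack([w.data for w in train_w]).astype(float),
            np.array([w.label for w in train_w]),
        )
        m = evaluate_fold(model, test_w)
        if m.accuracy is not None:
            accs.append(m.accuracy)
    return float(np.mean(accs))


def holdout_811_accuracy(
    sample_set: SampleSet,
    net_config: Optional[NetworkConfig] = None,
    train_params: Optional[TrainParams] = None,
    threshold: Optional[float] = None,
) -> float:
    """Window accuracy under a shuffled 8:1:1 split (validation unused)."""
    train_params = train_params or TrainParams()
    rng = np.random.default_rng(train_params.seed)
    windows = list(sample_set.windows)
    order = rng.permutation(len(windows))
    n = len(windows)
    test_idx = set(int(i) for i in order[: max(n // 10, 1)])
    val_idx = set(int(i) for i in order[max(n // 10, 1): 2 * max(n // 10, 1)])
    train_w = [w for i, w in enumerate(windows) if i not in test_idx | val_idx]
    test_w = [windows[i] for i in sorted(test_idx)]
    model = ChannelVoteClassifier(
        base=CnnBiLstmClassifier(
            config=net_config,
            epochs=train_params.epochs,
            batch_size=train_params.batch_size,
            learning_rate=train_params.learning_rate,
            balance=train_params.balance,
            random_state=train_params.fold_seed(0),
        ),
        threshold=threshold,
    )
    model.fit(
        np.stack([w.data for w in train_w]).astype(float),
        np.array([w.label for w in train_w]),
    )
    m = evaluate_fold(model, test_w)
    return m.accuracy if m.accuracy is not None else float("nan")
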