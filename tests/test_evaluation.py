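"""Channel voting, fold construction, metrics, and leakage auditing."""

import itertools

import numpy as np
import pytest
from sklearn.base import clone
from sklearn.metrics import confusion_matrix

from szbench.annotations_io import ChannelError
from szbench.evaluation import (
    ChannelVoteClassifier,
    EligibilityError,
    Fold,
    LeakageError,
    Metrics,
    TrainParams,
    VectorSample,
    audit_fold,
    evaluate_fold,
    make_loocv_folds,
    split_into_vectors,
    train_model,
    vote,
)
from szbench.network import CnnBiLstmClassifier, NetworkConfig
from szbench.sampling import LabeledSegment, WindowSample


def make_window(label=1, segment_id=0, n_channels=3, L=8, seizure=None, seed=0):
    rng = np.random.default_rng(seed)
    return WindowSample(
        data=rng.standard_normal((n_channels, L)),
        label=label,
        segment_id=segment_id,
        t_start=0.0,
        t_end=float(L),
        channels=tuple(f"EEG{i + 1:02d}" for i in range(n_channels)),
        source_seizure=seizure,
    )


class TestSplitIntoVectors:
    def test_channel_count_and_inheritance(self):
        w = make_window(label=1, segment_id=4, n_channels=23, L=16, seizure=2)
        vectors = split_into_vectors(w)
        assert len(vectors) == 23
        assert all(v.label == 1 and v.segment_id == 4 and v.source_seizure == 2
                   for v in vectors)
        assert [v.channel for v in vectors] == list(w.channels)

    def test_single_channel_window(self):
        w = make_window(n_channels=1)
        (v,) = split_into_vectors(w)
        assert np.array_equal(v.data, w.data[0])

    def test_rows_reconstruct_the_matrix(self):
        w = make_window(n_channels=5, L=12)
        back = np.vstack([v.data for v in split_into_vectors(w)])
        assert np.array_equal(back, w.data)


class TestVote:
    def test_strict_exceedance_at_half_of_23(self):
        assert vote([1] * 12 + [0] * 11, threshold=11.5) == 1
        assert vote([1] * 11 + [0] * 12, threshold=11.5) == 0

    def test_exhaustive_patterns_equal_majority_for_n5(self):
        for bits in itertools.product([0, 1], repeat=5):
            got = vote(list(bits), threshold=2.5)
            assert got == int(sum(bits) >= 3)

    @pytest.mark.parametrize("n", [1, 3, 5, 7])
    def test_half_threshold_is_majority_for_odd_n(self, n):
        for bits in itertools.product([0, 1], repeat=n):
            assert vote(list(bits), n / 2) == int(sum(bits) > n / 2)

    def test_empty_and_out_of_range(self):
        with pytest.raises(ValueError):
            vote([], 0.5)
        with pytest.raises(ValueError):
            vote([1, 0], 3.0)


class TestMetrics:
    def test_confusion_arithmetic(self):
        m = Metrics(tp=4, tn=3, fp=1, fn=2)
        assert m.accuracy == pytest.approx(0.7)
        assert m.sensitivity == pytest.approx(4 / 6)
        assert m.specificity == pytest.approx(0.75)

    def test_undefined_ratio_is_absent_not_zero(self):
        m = Metrics.from_predictions([1, 1, 1], [1, 1, 1])
        assert m.sensitivity == 1.0
        assert m.specificity is None

    def test_matches_sklearn_confusion_tally(self):
        rng = np.random.default_rng(0)
        yt = rng.integers(0, 2, 100)
        yp = rng.integers(0, 2, 100)
        m = Metrics.from_predictions(yt, yp)
        tn, fp, fn, tp = confusion_matrix(yt, yp).ravel()
        assert (m.tp, m.tn, m.fp, m.fn) == (tp, tn, fp, fn)


def seg(sid, a, b):
    return LabeledSegment(sid, (float(a), float(b)), 0, None)


class TestLoocvFolds:
    def test_five_seizures_make_five_folds(self):
        segs = [seg(i, 100 * i, 100 * i + 50) for i in range(5)]
        folds = make_loocv_folds([10, 11, 12, 13, 14], segs)
        assert len(folds) == 5
        for f in folds:
            assert len(f.train_seizures) == 4
            assert f.test_seizure not in f.train_seizures

    def test_two_seizures_are_ineligible(self):
        with pytest.raises(EligibilityError, match="at least three"):
            make_loocv_folds([0, 1], [], subject_id="chb99")

    def test_blocks_chronologically_contiguous_and_disjoint(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            n_seg = int(rng.integers(3, 12))
            t, segs = 0.0, []
            for i in range(n_seg):
                t += float(rng.integers(1, 50))
                d = float(rng.integers(10, 500))
                segs.append(seg(i, t, t + d))
                t += d
            n_folds = int(rng.integers(3, 6))
            folds = make_loocv_folds(list(range(n_folds)), segs)
            all_test = []
            for f in folds:
                assert not set(f.test_interictal_blocks) & set(f.train_interictal_blocks)
                all_test.extend(f.test_interictal_blocks)
                # contiguity: held-out ids form a run in chronological order
                ids = sorted(f.test_interictal_blocks)
                assert ids == list(range(min(ids), max(ids) + 1)) if ids else True
            assert sorted(all_test) == list(range(n_seg))

    def test_fold_construction_rejects_overlap(self):
        with pytest.raises(LeakageError):
            Fold(0, test_seizure=1, train_seizures=(1, 2),
                 test_interictal_blocks=(), train_interictal_blocks=())


TINY = NetworkConfig(conv_widths=(4, 4, 4, 4, 4), input_len=32, lstm_hidden=4)


def separable_vectors(n_per_class=24, L=32, seed=0):
    """Sine bursts vs white noise: trivially separable single-channel data."""
    rng = np.random.default_rng(seed)
    t = np.arange(L)
    vecs = []
    for i in range(n_per_class):
        pos = 3.0 * np.sin(2 * np.pi * t / 8 + rng.uniform(0, 6.28)) \
            + rng.standard_normal(L)
        neg = rng.standard_normal(L)
        vecs.append(VectorSample(pos, 1, segment_id=0, channel="A", t_start=0.0))
        vecs.append(VectorSample(neg, 0, segment_id=1, channel="A", t_start=0.0))
    return vecs


class TestTraining:
    def test_separable_classes_fit_to_high_training_accuracy(self):
        for seed in range(3):
            vecs = separable_vectors(seed=seed)
            params = TrainParams(epochs=60, batch_size=16, learning_rate=3e-3,
                                 seed=seed)
            clf = train_model(vecs, TINY, params)
            X = np.stack([v.data for v in vecs])
            y = np.array([v.label for v in vecs])
            assert clf.score(X, y) >= 0.95

    def test_single_class_training_rejected(self):
        vecs = [v for v in separable_vectors() if v.label == 1]
        with pytest.raises(ValueError, match="single class"):
            train_model(vecs, TINY, TrainParams(epochs=1))

    def test_same_seed_reproduces_weights(self):
        vecs = separable_vectors()
        a = train_model(vecs, TINY, TrainParams(epochs=3, seed=5))
        b = train_model(vecs, TINY, TrainParams(epochs=3, seed=5))
        for k, v in a.net_.params().items():
            assert np.array_equal(v, b.net_.params()[k]), k

    def test_estimator_is_sklearn_cloneable(self):
        clf = CnnBiLstmClassifier(config=TINY, epochs=2, random_state=3)
        c2 = clone(clf)
        assert c2.get_params()["config"] == TINY
        c2.set_params(epochs=5)
        assert c2.epochs == 5 and clf.epochs == 2


class TestEvaluateFold:
    def _fitted_vote_model(self, n_channels=3, L=32):
        rng = np.random.default_rng(0)
        t = np.arange(L)
        Xpos = 3.0 * np.sin(2 * np.pi * t / 8)[None, None, :] \
            + rng.standard_normal((20, n_channels, L))
        Xneg = rng.standard_normal((20, n_channels, L))
        X = np.concatenate([Xpos, Xneg])
        y = np.array([1] * 20 + [0] * 20)
        model = ChannelVoteClassifier(
            base=CnnBiLstmClassifier(config=TINY, epochs=25, random_state=0)
        )
        return model.fit(X, y)

    def test_metrics_match_manual_tally(self):
        model = self._fitted_vote_model()
        rng = np.random.default_rng(1)
        t = np.arange(32)
        wins = []
        for i in range(8):
            label = i % 2
            sig = 3.0 * np.sin(2 * np.pi * t / 8) if label else 0.0
            w = make_window(label=label, segment_id=i, n_channels=3, L=32, seed=i)
            w.data = sig + rng.standard_normal((3, 32))
            wins.append(w)
        m = evaluate_fold(model, wins)
        y_pred = model.predict(np.stack([w.data for w in wins]))
        ref = Metrics.from_predictions([w.label for w in wins], y_pred)
        assert m == ref
        assert m.tp + m.tn + m.fp + m.fn == 8

    def test_montage_mismatch_raises(self):
        model = self._fitted_vote_model(n_channels=3)
        bad = [make_window(n_channels=4, L=32)]
        with pytest.raises(ChannelError):
            evaluate_fold(model, bad)

    def test_empty_test_set_gives_zero_counts(self):
        model = self._fitted_vote_model()
        m = evaluate_fold(model, [])
        assert (m.tp, m.tn, m.fp, m.fn) == (0, 0, 0, 0)
        assert m.accuracy is None


class TestAudit:
    def test_overlapping_segments_raise(self):
        fold = Fold(0, test_seizure=1, train_seizures=(2, 3),
                    test_interictal_blocks=(5,), train_interictal_blocks=(6,))
        train = [make_window(label=0, segment_id=5)]
        test = [make_window(label=0, segment_id=5)]
        with pytest.raises(LeakageError, match="segments"):
            audit_fold(fold, train, test)

    def test_shared_source_seizure_raises(self):
        fold = Fold(0, test_seizure=1, train_seizures=(2,),
                    test_interictal_blocks=(), train_interictal_blocks=())
        train = [make_window(label=1, segment_id=1, seizure=7)]
        test = [make_window(label=1, segment_id=2, seizure=7)]
        with pytest.raises(LeakageError, match="seizures"):
            audit_fold(fold, train, test)

    def test_disjoint_provenance_passes(self):
        fold = Fold(0, test_seizure=1, train_seizures=(2,),
                    test_interictal_blocks=(5,), train_interictal_blocks=(6,))
        audit_fold(
            fold,
            [make_window(label=0, segment_id=6)],
            [make_window(label=0, segment_id=5)],
        )
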