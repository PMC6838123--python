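"""Evaluation machinery vs independent brute-force oracles."""

import numpy as np
import pytest

from hicsub import classifier as clf
from hicsub import evaluation as ev
from hicsub.autoencoder import TrainingConfig
from .conftest import make_track


def random_pair(n, seed, with_proba=False):
    rng = np.random.default_rng(seed)
    ref = make_track(rng.integers(0, 5, n))
    if with_proba:
        raw = rng.random((n, 5))
        proba = raw / raw.sum(axis=1, keepdims=True)
        pred = make_track(np.argmax(proba, axis=1), proba=proba)
    else:
        pred = make_track(rng.integers(0, 5, n))
    return pred, ref


class TestConfusion:
    def test_perfect_agreement(self):
        pred, ref = random_pair(40, 0)
        summ = ev.confusion(ref, ref)
        assert summ.overall_accuracy == 1.0
        assert np.trace(summ.matrix) == 40

    def test_known_mismatch_count(self):
        ref = make_track([0] * 10)
        pred = make_track([0] * 8 + [1, 2])
        assert ev.confusion(pred, ref).overall_accuracy == pytest.approx(0.8)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pairwise_tally_oracle(self, seed):
        pred, ref = random_pair(100, seed)
        summ = ev.confusion(pred, ref)
        for r in range(5):
            for c in range(5):
                expected = int(np.sum((ref.labels == r) & (pred.labels == c)))
                assert summ.matrix[r, c] == expected
            row = int(np.sum(ref.labels == r))
            if row:
                assert summ.per_class_accuracy[clf.LABELS[r]] == pytest.approx(
                    summ.matrix[r, r] / row
                )

    def test_na_bins_excluded_pairwise(self):
        ref = make_track([0, 1, -1, 2])
        pred = make_track([0, -1, 1, 2])
        assert ev.confusion(pred, ref).n == 2

    def test_disjoint_tracks_rejected(self):
        with pytest.raises(ValueError, match="no bins"):
            ev.confusion(make_track([-1, -1]), make_track([0, 1]))


def brute_force_aupr(scores, truth):
    """Threshold sweep over all distinct scores; step-wise integration."""
    order = np.argsort(-scores, kind="stable")
    s, t = scores[order], truth[order]
    area, prev_recall = 0.0, 0.0
    n_pos = t.sum()
    tp = fp = 0
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            tp += t[j]
            fp += 1 - t[j]
            j += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return area


class TestAupr:
    def test_perfect_scores(self):
        ref = np.array([0, 1, 2, 3, 4] * 4)
        proba = np.eye(5)[ref]
        out = ev.aupr(proba, ref)
        assert all(v == pytest.approx(1.0) for v in out.values())

    def test_constant_scores_give_prevalence(self):
        ref = np.array([0] * 3 + [1] * 7)
        proba = np.full((10, 5), 0.2)
        out = ev.aupr(proba, ref)
        assert out["A1"] == pytest.approx(0.3)
        assert out["A2"] == pytest.approx(0.7)

    def test_absent_class_is_nan_not_zero(self):
        ref = np.array([0, 0, 1, 1])
        proba = np.full((4, 5), 0.2)
        assert np.isnan(ev.aupr(proba, ref)["B3"])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_threshold_sweep_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ref = rng.integers(0, 5, 50)
        proba = rng.random((50, 5))
        out = ev.aupr(proba, ref)
        for c, name in enumerate(clf.LABELS):
            truth = (ref == c).astype(int)
            if truth.any():
                assert out[name] == pytest.approx(
                    brute_force_aupr(proba[:, c], truth), abs=1e-10
                )


class TestKfold:
    def _data(self, seed=0, n=150):
        rng = np.random.default_rng(seed)
        labels = np.repeat(np.arange(5), n // 5)
        latents = rng.normal(0, 0.3, (n, 8)) + 2.5 * labels[:, None]
        return latents, labels

    def test_folds_partition_data(self):
        from sklearn.model_selection import StratifiedKFold

        latents, labels = self._data()
        splitter = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        seen = []
        for _, te in splitter.split(latents, labels):
            assert not set(seen) & set(te)
            seen.extend(te)
        assert sorted(seen) == list(range(len(labels)))

    def test_cv_report_shape_and_determinism(self):
        latents, labels = self._data()
        cfg = TrainingConfig(seed=0, epochs=10)
        df1 = ev.kfold_cv(latents, labels, k=3, cfg=cfg, seed=1)
        df2 = ev.kfold_cv(latents, labels, k=3, cfg=cfg, seed=1)
        assert list(df1.columns) == ["overall"] + list(clf.LABELS)
        assert df1.equals(df2)
        assert df1.attrs["stratified"]

    def test_fold_variance_is_small_on_separable_data(self):
        latents, labels = self._data()
        df = ev.kfold_cv(latents, labels, k=5, cfg=TrainingConfig(seed=0, epochs=50), seed=2)
        assert df["overall"].var() < 0.01

    def test_small_class_falls_back_to_unstratified(self):
        latents, labels = self._data()
        labels = labels.copy()
        labels[labels == 4] = 3
        labels[-2:] = 4  # class smaller than k
        df = ev.kfold_cv(latents, labels, k=5, cfg=TrainingConfig(seed=0, epochs=5), seed=3)
        assert not df.attrs["stratified"]


class TestEnrichment:
    def test_constant_signal_gives_unit_fold_change(self):
        ann = make_track([0, 1, 2, 3, 4, 0])
        sig = ev.SignalTrack(ann.bins, np.full(6, 3.3))
        out = ev.enrichment_fold_change(sig, ann)
        assert all(v == pytest.approx(1.0) for v in out.values())

    def test_toy_median_arithmetic(self):
        ann = make_track([0, 0, 0, 1, 1, 2, 2, 3, 3])
        sig = ev.SignalTrack(ann.bins, np.array([4, 4, 4, 2, 2, 2, 2, 2, 2.0]))
        out = ev.enrichment_fold_change(sig, ann)
        assert out["A1"] == pytest.approx(2.0)
        assert out["A2"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_median_oracle(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 5, 80)
        values = rng.random(80) + 0.5
        ann = make_track(labels)
        out = ev.enrichment_fold_change(ev.SignalTrack(ann.bins, values), ann)
        global_med = np.median(values)
        for c, name in enumerate(clf.LABELS):
            if (labels == c).any():
                assert out[name] == pytest.approx(
                    np.median(values[labels == c]) / global_med
                )


class TestBoundaryProfile:
    def test_step_signal_across_single_boundary(self):
        labels = [1] * 6 + [2] * 6  # A2 run then B1 run
        sig_values = np.array([1.0] * 6 + [0.0] * 6)
        ann = make_track(labels)
        profile, n = ev.boundary_profile(
            ev.SignalTrack(ann.bins, sig_values), ann, ("A2", "B1")
        )
        assert n == 1
        np.testing.assert_allclose(profile, [1, 1, 1, 1, 0, 0, 0, 0])

    def test_boundary_at_chromosome_edge_dropped(self):
        labels = [1, 2, 2, 2, 2, 2]  # switch too close to the start
        ann = make_track(labels)
        sig = ev.SignalTrack(ann.bins, np.ones(6))
        profile, n = ev.boundary_profile(sig, ann, ("A2", "B1"))
        assert n == 0 and np.all(np.isnan(profile))

    def test_reversed_pair_is_mirror_on_symmetric_data(self):
        labels = [1] * 5 + [2] * 5 + [1] * 5
        values = np.array([1.0] * 5 + [0.0] * 5 + [1.0] * 5)
        ann = make_track(labels)
        sig = ev.SignalTrack(ann.bins, values)
        fwd, n1 = ev.boundary_profile(sig, ann, ("A2", "B1"))
        rev, n2 = ev.boundary_profile(sig, ann, ("B1", "A2"))
        assert n1 == n2 == 1
        np.testing.assert_allclose(fwd, rev[::-1])

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_window_average_oracle(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 5, 60)
        values = rng.random(60)
        ann = make_track(labels)
        sig = ev.SignalTrack(ann.bins, values)
        profile, n = ev.boundary_profile(sig, ann, ("A1", "A2"))
        windows = []
        for i in range(59):
            if labels[i] == 0 and labels[i + 1] == 1 and i - 3 >= 0 and i + 5 <= 60:
                windows.append(values[i - 3 : i + 5])
        assert n == len(windows)
        if windows:
            np.testing.assert_allclose(profile, np.mean(windows, axis=0))
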