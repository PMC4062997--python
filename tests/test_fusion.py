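"""Fusion vectors, k-NN behaviour, split protocol, evaluation, outdoor features."""

import numpy as np
import pandas as pd
import pytest

from behavtrace import fusion as fu
from behavtrace import synthdata as sd
from behavtrace import tables
from behavtrace.videoflow import DirectionHistogram


def brute_force_knn(train_X, train_labels, query, k):
    """Independent all-pairs scan with the lowest-index tie rule."""
    d = np.sqrt(((train_X - query) ** 2).sum(axis=1))
    order = sorted(range(len(d)), key=lambda i: (round(float(d[i]), 12), i))[:k]
    votes = {}
    for i in order:
        lab = train_labels[i]
        c, best = votes.get(lab, (0, i))
        votes[lab] = (c + 1, min(best, i))
    return min(votes.items(), key=lambda kv: (-kv[1][0], kv[1][1]))[0]


def table1_dataset(seed=0):
    """Dataset whose per-cell counts transcribe the repetition table."""
    counts = tables.repetition_counts()
    rng = np.random.default_rng(seed)
    rows = []
    for subject in counts.index:
        for code in counts.columns:
            for _ in range(int(counts.loc[subject, code])):
                rows.append((rng.normal(size=11), code, subject))
    X = np.stack([r[0] for r in rows])
    return fu.LabeledDataset(X, np.array([r[1] for r in rows]),
                             np.array([r[2] for r in rows]))


class TestFuse:
    def test_mode_lengths(self):
        h = DirectionHistogram(np.full(8, 0.125))
        a = np.array([0.2, 0.5, 0.8])
        assert len(fu.fuse(h, a, "video").values) == 8
        assert len(fu.fuse(h, a, "acc").values) == 3
        assert len(fu.fuse(h, a, "both").values) == 11

    def test_combined_vector_video_part_first(self):
        h = DirectionHistogram(np.arange(8) / 28.0)
        a = np.array([0.2, 0.5, 0.8])
        f = fu.fuse(h, a, "both")
        assert np.allclose(f.values[:8], h.bins)
        assert np.allclose(f.values[8:], a)

    def test_all_zero_histogram_propagates_flag(self):
        h = DirectionHistogram(np.zeros(8), undetermined=True)
        assert fu.fuse(h, np.zeros(3), "both").undetermined

    def test_missing_modality_rejected(self):
        with pytest.raises(ValueError):
            fu.fuse(None, np.zeros(3), "both")


class TestKnnClassify:
    def test_training_point_returns_own_label(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 5))
        ds = fu.LabeledDataset(X, np.array([f"c{i % 3}" for i in range(30)]),
                               np.array(["V1"] * 30))
        for i in (0, 7, 29):
            assert fu.knn_classify(ds, X[i]) == ds.labels[i]

    def test_two_separated_clusters_high_accuracy(self):
        rng = np.random.default_rng(1)
        centers = {"A": np.zeros(4), "B": np.full(4, 10.0)}
        X = np.concatenate([rng.normal(centers[l], 0.5, size=(100, 4))
                            for l in "AB"])
        labels = np.array(["A"] * 100 + ["B"] * 100)
        ds = fu.LabeledDataset(X, labels, np.array(["V1"] * 200))
        q = np.concatenate([rng.normal(centers[l], 0.5, size=(500, 4))
                            for l in "AB"])
        truth = np.array(["A"] * 500 + ["B"] * 500)
        # nearest-centroid oracle: same decision for well-separated clusters
        oracle = np.where(((q - centers["A"]) ** 2).sum(1)
                          < ((q - centers["B"]) ** 2).sum(1), "A", "B")
        preds = fu.knn_predict(ds, q)
        assert np.mean(preds == truth) >= 0.99
        assert np.mean(preds == oracle) >= 0.99

    def test_exact_tie_takes_lowest_record_index(self):
        X = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0]])
        ds = fu.LabeledDataset(X, np.array(["right", "left", "up"]),
                               np.array(["V1"] * 3))
        # origin is equidistant from records 0 and 1 (and 2)
        assert fu.knn_classify(ds, np.zeros(2)) == "right"

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 6))
        labels = np.array([f"c{i % 5}" for i in rng.permutation(200)])
        ds = fu.LabeledDataset(X, labels, np.array(["V1"] * 200))
        queries = rng.normal(size=(50, 6))
        for cfg in (fu.ClassifierConfig(k=1), fu.ClassifierConfig(k=3),
                    fu.ClassifierConfig(k=5)):
            preds = fu.knn_predict(ds, queries, cfg)
            expect = [brute_force_knn(X, labels, q, cfg.k) for q in queries]
            assert list(preds) == expect

    def test_training_order_permutation_invariant(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(120, 4))
        labels = np.array([f"c{i % 4}" for i in range(120)])
        ds = fu.LabeledDataset(X, labels, np.array(["V1"] * 120))
        perm = rng.permutation(120)
        ds_p = fu.LabeledDataset(X[perm], labels[perm], np.array(["V1"] * 120))
        queries = rng.normal(size=(40, 4))
        # continuous features: exact ties have measure zero here
        assert np.array_equal(fu.knn_predict(ds, queries),
                              fu.knn_predict(ds_p, queries))

    def test_dimension_mismatch_rejected(self):
        ds = fu.LabeledDataset(np.zeros((3, 4)), np.array(list("abc")),
                               np.array(["V1"] * 3))
        with pytest.raises(ValueError):
            fu.knn_classify(ds, np.zeros(5))


class TestLooSelectK:
    def test_constructed_dataset_prefers_k1(self):
        # each class: tight pairs far apart; k=1 perfect, k=3 pulls in wrong class
        X = np.array([[0.0], [0.1], [1.0], [1.1], [2.0], [2.1]])
        labels = np.array(["a", "a", "b", "b", "c", "c"])
        ds = fu.LabeledDataset(X, labels, np.array(["V1"] * 6))
        assert fu.loo_select_k(ds, (1, 3, 5)) == 1

    def test_duplicate_only_dataset_ties_to_smallest(self):
        X = np.zeros((8, 3))
        ds = fu.LabeledDataset(X, np.array(["a"] * 8), np.array(["V1"] * 8))
        assert fu.loo_select_k(ds, (5, 3, 1)) == 1

    def test_single_class_ties_to_smallest(self):
        rng = np.random.default_rng(0)
        ds = fu.LabeledDataset(rng.normal(size=(10, 2)), np.array(["a"] * 10),
                               np.array(["V1"] * 10))
        assert fu.loo_select_k(ds, (1, 3, 5)) == 1

    def test_empty_grid_rejected(self):
        ds = fu.LabeledDataset(np.zeros((2, 1)), np.array(["a", "b"]),
                               np.array(["V1"] * 2))
        with pytest.raises(ValueError):
            fu.loo_select_k(ds, ())


class TestSplitProtocol:
    def test_table1_counts_give_printed_sizes(self):
        ds = table1_dataset()
        learn, test = fu.split_protocol(ds, per_cell=10, seed=0)
        assert len(learn) == 2400
        assert len(test) == 4874

    def test_partition_and_cell_counts(self):
        ds = table1_dataset()
        learn, test = fu.split_protocol(ds, per_cell=10, seed=1)
        assert len(learn) + len(test) == len(ds)
        cells = pd.crosstab(learn.labels, learn.subjects)
        assert (cells == 10).all().all()

    def test_zero_per_cell_puts_everything_in_testing(self):
        ds = table1_dataset()
        learn, test = fu.split_protocol(ds, per_cell=0, seed=0)
        assert len(learn) == 0 and len(test) == len(ds)

    def test_deficient_cell_named(self):
        X = np.zeros((3, 2))
        ds = fu.LabeledDataset(X, np.array(["1a", "1a", "1b"]),
                               np.array(["V1"] * 3))
        with pytest.raises(ValueError, match="1b"):
            fu.split_protocol(ds, per_cell=2)


class TestEvaluate:
    def test_duplicated_testing_is_perfect(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 11))
        labels = np.array([tables.ACTIVITY_CODES[i % 12] for i in range(60)])
        subjects = np.array([f"V{i % 3 + 1}" for i in range(60)])
        ds = fu.LabeledDataset(X, labels, subjects)
        rep = fu.evaluate(ds, ds, mode="both")
        assert rep.overall == 100.0
        assert (rep.per_activity == 100.0).all()
        assert (rep.per_subject == 100.0).all()

    def test_confusion_matrix_consistent_with_overall(self):
        df = sd.indoor_feature_benchmark(n_per_cell=12, n_subjects=3, seed=2)
        ds = fu.LabeledDataset.from_frame(df)
        learn, test = fu.split_protocol(ds, per_cell=10, seed=2)
        rep = fu.evaluate(learn, test, mode="both")
        diag = sum(rep.confusion.at[l, l] for l in rep.confusion.index
                   if l in rep.confusion.columns)
        assert rep.overall == pytest.approx(100.0 * diag / rep.confusion.to_numpy().sum())

    def test_fused_mode_beats_single_modalities(self):
        df = sd.indoor_feature_benchmark(n_per_cell=14, n_subjects=6, seed=7)
        ds = fu.LabeledDataset.from_frame(df)
        learn, test = fu.split_protocol(ds, per_cell=10, seed=7)
        acc = {m: fu.evaluate(learn, test, mode=m).overall
               for m in ("video", "acc", "both")}
        assert acc["both"] >= max(acc["video"], acc["acc"])

    def test_unseen_label_counted_as_error(self):
        X = np.zeros((4, 2))
        learn = fu.LabeledDataset(X[:2], np.array(["a", "a"]), np.array(["V1"] * 2))
        test = fu.LabeledDataset(X[2:] + 5, np.array(["b", "b"]), np.array(["V1"] * 2))
        rep = fu.evaluate(learn, test)
        assert rep.overall == 0.0
        assert rep.unseen_labels == ("b",)


class TestOutdoorFeature:
    def _trace(self, label, duration, seed=0):
        script = sd.ActivityScript("V1", (sd.Segment(label, 0.0, duration),))
        trace, _ = sd.simulate_accelerometer(script, noise_sd=0.01, seed=seed)
        return trace

    def test_stationary_subject(self):
        trace = self._trace("standing", 30.0)
        track, _ = sd.simulate_gps_track([("standing", 30.0, 0.0)])
        from behavtrace.wearables import gps_speed
        feats = fu.outdoor_feature(trace, gps_speed(track), window=5.0)
        assert np.allclose(feats["speed_mean"], 0.0)
        # quiet trace: normalized |a| sum is the near-constant gravity share
        assert feats["accel_mean"].std() < 0.05

    def test_window_mean_invariance_for_constant_signals(self):
        trace = self._trace("standing", 40.0)
        track, _ = sd.simulate_gps_track([("walking", 40.0, 1.5)])
        from behavtrace.wearables import gps_speed
        sp = gps_speed(track)
        f1 = fu.outdoor_feature(trace, sp, window=5.0)
        f2 = fu.outdoor_feature(trace, sp, window=10.0)
        assert f1["speed_mean"].mean() == pytest.approx(f2["speed_mean"].mean(),
                                                        rel=0.01)

    def test_no_overlap_rejected(self):
        trace = self._trace("standing", 10.0)
        track = pd.DataFrame({"t": [100.0, 101.0], "lat": [50.0, 50.0],
                              "lon": [19.9, 19.9]})
        from behavtrace.wearables import gps_speed
        with pytest.raises(ValueError):
            fu.outdoor_feature(trace, gps_speed(track), window=5.0)

    def test_running_vs_standing_separable(self):
        """Windowed 2-D features support >= 80% 1-NN recognition."""
        rng = np.random.default_rng(9)
        feats, labels = [], []
        for label, speed in (("standing", 0.0), ("walking", 1.5), ("running", 3.0)):
            for seed in range(4):
                trace = self._trace(label, 60.0, seed=seed)
                track, _ = sd.simulate_gps_track([(label, 60.0, speed)],
                                                 jitter_m=0.5, seed=seed)
                from behavtrace.wearables import gps_speed
                f = fu.outdoor_feature(trace, gps_speed(track), window=4.0)
                feats.append(f[["accel_mean", "speed_mean"]].to_numpy())
                labels.extend([label] * len(f))
        X = np.concatenate(feats)
        y = np.array(labels)
        assert len(y) >= 100
        idx = rng.permutation(len(y))
        half = len(y) // 2
        train = fu.LabeledDataset(X[idx[:half]], y[idx[:half]],
                                  np.array(["V1"] * half))
        preds = fu.knn_predict(train, X[idx[half:]])
        assert np.mean(preds == y[idx[half:]]) >= 0.80
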