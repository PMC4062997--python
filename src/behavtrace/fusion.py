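"""Feature fusion and 1-NN activity recognition.

The indoor feature vector concatenates the 8-bin flow-direction histogram
(video part) with the processed 3-axis accelerometer sample, giving
[B1..B8 X Y Z] for the combined mode, the first 8 for video-only, the last
3 for accelerometer-only.  Classification is k-nearest-neighbor (k selected
to 1 by leave-one-out), the learning set is 10 random draws per
(activity, subject) cell and the testing set is the remainder, and
evaluation reports per-activity, per-subject, and overall accuracies.

The 2-D outdoor vector pairs the windowed mean of the normalized absolute
accelerometer sum with the windowed mean GPS speed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .videoflow import DirectionHistogram
from .wearables import AccelTrace

__all__ = [
    "MODALITY_SLICES",
    "FusedFeature",
    "LabeledDataset",
    "ClassifierConfig",
    "EvalReport",
    "fuse",
    "knn_classify",
    "knn_predict",
    "loo_select_k",
    "split_protocol",
    "evaluate",
    "outdoor_feature",
]

#: Column slice of the full 11-D vector used by each modality mode.
MODALITY_SLICES = {"video": slice(0, 8), "acc": slice(8, 11), "both": slice(0, 11)}

#: Default classification window length in seconds, as configured in the
#: study protocol.  See docs/methods.md for why this value is suspect.
DEFAULT_WINDOW_S = 160.0


@dataclass(frozen=True)
class FusedFeature:
    """Feature vector for one 25 Hz time point in one modality mode."""

    values: np.ndarray
    mode: str
    undetermined: bool = False
    timestamp: float | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        expected = {"video": 8, "acc": 3, "both": 11}[self.mode]
        if v.shape != (expected,):
            raise ValueError(f"mode {self.mode!r} expects length {expected}")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature components must be finite")
        object.__setattr__(self, "values", v)


def fuse(histogram: DirectionHistogram | np.ndarray | None,
         accel_sample: np.ndarray | None, mode: str = "both",
         timestamp: float | None = None) -> FusedFeature:
    """Concatenate modality parts per mode, video part first.

    The video histogram is the one held (zero-order) for this 25 Hz time
    point; an all-zero histogram propagates its "undetermined" flag.
    """
    if mode not in MODALITY_SLICES:
        raise ValueError(f"unknown mode {mode!r}")
    undetermined = False
    if mode in ("video", "both"):
        if histogram is None:
            raise ValueError("video part required for this mode")
        if isinstance(histogram, DirectionHistogram):
            video = histogram.bins
            undetermined = histogram.undetermined
        else:
            video = np.asarray(histogram, dtype=float)
            undetermined = not np.any(video)
    if mode in ("acc", "both"):
        if accel_sample is None:
            raise ValueError("accelerometer part required for this mode")
        acc = np.asarray(accel_sample, dtype=float)
    if mode == "video":
        values = video
    elif mode == "acc":
        values = acc
    else:
        values = np.concatenate([video, acc])
    return FusedFeature(values, mode, undetermined, timestamp)


@dataclass(frozen=True)
class LabeledDataset:
    """Feature records with activity labels and subject ids."""

    X: np.ndarray
    labels: np.ndarray
    subjects: np.ndarray

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        labels = np.asarray(self.labels)
        subjects = np.asarray(self.subjects)
        if not (len(X) == len(labels) == len(subjects)):
            raise ValueError("record counts differ")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "subjects", subjects)

    def __len__(self) -> int:
        return len(self.labels)

    def view(self, mode: str) -> "LabeledDataset":
        return LabeledDataset(self.X[:, MODALITY_SLICES[mode]], self.labels,
                              self.subjects)

    def take(self, idx) -> "LabeledDataset":
        idx = np.asarray(idx)
        return LabeledDataset(self.X[idx], self.labels[idx], self.subjects[idx])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LabeledDataset":
        feat_cols = [c for c in df.columns if c not in ("label", "subject")]
        return cls(df[feat_cols].to_numpy(float), df["label"].to_numpy(),
                   df["subject"].to_numpy())

    def to_frame(self) -> pd.DataFrame:
        d = self.X.shape[1]
        if d == 11:
            cols = [f"B{i}" for i in range(1, 9)] + ["X", "Y", "Z"]
        else:
            cols = [f"f{i}" for i in range(d)]
        df = pd.DataFrame(self.X, columns=cols)
        df["label"] = self.labels
        df["subject"] = self.subjects
        return df


@dataclass(frozen=True)
class ClassifierConfig:
    k: int = 1
    metric: str = "euclidean"
    tie_break: str = "lowest_index"
    seed: int = 0

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")


def _neighbor_indices(train_X: np.ndarray, queries: np.ndarray, k: int) -> np.ndarray:
    """k nearest training indices per query, distance then index order.

    Distances are recomputed exactly and sorted lexicographically by
    (distance, record index) so exact ties resolve to the lowest index.
    """
    nn = NearestNeighbors(n_neighbors=min(k, len(train_X))).fit(train_X)
    dist, idx = nn.kneighbors(queries)
    order = np.lexsort((idx, np.round(dist, 12)), axis=-1)
    return np.take_along_axis(idx, order, axis=-1)


def _vote(labels_k: np.ndarray, idx_k: np.ndarray):
    votes: dict = {}
    for lab, i in zip(labels_k, idx_k):
        c, best = votes.get(lab, (0, i))
        votes[lab] = (c + 1, min(best, i))
    # majority; ties -> label containing the lowest record index
    return min(votes.items(), key=lambda kv: (-kv[1][0], kv[1][1]))[0]


def knn_predict(train: LabeledDataset, queries: np.ndarray,
                cfg: ClassifierConfig = ClassifierConfig()) -> np.ndarray:
    """Predict labels for a (m, d) query block by k-NN majority vote."""
    if len(train) == 0:
        raise ValueError("training set is empty")
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    if queries.shape[1] != train.X.shape[1]:
        raise ValueError("feature dimensionality mismatch")
    idx = _neighbor_indices(train.X, queries, cfg.k)
    return np.array([_vote(train.labels[row], row) for row in idx])


def knn_classify(train: LabeledDataset, query,
                 cfg: ClassifierConfig = ClassifierConfig()):
    """Label of one query point (see :func:`knn_predict`)."""
    if isinstance(query, FusedFeature):
        query = query.values
    return knn_predict(train, np.asarray(query, float)[None, :], cfg)[0]


def loo_select_k(dataset: LabeledDataset, k_grid=(1, 3, 5, 7, 9)) -> int:
    """k maximizing leave-one-out accuracy; ties go to the smallest k."""
    k_grid = sorted(set(int(k) for k in k_grid))
    if not k_grid:
        raise ValueError("empty k grid")
    if len(dataset) < 2:
        raise ValueError("need at least 2 records")
    kmax = min(max(k_grid), len(dataset) - 1)
    nn = NearestNeighbors(n_neighbors=kmax + 1).fit(dataset.X)
    dist, idx = nn.kneighbors(dataset.X)
    order = np.lexsort((idx, np.round(dist, 12)), axis=-1)
    idx = np.take_along_axis(idx, order, axis=-1)
    # drop each record itself from its own neighbor list
    self_col = idx == np.arange(len(dataset))[:, None]
    neighbors = np.array([row[~m][:kmax] for row, m in zip(idx, self_col)])
    best_k, best_acc = None, -1.0
    for k in k_grid:
        kk = min(k, kmax)
        preds = np.array([_vote(dataset.labels[row[:kk]], row[:kk])
                          for row in neighbors])
        acc = float(np.mean(preds == dataset.labels))
        if acc > best_acc + 1e-12:
            best_k, best_acc = k, acc
    return best_k


def split_protocol(dataset: LabeledDataset, per_cell: int = 10, seed: int = 0,
                   ) -> tuple[LabeledDataset, LabeledDataset]:
    """Learning/testing split: ``per_cell`` random draws per (activity,
    subject) cell into the learning set, everything else into testing.

    Raises (naming the cell) when any cell holds fewer than ``per_cell``
    records.
    """
    if per_cell < 0:
        raise ValueError("per_cell must be >= 0")
    rng = np.random.default_rng(seed)
    learn_idx: list[int] = []
    cells = pd.DataFrame({"label": dataset.labels, "subject": dataset.subjects})
    for (lab, sub), grp in cells.groupby(["label", "subject"], sort=True):
        if len(grp) < per_cell:
            raise ValueError(
                f"cell (activity={lab!r}, subject={sub!r}) has only "
                f"{len(grp)} records, needs {per_cell}")
        chosen = rng.choice(grp.index.to_numpy(), size=per_cell, replace=False)
        learn_idx.extend(int(i) for i in chosen)
    learn_mask = np.zeros(len(dataset), dtype=bool)
    learn_mask[learn_idx] = True
    return dataset.take(np.flatnonzero(learn_mask)), dataset.take(np.flatnonzero(~learn_mask))


@dataclass(frozen=True)
class EvalReport:
    """Recognition-correctness tables (percent) for one modality mode."""

    mode: str
    per_activity: pd.Series
    per_subject: pd.Series
    overall: float
    confusion: pd.DataFrame
    unseen_labels: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        row = self.per_activity.copy()
        row["overall"] = self.overall
        return row.to_frame(self.mode).T


def evaluate(learning: LabeledDataset, testing: LabeledDataset,
             cfg: ClassifierConfig = ClassifierConfig(),
             mode: str = "both") -> EvalReport:
    """Classify the testing set and tabulate recognition correctness.

    Testing labels absent from the learning set are counted as errors and
    surfaced in ``unseen_labels``.  The overall accuracy is consistent with
    the stored confusion matrix by construction.
    """
    train = learning.view(mode) if learning.X.shape[1] == 11 else learning
    test = testing.view(mode) if testing.X.shape[1] == 11 else testing
    preds = knn_predict(train, test.X, cfg)
    truth = test.labels
    correct = preds == truth
    unseen = tuple(sorted(set(truth) - set(train.labels)))

    act = pd.Series(correct).groupby(pd.Series(truth)).mean() * 100.0
    sub = pd.Series(correct).groupby(pd.Series(test.subjects)).mean() * 100.0
    conf = pd.crosstab(pd.Series(truth, name="true"),
                       pd.Series(preds, name="predicted"))
    overall = float(np.mean(correct)) * 100.0
    return EvalReport(mode, act, sub, overall, conf, unseen)


def outdoor_feature(accel: AccelTrace, speed: pd.DataFrame,
                    window: float = 5.0) -> pd.DataFrame:
    """2-D outdoor features per window: (mean normalized |a| sum, mean speed).

    The absolute three-axis sum |ax|+|ay|+|az| is normalized by its maximum
    over the trace; both it and the GPS speed series are averaged over
    consecutive ``window``-second windows of the overlapping time span.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    t0 = max(accel.t[0], float(speed["t"].iloc[0]))
    t1 = min(accel.t[-1], float(speed["t"].iloc[-1]))
    if t1 <= t0:
        raise ValueError("no temporal overlap between accelerometer and GPS")
    s = np.abs(accel.ax) + np.abs(accel.ay) + np.abs(accel.az)
    smax = float(np.max(s))
    if smax > 0:
        s = s / smax
    edges = np.arange(t0, t1 + 1e-9, window)
    if len(edges) < 2:
        edges = np.array([t0, t1])
    rows = []
    st = speed["t"].to_numpy(float)
    sv = speed["speed"].to_numpy(float)
    for lo, hi in zip(edges[:-1], edges[1:]):
        a_sel = (accel.t >= lo) & (accel.t < hi)
        g_sel = (st >= lo) & (st < hi)
        if not a_sel.any() or not g_sel.any():
            continue
        rows.append({"t": (lo + hi) / 2,
                     "accel_mean": float(np.mean(s[a_sel])),
                     "speed_mean": float(np.mean(sv[g_sel]))})
    return pd.DataFrame(rows)
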