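"""Pose-contribution states, DTW behavioral distance, and behavioral records.

A subject state at one time point is a convex combination of P = 7
elementary poses — the six movement classes of the indoor activity
vocabulary plus "undetermined" — represented by contribution coefficients
w_p (non-negative, summing to 1).  The distance between two behavioral
sequences is computed by dynamic time warping over an l1-by-l2 matrix of
squared state differences

    d[i, j] = sum_p (w_p,1[i] - w_p,2[j])^2

with monotone alignment paths stepping through {(1,0), (0,1), (1,1)} from
(1,1) to (l1,l2); the reported cost is the sum of d along the optimal path.
Behavioral patterns summarize labeled record segments (mean/std duration,
probability-ordered successors); pattern clustering groups sequences by
pairwise DTW cost; the behavioral record itself is a two-level graph of
zone visits (outer) and probability-ordered status nodes (inner).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, squareform

from .tables import MOVEMENT_CLASS, N_POSES, POSE_CLASSES, UNDETERMINED

__all__ = [
    "StateVector",
    "DTWResult",
    "BehavioralPattern",
    "BehavioralRecord",
    "ClusterResult",
    "state_from_classification",
    "distance_matrix",
    "dtw",
    "pattern_statistics",
    "cluster_patterns",
    "record_append",
]


@dataclass(frozen=True)
class StateVector:
    """P = 7 pose-contribution coefficients w_p at one time point."""

    w: np.ndarray
    timestamp: float | None = None

    def __post_init__(self):
        w = np.asarray(self.w, dtype=float)
        if w.shape != (N_POSES,):
            raise ValueError(f"state must have {N_POSES} components")
        if np.any(w < -1e-12):
            raise ValueError("contributions must be non-negative")
        s = w.sum()
        if abs(s - 1.0) > 1e-9:
            raise ValueError("contributions must sum to 1")
        object.__setattr__(self, "w", np.clip(w, 0.0, None))

    @property
    def dominant_pose(self) -> str:
        return POSE_CLASSES[int(np.argmax(self.w))]


def state_from_classification(labels, distances=None,
                              undetermined_threshold: float | None = None,
                              timestamp: float | None = None) -> StateVector:
    """State vector from k-NN votes.

    The 12 activity codes collapse to their 6 movement classes (1a/1b -> 1,
    ...); contributions are vote fractions over the k neighbor labels.  When
    ``distances`` are given and the nearest neighbor is farther than
    ``undetermined_threshold``, the full mass goes to "undetermined".
    """
    labels = list(labels)
    if not labels:
        raise ValueError("need at least one vote")
    w = np.zeros(N_POSES)
    if (undetermined_threshold is not None and distances is not None
            and float(np.min(distances)) > undetermined_threshold):
        w[UNDETERMINED] = 1.0
        return StateVector(w, timestamp)
    for lab in labels:
        if lab == "undetermined":
            w[UNDETERMINED] += 1.0
        else:
            w[MOVEMENT_CLASS[lab]] += 1.0
    return StateVector(w / w.sum(), timestamp)


def _as_matrix(x) -> np.ndarray:
    if len(x) == 0:
        raise ValueError("sequence must be nonempty")
    if isinstance(x[0], StateVector):
        return np.stack([s.w for s in x])
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2:
        raise ValueError("sequence must be a list of states or an (l, P) array")
    return arr


def distance_matrix(x1, x2) -> np.ndarray:
    """l1-by-l2 matrix of squared state differences d[i, j]."""
    m1, m2 = _as_matrix(x1), _as_matrix(x2)
    if m1.shape[1] != m2.shape[1]:
        raise ValueError("state dimensionality differs between the sequences")
    return cdist(m1, m2, metric="sqeuclidean")


@dataclass(frozen=True)
class DTWResult:
    """Optimal alignment: total cost, path, and per-step d-values."""

    cost: float
    path: tuple[tuple[int, int], ...]  # 0-based (i, j), (0,0) .. (l1-1, l2-1)
    step_costs: tuple[float, ...]


def dtw(x1, x2, root_distance: bool = False) -> DTWResult:
    """Dynamic time warping over the squared-difference state distance.

    Dynamic program with local steps {(1,0), (0,1), (1,1)} and fixed
    endpoints; the cost is the sum of d along the optimal path and the path
    is recovered by backtracking (diagonal preferred on ties).  With
    ``root_distance`` the square-rooted (Euclidean) per-cell distance is
    accumulated instead.
    """
    d = distance_matrix(x1, x2)
    if root_distance:
        d = np.sqrt(d)
    l1, l2 = d.shape
    acc = np.full((l1, l2), np.inf)
    acc[0, 0] = d[0, 0]
    for i in range(l1):
        for j in range(l2):
            if i == 0 and j == 0:
                continue
            best = np.inf
            if i > 0 and j > 0:
                best = acc[i - 1, j - 1]
            if i > 0:
                best = min(best, acc[i - 1, j])
            if j > 0:
                best = min(best, acc[i, j - 1])
            acc[i, j] = d[i, j] + best
    # backtracking
    path = [(l1 - 1, l2 - 1)]
    i, j = l1 - 1, l2 - 1
    while (i, j) != (0, 0):
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            candidates = ((acc[i - 1, j - 1], (i - 1, j - 1)),
                          (acc[i - 1, j], (i - 1, j)),
                          (acc[i, j - 1], (i, j - 1)))
            _, (i, j) = min(candidates, key=lambda c: c[0])
        path.append((i, j))
    path.reverse()
    steps = tuple(float(d[i, j]) for i, j in path)
    return DTWResult(float(acc[l1 - 1, l2 - 1]), tuple(path), steps)


# ---------------------------------------------------------------------------
# behavioral patterns
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BehavioralPattern:
    """Statistics of one status label in a behavioral record."""

    label: str
    mean_duration: float
    std_duration: float
    successors: tuple[tuple[str, float], ...]  # probability-ordered, desc
    n_occurrences: int

    def __post_init__(self):
        if self.successors:
            total = sum(p for _, p in self.successors)
            if abs(total - 1.0) > 1e-9:
                raise ValueError("successor probabilities must sum to 1")


def pattern_statistics(segments) -> dict[str, BehavioralPattern]:
    """Per-label duration statistics and successor probabilities.

    ``segments`` is the time-ordered list of (label, duration) record
    sections.  Successor probabilities are the observed transition
    frequencies to the immediately following segment; the final segment
    contributes no transition.  Durations use the population (n) std so a
    single occurrence reports 0.
    """
    segments = [(str(lab), float(dur)) for lab, dur in segments]
    if not segments:
        raise ValueError("need at least one segment")
    durations: dict[str, list[float]] = {}
    transitions: dict[str, dict[str, int]] = {}
    for (lab, dur), nxt in zip(segments, segments[1:] + [None]):
        durations.setdefault(lab, []).append(dur)
        if nxt is not None:
            transitions.setdefault(lab, {})
            transitions[lab][nxt[0]] = transitions[lab].get(nxt[0], 0) + 1
    out = {}
    for lab, durs in durations.items():
        trans = transitions.get(lab, {})
        total = sum(trans.values())
        succ = tuple(sorted(((t, c / total) for t, c in trans.items()),
                            key=lambda x: (-x[1], x[0]))) if total else ()
        out[lab] = BehavioralPattern(
            label=lab,
            mean_duration=float(np.mean(durs)),
            std_duration=float(np.std(durs)),
            successors=succ,
            n_occurrences=len(durs),
        )
    return out


@dataclass(frozen=True)
class ClusterResult:
    """Grouping of sequences by pairwise DTW cost."""

    group_of: tuple[int, ...]        # group index per sequence
    symbols: tuple[str, ...]         # unique symbol per group, G1, G2, ...
    pairwise_cost: np.ndarray


def cluster_patterns(sequences, linkage_threshold: float,
                     method: str = "average") -> ClusterResult:
    """Agglomerative grouping on pairwise DTW costs.

    Groups are cut at ``linkage_threshold`` cophenetic distance and labeled
    with fresh symbols in order of first appearance.  A zero threshold keeps
    every sequence separate unless it duplicates another exactly.
    """
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    n = len(sequences)
    mats = [_as_matrix(s) for s in sequences]
    cost = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            c = dtw(mats[i], mats[j]).cost
            cost[i, j] = cost[j, i] = c
    z = linkage(squareform(cost, checks=False), method=method)
    raw = fcluster(z, t=linkage_threshold, criterion="distance")
    remap: dict[int, int] = {}
    groups = []
    for r in raw:
        if r not in remap:
            remap[r] = len(remap)
        groups.append(remap[r])
    symbols = tuple(f"G{k + 1}" for k in range(len(remap)))
    return ClusterResult(tuple(groups), symbols, cost)


# ---------------------------------------------------------------------------
# two-level behavioral record
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InnerNode:
    """Status hypothesis node: state plus a probability-ordered status list."""

    timestamp: float
    state: StateVector
    candidates: tuple[tuple[str, float], ...]  # sorted by probability desc


@dataclass(frozen=True)
class ZoneVisit:
    """Outer node: one contiguous stay in a zone."""

    zone: str
    entered: float
    inner: tuple[InnerNode, ...] = ()


@dataclass(frozen=True)
class BehavioralRecord:
    """Append-only two-level graph: zone visits holding status nodes."""

    outer: tuple[ZoneVisit, ...] = ()
    valid_zones: frozenset[str] | None = None

    @property
    def current_zone(self) -> str | None:
        return self.outer[-1].zone if self.outer else None


def record_append(record: BehavioralRecord, zone: str, state: StateVector,
                  candidates, timestamp: float = 0.0) -> BehavioralRecord:
    """Return a new record with one more inner node.

    A new outer node is opened only when the zone changes; candidate status
    lists are stored sorted by probability descending.  History nodes are
    never mutated (the record is a persistent structure of tuples).
    """
    if record.valid_zones is not None and zone not in record.valid_zones:
        raise KeyError(f"unknown zone {zone!r}")
    cand = tuple(sorted(((str(l), float(p)) for l, p in candidates),
                        key=lambda x: (-x[1], x[0])))
    node = InnerNode(float(timestamp), state, cand)
    if record.outer and record.outer[-1].zone == zone:
        last = record.outer[-1]
        new_last = ZoneVisit(last.zone, last.entered, last.inner + (node,))
        outer = record.outer[:-1] + (new_last,)
    else:
        outer = record.outer + (ZoneVisit(zone, float(timestamp), (node,)),)
    return BehavioralRecord(outer, record.valid_zones)
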