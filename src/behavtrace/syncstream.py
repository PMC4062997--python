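"""Ordering and synchronization of wearable and premise data streams.

The two modalities see the same subject but reach the server with different
processing and transmission delays.  Alignment works on motion envelopes —
|a| magnitude for the wearable stream, per-flow-step mean |OF| for the
premise camera — by (1) finding salient sections as the top 5% of envelope
values over a trailing 15 min history, (2) estimating the lag maximizing the
normalized cross-correlation between the two envelopes around such a
section, and (3) accepting the new delay only when the correlation exceeds
a 0.7 gate, so that not every rapid movement retunes the clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .videoflow import FrameSequence, compute_optical_flow, select_frame_pairs
from .wearables import AccelTrace

__all__ = [
    "TimestampedSeries",
    "SyncState",
    "motion_envelope",
    "detect_salient_sections",
    "estimate_delay",
    "update_delay",
    "apply_compensation",
    "synchronize",
]

#: Resampling rate used for the lag search.  One lag step = one sample at
#: this rate, fine enough to resolve delays to the accelerometer grid.
CORRELATION_RATE = 100.0


@dataclass(frozen=True)
class TimestampedSeries:
    """Scalar series on its own clock, with the source's fixed pipeline delay."""

    t: np.ndarray
    v: np.ndarray
    source: str = "wearable"  # or "premise"
    nominal_delay: float = 0.0

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.v, dtype=float)
        if len(t) != len(v):
            raise ValueError("t and v lengths differ")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "v", v)

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class SyncState:
    """Current delay estimate and its provenance.

    ``horizon`` is the trailing history (s) over which salient-section
    thresholds adapt; 900 s = 15 min by default.
    """

    delay: float = 0.0
    last_corr: float = float("nan")
    horizon: float = 900.0
    log: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")


def motion_envelope(source, **flow_kwargs) -> TimestampedSeries:
    """Motion envelope of either modality on its own timeline.

    Wearable: acceleration magnitude sqrt(ax²+ay²+az²).  Premise: mean |OF|
    over the frame for each flow step, timestamped at the midpoint of its
    frame pair (a velocity proxy; cross-correlation alignment is invariant
    to monotone channel transforms of matched events).
    """
    if isinstance(source, AccelTrace):
        v = np.sqrt(source.ax ** 2 + source.ay ** 2 + source.az ** 2)
        return TimestampedSeries(source.t, v, source="wearable")
    if isinstance(source, FrameSequence):
        pairs = select_frame_pairs(len(source))
        if not pairs:
            raise ValueError("movie too short for a single flow step")
        t = np.empty(len(pairs))
        v = np.empty(len(pairs))
        for k, (i, j) in enumerate(pairs):
            flow = compute_optical_flow(source.frames[i - 1], source.frames[j - 1],
                                        **flow_kwargs)
            v[k] = float(np.mean(flow.modulus))
            t[k] = ((i - 1) + (j - 1)) / 2.0 / source.fps
        return TimestampedSeries(t, v, source="premise")
    raise TypeError(f"unsupported source type {type(source).__name__}")


def detect_salient_sections(env: TimestampedSeries, state: SyncState | None = None,
                            quantile: float = 0.95,
                            min_history: float = 60.0) -> list[tuple[float, float]]:
    """Maximal runs where the envelope reaches its trailing-history quantile.

    The threshold is the ``quantile`` (default: top 5%) of envelope values
    within the trailing ``state.horizon`` seconds.  A constant envelope has
    no salient sections.  Requires at least ``min_history`` seconds of data.
    """
    horizon = state.horizon if state is not None else 900.0
    if len(env) < 2 or env.t[-1] - env.t[0] < min_history:
        raise ValueError(f"need at least {min_history} s of history")
    sel = env.t >= env.t[-1] - horizon
    window = env.v[sel]
    if np.ptp(window) == 0:
        return []
    thr = float(np.quantile(window, quantile))
    above = env.v >= thr
    above &= sel
    sections = []
    start = None
    for k, flag in enumerate(above):
        if flag and start is None:
            start = env.t[k]
        elif not flag and start is not None:
            sections.append((start, env.t[k - 1]))
            start = None
    if start is not None:
        sections.append((start, env.t[-1]))
    return sections


def _pearson_lags(a: np.ndarray, b_full: np.ndarray, offset: int,
                  max_shift: int) -> np.ndarray:
    """Pearson correlation of ``a`` against windows of ``b_full`` shifted by
    each integer lag in [-max_shift, max_shift]; index 0 = lag -max_shift."""
    n = len(a)
    a0 = a - a.mean()
    sa = np.sqrt(np.sum(a0 ** 2))
    out = np.full(2 * max_shift + 1, -np.inf)
    for k in range(-max_shift, max_shift + 1):
        lo = offset + k
        seg = b_full[lo:lo + n]
        b0 = seg - seg.mean()
        sb = np.sqrt(np.sum(b0 ** 2))
        if sa == 0 or sb == 0:
            out[k + max_shift] = 0.0
        else:
            out[k + max_shift] = float(np.dot(a0, b0) / (sa * sb))
    return out


def estimate_delay(env_a: TimestampedSeries, env_b: TimestampedSeries,
                   max_lag: float, section: tuple[float, float] | None = None,
                   rate: float = CORRELATION_RATE) -> tuple[float, float]:
    """Lag by which stream B trails stream A, from normalized cross-correlation.

    Both envelopes are resampled (linear interpolation) to ``rate`` and the
    Pearson correlation is evaluated at every integer lag within
    ±``max_lag``; the arg-max lag and its correlation are returned.  A
    positive delay means events appear later in B than in A.  ``section``
    restricts the comparison to a time window of A (ground-truth events);
    B must cover that window padded by ``max_lag`` on each side.
    """
    dt = 1.0 / rate
    if section is None:
        section = (env_a.t[0], env_a.t[-1])
    s0, s1 = section
    s0 = max(s0, env_a.t[0])
    s1 = min(s1, env_a.t[-1])
    if s1 - s0 < 2 * dt:
        raise ValueError("section too short")
    if env_b.t[0] > s0 - max_lag or env_b.t[-1] < s1 + max_lag:
        raise ValueError("stream B does not cover the section padded by max_lag")
    ts = np.arange(s0, s1 + dt / 2, dt)
    a = np.interp(ts, env_a.t, env_a.v)
    max_shift = int(round(max_lag / dt))
    tb = np.arange(s0 - max_lag, s1 + max_lag + dt / 2, dt)
    b = np.interp(tb, env_b.t, env_b.v)
    offset = max_shift  # index in tb of time s0
    corrs = _pearson_lags(a, b, offset, max_shift)
    best = int(np.argmax(corrs))
    delay = (best - max_shift) * dt
    return float(delay), float(corrs[best])


def update_delay(state: SyncState, delay: float, corr: float,
                 gate: float = 0.70) -> SyncState:
    """Replace the delay estimate only when the correlation clears the gate.

    The decision (accepted or not) is appended to the state's log either
    way, so gate behaviour is auditable.
    """
    if not -1.0 - 1e-9 <= corr <= 1.0 + 1e-9:
        raise ValueError("correlation must lie in [-1, 1]")
    accepted = corr > gate
    entry = {"delay": float(delay), "corr": float(corr), "accepted": accepted}
    new_log = state.log + (entry,)
    if accepted:
        return replace(state, delay=float(delay), last_corr=float(corr), log=new_log)
    return replace(state, last_corr=float(corr), log=new_log)


def apply_compensation(series, state: SyncState):
    """Shift timestamps back by the estimated plus nominal processing delay."""
    if not np.isfinite(state.delay):
        raise ValueError("delay estimate is not finite")
    nominal = getattr(series, "nominal_delay", 0.0)
    shift = state.delay + nominal
    if isinstance(series, TimestampedSeries):
        return replace(series, t=series.t - shift)
    if isinstance(series, AccelTrace):
        return AccelTrace(series.t - shift, series.ax, series.ay, series.az,
                          fs=series.fs)
    raise TypeError(f"unsupported series type {type(series).__name__}")


def synchronize(premise_env: TimestampedSeries, wearable_env: TimestampedSeries,
                state: SyncState, max_lag: float = 3.0,
                quantile: float = 0.95, min_history: float = 5.0,
                gate: float = 0.70) -> SyncState:
    """One detect → estimate → update cycle.

    Salient sections are detected on the wearable envelope; the strongest
    one is cross-correlated against the premise envelope and the gated
    delay update applied.  Returns the (possibly unchanged) new state.
    """
    sections = detect_salient_sections(wearable_env, state, quantile=quantile,
                                       min_history=min_history)
    if not sections:
        return state
    peak = max(sections,
               key=lambda s: float(np.max(
                   wearable_env.v[(wearable_env.t >= s[0]) & (wearable_env.t <= s[1])])))
    # screen the premise history for the wearable's salient pattern: the
    # reference window is the wearable section plus a little context, so the
    # correlation is dominated by the matched event itself
    pad = 0.5
    s0 = max(peak[0] - pad, wearable_env.t[0], premise_env.t[0] + max_lag)
    s1 = min(peak[1] + pad, wearable_env.t[-1], premise_env.t[-1] - max_lag)
    if s1 - s0 < 0.5:
        return state  # not enough overlap to attempt an estimate
    # lag by which the premise stream trails the wearable = minus the
    # wearable's own delay relative to the premise clock
    lag, corr = estimate_delay(wearable_env, premise_env, max_lag,
                               section=(s0, s1))
    return update_delay(state, -lag, corr, gate=gate)
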