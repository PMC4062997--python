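"""Wearable-sensor signal processing.

Covers the accelerometer preprocessing chain used before activity
classification (offset removal, 0.2 s smoothing, per-subject amplitude
normalization, unit-range mapping, fourfold decimation 100 Hz -> 25 Hz),
threshold-based fall detection on the absolute axis sum, Pan–Tompkins QRS
detection and heart-rate estimation for single-lead ECG, GPS ground-speed
estimation, and per-axis summary statistics of acceleration strips.

All accelerations are in g, timestamps in seconds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "AccelTrace",
    "ProcessedAccel",
    "SignalTrace",
    "TraceSummary",
    "QRSResult",
    "subtract_offset",
    "smooth",
    "normalize_subject",
    "to_unit_range",
    "decimate",
    "preprocess",
    "detect_fall",
    "pan_tompkins_qrs",
    "gps_speed",
    "summarize_trace",
    "read_accel_csv",
    "write_accel_csv",
    "read_signal_csv",
    "read_gps_csv",
]


def _as_channels(t, x, y, z):
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (len(t) == len(x) == len(y) == len(z)):
        raise ValueError("channel lengths differ")
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("timestamps must be strictly increasing")
    return t, x, y, z


@dataclass(frozen=True)
class AccelTrace:
    """3-axis accelerometer strip: timestamps (s) and accelerations (g)."""

    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    fs: float = 100.0

    def __post_init__(self):
        t, x, y, z = _as_channels(self.t, self.ax, self.ay, self.az)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "ax", x)
        object.__setattr__(self, "ay", y)
        object.__setattr__(self, "az", z)
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def channels(self) -> np.ndarray:
        """(n, 3) array of [ax ay az]."""
        return np.column_stack([self.ax, self.ay, self.az])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "x": self.ax, "y": self.ay, "z": self.az})


@dataclass(frozen=True)
class ProcessedAccel:
    """Fully preprocessed [x y z] feature trace, values in [0, 1], 25 Hz."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    fs: float = 25.0

    def __post_init__(self):
        t, x, y, z = _as_channels(self.t, self.x, self.y, self.z)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "z", z)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def channels(self) -> np.ndarray:
        return np.column_stack([self.x, self.y, self.z])


@dataclass(frozen=True)
class SignalTrace:
    """Generic single-channel trace (e.g., single-lead ECG)."""

    t: np.ndarray
    v: np.ndarray
    fs: float

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
class TraceSummary:
    """Per-axis MEAN / STD / MIN / MAX of an acceleration strip (in g)."""

    table: pd.DataFrame  # rows ACCX/ACCY/ACCZ, columns MEAN STD MIN MAX

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


@dataclass(frozen=True)
class QRSResult:
    beat_indices: np.ndarray
    beat_times: np.ndarray
    heart_rate_bpm: float  # NaN when undefined
    undefined: bool = False


# ---------------------------------------------------------------------------
# accelerometer preprocessing chain (in the order it is applied)
# ---------------------------------------------------------------------------

def subtract_offset(trace: AccelTrace, baseline: tuple[float, float] = (0.0, 10.0),
                    min_duration: float = 10.0) -> AccelTrace:
    """Remove the per-axis local offset.

    The offset of each axis is its average over a motionless baseline window
    (``baseline`` in seconds on the trace's own timeline, 10 s by default)
    and is subtracted from the whole axis.
    """
    t0, t1 = baseline
    if t1 - t0 < min_duration:
        raise ValueError(f"baseline window must span at least {min_duration} s")
    sel = (trace.t >= t0) & (trace.t < t1)
    if not np.any(sel):
        raise ValueError("baseline window lies outside the trace")
    if trace.t[sel][-1] - trace.t[sel][0] < min_duration - 2.0 / trace.fs:
        raise ValueError(f"baseline segment shorter than {min_duration} s")
    return replace(
        trace,
        ax=trace.ax - trace.ax[sel].mean(),
        ay=trace.ay - trace.ay[sel].mean(),
        az=trace.az - trace.az[sel].mean(),
    )


def _moving_average(v: np.ndarray, w: int) -> np.ndarray:
    # centered window; edges use the shrunken overlap so length is preserved
    kernel = np.ones(w)
    num = np.convolve(v, kernel, mode="same")
    den = np.convolve(np.ones_like(v), kernel, mode="same")
    return num / den


def smooth(trace: AccelTrace, window: float = 0.2) -> AccelTrace:
    """Centered moving average over ``window`` seconds (distortion removal)."""
    if window <= 0:
        raise ValueError("window must be positive")
    w = int(round(window * trace.fs))
    if w < 2:
        raise ValueError("window must cover at least 2 samples")
    if w % 2 == 0:
        w += 1  # keep the window symmetric around the sample
    return replace(
        trace,
        ax=_moving_average(trace.ax, w),
        ay=_moving_average(trace.ay, w),
        az=_moving_average(trace.az, w),
    )


def normalize_subject(traces: list[AccelTrace]) -> tuple[list[AccelTrace], float]:
    """Per-subject amplitude normalization.

    Every sample of every trace in the subject's corpus is divided by the
    maximal absolute value found across *all* of that subject's measurements,
    so afterwards max |value| over the corpus is 1.  Returns the scaled
    corpus and the scale used.
    """
    if not traces:
        raise ValueError("empty corpus")
    scale = max(float(np.max(np.abs(tr.channels))) for tr in traces)
    if scale == 0:
        raise ValueError("all-zero corpus cannot be normalized")
    out = [replace(tr, ax=tr.ax / scale, ay=tr.ay / scale, az=tr.az / scale)
           for tr in traces]
    return out, scale


def to_unit_range(trace: AccelTrace) -> ProcessedAccel:
    """Affine map of subject-normalized values from [-1, 1] into [0, 1]."""
    ch = trace.channels
    if np.min(ch) < -1 - 1e-12 or np.max(ch) > 1 + 1e-12:
        raise ValueError("input must lie within [-1, 1]; run normalize_subject first")
    f = lambda v: np.clip((v + 1.0) / 2.0, 0.0, 1.0)
    return ProcessedAccel(t=trace.t, x=f(trace.ax), y=f(trace.ay), z=f(trace.az),
                          fs=trace.fs)


def decimate(trace, factor: int = 4):
    """Keep every ``factor``-th sample starting at index 0; fs /= factor.

    Plain subsampling: the preceding 0.2 s moving average already acts as the
    low-pass stage.  Works on AccelTrace and ProcessedAccel alike.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError("factor must be an integer >= 1")
    factor = int(factor)
    if factor == 1:
        return trace
    fields = {f.name: getattr(trace, f.name) for f in dataclasses.fields(trace)}
    out = {}
    for name, val in fields.items():
        if isinstance(val, np.ndarray):
            out[name] = val[::factor]
        elif name == "fs":
            out[name] = val / factor
        else:
            out[name] = val
    return type(trace)(**out)


def preprocess(trace: AccelTrace, corpus: list[AccelTrace] | None = None,
               baseline: tuple[float, float] = (0.0, 10.0),
               window: float = 0.2, factor: int = 4) -> ProcessedAccel:
    """Full feature chain: offset -> smooth -> subject-normalize -> [0,1] -> decimate.

    ``corpus`` is the subject's full set of measurements used for amplitude
    normalization; when omitted the trace itself is the corpus.
    """
    stage = smooth(subtract_offset(trace, baseline), window)
    if corpus is None:
        corpus_stage = [stage]
    else:
        corpus_stage = [smooth(subtract_offset(tr, baseline), window) for tr in corpus]
        if not any(tr is trace for tr in corpus):
            corpus_stage.append(stage)
    scale = max(float(np.max(np.abs(tr.channels))) for tr in corpus_stage)
    if scale == 0:
        raise ValueError("all-zero corpus cannot be normalized")
    stage = replace(stage, ax=stage.ax / scale, ay=stage.ay / scale, az=stage.az / scale)
    return decimate(to_unit_range(stage), factor)


# ---------------------------------------------------------------------------
# fall detection
# ---------------------------------------------------------------------------

def detect_fall(trace: AccelTrace, trigger: float = 2.5,
                refractory: float = 1.0) -> list[float]:
    """Times where the absolute three-axis sum |ax|+|ay|+|az| exceeds ``trigger``.

    Consecutive exceedances within ``refractory`` seconds are merged into a
    single event (reported at the first exceedance).
    """
    if trigger <= 0:
        raise ValueError("trigger must be positive")
    s = np.abs(trace.ax) + np.abs(trace.ay) + np.abs(trace.az)
    above = np.flatnonzero(s > trigger)
    events: list[float] = []
    for i in above:
        ti = float(trace.t[i])
        if not events or ti - events[-1] > refractory:
            events.append(ti)
    return events


# ---------------------------------------------------------------------------
# Pan–Tompkins QRS detection
# ---------------------------------------------------------------------------

def pan_tompkins_qrs(ecg: SignalTrace, f_lo: float = 5.0, f_hi: float = 15.0,
                     integration_window: float = 0.150,
                     refractory: float = 0.2) -> QRSResult:
    """QRS detection: bandpass -> derivative -> squaring -> moving-window
    integration -> adaptive dual-threshold peak picking.

    The bandpass (5–15 Hz) isolates QRS energy; the 150 ms integration window
    matches the typical QRS width.  Signal/noise running estimates (SPKI/NPKI)
    set the detection threshold adaptively.  Heart rate is 60 / median RR.
    """
    fs = ecg.fs
    if fs < 100:
        raise ValueError("sampling rate must be >= 100 Hz")
    n = len(ecg)
    if n / fs < 5.0:
        raise ValueError("trace shorter than 5 s")

    v = ecg.v - np.mean(ecg.v)
    if np.allclose(v, 0):
        return QRSResult(np.array([], int), np.array([]), float("nan"), undefined=True)

    sos = sps.butter(2, [f_lo, f_hi], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, v)
    deriv = np.gradient(bp) * fs
    sq = deriv ** 2
    w = max(1, int(round(integration_window * fs)))
    integ = np.convolve(sq, np.ones(w) / w, mode="same")

    # candidate peaks, at least one refractory period apart
    dist = max(1, int(round(refractory * fs)))
    peaks, _ = sps.find_peaks(integ, distance=dist)
    if len(peaks) == 0:
        return QRSResult(np.array([], int), np.array([]), float("nan"), undefined=True)

    # adaptive dual-threshold (SPKI/NPKI) scan
    init = integ[: int(2 * fs)]
    spki = float(np.max(init)) * 0.6
    npki = float(np.mean(init)) * 0.5
    beats: list[int] = []
    for p in peaks:
        thr = npki + 0.25 * (spki - npki)
        if integ[p] > thr:
            beats.append(p)
            spki = 0.125 * integ[p] + 0.875 * spki
        else:
            npki = 0.125 * integ[p] + 0.875 * npki

    # refine each detection to the dominant R deflection of the bandpassed
    # signal inside the integration window (zero-phase filtering keeps R in place)
    half = w
    refined = []
    for p in beats:
        lo = max(0, p - half)
        hi = min(n, p + half + 1)
        refined.append(lo + int(np.argmax(np.abs(bp[lo:hi]))))
    refined_arr = np.unique(np.asarray(refined, dtype=int))

    beat_times = ecg.t[refined_arr]
    if len(refined_arr) < 2:
        return QRSResult(refined_arr, beat_times, float("nan"), undefined=True)
    rr = np.diff(beat_times)
    hr = 60.0 / float(np.median(rr))
    return QRSResult(refined_arr, beat_times, hr, undefined=False)


# ---------------------------------------------------------------------------
# GPS speed
# ---------------------------------------------------------------------------

_EARTH_RADIUS_M = 6371000.0


def _haversine_m(lat1, lon1, lat2, lon2):
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return 2 * _EARTH_RADIUS_M * np.arcsin(np.sqrt(a))


def gps_speed(track: pd.DataFrame) -> pd.DataFrame:
    """Ground speed (m/s) between consecutive GPS fixes.

    ``track`` needs columns ``t`` (s), ``lat``, ``lon`` (degrees).  Returns a
    frame with the midpoint time of each consecutive pair and the haversine
    distance divided by the time delta (non-negative by construction).
    """
    if len(track) < 2:
        raise ValueError("need at least 2 GPS fixes")
    t = track["t"].to_numpy(dtype=float)
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("duplicate or non-increasing timestamps in GPS track")
    lat = track["lat"].to_numpy(dtype=float)
    lon = track["lon"].to_numpy(dtype=float)
    dist = _haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:])
    return pd.DataFrame({"t": (t[:-1] + t[1:]) / 2, "speed": dist / dt})


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def summarize_trace(trace: AccelTrace) -> TraceSummary:
    """Per-axis MEAN, STD (sample, n-1), MIN, MAX in g."""
    if len(trace) == 0:
        raise ValueError("empty trace")
    rows = {}
    for name, ch in (("ACCX", trace.ax), ("ACCY", trace.ay), ("ACCZ", trace.az)):
        rows[name] = {
            "MEAN": float(np.mean(ch)),
            "STD": float(np.std(ch, ddof=1)) if len(ch) > 1 else 0.0,
            "MIN": float(np.min(ch)),
            "MAX": float(np.max(ch)),
        }
    return TraceSummary(pd.DataFrame(rows).T[["MEAN", "STD", "MIN", "MAX"]])


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_accel_csv(path, fs: float | None = None) -> AccelTrace:
    df = pd.read_csv(path)
    t = df["t"].to_numpy(dtype=float)
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 100.0
    return AccelTrace(t, df["x"].to_numpy(float), df["y"].to_numpy(float),
                      df["z"].to_numpy(float), fs=fs)


def write_accel_csv(trace: AccelTrace, path) -> None:
    trace.to_frame().to_csv(path, index=False)


def read_signal_csv(path, fs: float | None = None) -> SignalTrace:
    df = pd.read_csv(path)
    t = df["t"].to_numpy(dtype=float)
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    return SignalTrace(t, df["v"].to_numpy(float), fs=fs)


def read_gps_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)[["t", "lat", "lon"]]
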