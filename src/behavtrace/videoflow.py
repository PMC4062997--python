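"""Optical-flow pose features from premise-embedded cameras.

Pipeline: dense Horn–Schunck optical flow between frame pairs three frames
apart (120 ms at 25 fps), binarization of the flow modulus with a constant
threshold, silhouette recovery as the intersection of two consecutive
binarized flows, a ~4 px dilated edge band around the silhouette contour,
and an 8-bin histogram of flow directions (B1..B8, centers 0°, 45°, ...,
315°) restricted to that band.  Stacking the histograms over flow steps
gives the time-angle representation of a movie.

Angle convention: the image y axis points down, so the direction of a flow
vector (u, v) is atan2(-v, u) — 0° is motion toward the right of the scene
(bin B1) and 180° toward the left (bin B5).
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

__all__ = [
    "FrameSequence",
    "FlowField",
    "SilhouetteMask",
    "DirectionHistogram",
    "TimeAngleMatrix",
    "select_frame_pairs",
    "compute_optical_flow",
    "binarize_flow",
    "silhouette_from_masks",
    "edge_band",
    "direction_histogram",
    "time_angle_representation",
    "disk_element",
    "read_frame_dir",
    "write_frame_dir",
]

#: Default binarization threshold for |OF| (px per frame-pair interval).
#: Small enough to catch slow movers in synthetic scenes; tune per camera.
DEFAULT_FLOW_THRESHOLD = 0.3

#: Bin centers in degrees, B1..B8.
BIN_CENTERS = np.arange(8) * 45.0


@dataclass(frozen=True)
class FrameSequence:
    """Ordered grayscale frames (n, H, W) with their frame rate."""

    frames: np.ndarray
    fps: float = 25.0

    def __post_init__(self):
        frames = np.asarray(self.frames, dtype=float)
        if frames.ndim != 3:
            raise ValueError("frames must be a (n, H, W) array")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        object.__setattr__(self, "frames", frames)

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_size(self) -> tuple[int, int]:
        """(width, height) in pixels."""
        return self.frames.shape[2], self.frames.shape[1]


@dataclass(frozen=True)
class FlowField:
    """Per-pixel motion (u right, v down) in px per frame-pair interval."""

    u: np.ndarray
    v: np.ndarray

    def __post_init__(self):
        u = np.asarray(self.u, dtype=float)
        v = np.asarray(self.v, dtype=float)
        if u.shape != v.shape:
            raise ValueError("u and v shapes differ")
        if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
            raise ValueError("flow must be finite")
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "v", v)

    @property
    def modulus(self) -> np.ndarray:
        return np.hypot(self.u, self.v)

    @property
    def shape(self):
        return self.u.shape


@dataclass(frozen=True)
class SilhouetteMask:
    """Binary silhouette plus the flow-step indices it was built from."""

    mask: np.ndarray
    provenance: tuple[int, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))


@dataclass(frozen=True)
class DirectionHistogram:
    """Normalized 8-bin flow-direction histogram (B1..B8).

    ``undetermined`` is set when no flow pixel contributed (all bins zero).
    """

    bins: np.ndarray
    undetermined: bool = False

    def __post_init__(self):
        b = np.asarray(self.bins, dtype=float)
        if b.shape != (8,):
            raise ValueError("histogram must have 8 bins")
        object.__setattr__(self, "bins", b)

    @property
    def argmax_bin(self) -> int:
        """1-based index of the dominant bin (B1..B8)."""
        return int(np.argmax(self.bins)) + 1


@dataclass(frozen=True)
class TimeAngleMatrix:
    """Rows = bins B1..B8, columns = flow step index n."""

    matrix: np.ndarray
    pairs: tuple[tuple[int, int], ...]
    undetermined: tuple[bool, ...] = field(default=())

    @property
    def n_steps(self) -> int:
        return self.matrix.shape[1]


def select_frame_pairs(n_frames: int, stride: int = 3, span: int = 3) -> list[tuple[int, int]]:
    """Frame pairs (n*stride, n*stride + span), 1-based, for n = 1, 2, ...

    Pairs are emitted while the second frame number stays within the movie.
    A movie too short for a single pair yields an empty list.
    """
    pairs = []
    n = 1
    while n * stride + span <= n_frames:
        pairs.append((n * stride, n * stride + span))
        n += 1
    return pairs


def _hs_derivatives(a: np.ndarray, b: np.ndarray):
    # first-order forward differences averaged over the 2x2x2 cube of the
    # two-frame volume (classic estimator for a first-order scheme)
    kx = np.array([[-1.0, 1.0], [-1.0, 1.0]]) * 0.25
    ky = np.array([[-1.0, -1.0], [1.0, 1.0]]) * 0.25
    kt = np.array([[1.0, 1.0], [1.0, 1.0]]) * 0.25
    mode = "nearest"
    ix = ndimage.correlate(a, kx, mode=mode) + ndimage.correlate(b, kx, mode=mode)
    iy = ndimage.correlate(a, ky, mode=mode) + ndimage.correlate(b, ky, mode=mode)
    it = ndimage.correlate(b, kt, mode=mode) - ndimage.correlate(a, kt, mode=mode)
    return ix, iy, it


_HS_AVG_KERNEL = np.array([
    [1 / 12, 1 / 6, 1 / 12],
    [1 / 6, 0.0, 1 / 6],
    [1 / 12, 1 / 6, 1 / 12],
])


def compute_optical_flow(frame_a: np.ndarray, frame_b: np.ndarray,
                         alpha: float = 1.0, n_iter: int = 100,
                         tol: float = 1e-4,
                         return_energy: bool = False):
    """Dense Horn–Schunck optical flow between two grayscale frames.

    Minimizes the sum of the linearized brightness-constancy residual and an
    ``alpha``-weighted smoothness term via Jacobi iterations; gradients use
    first-order finite differences.  Iterations stop after ``n_iter`` rounds
    or when the mean flow update falls below ``tol``.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frame sizes differ")
    ix, iy, it = _hs_derivatives(a, b)
    u = np.zeros_like(a)
    v = np.zeros_like(a)
    denom = alpha ** 2 + ix ** 2 + iy ** 2
    energies: list[float] = []
    for _ in range(n_iter):
        u_avg = ndimage.correlate(u, _HS_AVG_KERNEL, mode="nearest")
        v_avg = ndimage.correlate(v, _HS_AVG_KERNEL, mode="nearest")
        coef = (ix * u_avg + iy * v_avg + it) / denom
        u_new = u_avg - ix * coef
        v_new = v_avg - iy * coef
        delta = float(np.mean(np.abs(u_new - u) + np.abs(v_new - v)))
        u, v = u_new, v_new
        if return_energy:
            data = (ix * u + iy * v + it) ** 2
            gu = np.gradient(u)
            gv = np.gradient(v)
            smoothness = gu[0] ** 2 + gu[1] ** 2 + gv[0] ** 2 + gv[1] ** 2
            energies.append(float(np.sum(data + alpha ** 2 * smoothness)))
        if delta < tol:
            break
    flow = FlowField(u, v)
    if return_energy:
        return flow, energies
    return flow


def binarize_flow(flow: FlowField, threshold: float = DEFAULT_FLOW_THRESHOLD) -> np.ndarray:
    """Moving-object mask: pixels whose |OF| reaches the constant threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return flow.modulus >= threshold


def silhouette_from_masks(mask_n: np.ndarray, mask_n_plus_1: np.ndarray,
                          provenance: tuple[int, ...] = ()) -> SilhouetteMask:
    """Silhouette as the common part of two consecutive binarized flows."""
    m1 = np.asarray(mask_n, dtype=bool)
    m2 = np.asarray(mask_n_plus_1, dtype=bool)
    if m1.shape != m2.shape:
        raise ValueError("mask shapes differ")
    return SilhouetteMask(m1 & m2, provenance)


def disk_element(radius: int) -> np.ndarray:
    """Disk structuring element approximated on the pixel grid."""
    r = int(radius)
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return (xx ** 2 + yy ** 2) <= r ** 2


def edge_band(silhouette: SilhouetteMask | np.ndarray, band_px: int = 4) -> np.ndarray:
    """Silhouette contour dilated to a band about ``band_px`` pixels wide.

    The contour is the silhouette minus its erosion (inner boundary); the
    band is its morphological dilation with a disk of radius band_px // 2.
    An empty silhouette yields an empty band.
    """
    if band_px < 1:
        raise ValueError("band_px must be >= 1")
    mask = silhouette.mask if isinstance(silhouette, SilhouetteMask) else np.asarray(silhouette, bool)
    if not mask.any():
        return np.zeros_like(mask)
    eroded = ndimage.binary_erosion(mask, structure=np.ones((3, 3), bool),
                                    border_value=0)
    contour = mask & ~eroded
    radius = max(1, band_px // 2)
    return ndimage.binary_dilation(contour, structure=disk_element(radius))


def direction_histogram(flow: FlowField, band: np.ndarray) -> DirectionHistogram:
    """Normalized histogram of flow directions inside the edge band.

    Each contributing pixel's angle atan2(-v, u) falls in the bin whose
    center (0°, 45°, ..., 315°) is nearest; bin i covers
    [45(i-1) - 22.5°, 45(i-1) + 22.5°).  Counts are unweighted (the
    magnitude is already gated by binarization) and L1-normalized.
    """
    band = np.asarray(band, dtype=bool)
    if band.shape != flow.shape:
        raise ValueError("band and flow shapes differ")
    sel = band & (flow.modulus > 0)
    if not sel.any():
        return DirectionHistogram(np.zeros(8), undetermined=True)
    ang = np.degrees(np.arctan2(-flow.v[sel], flow.u[sel])) % 360.0
    idx = np.floor((ang + 22.5) / 45.0).astype(int) % 8
    counts = np.bincount(idx, minlength=8).astype(float)
    return DirectionHistogram(counts / counts.sum(), undetermined=False)


def time_angle_representation(seq: FrameSequence, stride: int = 3, span: int = 3,
                              threshold: float = DEFAULT_FLOW_THRESHOLD,
                              band_px: int = 4, alpha: float = 1.0,
                              n_iter: int = 100) -> TimeAngleMatrix:
    """Histogram column per flow step: the movie's time-angle representation.

    Flow step n (pair n*stride, n*stride + span) is masked by the silhouette
    obtained from its own binarized flow intersected with the next step's
    (the last step reuses its predecessor), then summarized as a direction
    histogram.  Static stretches yield all-zero columns.
    """
    pairs = select_frame_pairs(len(seq), stride, span)
    if len(pairs) < 2:
        raise ValueError("need at least 2 frame pairs")
    flows = [compute_optical_flow(seq.frames[i - 1], seq.frames[j - 1],
                                  alpha=alpha, n_iter=n_iter)
             for i, j in pairs]
    masks = [binarize_flow(fl, threshold) for fl in flows]
    cols = []
    flags = []
    for n, fl in enumerate(flows):
        partner = n + 1 if n + 1 < len(masks) else n - 1
        sil = silhouette_from_masks(masks[n], masks[partner], provenance=(n, partner))
        band = edge_band(sil, band_px)
        h = direction_histogram(fl, band)
        cols.append(h.bins)
        flags.append(h.undetermined)
    return TimeAngleMatrix(np.column_stack(cols), tuple(pairs), tuple(flags))


# ---------------------------------------------------------------------------
# frame-directory I/O (zero-padded PNGs + JSON manifest)
# ---------------------------------------------------------------------------

def write_frame_dir(seq: FrameSequence, out_dir) -> None:
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for k, frame in enumerate(seq.frames):
        img = np.clip(frame * 255.0, 0, 255).astype(np.uint8)
        iio.imwrite(out / f"frame_{k:06d}.png", img)
    w, h = seq.frame_size
    manifest = {"fps": seq.fps, "frame_size": [w, h], "n_frames": len(seq)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_frame_dir(in_dir) -> FrameSequence:
    src = pathlib.Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    files = sorted(src.glob("frame_*.png"))
    frames = np.stack([iio.imread(f).astype(float) / 255.0 for f in files])
    return FrameSequence(frames, fps=manifest["fps"])
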