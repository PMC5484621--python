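"""Frame-differencing locomotor activity.

The behavioral readout is deliberately simple and shape-agnostic: two frames
separated by a differencing interval (5 s or 60 s) are subtracted pixel by
pixel, the absolute difference is normalized by the mean intensity of the
two frames over the well ROI, smoothed with a Gaussian filter (sigma = 1 px)
to suppress sensor noise, and thresholded at 0.25; the number of ROI pixels
above threshold is the *activity* of that frame pair.  Highly mobile animals
change many pixels, quiescent or dead animals change none.

Conventions
-----------
* The absolute difference is used, so activity is symmetric in frame order.
* The normalization denominator is the scalar mean of ``(I_a + I_b) / 2``
  over the well ROI (per-well, not whole-frame), which makes unevenly
  illuminated wells comparable.  A whole-frame denominator is available via
  ``norm_scope="frame"``.
* Activity is invariant under a global rescaling of both frames (dark-field
  gain changes) because the numerator and denominator scale together.
* Differencing pairs advance at the native frame step, so 60-s pairs overlap
  (sliding); this makes "maximum 60-s activity inside a window" well defined.
  Disjoint pairing is available via ``sliding=False``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError
from .geometry import WellMap

__all__ = [
    "FrameStack",
    "ActivityTrace",
    "normalized_difference",
    "activity_between",
    "trace_for_interval",
    "traces_to_frame",
]

logger = logging.getLogger(__name__)

#: binary threshold on the smoothed normalized intensity change
DEFAULT_THRESHOLD = 0.25
#: Gaussian smoothing width in pixels
DEFAULT_SIGMA = 1.0
#: pairing tolerance, as a fraction of the native frame interval
PAIRING_TOLERANCE = 0.4


@dataclass
class FrameStack:
    """An ordered, timestamped grayscale image sequence.

    ``frames`` is a ``(T, H, W)`` array (any integer or float dtype);
    ``timestamps`` are seconds, strictly increasing.
    """

    frames: np.ndarray
    timestamps: np.ndarray
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ConfigurationError("frames must be a (T, H, W) array")
        if len(self.timestamps) != len(self.frames):
            raise ConfigurationError("one timestamp per frame required")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ConfigurationError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def frame_interval_s(self) -> float:
        if len(self.timestamps) < 2:
            raise ValueError("need >= 2 frames to infer a frame interval")
        return float(np.median(np.diff(self.timestamps)))

    def select(self, t0: float, t1: float) -> "FrameStack":
        """Sub-stack of frames with ``t0 <= t < t1``."""
        keep = (self.timestamps >= t0) & (self.timestamps < t1)
        return FrameStack(self.frames[keep], self.timestamps[keep], self.bit_depth)

    @classmethod
    def from_tiff(
        cls,
        path,
        timestamps=None,
        frame_interval_s: float | None = None,
        t0: float = 0.0,
    ) -> "FrameStack":
        """Read a multi-page TIFF.

        Timestamps come from a sidecar CSV with columns
        ``frame_index, time_s`` (or ``unix_time_s``), an explicit array, or a
        constant ``frame_interval_s`` starting at ``t0``.
        """
        frames = tifffile.imread(str(path))
        if frames.ndim == 2:
            frames = frames[None]
        if timestamps is not None and not isinstance(timestamps, (list, np.ndarray)):
            tbl = pd.read_csv(timestamps)
            col = "time_s" if "time_s" in tbl.columns else "unix_time_s"
            ts = tbl.sort_values("frame_index")[col].to_numpy(dtype=float)
        elif timestamps is not None:
            ts = np.asarray(timestamps, dtype=float)
        elif frame_interval_s is not None:
            ts = t0 + frame_interval_s * np.arange(len(frames))
        else:
            raise ConfigurationError("provide timestamps or frame_interval_s")
        bit_depth = 16 if frames.dtype.itemsize > 1 else 8
        return cls(frames, ts, bit_depth)

    @classmethod
    def from_directory(cls, directory, frame_interval_s: float, t0: float = 0.0) -> "FrameStack":
        """Read numerically ordered PNG/TIFF frames from a directory."""
        import imageio.v3 as iio

        paths = sorted(
            p for p in Path(directory).iterdir()
            if p.suffix.lower() in {".png", ".tif", ".tiff"}
        )
        if not paths:
            raise ConfigurationError(f"no image frames found in {directory}")
        frames = np.stack([np.asarray(iio.imread(p)) for p in paths])
        if frames.ndim == 4:  # RGB -> grayscale by mean
            frames = frames.mean(axis=-1)
        ts = t0 + frame_interval_s * np.arange(len(frames))
        return cls(frames, ts)


@dataclass
class ActivityTrace:
    """Per-well activity time series at a stated differencing interval.

    ``times`` are the midpoints of each frame pair (seconds); ``pair_starts``
    and ``pair_ends`` retain the actual pair endpoints, which downstream
    windowing (pre/post stimulus) needs.  ``values`` are non-negative
    changed-pixel counts bounded by the ROI pixel count.
    """

    well_index: int
    interval_s: float
    times: np.ndarray
    values: np.ndarray
    pair_starts: np.ndarray = field(default=None)  # type: ignore[assignment]
    pair_ends: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values)
        if self.pair_starts is None:
            self.pair_starts = self.times - self.interval_s / 2.0
        if self.pair_ends is None:
            self.pair_ends = self.times + self.interval_s / 2.0
        self.pair_starts = np.asarray(self.pair_starts, dtype=float)
        self.pair_ends = np.asarray(self.pair_ends, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("activity values must be non-negative")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("trace times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)

    @classmethod
    def from_pairs(cls, well_index, interval_s, pair_starts, values) -> "ActivityTrace":
        starts = np.asarray(pair_starts, dtype=float)
        ends = starts + interval_s
        return cls(well_index, interval_s, (starts + ends) / 2.0, np.asarray(values),
                   starts, ends)


def _roi_mean(frame_a: np.ndarray, frame_b: np.ndarray, roi) -> float:
    """Mean of the frame-average image over the ROI (scalar denominator)."""
    a = frame_a[roi].astype(np.float64)
    b = frame_b[roi].astype(np.float64)
    return float((a.mean() + b.mean()) / 2.0)


def normalized_difference(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    roi: tuple[np.ndarray, np.ndarray],
    norm_scope: str = "well",
) -> np.ndarray:
    """Full-frame map of ``|I_b - I_a|`` / (mean ROI intensity of the pair).

    The map is computed over the whole frame (so that subsequent smoothing
    has spatial context at the ROI boundary) but normalized by the scalar
    mean intensity over ``roi`` — or over the whole frame when
    ``norm_scope="frame"``.  Symmetric in ``(frame_a, frame_b)`` and
    invariant to scaling both frames by a common constant.

    Blank input (zero mean intensity) is a flagged-degenerate case: a
    warning is emitted and an all-zero map returned, so downstream activity
    is zero rather than NaN.
    """
    if frame_a.shape != frame_b.shape:
        raise ValueError("frames must share dimensions")
    a = frame_a.astype(np.float64)
    b = frame_b.astype(np.float64)
    if norm_scope == "frame":
        denom = float((a.mean() + b.mean()) / 2.0)
    elif norm_scope == "well":
        if len(roi[0]) == 0:
            raise ValueError("empty ROI")
        denom = _roi_mean(a, b, roi)
    else:
        raise ValueError(f"unknown norm_scope {norm_scope!r}")
    if denom <= 0:
        warnings.warn(
            "blank frame pair (zero mean intensity); activity defined as 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.zeros_like(a)
    return np.abs(b - a) / denom


def activity_between(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    roi: tuple[np.ndarray, np.ndarray],
    sigma_px: float = DEFAULT_SIGMA,
    threshold: float = DEFAULT_THRESHOLD,
    norm_scope: str = "well",
) -> int:
    """Changed-pixel count for one frame pair over one well ROI.

    Pipeline order: absolute difference -> normalize by mean pair intensity
    -> Gaussian smooth (``sigma_px``) -> binary threshold -> count ROI pixels
    above threshold.
    """
    if sigma_px < 0:
        raise ValueError("sigma_px must be >= 0")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    diff = normalized_difference(frame_a, frame_b, roi, norm_scope=norm_scope)
    smooth = gaussian_filter(diff, sigma_px) if sigma_px > 0 else diff
    return int(np.count_nonzero(smooth[roi] > threshold))


def _pair_indices(
    timestamps: np.ndarray, interval_s: float, sliding: bool, tol_s: float
) -> list[tuple[int, int]]:
    """Indices (i, j) with ``t_j ~= t_i + interval`` within tolerance."""
    pairs = []
    i = 0
    n = len(timestamps)
    while i < n:
        target = timestamps[i] + interval_s
        j = int(np.searchsorted(timestamps, target))
        best = None
        for cand in (j - 1, j):
            if cand <= i or cand >= n:
                continue
            err = abs(timestamps[cand] - target)
            if err <= tol_s and (best is None or err < abs(timestamps[best] - target)):
                best = cand
        if best is not None:
            pairs.append((i, best))
            i = best if not sliding else i + 1
        else:
            logger.debug("no frame within tolerance of t=%.1f s; pair skipped", target)
            i += 1
    return pairs


def trace_for_interval(
    stack: FrameStack,
    well_map: WellMap,
    interval_s: float,
    sigma_px: float = DEFAULT_SIGMA,
    threshold: float = DEFAULT_THRESHOLD,
    sliding: bool = True,
    intensity_bounds: tuple[float, float] | None = None,
) -> list[ActivityTrace]:
    """Activity traces (one per well) at the requested differencing interval.

    Frame pairs ``(t, t + interval_s)`` are matched within ±40% of the native
    frame interval and advance at the native frame step (overlapping pairs)
    unless ``sliding=False``.  Pairs without a partner frame are skipped and
    logged.  ``intensity_bounds``, when given, drops pairs whose whole-frame
    mean intensity falls outside ``(lo, hi)`` (blank/overexposed frames) —
    dropped, never silently zeroed.

    Implementation note: smoothing is linear, so the smoothed normalized map
    is evaluated as ``gaussian_filter(|diff|)`` once per pair and compared
    with ``threshold * roi_mean`` per well; this matches
    :func:`activity_between` up to floating-point rounding at exact
    threshold ties.
    """
    if len(stack) < 2:
        raise ValueError("need at least two frames")
    native = stack.frame_interval_s
    if interval_s < native:
        raise ValueError("differencing interval shorter than frame spacing")
    tol = PAIRING_TOLERANCE * native
    pairs = _pair_indices(stack.timestamps, interval_s, sliding, tol)
    rois = well_map.roi_indices(stack.frame_shape)
    frames = stack.frames
    ts = stack.timestamps

    starts: list[float] = []
    per_well: list[list[int]] = [[] for _ in range(well_map.n_wells)]
    for i, j in pairs:
        a = frames[i].astype(np.float32)
        b = frames[j].astype(np.float32)
        if intensity_bounds is not None:
            m = float((a.mean() + b.mean()) / 2.0)
            if not intensity_bounds[0] <= m <= intensity_bounds[1]:
                logger.info("pair (%.0f, %.0f s) dropped: mean intensity %.1f", ts[i], ts[j], m)
                continue
        smooth = gaussian_filter(np.abs(b - a), sigma_px) if sigma_px > 0 else np.abs(b - a)
        starts.append(float(ts[i]))
        for w, roi in enumerate(rois):
            m = _roi_mean(a, b, roi)
            if m <= 0:
                warnings.warn(
                    f"blank ROI (well {w}) at t={ts[i]:.0f}s; activity defined as 0",
                    RuntimeWarning,
                    stacklevel=2,
                )
                per_well[w].append(0)
            else:
                per_well[w].append(int(np.count_nonzero(smooth[roi] > threshold * m)))

    starts_arr = np.asarray(starts)
    out = []
    for w in range(well_map.n_wells):
        out.append(
            ActivityTrace.from_pairs(w, interval_s, starts_arr, np.asarray(per_well[w], dtype=int))
        )
    return out


def traces_to_frame(traces: list[ActivityTrace], plate_id: str = "plate") -> pd.DataFrame:
    """Tidy export: one row per (well, pair)."""
    chunks = []
    for tr in traces:
        chunks.append(
            pd.DataFrame(
                {
                    "plate_id": plate_id,
                    "well_index": tr.well_index,
                    "interval_s": tr.interval_s,
                    "time_s": tr.times,
                    "activity_px": tr.values,
                }
            )
        )
    return pd.concat(chunks, ignore_index=True)
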