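"""Effector trajectories and the two kinematic statistics.

The palm is the centroid of the pinky, index and wrist landmarks; the trunk
is the centroid of both shoulders and both hips; the shoulder effector is the
paretic-side shoulder landmark itself.  Two statistics summarize a block:

* **bivariate variable error (BVE)** — the root-mean-square Euclidean
  deviation of a 2D point set from its own centroid,

      BVE = sqrt( (1/n) * sum_i ((x_i - x_c)^2 + (y_i - y_c)^2) ),

  i.e. BVE^2 equals the population variance of x plus the population
  variance of y.  It captures summed positional variability across both
  directions; here it is computed over the continuous position data of a
  whole block, not per-trial endpoints.

* **framewise / mean speed** — the Euclidean distance between consecutive
  frames divided by the frame period (exactly 1/fps), averaged over the
  block.

All quantities are in pixels and pixels/second (single-camera 2D capture;
no metric calibration is assumed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .errors import EmptySeriesError, InsufficientFramesError, ValidationError
from .landmark_io import LandmarkSeries

_EFFECTOR_LANDMARKS = {
    "palm": ("pinky", "index", "wrist"),
    "trunk": ("shoulder_left", "shoulder_right", "hip_left", "hip_right"),
}


@dataclass
class PointTrack:
    """A single effector's 2D trajectory within one block.

    ``xy`` is an (n, 2) pixel array.  ``frame_index`` (optional) carries the
    source frame numbers so that speed computations can recognize
    discontinuities left by dropped frames.
    """

    label: str
    xy: np.ndarray
    fps: float
    frame_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=np.float64)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValidationError(f"xy must be (n, 2), got shape {self.xy.shape}")
        if self.fps <= 0:
            raise ValidationError(f"fps must be > 0, got {self.fps}")
        if not np.isfinite(self.xy).all():
            raise ValidationError("track coordinates must be finite")
        if self.frame_index is not None:
            self.frame_index = np.asarray(self.frame_index, dtype=np.int64)
            if self.frame_index.shape != (len(self.xy),):
                raise ValidationError("frame_index length must match xy")

    @property
    def n(self) -> int:
        return len(self.xy)


def _effector_track(series: LandmarkSeries, label: str, landmarks: tuple[str, ...]) -> PointTrack:
    if series.n_frames == 0:
        raise EmptySeriesError(f"cannot build {label} track from an empty series")
    cols = np.stack([series.column(name) for name in landmarks])  # (k, n, 2)
    return PointTrack(label, cols.mean(axis=0), series.fps, series.frame_index)


def palm_track(series: LandmarkSeries) -> PointTrack:
    """Palm effector: per-frame mean of pinky, index and wrist positions."""
    return _effector_track(series, "palm", _EFFECTOR_LANDMARKS["palm"])


def trunk_track(series: LandmarkSeries) -> PointTrack:
    """Trunk effector: per-frame mean of both shoulders and both hips."""
    return _effector_track(series, "trunk", _EFFECTOR_LANDMARKS["trunk"])


def shoulder_track(series: LandmarkSeries, side: str) -> PointTrack:
    """The paretic-side shoulder landmark positions, unmodified."""
    if side not in ("L", "R"):
        raise ValidationError(f"side must be 'L' or 'R', got {side!r}")
    if series.n_frames == 0:
        raise EmptySeriesError("cannot build shoulder track from an empty series")
    name = "shoulder_left" if side == "L" else "shoulder_right"
    return PointTrack("shoulder", series.column(name), series.fps, series.frame_index)


def centroid(track: PointTrack) -> np.ndarray:
    """Component-wise mean position (x_c, y_c) of the track."""
    if track.n == 0:
        raise EmptySeriesError("centroid of an empty track")
    return track.xy.mean(axis=0)


def bve(track: PointTrack) -> float:
    """Bivariate variable error of the track about its own centroid (pixels).

    Uses population (1/n) normalization; the reference point is the mean
    position of the same points.
    """
    if track.n == 0:
        raise EmptySeriesError("BVE of an empty track")
    d = track.xy - track.xy.mean(axis=0)
    return float(np.sqrt(np.mean(np.einsum("ij,ij->i", d, d))))


def framewise_speed(track: PointTrack) -> np.ndarray:
    """Per-step speeds (pixels/second): Euclidean step length times fps.

    Returns n-1 values; the elapsed time per step is taken as exactly 1/fps
    regardless of frame-index gaps (see :func:`mean_speed` for gap handling).
    """
    if track.n < 2:
        raise InsufficientFramesError(f"framewise speed needs >= 2 frames, got {track.n}")
    steps = np.diff(track.xy, axis=0)
    return np.hypot(steps[:, 0], steps[:, 1]) * track.fps


def mean_speed(track: PointTrack, exclude_gaps: bool = True) -> float:
    """Mean of the framewise speeds (pixels/second).

    When the track carries frame indices and ``exclude_gaps`` is true, steps
    spanning a dropped-frame boundary (frame-index difference > 1) are
    excluded: such steps cover an unknown true path and would otherwise
    register as spurious velocity spikes.
    """
    speeds = framewise_speed(track)
    if exclude_gaps and track.frame_index is not None:
        contiguous = np.diff(track.frame_index) == 1
        speeds = speeds[contiguous]
        if len(speeds) == 0:
            raise InsufficientFramesError("no contiguous frame pairs for mean speed")
    return float(speeds.mean())


def median_filter(track: PointTrack, kernel: int = 5) -> PointTrack:
    """Optional per-coordinate median filter (off by default everywhere);
    kernel must be odd."""
    if kernel % 2 != 1 or kernel < 1:
        raise ValidationError(f"kernel must be a positive odd integer, got {kernel}")
    xy = np.column_stack(
        [scipy.signal.medfilt(track.xy[:, 0], kernel), scipy.signal.medfilt(track.xy[:, 1], kernel)]
    )
    return PointTrack(track.label, xy, track.fps, track.frame_index)
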