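"""Landmark time-series and participant-metadata I/O.

The package tracks eight body landmarks per frame: pinky, index and wrist of
the paretic hand, the paretic elbow, both shoulders and both hips.  Series are
stored in image coordinates (pixels, origin top-left, y increasing downward)
at a fixed frame rate.

Two plain-text dialects are defined here:

* landmark CSV — one row per (frame, landmark) with header
  ``participant_id,day,block,frame,fps,landmark,x,y,visibility``;
* participant CSV — one row per participant with header
  ``participant_id,age,sex,time_since_stroke_months,hemisphere,fma_ue``.

An adapter ingests raw 33-landmark full-body pose-estimator output
(normalized coordinates plus a per-landmark visibility score) and reduces it
to the eight landmarks of interest, resolving the hand side from the
participant's paretic side.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import EmptySeriesError, FormatError, ValidationError

#: Canonical landmark order; every array in a LandmarkSeries uses this column
#: order.  Hand landmarks (pinky/index/wrist/elbow) refer to the paretic side.
LANDMARK_NAMES: tuple[str, ...] = (
    "pinky",
    "index",
    "wrist",
    "elbow",
    "shoulder_left",
    "shoulder_right",
    "hip_left",
    "hip_right",
)

# Indices into the 33-point full-body pose convention.  Side-dependent
# landmarks map (left, right) source indices; the hand side is resolved per
# participant from the paretic side.
_POSE33_SIDED = {
    "pinky": {"L": 17, "R": 18},
    "index": {"L": 19, "R": 20},
    "wrist": {"L": 15, "R": 16},
    "elbow": {"L": 13, "R": 14},
}
_POSE33_FIXED = {
    "shoulder_left": 11,
    "shoulder_right": 12,
    "hip_left": 23,
    "hip_right": 24,
}

LANDMARK_CSV_COLUMNS = (
    "participant_id",
    "day",
    "block",
    "frame",
    "fps",
    "landmark",
    "x",
    "y",
    "visibility",
)
PARTICIPANT_CSV_COLUMNS = (
    "participant_id",
    "age",
    "sex",
    "time_since_stroke_months",
    "hemisphere",
    "fma_ue",
)


def pose33_indices(paretic_side: str) -> dict[str, int]:
    """Map each tracked landmark name to its index in the 33-point convention.

    ``paretic_side`` ('L' or 'R') selects the source side for the hand
    landmarks; shoulders and hips are side-fixed.
    """
    if paretic_side not in ("L", "R"):
        raise ValidationError(f"paretic_side must be 'L' or 'R', got {paretic_side!r}")
    out = {name: sides[paretic_side] for name, sides in _POSE33_SIDED.items()}
    out.update(_POSE33_FIXED)
    return out


@dataclass
class ParticipantInfo:
    """Demographics and impairment for one participant.

    ``fma_ue`` is the upper-extremity Fugl-Meyer score (0-66, higher = less
    impaired).  The paretic side is contralateral to the lesioned hemisphere
    and is derived, not stored independently.
    """

    participant_id: str
    age: float
    sex: str
    time_since_stroke_months: float
    hemisphere_of_stroke: str
    fma_ue: int

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValidationError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if self.hemisphere_of_stroke not in ("L", "R"):
            raise ValidationError(
                f"hemisphere_of_stroke must be 'L' or 'R', got {self.hemisphere_of_stroke!r}"
            )
        if not 0 <= self.fma_ue <= 66:
            raise ValidationError(f"fma_ue must be in [0, 66], got {self.fma_ue}")

    @property
    def paretic_side(self) -> str:
        return "R" if self.hemisphere_of_stroke == "L" else "L"


@dataclass
class LandmarkSeries:
    """Time-indexed 2D positions (+ visibility) for the 8 tracked landmarks
    of one block recording.

    ``x``, ``y`` and ``visibility`` are ``(n_frames, 8)`` float arrays with
    columns ordered as :data:`LANDMARK_NAMES`; coordinates are pixels in image
    convention.  ``frame_index`` is strictly increasing but need not be
    contiguous (preprocessing may drop frames).
    """

    participant_id: str
    day: int
    block: int
    fps: float
    frame_index: np.ndarray
    x: np.ndarray
    y: np.ndarray
    visibility: np.ndarray
    n_interpolated: int = 0
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=np.int64)
        for name in ("x", "y", "visibility"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))

    @property
    def n_frames(self) -> int:
        return len(self.frame_index)

    def validate(self) -> None:
        n = self.n_frames
        k = len(LANDMARK_NAMES)
        if self.fps <= 0:
            raise ValidationError(f"fps must be > 0, got {self.fps}")
        for name in ("x", "y", "visibility"):
            arr = getattr(self, name)
            if arr.shape != (n, k):
                raise ValidationError(f"{name} has shape {arr.shape}, expected {(n, k)}")
        if n and np.any(np.diff(self.frame_index) <= 0):
            raise ValidationError("frame_index must be strictly increasing")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValidationError("x and y must be finite")
        if np.any(self.visibility < 0) or np.any(self.visibility > 1):
            raise ValidationError("visibility must lie in [0, 1]")

    def column(self, landmark: str) -> np.ndarray:
        """Return the (n, 2) xy trajectory of one landmark."""
        j = LANDMARK_NAMES.index(landmark)
        return np.column_stack([self.x[:, j], self.y[:, j]])

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format view: one row per (frame, landmark)."""
        n, k = self.n_frames, len(LANDMARK_NAMES)
        return pd.DataFrame(
            {
                "participant_id": np.repeat(self.participant_id, n * k),
                "day": np.repeat(self.day, n * k),
                "block": np.repeat(self.block, n * k),
                "frame": np.repeat(self.frame_index, k),
                "fps": np.repeat(self.fps, n * k),
                "landmark": np.tile(np.array(LANDMARK_NAMES, dtype=object), n),
                "x": self.x.ravel(),
                "y": self.y.ravel(),
                "visibility": self.visibility.ravel(),
            }
        )


def _series_from_group(key, g: pd.DataFrame) -> LandmarkSeries:
    pid, day, block = key
    fps_vals = g["fps"].unique()
    if len(fps_vals) != 1:
        raise ValidationError(
            f"fps not constant within block {pid!r} day {day} block {block}: {sorted(fps_vals)}"
        )
    if g.duplicated(["frame", "landmark"]).any():
        raise ValidationError(
            f"duplicate (frame, landmark) rows in {pid!r} day {day} block {block}"
        )
    frames = np.sort(g["frame"].unique())
    n, k = len(frames), len(LANDMARK_NAMES)
    x = np.zeros((n, k))
    y = np.zeros((n, k))
    vis = np.zeros((n, k))
    row = pd.Series(np.arange(n), index=frames)
    col = {name: j for j, name in enumerate(LANDMARK_NAMES)}
    i = row[g["frame"]].to_numpy()
    j = g["landmark"].map(col).to_numpy()
    x[i, j] = g["x"].to_numpy()
    y[i, j] = g["y"].to_numpy()
    vis[i, j] = g["visibility"].to_numpy()
    # (frame, landmark) combinations absent from the file keep visibility 0
    # and are treated as missing by preprocess().
    series = LandmarkSeries(
        participant_id=str(pid),
        day=int(day),
        block=int(block),
        fps=float(fps_vals[0]),
        frame_index=frames,
        x=x,
        y=y,
        visibility=vis,
    )
    series.validate()
    return series


def read_landmark_csv(
    path: str | Path, frame_range: tuple[int, int] | None = None
) -> list[LandmarkSeries]:
    """Read a landmark CSV into one :class:`LandmarkSeries` per
    (participant, day, block) group.

    ``frame_range`` optionally restricts ingestion to frame indices in
    ``[start, stop)`` (recordings are otherwise assumed pre-trimmed to the
    task interval).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in LANDMARK_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"landmark CSV {path} is missing column(s): {', '.join(missing)}")
    unknown = set(df["landmark"].unique()) - set(LANDMARK_NAMES)
    if unknown:
        raise ValidationError(
            f"unknown landmark name(s) {sorted(unknown)}; expected one of {LANDMARK_NAMES}"
        )
    if frame_range is not None:
        lo, hi = frame_range
        df = df[(df["frame"] >= lo) & (df["frame"] < hi)]
    out = []
    for key, g in df.groupby(["participant_id", "day", "block"], sort=True):
        out.append(_series_from_group(key, g))
    return out


def write_landmark_csv(series: Sequence[LandmarkSeries], path: str | Path) -> None:
    """Write series to the landmark CSV dialect (round-trips exactly:
    floats are emitted with shortest round-trip representation)."""
    if series:
        df = pd.concat([s.to_frame() for s in series], ignore_index=True)
    else:
        df = pd.DataFrame(columns=list(LANDMARK_CSV_COLUMNS))
    df.to_csv(path, index=False)


def read_participants_csv(path: str | Path) -> list[ParticipantInfo]:
    df = pd.read_csv(path)
    missing = [c for c in PARTICIPANT_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"participant CSV {path} is missing column(s): {', '.join(missing)}")
    return [
        ParticipantInfo(
            participant_id=str(r.participant_id),
            age=float(r.age),
            sex=str(r.sex),
            time_since_stroke_months=float(r.time_since_stroke_months),
            hemisphere_of_stroke=str(r.hemisphere),
            fma_ue=int(r.fma_ue),
        )
        for r in df.itertuples()
    ]


def write_participants_csv(participants: Sequence[ParticipantInfo], path: str | Path) -> None:
    pd.DataFrame(
        {
            "participant_id": [p.participant_id for p in participants],
            "age": [p.age for p in participants],
            "sex": [p.sex for p in participants],
            "time_since_stroke_months": [p.time_since_stroke_months for p in participants],
            "hemisphere": [p.hemisphere_of_stroke for p in participants],
            "fma_ue": [p.fma_ue for p in participants],
        }
    ).to_csv(path, index=False)


def reference_cohort() -> list[ParticipantInfo]:
    """The seven-participant sub-acute/chronic stroke cohort used throughout
    the documentation and examples (ages 67-79, FMA-UE 40-66)."""
    rows = [
        ("P1", 76, "F", 57, "L", 60),
        ("P2", 79, "F", 157, "R", 60),
        ("P3", 73, "M", 2, "L", 62),
        ("P4", 79, "M", 128, "R", 60),
        ("P5", 67, "F", 261, "L", 40),
        ("P6", 77, "M", 50, "R", 66),
        ("P7", 77, "F", 157, "R", 63),
    ]
    return [
        ParticipantInfo(pid, age, sex, tss, hemi, fma)
        for pid, age, sex, tss, hemi, fma in rows
    ]


def adapt_pose33(
    raw: Iterable[dict],
    info: ParticipantInfo,
    fps: float,
    frame_size: tuple[int, int],
    day: int = 1,
    block: int = 1,
) -> LandmarkSeries:
    """Reduce raw 33-landmark pose-estimator frames to a LandmarkSeries.

    ``raw`` yields records ``{"frame": i, "landmarks": [{"x", "y",
    "visibility"} x 33]}`` with normalized coordinates in [0, 1].  The eight
    landmarks of interest are selected (hand side resolved from
    ``info.paretic_side``) and coordinates converted to pixels by scaling
    with the frame width/height.  Frames missing a required landmark are kept
    with visibility 0 so that downstream preprocessing handles them.
    """
    width, height = frame_size
    if width <= 0 or height <= 0:
        raise ValidationError(f"frame width/height must be > 0, got {frame_size}")
    idx = pose33_indices(info.paretic_side)
    order = [idx[name] for name in LANDMARK_NAMES]
    records = sorted(raw, key=lambda r: r["frame"])
    n, k = len(records), len(LANDMARK_NAMES)
    frames = np.empty(n, dtype=np.int64)
    x = np.zeros((n, k))
    y = np.zeros((n, k))
    vis = np.zeros((n, k))
    for i, rec in enumerate(records):
        frames[i] = rec["frame"]
        lms = rec["landmarks"]
        for j, src in enumerate(order):
            if src < len(lms) and lms[src] is not None:
                lm = lms[src]
                x[i, j] = float(lm["x"]) * width
                y[i, j] = float(lm["y"]) * height
                vis[i, j] = float(lm.get("visibility", 1.0))
            # else: flagged missing (visibility stays 0)
    series = LandmarkSeries(info.participant_id, day, block, float(fps), frames, x, y, vis)
    series.validate()
    return series


def read_pose33_jsonl(path: str | Path) -> list[dict]:
    """Read pose-estimator per-frame records serialized as JSON lines."""
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]


def _interpolate_column(
    xy: np.ndarray, vis: np.ndarray, frame_index: np.ndarray, missing: np.ndarray, max_gap: int
) -> np.ndarray:
    """Fill interior missing runs of length <= max_gap in-place (linear in
    frame index); return boolean mask of samples actually filled."""
    filled = np.zeros(len(missing), dtype=bool)
    n = len(missing)
    i = 0
    while i < n:
        if not missing[i]:
            i += 1
            continue
        j = i
        while j < n and missing[j]:
            j += 1
        # run [i, j); interior only, bounded by valid samples
        if i > 0 and j < n and (j - i) <= max_gap:
            t0, t1 = frame_index[i - 1], frame_index[j]
            w = (frame_index[i:j] - t0) / (t1 - t0)
            xy[i:j, 0] = xy[i - 1, 0] + w * (xy[j, 0] - xy[i - 1, 0])
            xy[i:j, 1] = xy[i - 1, 1] + w * (xy[j, 1] - xy[i - 1, 1])
            vis[i:j] = vis[i - 1] + w * (vis[j] - vis[i - 1])
            filled[i:j] = True
            missing[i:j] = False
        i = j
    return filled


def preprocess(
    series: LandmarkSeries,
    visibility_threshold: float = 0.5,
    max_gap: int = 5,
) -> LandmarkSeries:
    """Confidence-gate, gap-fill and complete a landmark series.

    Samples with visibility strictly below ``visibility_threshold`` are
    treated as missing.  Interior missing runs of at most ``max_gap`` frames
    per landmark are linearly interpolated; frames still missing any landmark
    are dropped.  With threshold 0 the operation is the identity.  The output
    records how many retained frames contain interpolated samples
    (``n_interpolated``) and how many frames were dropped (``n_dropped``).
    """
    series.validate()
    n, k = series.n_frames, len(LANDMARK_NAMES)
    x = series.x.copy()
    y = series.y.copy()
    vis = series.visibility.copy()
    missing = vis < visibility_threshold
    interp_frames = np.zeros(n, dtype=bool)
    for j in range(k):
        xy = np.column_stack([x[:, j], y[:, j]])
        col_missing = missing[:, j].copy()
        filled = _interpolate_column(xy, vis[:, j], series.frame_index, col_missing, max_gap)
        x[:, j], y[:, j] = xy[:, 0], xy[:, 1]
        missing[:, j] = col_missing
        interp_frames |= filled
    keep = ~missing.any(axis=1)
    n_dropped = int((~keep).sum())
    if not keep.any():
        raise EmptySeriesError(
            f"all {n} frames dropped in {series.participant_id!r} "
            f"day {series.day} block {series.block}"
        )
    out = replace(
        series,
        frame_index=series.frame_index[keep],
        x=x[keep],
        y=y[keep],
        visibility=np.clip(vis[keep], 0.0, 1.0),
        n_interpolated=int((interp_frames & keep).sum()),
        n_dropped=n_dropped,
    )
    out.validate()
    return out
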