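"""Synthetic reaching sessions with known ground-truth kinematics.

The generator emulates a multi-session gamified reaching protocol: each
participant completes several days of practice, each day split into blocks of
target-directed paretic-arm reaches recorded by a single fixed camera as 2D
landmark time series.  It exists so that every pipeline stage — ingest,
preprocessing, effector extraction, block statistics and group models — can
be exercised against analytically known quantities; it does not attempt
biomechanical realism.

Movement model
--------------
Each reach drives the palm from its current position to a random target
inside a calibrated workspace rectangle along a straight line with the
canonical minimum-jerk position fraction

    p(tau) = 10 tau^3 - 15 tau^4 + 6 tau^5,   tau = t / T.

Reach amplitudes and durations are Gaussian per reach; a per-day speed gain
divides durations, emulating faster reaching with practice.  Proximal
"compensation" is modelled by coupling: the trunk translates by
``trunk_coupling`` times the palm displacement (its own minimum-jerk profile,
inherited from the palm), and the paretic shoulder additionally moves by
``shoulder_coupling`` times the palm displacement on top of the trunk.
Couplings vary across participants and are constructed to correlate
negatively with the impairment score (FMA-UE): more impaired participants
lean more.

The eight landmarks sit at fixed body offsets from the palm and trunk.  The
three hand landmarks are offset symmetrically (their centroid is exactly the
simulated palm path) and share a single per-frame jitter vector — a pose
estimator localizes the hand as a unit, so its finger/wrist estimates shake
coherently — while the elbow, shoulders and hips receive independent
isotropic Gaussian jitter of the same standard deviation.  Consequently a
stationary palm with jitter sigma has BVE exactly sqrt(2)*sigma in
expectation, as does a single jittered landmark; the four-landmark trunk
centroid averages four independent jitters and has jitter-only BVE
sqrt(2)*sigma/2.

All randomness derives from ``SimConfig.seed`` through per-(participant,
day, block) seed-sequence spawn keys, so identical configurations produce
bit-identical output and per-block quantities can be regenerated in
isolation.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import UnsupportedConfigurationError, ValidationError
from .landmark_io import (
    LANDMARK_NAMES,
    LandmarkSeries,
    ParticipantInfo,
    write_landmark_csv,
    write_participants_csv,
)


@dataclass
class SimConfig:
    """Study-protocol and movement-model parameters.

    Defaults mirror the emulated protocol: 5 days x 5 blocks x 200 reaches
    per block (1000 per session, 5000 per participant overall), 30 Hz
    sampling of a 1920x1080 frame.
    """

    n_participants: int = 7
    days: int = 5
    blocks_per_day: int = 5
    movements_per_block: int = 200
    fps: float = 30.0
    frame_size: tuple[int, int] = (1920, 1080)
    reach_amplitude: tuple[float, float] = (150.0, 30.0)  # pixels (mean, SD)
    reach_duration: tuple[float, float] = (0.8, 0.15)  # seconds (mean, SD)
    jitter_sd: float = 2.0  # pixels
    trunk_coupling: float = 0.08
    shoulder_coupling: float = 0.15
    day_speed_gain: float = 1.1
    participant_sd: float = 0.02
    fma_ue_range: tuple[int, int] = (40, 66)
    dwell_frames: int = 0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_participants", "days", "blocks_per_day", "movements_per_block"):
            if int(getattr(self, name)) < 1:
                raise ValidationError(f"{name} must be a positive integer, got {getattr(self, name)}")
        if self.fps <= 0:
            raise ValidationError(f"fps must be > 0, got {self.fps}")
        if self.frame_size[0] <= 0 or self.frame_size[1] <= 0:
            raise ValidationError(f"frame_size must be positive, got {self.frame_size}")
        for name in ("trunk_coupling", "shoulder_coupling"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.reach_amplitude[1] < 0 or self.reach_duration[1] < 0:
            raise ValidationError("reach_amplitude / reach_duration SDs must be >= 0")
        if self.reach_duration[0] <= 0:
            raise ValidationError(f"reach_duration mean must be > 0, got {self.reach_duration[0]}")
        if self.jitter_sd < 0:
            raise ValidationError(f"jitter_sd must be >= 0, got {self.jitter_sd}")
        if self.day_speed_gain <= 0:
            raise ValidationError(f"day_speed_gain must be > 0, got {self.day_speed_gain}")
        if self.participant_sd < 0:
            raise ValidationError(f"participant_sd must be >= 0, got {self.participant_sd}")
        lo, hi = self.fma_ue_range
        if not (0 <= lo <= hi <= 66):
            raise ValidationError(f"fma_ue_range must satisfy 0 <= lo <= hi <= 66, got {self.fma_ue_range}")
        if self.dwell_frames < 0:
            raise ValidationError(f"dwell_frames must be >= 0, got {self.dwell_frames}")

    # protocol arithmetic ---------------------------------------------------
    @property
    def movements_per_session(self) -> int:
        return self.blocks_per_day * self.movements_per_block

    @property
    def movements_total(self) -> int:
        """Movements per participant across the whole protocol."""
        return self.days * self.movements_per_session


@dataclass
class GroundTruth:
    """Analytic per-block and per-participant quantities of a simulated cohort."""

    expected_jitter_bve_palm: float
    expected_jitter_bve_shoulder: float
    expected_jitter_bve_trunk: float
    participants: dict[str, dict]
    blocks: list[dict]

    def block(self, participant_id: str, day: int, block: int) -> dict:
        for rec in self.blocks:
            if (rec["participant_id"], rec["day"], rec["block"]) == (participant_id, day, block):
                return rec
        raise KeyError((participant_id, day, block))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def minimum_jerk_fraction(tau: np.ndarray) -> np.ndarray:
    """Position fraction of the minimum-jerk point-to-point profile."""
    tau = np.asarray(tau, dtype=np.float64)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


@dataclass
class _Traits:
    info: ParticipantInfo
    trunk_coupling: float
    shoulder_coupling: float
    home_palm: np.ndarray
    home_trunk: np.ndarray
    offsets: dict[str, np.ndarray]
    workspace: tuple[float, float, float, float]  # x0, x1, y0, y1


def _participant_traits(config: SimConfig, p_idx: int) -> _Traits:
    rng = _rng(config.seed, p_idx)
    lo, hi = config.fma_ue_range
    fma = int(rng.integers(lo, hi + 1))
    severity = (hi - fma) / (hi - lo) if hi > lo else 0.5
    c_t = float(np.clip(config.trunk_coupling * (0.5 + severity)
                        + rng.normal(0.0, config.participant_sd), 0.0, 1.0))
    c_s = float(np.clip(config.shoulder_coupling * (0.5 + severity)
                        + rng.normal(0.0, config.participant_sd), 0.0, 1.0))
    info = ParticipantInfo(
        participant_id=f"S{p_idx + 1:02d}",
        age=float(int(np.clip(rng.normal(75.0, 4.0), 40, 95))),
        sex="F" if rng.random() < 0.5 else "M",
        time_since_stroke_months=float(int(rng.integers(2, 262))),
        hemisphere_of_stroke="L" if rng.random() < 0.5 else "R",
        fma_ue=fma,
    )
    w, h = config.frame_size
    workspace = (0.35 * w, 0.90 * w, 0.15 * h, 0.80 * h)
    home_palm = np.array([(workspace[0] + workspace[1]) / 2, (workspace[2] + workspace[3]) / 2])
    home_trunk = np.array([0.22 * w, 0.55 * h])
    scale = float(rng.normal(1.0, 0.05))
    offsets = {
        # hand offsets sum to zero: palm centroid == simulated palm path
        "pinky": np.array([-12.0, 8.0]) * scale,
        "index": np.array([12.0, 8.0]) * scale,
        "wrist": np.array([0.0, -16.0]) * scale,
        "elbow": np.array([0.0, 12.0]) * scale,
        "shoulder_left": np.array([-80.0, -120.0]) * scale,
        "shoulder_right": np.array([80.0, -120.0]) * scale,
        "hip_left": np.array([-55.0, 110.0]) * scale,
        "hip_right": np.array([55.0, 110.0]) * scale,
    }
    return _Traits(info, c_t, c_s, home_palm, home_trunk, offsets, workspace)


@dataclass
class _BlockPlan:
    starts: np.ndarray  # (r, 2) reach start positions
    targets: np.ndarray  # (r, 2)
    amplitudes: np.ndarray  # (r,) actual straight-line lengths
    frames_per_reach: np.ndarray  # (r,) ints, each >= 2

    @property
    def n_frames(self) -> int:
        return int(self.frames_per_reach.sum())

    @property
    def path_length(self) -> float:
        return float(self.amplitudes.sum())


def _block_plan(config: SimConfig, traits: _Traits, p_idx: int, day: int, block: int) -> _BlockPlan:
    # keyed by (participant, block) but not day: the day enters only through
    # the speed gain, so with gain 1 the noise-free plan is day-invariant
    rng = _rng(config.seed, p_idx, block, 0)
    r = config.movements_per_block
    a_mu, a_sd = config.reach_amplitude
    t_mu, t_sd = config.reach_duration
    amps = np.clip(rng.normal(a_mu, a_sd, size=r), 0.0, None)
    durations = np.clip(rng.normal(t_mu, t_sd, size=r), 2.0 / config.fps, None)
    # practice speeds movements up: durations shrink by the per-day gain
    durations = durations / config.day_speed_gain ** (day - 1)
    frames = np.maximum(np.ceil(durations * config.fps).astype(np.int64), 2)
    x0, x1, y0, y1 = traits.workspace
    center = np.array([(x0 + x1) / 2, (y0 + y1) / 2])
    pos = traits.home_palm.copy()
    starts = np.empty((r, 2))
    targets = np.empty((r, 2))
    actual = np.empty(r)
    for i in range(r):
        starts[i] = pos
        a = amps[i]
        target = pos
        for _ in range(20):
            theta = rng.uniform(0.0, 2.0 * np.pi)
            cand = pos + a * np.array([np.cos(theta), np.sin(theta)])
            if x0 <= cand[0] <= x1 and y0 <= cand[1] <= y1:
                target = cand
                break
        else:
            # head toward the workspace centre; clamp inside if overshooting
            d = center - pos
            norm = np.hypot(*d)
            cand = pos + (a * d / norm if norm > 0 else 0.0)
            target = np.clip(cand, [x0, y0], [x1, y1])
        targets[i] = target
        actual[i] = float(np.hypot(*(target - pos)))
        pos = target
    return _BlockPlan(starts, targets, actual, frames)


def _palm_path(plan: _BlockPlan) -> np.ndarray:
    """Noise-free palm positions, one row per frame (sum of frames_per_reach)."""
    parts = []
    for i in range(len(plan.amplitudes)):
        m = plan.frames_per_reach[i]
        frac = minimum_jerk_fraction(np.linspace(0.0, 1.0, m))
        parts.append(plan.starts[i] + frac[:, None] * (plan.targets[i] - plan.starts[i]))
    return np.concatenate(parts, axis=0)


def _simulate_block(
    config: SimConfig, traits: _Traits, p_idx: int, day: int, block: int
) -> tuple[LandmarkSeries, dict]:
    plan = _block_plan(config, traits, p_idx, day, block)
    palm = _palm_path(plan)
    if config.dwell_frames:
        # hold at each reach end; appended per reach in frame order
        held = []
        k = 0
        for m in plan.frames_per_reach:
            seg = palm[k : k + m]
            held.append(seg)
            held.append(np.repeat(seg[-1:], config.dwell_frames, axis=0))
            k += m
        palm = np.concatenate(held, axis=0)
    n = len(palm)
    disp = palm - traits.home_palm
    trunk = traits.home_trunk + traits.trunk_coupling * disp
    info = traits.info
    paretic_shoulder_name = "shoulder_left" if info.paretic_side == "L" else "shoulder_right"

    jr = _rng(config.seed, p_idx, day, block, 1)
    sd = config.jitter_sd
    hand_jit = jr.normal(0.0, sd, size=(n, 2)) if sd > 0 else np.zeros((n, 2))

    k = len(LANDMARK_NAMES)
    x = np.empty((n, k))
    y = np.empty((n, k))
    shoulder_extra = traits.shoulder_coupling * disp
    clean = {}
    for name in LANDMARK_NAMES:
        off = traits.offsets[name]
        if name in ("pinky", "index", "wrist"):
            base = palm + off
        elif name == "elbow":
            sh = trunk + traits.offsets[paretic_shoulder_name] + shoulder_extra
            base = 0.5 * (palm + sh) + off
        elif name == paretic_shoulder_name:
            base = trunk + off + shoulder_extra
        else:
            base = trunk + off
        clean[name] = base
    for j, name in enumerate(LANDMARK_NAMES):
        if name in ("pinky", "index", "wrist"):
            jit = hand_jit
        elif sd > 0:
            jit = jr.normal(0.0, sd, size=(n, 2))
        else:
            jit = 0.0
        noisy = clean[name] + jit
        x[:, j] = noisy[:, 0]
        y[:, j] = noisy[:, 1]
    series = LandmarkSeries(
        participant_id=info.participant_id,
        day=day,
        block=block,
        fps=config.fps,
        frame_index=np.arange(n, dtype=np.int64),
        x=x,
        y=y,
        visibility=np.ones((n, k)),
    )
    path_bve = _point_set_bve(palm)
    truth = {
        "participant_id": info.participant_id,
        "day": day,
        "block": block,
        "n_frames": n,
        "n_reaches": int(config.movements_per_block),
        "path_length": plan.path_length,
        "noise_free_mean_speed": plan.path_length * config.fps / (n - 1) if n > 1 else 0.0,
        "palm_path_bve": path_bve,
        "trunk_bve_contribution": traits.trunk_coupling * path_bve,
        "shoulder_bve_contribution": (traits.trunk_coupling + traits.shoulder_coupling) * path_bve,
        # the measured trunk centroid also carries 1/4 of the paretic
        # shoulder's extra excursion
        "trunk_centroid_bve_contribution": (
            traits.trunk_coupling + traits.shoulder_coupling / 4.0
        ) * path_bve,
    }
    return series, truth


def _point_set_bve(xy: np.ndarray) -> float:
    d = xy - xy.mean(axis=0)
    return float(np.sqrt(np.mean(np.einsum("ij,ij->i", d, d))))


def simulate_cohort(
    config: SimConfig,
) -> tuple[list[LandmarkSeries], list[ParticipantInfo], GroundTruth]:
    """Generate a full cohort: one LandmarkSeries per (participant, day,
    block), participant metadata, and the analytic ground truth."""
    config.validate()
    series: list[LandmarkSeries] = []
    participants: list[ParticipantInfo] = []
    truth_participants: dict[str, dict] = {}
    truth_blocks: list[dict] = []
    for p_idx in range(config.n_participants):
        traits = _participant_traits(config, p_idx)
        participants.append(traits.info)
        truth_participants[traits.info.participant_id] = {
            "fma_ue": traits.info.fma_ue,
            "trunk_coupling": traits.trunk_coupling,
            "shoulder_coupling": traits.shoulder_coupling,
        }
        for day in range(1, config.days + 1):
            for block in range(1, config.blocks_per_day + 1):
                s, truth = _simulate_block(config, traits, p_idx, day, block)
                series.append(s)
                truth_blocks.append(truth)
    gt = GroundTruth(
        expected_jitter_bve_palm=math.sqrt(2.0) * config.jitter_sd,
        expected_jitter_bve_shoulder=math.sqrt(2.0) * config.jitter_sd,
        expected_jitter_bve_trunk=math.sqrt(2.0) * config.jitter_sd / 2.0,
        participants=truth_participants,
        blocks=truth_blocks,
    )
    return series, participants, gt


def expected_mean_speed(
    config: SimConfig, participant: int, day: int, block: int | None = None
) -> float:
    """Closed-form mean palm speed of the noise-free simulation.

    The minimum-jerk path of each reach is a straight segment, so the total
    path length of a block is the sum of reach amplitudes and the mean speed
    is ``path_length * fps / (n_frames - 1)``.  ``participant`` is the
    0-based participant index; with ``block=None`` the per-block values of
    that day are averaged.  Only defined for ``jitter_sd == 0`` (noise adds
    path length).
    """
    if config.jitter_sd != 0:
        raise UnsupportedConfigurationError(
            "expected_mean_speed is a noise-free oracle; set jitter_sd=0"
        )
    config.validate()
    traits = _participant_traits(config, participant)
    blocks = [block] if block is not None else list(range(1, config.blocks_per_day + 1))
    vals = []
    for b in blocks:
        plan = _block_plan(config, traits, participant, day, b)
        n = plan.n_frames + config.dwell_frames * len(plan.frames_per_reach)
        vals.append(plan.path_length * config.fps / (n - 1))
    return float(np.mean(vals))


def write_cohort(
    config: SimConfig,
    out_dir: str | Path,
) -> tuple[Path, Path, Path]:
    """Simulate a cohort and write the landmark CSV, participant CSV and
    ground-truth JSON into ``out_dir``; returns the three paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series, participants, gt = simulate_cohort(config)
    lm_path = out / "landmarks.csv"
    meta_path = out / "participants.csv"
    gt_path = out / "ground_truth.json"
    write_landmark_csv(series, lm_path)
    write_participants_csv(participants, meta_path)
    gt.to_json(gt_path)
    return lm_path, meta_path, gt_path


def simulate_outcome_table(
    n_participants: int,
    effects: dict[str, float],
    tau_participant: float = 25.0,
    tau_day: float = 4.0,
    sigma: float = 5.0,
    days: tuple[int, int] = (1, 5),
    blocks: tuple[int, int] = (1, 5),
    outcome: str = "bve_palm",
    seed: int = 0,
) -> pd.DataFrame:
    """Outcome-level cohort generator for mixed-model parameter recovery.

    Builds one row per (participant, day, block) on the endpoint grid with
    covariates ``bve_trunk`` (|N(10, 5)|), ``bve_shoulder`` (|N(20, 10)|) and
    a per-participant ``fma_ue`` drawn uniformly from 30..66, then

        y = b0 + b_day*[day=last] + b_block*[block=last]
            + b_day_block*[day=last][block=last]
            + b_trunk*trunk + b_shoulder*shoulder + b_ts*trunk*shoulder
            + b_fma*fma + u_p + u_pd + eps,

    with ``u_p ~ N(0, tau_participant)``, ``u_pd ~ N(0, tau_day)`` (one draw
    per participant-day) and ``eps ~ N(0, sigma)`` — variances given as
    variances, not SDs.  ``effects`` supplies the coefficients by key
    (``intercept``, ``day``, ``block``, ``day_block``, ``bve_trunk``,
    ``bve_shoulder``, ``trunk_shoulder``, ``fma_ue``); omitted keys are 0.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(90,)))
    e = {k: float(effects.get(k, 0.0)) for k in (
        "intercept", "day", "block", "day_block",
        "bve_trunk", "bve_shoulder", "trunk_shoulder", "fma_ue")}
    rows = []
    for p in range(n_participants):
        pid = f"S{p + 1:03d}"
        fma = int(rng.integers(30, 67))
        u_p = rng.normal(0.0, math.sqrt(tau_participant))
        for day in days:
            u_pd = rng.normal(0.0, math.sqrt(tau_day))
            for block in blocks:
                trunk = abs(rng.normal(10.0, 5.0))
                shoulder = abs(rng.normal(20.0, 10.0))
                is_day = float(day == days[-1])
                is_block = float(block == blocks[-1])
                y = (
                    e["intercept"]
                    + e["day"] * is_day
                    + e["block"] * is_block
                    + e["day_block"] * is_day * is_block
                    + e["bve_trunk"] * trunk
                    + e["bve_shoulder"] * shoulder
                    + e["trunk_shoulder"] * trunk * shoulder
                    + e["fma_ue"] * fma
                    + u_p
                    + u_pd
                    + rng.normal(0.0, math.sqrt(sigma))
                )
                rows.append(
                    {
                        "participant_id": pid,
                        "day": day,
                        "block": block,
                        "bve_trunk": trunk,
                        "bve_shoulder": shoulder,
                        "fma_ue": fma,
                        outcome: y,
                    }
                )
    return pd.DataFrame(rows)
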