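"""Per-block summaries, the group mean/SD table and change scores.

A block summary holds the four primary outcomes — palm, shoulder and trunk
BVE plus mean palm speed — together with shoulder/trunk mean speeds (computed
and stored, though only palm speed enters the group models) and the
preprocessing bookkeeping counts.

The group table reports across-participant mean and sample SD (n-1) for each
outcome in each (day, block) cell of an analysis grid; the default grid is
the endpoint design {first, last day} x {first, last block}.  Change scores
are last-minus-first-block differences per participant, joined with the
participant's impairment score.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import kinematics
from .errors import ReachkinError, ValidationError
from .landmark_io import LandmarkSeries, ParticipantInfo

OUTCOME_COLUMNS = (
    "bve_palm",
    "bve_shoulder",
    "bve_trunk",
    "mean_speed_palm",
    "mean_speed_shoulder",
    "mean_speed_trunk",
)

#: Outcomes entering the change-score records and quadrant plots.
CHANGE_OUTCOMES = ("bve_palm", "bve_shoulder", "bve_trunk", "mean_speed_palm")


@dataclass
class BlockSummary:
    """Kinematic outcomes for one (participant, day, block)."""

    participant_id: str
    day: int
    block: int
    bve_palm: float
    bve_shoulder: float
    bve_trunk: float
    mean_speed_palm: float
    mean_speed_shoulder: float
    mean_speed_trunk: float
    n_frames: int
    n_interpolated: int
    n_dropped: int


def summarize_block(series: LandmarkSeries, info: ParticipantInfo) -> BlockSummary:
    """Compute palm/shoulder/trunk tracks and their statistics for one block.

    The series must already be preprocessed (no missing landmarks).  Errors
    from the underlying operations are re-raised with the block identity
    attached.
    """
    try:
        palm = kinematics.palm_track(series)
        shoulder = kinematics.shoulder_track(series, info.paretic_side)
        trunk = kinematics.trunk_track(series)
        return BlockSummary(
            participant_id=series.participant_id,
            day=series.day,
            block=series.block,
            bve_palm=kinematics.bve(palm),
            bve_shoulder=kinematics.bve(shoulder),
            bve_trunk=kinematics.bve(trunk),
            mean_speed_palm=kinematics.mean_speed(palm),
            mean_speed_shoulder=kinematics.mean_speed(shoulder),
            mean_speed_trunk=kinematics.mean_speed(trunk),
            n_frames=series.n_frames,
            n_interpolated=series.n_interpolated,
            n_dropped=series.n_dropped,
        )
    except ReachkinError as exc:
        raise type(exc)(
            f"{exc} [participant {series.participant_id!r} day {series.day} "
            f"block {series.block}]"
        ) from exc


def summaries_to_frame(summaries: Sequence[BlockSummary]) -> pd.DataFrame:
    """One row per (participant, day, block)."""
    if not summaries:
        return pd.DataFrame(
            columns=["participant_id", "day", "block", *OUTCOME_COLUMNS,
                     "n_frames", "n_interpolated", "n_dropped"]
        )
    return pd.DataFrame([asdict(s) for s in summaries])


def _check_unique(df: pd.DataFrame) -> None:
    dup = df.duplicated(["participant_id", "day", "block"])
    if dup.any():
        rows = df.loc[dup, ["participant_id", "day", "block"]].to_records(index=False)
        raise ValidationError(f"duplicate (participant, day, block) summaries: {list(rows)}")


def group_table(
    summaries: Sequence[BlockSummary] | pd.DataFrame,
    days: Sequence[int] = (1, 5),
    blocks: Sequence[int] = (1, 5),
) -> pd.DataFrame:
    """Across-participant mean and sample SD per outcome per (day, block) cell.

    SD uses the n-1 convention and is reported as NaN when a cell holds a
    single participant.  Cells are ordered day-major.
    """
    df = summaries if isinstance(summaries, pd.DataFrame) else summaries_to_frame(summaries)
    _check_unique(df)
    df = df[df["day"].isin(days) & df["block"].isin(blocks)]
    rows = []
    for day in sorted(days):
        for block in sorted(blocks):
            cell = df[(df["day"] == day) & (df["block"] == block)]
            row: dict = {"day": day, "block": block, "n_participants": len(cell)}
            for outcome in OUTCOME_COLUMNS:
                vals = cell[outcome].to_numpy(dtype=float)
                row[f"{outcome}_mean"] = float(np.mean(vals)) if len(vals) else np.nan
                row[f"{outcome}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def change_scores(
    summaries: Sequence[BlockSummary] | pd.DataFrame,
    participants: Sequence[ParticipantInfo],
    first: tuple[int, int] = (1, 1),
    last: tuple[int, int] = (5, 5),
) -> tuple[pd.DataFrame, list[str]]:
    """Last-minus-first-block change per participant for each outcome.

    Returns ``(changes, skipped)`` where ``changes`` has one row per
    participant possessing both endpoint blocks (columns ``delta_<outcome>``
    plus ``fma_ue``) and ``skipped`` lists participants missing an endpoint
    (reported, never silently dropped).
    """
    df = summaries if isinstance(summaries, pd.DataFrame) else summaries_to_frame(summaries)
    _check_unique(df)
    fma = {p.participant_id: p.fma_ue for p in participants}
    rows, skipped = [], []
    for pid in sorted(df["participant_id"].unique()):
        sub = df[df["participant_id"] == pid]
        a = sub[(sub["day"] == first[0]) & (sub["block"] == first[1])]
        b = sub[(sub["day"] == last[0]) & (sub["block"] == last[1])]
        if len(a) != 1 or len(b) != 1:
            skipped.append(pid)
            continue
        row = {"participant_id": pid, "fma_ue": fma.get(pid, np.nan)}
        for outcome in CHANGE_OUTCOMES:
            row[f"delta_{outcome}"] = float(b[outcome].iloc[0]) - float(a[outcome].iloc[0])
        rows.append(row)
    cols = ["participant_id", *(f"delta_{o}" for o in CHANGE_OUTCOMES), "fma_ue"]
    changes = pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)
    return changes, skipped
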