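"""Figure styles for the endpoint analysis.

Trajectory panels draw palm/shoulder/trunk paths per block with the initial
trunk outline (shoulders + hips polygon); BVE bar charts cover the 2x2
endpoint grid; the change "quadrant" plot scatters per-participant change in
hand outcomes against change in proximal (trunk/shoulder) BVE, shaded by
impairment score (darker = more impaired).

Storage uses image coordinates (y down); all plots flip the y axis so that
upward on screen is upward in the figure.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from . import kinematics
from .aggregation import CHANGE_OUTCOMES
from .landmark_io import LandmarkSeries, ParticipantInfo

log = logging.getLogger(__name__)

_TRACK_COLORS = {"palm": "tab:blue", "shoulder": "tab:orange", "trunk": "tab:green"}


def _trunk_outline(series: LandmarkSeries):
    order = ("shoulder_left", "shoulder_right", "hip_right", "hip_left")
    pts = [series.column(name)[0] for name in order]
    pts.append(pts[0])
    return [p[0] for p in pts], [p[1] for p in pts]


def plot_trajectories(
    blocks: Sequence[LandmarkSeries], info: ParticipantInfo, path: str | Path
) -> Path:
    """One panel per block: palm/shoulder/trunk paths + initial trunk outline."""
    n = len(blocks)
    fig, axes = plt.subplots(1, n, figsize=(4 * n, 4), squeeze=False)
    for ax, series in zip(axes[0], blocks):
        tracks = {
            "palm": kinematics.palm_track(series),
            "shoulder": kinematics.shoulder_track(series, info.paretic_side),
            "trunk": kinematics.trunk_track(series),
        }
        for label, track in tracks.items():
            ax.plot(track.xy[:, 0], track.xy[:, 1], lw=0.5,
                    color=_TRACK_COLORS[label], label=label)
        ox, oy = _trunk_outline(series)
        ax.fill(ox, oy, color="black", alpha=0.6, zorder=0)
        ax.set_title(f"day {series.day} block {series.block}")
        ax.invert_yaxis()  # image coords: flip so up is up
        ax.set_aspect("equal")
    axes[0][0].legend(fontsize=8)
    fig.suptitle(f"{info.participant_id} (FMA-UE {info.fma_ue})")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_bve_bars(summaries: pd.DataFrame, participant_id: str, path: str | Path) -> Path:
    """Palm/shoulder/trunk BVE bars across the participant's analysed blocks."""
    sub = summaries[summaries["participant_id"] == participant_id].sort_values(["day", "block"])
    labels = [f"D{d}B{b}" for d, b in zip(sub["day"], sub["block"])]
    fig, axes = plt.subplots(1, 3, figsize=(10, 3.2), sharex=True)
    for ax, outcome in zip(axes, ("bve_palm", "bve_shoulder", "bve_trunk")):
        ax.bar(labels, sub[outcome], color="tab:gray")
        ax.set_title(outcome.replace("bve_", "BVE "))
        ax.set_ylabel("pixels")
    fig.suptitle(participant_id)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_change_quadrants(changes: pd.DataFrame, path: str | Path) -> Path | None:
    """Change in hand outcomes vs change in trunk (top) / shoulder (bottom)
    BVE, one point per participant, shaded by FMA-UE (darker = lower score).

    Returns None (with a logged warning) when the change table is empty.
    """
    if changes.empty:
        log.warning("change table is empty; quadrant plot skipped")
        return None
    hand = [o for o in CHANGE_OUTCOMES if o in ("mean_speed_palm", "bve_palm")]
    proximal = ["bve_trunk", "bve_shoulder"]
    fig, axes = plt.subplots(2, 2, figsize=(8, 8))
    sc = None
    for i, prox in enumerate(proximal):
        for j, outcome in enumerate(hand):
            ax = axes[i][j]
            sc = ax.scatter(
                changes[f"delta_{prox}"],
                changes[f"delta_{outcome}"],
                c=changes["fma_ue"],
                cmap="viridis",
                vmin=0,
                vmax=66,
                edgecolor="k",
            )
            ax.axhline(0, ls="--", c="gray", lw=0.8)
            ax.axvline(0, ls="--", c="gray", lw=0.8)
            ax.set_xlabel(f"Δ {prox}")
            ax.set_ylabel(f"Δ {outcome}")
    fig.colorbar(sc, ax=axes, label="FMA-UE (/66)", shrink=0.8)
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
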