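import numpy as np
import pytest

from reachkin import LANDMARK_NAMES, LandmarkSeries, ParticipantInfo, SimConfig, simulate_cohort


def make_series(
    positions: dict[str, np.ndarray],
    fps: float = 30.0,
    visibility: np.ndarray | None = None,
    participant_id: str = "P1",
    day: int = 1,
    block: int = 1,
) -> LandmarkSeries:
    """Build a LandmarkSeries from per-landmark (n, 2) arrays; landmarks not
    given are held at a fixed default position."""
    n = len(next(iter(positions.values())))
    defaults = {name: np.tile([100.0 + 10 * j, 200.0], (n, 1))
                for j, name in enumerate(LANDMARK_NAMES)}
    defaults.update({k: np.asarray(v, dtype=float) for k, v in positions.items()})
    x = np.column_stack([defaults[name][:, 0] for name in LANDMARK_NAMES])
    y = np.column_stack([defaults[name][:, 1] for name in LANDMARK_NAMES])
    vis = np.ones((n, len(LANDMARK_NAMES))) if visibility is None else visibility
    return LandmarkSeries(participant_id, day, block, fps, np.arange(n), x, y, vis)


@pytest.fixture
def participant() -> ParticipantInfo:
    return ParticipantInfo("P1", 70, "F", 24, "L", 55)  # paretic side R


@pytest.fixture(scope="session")
def small_cohort():
    """Full 5x5 protocol shape at 3 reaches per block: 7 participants,
    fast enough for end-to-end tests."""
    cfg = SimConfig(n_participants=7, days=5, blocks_per_day=5, movements_per_block=3, seed=42)
    series, participants, truth = simulate_cohort(cfg)
    return cfg, series, participants, truth
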