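import numpy as np
import pandas as pd
import pytest

from handmotion.session import (
    HAND_LEFT,
    HAND_RIGHT,
    N_LANDMARKS,
    Session,
    SessionMeta,
)
from handmotion.simulate import SimConfig, simulate_session


def session_from_positions(meta: SessionMeta, positions: dict) -> Session:
    """Build a session where each present hand carries all 21 landmarks at
    one point per frame.

    ``positions[hand]`` is an (n_frames, 2) array; NaN rows mean the hand is
    absent (tracking loss) at that frame.
    """
    frames, hands, lms, xs, ys = [], [], [], [], []
    for hand, pos in positions.items():
        pos = np.asarray(pos, dtype=float)
        present = np.flatnonzero(np.isfinite(pos).all(axis=1))
        frames.append(np.repeat(present, N_LANDMARKS))
        hands.append(np.full(len(present) * N_LANDMARKS, hand, dtype=object))
        lms.append(np.tile(np.arange(N_LANDMARKS), len(present)))
        xs.append(np.repeat(pos[present, 0], N_LANDMARKS))
        ys.append(np.repeat(pos[present, 1], N_LANDMARKS))
    if frames:
        records = pd.DataFrame(
            {
                "frame_index": np.concatenate(frames),
                "hand": np.concatenate(hands),
                "landmark_id": np.concatenate(lms),
                "x_px": np.round(np.concatenate(xs), 2),
                "y_px": np.round(np.concatenate(ys), 2),
            }
        )
    else:
        records = None
    return Session(meta, records).validate()


def constant_session(
    n_frames: int,
    fps: float = 30.0,
    width: int = 1920,
    height: int = 1080,
    point=None,
    hands=(HAND_LEFT, HAND_RIGHT),
) -> Session:
    """Both (or chosen) hands motionless at ``point`` for every frame."""
    point = point if point is not None else (width / 2, height / 2)
    meta = SessionMeta(
        "const", fps=fps, width_px=width, height_px=height,
        duration_s=n_frames / fps,
    )
    pos = np.tile(np.asarray(point, dtype=float), (n_frames, 1))
    return session_from_positions(meta, {hand: pos for hand in hands})


def schedule_cells(truth, hand: str, n_frames: int) -> np.ndarray:
    """Per-frame anchor cell implied by a simulator schedule."""
    cells = np.zeros(n_frames, dtype=np.int16)
    sched = truth.schedule[truth.schedule["hand"] == hand]
    for row in sched.itertuples(index=False):
        if row.start_frame >= 0:
            cells[row.start_frame : row.end_frame + 1] = row.cell
    return cells


@pytest.fixture(scope="session")
def short_sim():
    """One deterministic 60 s simulated session with its ground truth."""
    config = SimConfig(duration_s=60.0)
    session, truth = simulate_session(config, seed=7)
    return config, session, truth


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free, dropout-free simulation: occupancy equals the schedule."""
    config = SimConfig(
        duration_s=120.0,
        sigma_px=0.0,
        jitter_px=0.0,
        theta_per_s=60.0,
        dropout_p0=0.0,
        dropout_p1=0.0,
        p_null=0.0,
    )
    session, truth = simulate_session(config, seed=11)
    return config, session, truth
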