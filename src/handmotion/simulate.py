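"""Semi-Markov simulator of bimanual surgical hand-landmark streams.

The surgeon model alternates long drilling dwells in the center cell with
excursions of the dominant hand to semantically anchored cells: the
instrument table (cell 4), the microscope handles (a top-row cell, 1-3) and
the trash bin (cell 7). Dwell durations are lognormal — positive and
right-skewed, matching the large spreads seen in real cell-timing data — so
the state process is semi-Markov rather than frame-wise Markov. The
non-dominant hand stays at the field (configurable).

Within a state, the hand's occupancy landmark follows a mean-reverting
(Ornstein-Uhlenbeck) walk toward the state's anchor point: smooth, bounded
trajectories whose stationary jitter stands in for drilling micro-motion.
The other 20 landmarks hang off a fixed hand-shaped template with small
independent jitter.

Tracking loss is modelled per hand-frame: a base dropout probability plus a
brightness excess inside a disc at frame center, where microscope glare
defeats the detector. Null-handedness records are injected at a small
per-frame rate. Everything is reproducible from a single integer seed, and
every simulated session ships with its ground truth (state schedule, dropout
log, null log) for recovery testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .grid import GridSpec, make_grid
from .session import (
    HAND_LEFT,
    HAND_NONE,
    HAND_RIGHT,
    N_LANDMARKS,
    NULL_LANDMARK_ID,
    Session,
    SessionMeta,
)

STATE_DRILL = "drill"
STATE_INSTRUMENT = "instrument_change"
STATE_MICROSCOPE = "microscope_adjust"
STATE_TRASH = "trash"

_SCHEDULE_COLUMNS = (
    "hand",
    "kind",
    "cell",
    "start_s",
    "end_s",
    "start_frame",
    "end_frame",
)


@dataclass(frozen=True)
class StateParams:
    """One excursion state: anchor cell(s), lognormal dwell, entry probability.

    ``prob`` is the probability that a drilling dwell is followed by this
    excursion; the probabilities over excursion kinds may sum to < 1, the
    remainder continuing to drill.
    """

    cells: tuple
    dwell_mean_s: float
    dwell_sd_s: float
    prob: float
    dwell_min_s: float = 1.0

    def __post_init__(self):
        if not 0 <= self.prob <= 1:
            raise ValueError(f"prob must be in [0, 1], got {self.prob}")
        if self.dwell_mean_s <= 0 or self.dwell_sd_s < 0:
            raise ValueError("dwell mean must be > 0 and SD >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated procedure.

    Defaults emulate a 10-minute mastoidectomy at 30 fps on a 1920x1080
    frame: drilling dominates (~50 s dwells), with roughly four instrument
    changes (~21.5 s at the table) and four microscope adjustments (~4.4 s
    at the handles) per session, plus occasional trash visits. Dropout
    defaults give ~86% overall detection with a glare disc at frame center.
    """

    duration_s: float = 600.0
    fps: float = 30.0
    width_px: int = 1920
    height_px: int = 1080
    # drilling dwell (center cell)
    drill_dwell_mean_s: float = 50.0
    drill_dwell_sd_s: float = 20.0
    drill_dwell_min_s: float = 5.0
    # excursion states of the dominant hand
    instrument: StateParams = StateParams((4,), 21.5, 12.4, 0.40)
    microscope: StateParams = StateParams((1, 2, 3), 4.4, 5.7, 0.35)
    trash: StateParams = StateParams((7,), 5.5, 9.1, 0.25)
    # trajectory kinematics
    theta_per_s: float = 8.0     # mean-reversion rate toward the anchor
    sigma_px: float = 60.0       # diffusion, px / sqrt(s)
    jitter_px: float = 2.0       # per-landmark detector jitter (SD)
    hand_scale_px: float = 80.0  # hand-template scale
    hand_separation_px: float = 160.0  # lateral offset between the two hands
    # dropout and null detections
    dropout_p0: float = 0.08     # base per-hand-frame dropout probability
    dropout_p1: float = 0.08     # brightness excess inside the glare disc
    dropout_radius_px: float = 250.0
    p_null: float = 0.025        # null records per frame (expected)
    dominant_hand: str = HAND_RIGHT
    nondominant_excursions: bool = False

    def __post_init__(self):
        total_prob = self.instrument.prob + self.microscope.prob + self.trash.prob
        if total_prob > 1 + 1e-12:
            raise ValueError(
                f"excursion probabilities sum to {total_prob} > 1"
            )
        for name in ("dropout_p0", "dropout_p1", "p_null"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if min(self.theta_per_s, self.sigma_px, self.dropout_radius_px) < 0:
            raise ValueError("theta, sigma and dropout radius must be >= 0")
        if self.duration_s <= 0 or self.fps <= 0:
            raise ValueError("duration_s and fps must be > 0")

    @property
    def excursions(self) -> dict:
        return {
            STATE_INSTRUMENT: self.instrument,
            STATE_MICROSCOPE: self.microscope,
            STATE_TRASH: self.trash,
        }

    @property
    def nondominant_hand(self) -> str:
        return HAND_LEFT if self.dominant_hand == HAND_RIGHT else HAND_RIGHT

    @classmethod
    def from_dict(cls, payload: dict) -> "SimConfig":
        """Build from a plain mapping (e.g. a parsed YAML config file)."""
        payload = dict(payload)
        for key in ("instrument", "microscope", "trash"):
            if key in payload and isinstance(payload[key], dict):
                sub = dict(payload[key])
                if "cells" in sub:
                    sub["cells"] = tuple(sub["cells"])
                payload[key] = StateParams(**sub)
        return cls(**payload)


@dataclass
class SimGroundTruth:
    """What actually happened in a simulated session.

    schedule
        one row per state visit: hand, kind, anchor cell, start/end seconds
        (half-open, tiling [0, duration_s] per hand) and the inclusive frame
        span; filled by :func:`state_schedule`.
    detected
        per hand, a boolean array over frames — False marks dropout; filled
        by :func:`render_session`.
    null_frames
        frame indices carrying injected null records.
    """

    schedule: pd.DataFrame
    detected: dict = field(default_factory=dict)
    null_frames: np.ndarray = field(
        default_factory=lambda: np.array([], dtype=np.int64)
    )

    def excursions(self, hand: str = None) -> pd.DataFrame:
        sub = self.schedule[self.schedule["kind"] != STATE_DRILL]
        if hand is not None:
            sub = sub[sub["hand"] == hand]
        return sub.reset_index(drop=True)


def lognormal_params(mean: float, sd: float) -> tuple:
    """(mu, sigma) of a lognormal with the given mean and SD."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - 0.5 * sigma2, math.sqrt(sigma2)


def sample_dwell(
    mean_s: float, sd_s: float, rng: np.random.Generator, size=None
):
    """Lognormal dwell draws with the requested first two moments."""
    mu, sigma = lognormal_params(mean_s, sd_s)
    return rng.lognormal(mu, sigma, size=size)


def _hand_states(config: SimConfig, rng: np.random.Generator, excursions: bool):
    """Alternating drill/excursion states tiling [0, duration_s].

    The schedule always begins and ends in drilling: an excursion that would
    overflow the session is replaced by drilling to the end, so scheduled
    excursions are never truncated below their minimum dwell.
    """
    duration = config.duration_s
    kinds = list(config.excursions)
    probs = np.array([config.excursions[k].prob for k in kinds])
    states = []
    t = 0.0
    while t < duration:
        dwell = max(
            sample_dwell(config.drill_dwell_mean_s, config.drill_dwell_sd_s, rng),
            config.drill_dwell_min_s,
        )
        if not excursions or t + dwell >= duration:
            states.append((STATE_DRILL, 5, t, min(t + dwell, duration)))
            if t + dwell >= duration:
                break
            t += dwell
            continue
        states.append((STATE_DRILL, 5, t, t + dwell))
        t += dwell
        u = rng.random()
        cumulative = np.cumsum(probs)
        idx = int(np.searchsorted(cumulative, u, side="right"))
        if idx >= len(kinds):  # remainder: keep drilling
            continue
        kind = kinds[idx]
        params = config.excursions[kind]
        exc_dwell = max(
            sample_dwell(params.dwell_mean_s, params.dwell_sd_s, rng),
            params.dwell_min_s,
        )
        cell = int(rng.choice(params.cells))
        if t + exc_dwell > duration:
            # would be truncated: extend drilling to the end instead
            states[-1] = (STATE_DRILL, 5, states[-1][2], duration)
            break
        states.append((kind, cell, t, t + exc_dwell))
        t += exc_dwell
    # coalesce back-to-back drill states
    merged = []
    for kind, cell, start, end in states:
        if merged and kind == STATE_DRILL and merged[-1][0] == STATE_DRILL:
            merged[-1] = (kind, cell, merged[-1][2], end)
        else:
            merged.append((kind, cell, start, end))
    return merged


def state_schedule(config: SimConfig, seed=None) -> SimGroundTruth:
    """Draw the semi-Markov state schedule for both hands.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator
    ) else seed
    n_frames = int(round(config.duration_s * config.fps))
    frame_times = np.arange(n_frames) / config.fps

    rows = []
    for hand in (config.dominant_hand, config.nondominant_hand):
        excursions = (
            hand == config.dominant_hand or config.nondominant_excursions
        )
        states = _hand_states(config, rng, excursions)
        starts = np.array([s[2] for s in states])
        state_of_frame = np.searchsorted(starts, frame_times, side="right") - 1
        for i, (kind, cell, start, end) in enumerate(states):
            frames = np.flatnonzero(state_of_frame == i)
            rows.append(
                {
                    "hand": hand,
                    "kind": kind,
                    "cell": cell,
                    "start_s": start,
                    "end_s": end,
                    "start_frame": int(frames[0]) if len(frames) else -1,
                    "end_frame": int(frames[-1]) if len(frames) else -1,
                }
            )
    schedule = pd.DataFrame(rows, columns=list(_SCHEDULE_COLUMNS))
    return SimGroundTruth(schedule=schedule)


# 21-landmark hand template (unit scale, image coordinates: y grows downward,
# fingers extend toward smaller y). Index order follows the standard hand
# landmarker: 0 wrist, 1-4 thumb, 5-8 index, 9-12 middle, 13-16 ring,
# 17-20 pinky. Offsets are re-centered so landmark 12 (middle fingertip,
# the occupancy proxy) sits at the trajectory point.
_TEMPLATE = np.array(
    [
        (0.00, 0.00),                                        # wrist
        (-0.35, -0.15), (-0.55, -0.35), (-0.70, -0.50), (-0.80, -0.65),
        (-0.25, -0.70), (-0.30, -0.95), (-0.32, -1.12), (-0.34, -1.25),
        (0.00, -0.75), (0.00, -1.05), (0.00, -1.25), (0.00, -1.40),
        (0.20, -0.72), (0.25, -1.00), (0.28, -1.18), (0.30, -1.30),
        (0.40, -0.65), (0.48, -0.85), (0.52, -1.00), (0.55, -1.10),
    ]
)
_TEMPLATE = _TEMPLATE - _TEMPLATE[12]


def _hand_template(hand: str, scale: float) -> np.ndarray:
    template = _TEMPLATE * scale
    if hand == HAND_LEFT:
        template = template * np.array([-1.0, 1.0])
    return template


def _anchor_track(
    truth: SimGroundTruth, hand: str, grid: GridSpec, offset_x: float, n: int
) -> np.ndarray:
    sched = truth.schedule[truth.schedule["hand"] == hand]
    anchors = np.empty((n, 2))
    for row in sched.itertuples(index=False):
        if row.start_frame < 0:
            continue
        cx, cy = grid.cell_center(int(row.cell))
        anchors[row.start_frame : row.end_frame + 1] = (cx + offset_x, cy)
    return anchors


def render_session(
    truth: SimGroundTruth,
    config: SimConfig,
    seed=None,
    procedure_id: str = "sim",
) -> Session:
    """Render a schedule into a landmark stream; completes ``truth`` in place
    (dropout and null logs)."""
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator
    ) else seed
    meta = SessionMeta(
        procedure_id=procedure_id,
        fps=config.fps,
        width_px=config.width_px,
        height_px=config.height_px,
        duration_s=config.duration_s,
    )
    n = meta.n_frames
    grid = make_grid(config.width_px, config.height_px)
    center = np.array([config.width_px / 2.0, config.height_px / 2.0])
    dt = 1.0 / config.fps
    alpha = min(config.theta_per_s * dt, 1.0)  # clamp for stability

    frames_all, hands_all, lms_all, xs_all, ys_all = [], [], [], [], []
    for hand in (config.dominant_hand, config.nondominant_hand):
        offset_x = (
            0.5 if hand == config.dominant_hand else -0.5
        ) * config.hand_separation_px
        if config.dominant_hand == HAND_LEFT:
            offset_x = -offset_x
        anchors = _anchor_track(truth, hand, grid, offset_x, n)

        noise = rng.standard_normal((n, 2)) * (config.sigma_px * math.sqrt(dt))
        pos = np.empty((n, 2))
        p = anchors[0].copy()
        for t in range(n):
            p = p + alpha * (anchors[t] - p) + noise[t]
            pos[t] = p

        # dropout decided from the pre-jitter trajectory point
        dist = np.linalg.norm(pos - center, axis=1)
        p_drop = config.dropout_p0 + config.dropout_p1 * (
            dist < config.dropout_radius_px
        )
        detected = rng.random(n) >= p_drop
        truth.detected[hand] = detected

        landmarks = (
            pos[:, None, :]
            + _hand_template(hand, config.hand_scale_px)[None, :, :]
            + rng.standard_normal((n, N_LANDMARKS, 2)) * config.jitter_px
        )
        landmarks[..., 0] = np.clip(
            landmarks[..., 0], 0.0, config.width_px - 0.01
        )
        landmarks[..., 1] = np.clip(
            landmarks[..., 1], 0.0, config.height_px - 0.01
        )
        landmarks = np.round(landmarks, 2)

        det_frames = np.flatnonzero(detected)
        frames_all.append(np.repeat(det_frames, N_LANDMARKS))
        hands_all.append(np.full(len(det_frames) * N_LANDMARKS, hand, dtype=object))
        lms_all.append(np.tile(np.arange(N_LANDMARKS), len(det_frames)))
        xs_all.append(landmarks[det_frames, :, 0].ravel())
        ys_all.append(landmarks[det_frames, :, 1].ravel())

    null_frames = np.flatnonzero(rng.random(n) < config.p_null)
    truth.null_frames = null_frames
    if len(null_frames):
        frames_all.append(null_frames)
        hands_all.append(np.full(len(null_frames), HAND_NONE, dtype=object))
        lms_all.append(np.full(len(null_frames), NULL_LANDMARK_ID))
        xs_all.append(np.full(len(null_frames), np.nan))
        ys_all.append(np.full(len(null_frames), np.nan))

    records = pd.DataFrame(
        {
            "frame_index": np.concatenate(frames_all).astype(np.int64),
            "hand": np.concatenate(hands_all),
            "landmark_id": np.concatenate(lms_all).astype(np.int64),
            "x_px": np.concatenate(xs_all),
            "y_px": np.concatenate(ys_all),
        }
    )
    return Session(meta, records).validate()


def simulate_session(
    config: SimConfig, seed=None, procedure_id: str = "sim"
) -> tuple:
    """Schedule + render with one RNG stream; returns (Session, truth)."""
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator
    ) else seed
    truth = state_schedule(config, rng)
    session = render_session(truth, config, rng, procedure_id=procedure_id)
    return session, truth


def simulate_batch(config: SimConfig, n_procedures: int, seed=None) -> list:
    """Independent procedures with child seeds spawned from ``seed``.

    Returns ``[(Session, SimGroundTruth), ...]``; fully reproducible.
    """
    if n_procedures < 1:
        raise ValueError("n_procedures must be >= 1")
    root = np.random.SeedSequence(seed)
    out = []
    for i, child in enumerate(root.spawn(n_procedures), start=1):
        rng = np.random.default_rng(child)
        out.append(simulate_session(config, rng, procedure_id=f"proc_{i}"))
    return out
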