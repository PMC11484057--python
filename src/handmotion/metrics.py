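"""Detection-performance accounting and per-cell dwell-time statistics.

Detection performance is the fraction of the maximum possible landmark
records (frames x 21 landmarks x 2 hands) actually emitted. Dwell time in a
grid cell is summed over BOTH hands, so per-cell totals are bounded by twice
the session duration.

Display convention
------------------
Reported percentages and rates are *truncated* (floored) at display
precision, never rounded — truncation is the unique convention under which
all detection-performance and hand-share figures close against their raw
counts (e.g. 51.72 -> 51.7, 49.49 -> 49.4, 84.87 -> 84.8, 1082.69 -> 1082).
The one exception is the null-detection share, which sits near the display
resolution and is rounded so that a nonzero null count never displays as
zero (0.07 -> 0.1). Full precision is always retained internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import CELL_IDS, UNDETECTED, CellSeries
from .session import HAND_LEFT, HAND_NONE, HAND_RIGHT, N_LANDMARKS, Session, SessionMeta

#: landmark slots per frame: 21 landmarks x 2 hands
LANDMARKS_PER_FRAME = 2 * N_LANDMARKS


def truncate(value: float, decimals: int = 1) -> float:
    """Floor ``value`` at ``decimals`` decimal places (display convention)."""
    factor = 10 ** decimals
    return math.floor(value * factor) / factor


# ---------------------------------------------------------------------------
# detection performance
# ---------------------------------------------------------------------------

def detection_performance_pct(n_total: int, n_frames: int) -> float:
    """Full-precision detection performance: 100 * records / (frames * 42)."""
    if n_frames <= 0:
        raise ValueError("detection performance undefined for zero frames")
    return 100.0 * n_total / (n_frames * LANDMARKS_PER_FRAME)


def hand_share_pcts(n_right: int, n_left: int, n_null: int) -> tuple:
    """Full-precision (right, left, null) shares of all records."""
    n_total = n_right + n_left + n_null
    if n_total <= 0:
        raise ValueError("hand shares undefined for an empty session")
    return tuple(100.0 * n / n_total for n in (n_right, n_left, n_null))


@dataclass(frozen=True)
class PerformanceReport:
    """Detection counts and rates for one session (full precision inside,
    truncation applied by :meth:`display`)."""

    n_total: int
    n_right: int
    n_left: int
    n_null: int
    n_frames: int
    duration_s: float
    fps: float

    def __post_init__(self):
        if self.n_total != self.n_right + self.n_left + self.n_null:
            raise ValueError("n_total must equal n_right + n_left + n_null")

    @classmethod
    def from_session(cls, session: Session) -> "PerformanceReport":
        hands = session.records["hand"]
        return cls(
            n_total=len(hands),
            n_right=int((hands == HAND_RIGHT).sum()),
            n_left=int((hands == HAND_LEFT).sum()),
            n_null=int((hands == HAND_NONE).sum()),
            n_frames=session.meta.n_frames,
            duration_s=session.meta.duration_s,
            fps=session.meta.fps,
        )

    @classmethod
    def from_counts(
        cls,
        n_total: int,
        n_right: int,
        n_left: int,
        n_null: int,
        duration_s: float,
        fps: float = 30.0,
    ) -> "PerformanceReport":
        """Build a report from printed summary counts (no record table)."""
        return cls(
            n_total=n_total,
            n_right=n_right,
            n_left=n_left,
            n_null=n_null,
            n_frames=int(round(duration_s * fps)),
            duration_s=duration_s,
            fps=fps,
        )

    @property
    def performance_pct(self) -> float:
        return detection_performance_pct(self.n_total, self.n_frames)

    @property
    def right_pct(self) -> float:
        return hand_share_pcts(self.n_right, self.n_left, self.n_null)[0]

    @property
    def left_pct(self) -> float:
        return hand_share_pcts(self.n_right, self.n_left, self.n_null)[1]

    @property
    def null_pct(self) -> float:
        return hand_share_pcts(self.n_right, self.n_left, self.n_null)[2]

    @property
    def detections_per_second(self) -> float:
        if self.duration_s <= 0:
            raise ValueError("detections/second undefined for zero duration")
        return self.n_total / self.duration_s

    def display(self) -> dict:
        """Reported values at display precision (see module docstring)."""
        return {
            "n_total": self.n_total,
            "n_right": self.n_right,
            "n_left": self.n_left,
            "n_null": self.n_null,
            "performance_pct": truncate(self.performance_pct, 1),
            "right_pct": truncate(self.right_pct, 1),
            "left_pct": truncate(self.left_pct, 1),
            "null_pct": round(self.null_pct, 1),
            "detections_per_second": int(self.detections_per_second),
        }


def detection_performance(session: Session) -> float:
    """Detection performance in percent, truncated to one decimal.

    An empty session over a nonzero number of frames scores 0.0.
    """
    report = PerformanceReport.from_session(session)
    return truncate(report.performance_pct, 1)


def hand_shares(session: Session) -> tuple:
    """(right_pct, left_pct, null_pct) at display precision."""
    report = PerformanceReport.from_session(session)
    return (
        truncate(report.right_pct, 1),
        truncate(report.left_pct, 1),
        round(report.null_pct, 1),
    )


def detections_per_second(session: Session) -> int:
    """Average landmark records per second, truncated to an integer."""
    if session.meta.duration_s <= 0:
        raise ValueError("detections/second undefined for zero duration")
    return int(session.n_records / session.meta.duration_s)


# ---------------------------------------------------------------------------
# dwell times
# ---------------------------------------------------------------------------

def occupancy_frame_counts(series: CellSeries) -> np.ndarray:
    """Frame counts indexed 0..9 (0 = UNDETECTED, 1-9 = cells)."""
    return np.bincount(series.cells, minlength=10)[:10]


def dwell_times(
    series_left: CellSeries, series_right: CellSeries, meta: SessionMeta
) -> pd.Series:
    """Seconds per cell, summed over both hands.

    UNDETECTED frames contribute to no cell, so
    ``sum(dwell) + undetected_left/fps + undetected_right/fps``
    equals ``2 * duration_s`` exactly.
    """
    if len(series_left) != meta.n_frames or len(series_right) != meta.n_frames:
        raise ValueError(
            f"series length must equal n_frames={meta.n_frames}, got "
            f"left={len(series_left)} right={len(series_right)}"
        )
    counts = occupancy_frame_counts(series_left) + occupancy_frame_counts(
        series_right
    )
    return pd.Series(
        counts[1:10] / meta.fps, index=list(CELL_IDS), name="dwell_s"
    )


def undetected_time(series: CellSeries, meta: SessionMeta) -> float:
    """Seconds of tracking loss for one hand."""
    return int((series.cells == UNDETECTED).sum()) / meta.fps


def aggregate_dwell(tables) -> pd.DataFrame:
    """Cross-procedure mean and sample SD (n-1) of per-cell dwell seconds.

    ``tables``: one per-cell Series per procedure (>= 2 required for the SD).
    Returns a DataFrame indexed by cell id with columns ``mean_s``, ``sd_s``.
    """
    tables = list(tables)
    if len(tables) < 2:
        raise ValueError(
            "aggregate dwell SD needs >= 2 procedures, got "
            f"{len(tables)}"
        )
    stacked = pd.DataFrame(
        [t.reindex(list(CELL_IDS), fill_value=0.0) for t in tables]
    )
    return pd.DataFrame(
        {"mean_s": stacked.mean(axis=0), "sd_s": stacked.std(axis=0, ddof=1)}
    )


def heatmap_matrix(aggregate: pd.DataFrame) -> np.ndarray:
    """3x3 matrix of mean dwell seconds, ``matrix[r][c]`` = cell ``3r+c+1``."""
    return (
        aggregate["mean_s"].reindex(list(CELL_IDS)).to_numpy().reshape(3, 3)
    )
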