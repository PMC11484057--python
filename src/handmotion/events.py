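"""Workflow-event segmentation from grid-cell occupancy excursions.

The center cell (5) holds the surgical field; excursions of the occupancy
landmark into other cells mark workflow events. Excursions reaching the top
row (cells 1-3, microscope handles) are microscope adjustments — visible as
coordinate-trace spikes toward 0 px, the top of the image; excursions into
cell 4 (instrument table) are instrument changes; cell 7 (trash bin) visits
are trash events. A reach necessarily sweeps intermediate cells, so mixed
excursions are classified by precedence MICROSCOPE > INSTRUMENT > TRASH >
OTHER.

Segmentation is deliberately parameter-light: fill short tracking-loss gaps,
take maximal non-center runs, merge same-kind runs separated by brief
returns, drop sub-threshold blips.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .grid import UNDETECTED, CellSeries
from .session import SessionMeta


class EventKind(str, enum.Enum):
    INSTRUMENT_CHANGE = "instrument_change"
    MICROSCOPE_ADJUST = "microscope_adjust"
    TRASH = "trash"
    OTHER = "other"


#: center cell of the grid — the surgical field, not an event
CENTER_CELL = 5
MICROSCOPE_CELLS = frozenset({1, 2, 3})
INSTRUMENT_CELL = 4
TRASH_CELL = 7


def classify_cells(cells_visited) -> EventKind:
    """Event kind of an excursion from the set of cells it visited."""
    cells = set(cells_visited)
    if cells & MICROSCOPE_CELLS:
        return EventKind.MICROSCOPE_ADJUST
    if INSTRUMENT_CELL in cells:
        return EventKind.INSTRUMENT_CHANGE
    if TRASH_CELL in cells:
        return EventKind.TRASH
    return EventKind.OTHER


@dataclass(frozen=True)
class EventConfig:
    """Segmentation knobs, all in seconds.

    gap_fill_s
        UNDETECTED runs strictly shorter than this are bridged with the
        preceding cell, so single-frame glare dropouts do not split one
        excursion into many.
    merge_gap_s
        consecutive same-kind excursions separated (in center-cell or
        UNDETECTED frames) by less than this are one event.
    min_duration_s
        events shorter than this are discarded as blips.
    """

    gap_fill_s: float = 0.5
    merge_gap_s: float = 1.0
    min_duration_s: float = 0.5

    def __post_init__(self):
        if min(self.gap_fill_s, self.merge_gap_s, self.min_duration_s) < 0:
            raise ValueError("event-config durations must be >= 0")


@dataclass
class Event:
    """One classified excursion, inclusive in frames.

    ``start_s = start_frame/fps`` and ``end_s = (end_frame+1)/fps`` (half-open
    in time), so ``duration_s == (end_frame - start_frame + 1)/fps``.
    """

    kind: EventKind
    hand: str
    start_frame: int
    end_frame: int
    start_s: float
    end_s: float
    cells_visited: frozenset = field(default_factory=frozenset)

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def _runs(mask: np.ndarray):
    """(start, end_inclusive) spans of True runs."""
    edges = np.flatnonzero(np.diff(np.r_[0, mask.astype(np.int8), 0]))
    return list(zip(edges[::2], edges[1::2] - 1))


def detect_events(
    series: CellSeries, meta: SessionMeta, config: EventConfig = None
) -> list:
    """Segment one hand's occupancy series into time-ordered, disjoint events.

    Steps: (1) bridge UNDETECTED runs shorter than ``gap_fill_s`` with the
    preceding cell; (2) take maximal runs of non-center cells; (3) classify
    each run from the cells it visits; (4) merge adjacent same-kind runs
    separated by less than ``merge_gap_s``; (5) drop events shorter than
    ``min_duration_s``.
    """
    config = config or EventConfig()
    cells = np.asarray(series.cells, dtype=np.int16).copy()
    if len(cells) != meta.n_frames:
        raise ValueError(
            f"series length {len(cells)} != n_frames {meta.n_frames}"
        )
    fps = meta.fps

    gap_frames = config.gap_fill_s * fps
    for start, end in _runs(cells == UNDETECTED):
        if start > 0 and (end - start + 1) < gap_frames:
            cells[start : end + 1] = cells[start - 1]

    raw = []
    for start, end in _runs((cells != UNDETECTED) & (cells != CENTER_CELL)):
        visited = frozenset(int(c) for c in np.unique(cells[start : end + 1]))
        raw.append((start, end, visited, classify_cells(visited)))

    merged = []
    merge_frames = config.merge_gap_s * fps
    for start, end, visited, kind in raw:
        if merged:
            p_start, p_end, p_visited, p_kind = merged[-1]
            if kind == p_kind and (start - p_end - 1) < merge_frames:
                merged[-1] = (p_start, end, p_visited | visited, kind)
                continue
        merged.append((start, end, visited, kind))

    events = []
    for start, end, visited, kind in merged:
        duration = (end - start + 1) / fps
        if duration < config.min_duration_s:
            continue
        events.append(
            Event(
                kind=kind,
                hand=series.hand,
                start_frame=int(start),
                end_frame=int(end),
                start_s=start / fps,
                end_s=(end + 1) / fps,
                cells_visited=visited,
            )
        )
    return events


@dataclass(frozen=True)
class KindStats:
    count: int
    mean_s: float  # NaN when count == 0
    sd_s: float    # NaN when count < 2 (sample SD undefined)


def event_stats(events) -> dict:
    """Per-kind count / mean / sample SD (n-1) of event durations."""
    stats = {}
    for kind in EventKind:
        durations = np.array(
            [e.duration_s for e in events if e.kind == kind], dtype=float
        )
        n = len(durations)
        stats[kind] = KindStats(
            count=n,
            mean_s=float(durations.mean()) if n else math.nan,
            sd_s=float(durations.std(ddof=1)) if n >= 2 else math.nan,
        )
    return stats


@dataclass
class MatchResult:
    """Outcome of matching detected events against a ground-truth schedule.

    ``precision`` is NaN when nothing was detected; ``recall`` is NaN when
    the truth holds no events.
    """

    n_detected: int
    n_truth: int
    n_matched: int
    matches: list  # (detected_idx, truth_idx, start_err_s, end_err_s)

    @property
    def precision(self) -> float:
        return self.n_matched / self.n_detected if self.n_detected else math.nan

    @property
    def recall(self) -> float:
        return self.n_matched / self.n_truth if self.n_truth else math.nan


def match_events(detected, truth, tol_s: float = 1.0) -> MatchResult:
    """Greedy one-to-one interval matching of detected vs true events.

    ``truth`` is a SimGroundTruth (its excursion schedule for the detected
    hand is used) or an explicit iterable of ``(kind, start_s, end_s)``.
    A pair matches when kinds agree and the detected interval, widened by
    ``tol_s`` on both sides, overlaps the true one.
    """
    if tol_s < 0:
        raise ValueError("tolerance must be >= 0")
    detected = list(detected)
    truth_events = _truth_intervals(truth, detected)

    matched_det = set()
    matches = []
    for t_idx, (kind, t_start, t_end) in enumerate(truth_events):
        for d_idx, ev in enumerate(detected):
            if d_idx in matched_det or ev.kind != kind:
                continue
            if ev.start_s - tol_s < t_end and ev.end_s + tol_s > t_start:
                matched_det.add(d_idx)
                matches.append(
                    (d_idx, t_idx, ev.start_s - t_start, ev.end_s - t_end)
                )
                break
    return MatchResult(
        n_detected=len(detected),
        n_truth=len(truth_events),
        n_matched=len(matches),
        matches=matches,
    )


def _truth_intervals(truth, detected):
    if hasattr(truth, "schedule"):
        hands = {e.hand for e in detected}
        sched = truth.schedule
        sub = sched[sched["kind"] != "drill"]
        if hands:
            sub = sub[sub["hand"].isin(hands)]
        return [
            (EventKind(row.kind), float(row.start_s), float(row.end_s))
            for row in sub.itertuples(index=False)
        ]
    out = []
    for kind, start, end in truth:
        out.append((EventKind(kind), float(start), float(end)))
    return out
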