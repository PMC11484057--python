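"""End-to-end analysis: session -> occupancy -> metrics -> events.

Thin orchestration over the grid, metrics and events modules; this is what
the ``analyze`` and ``report`` CLI subcommands call.
"""

from __future__ import annotations

from .events import EventConfig, detect_events, event_stats
from .grid import GridSpec, cell_series, make_grid
from .metrics import (
    PerformanceReport,
    aggregate_dwell,
    dwell_times,
    heatmap_matrix,
    undetected_time,
)
from .session import HAND_LEFT, HAND_RIGHT, MIDDLE_FINGERTIP, Session


def analyze_session(
    session: Session,
    grid: GridSpec = None,
    event_config: EventConfig = None,
    landmark_id: int = MIDDLE_FINGERTIP,
    dominant_hand: str = HAND_RIGHT,
) -> dict:
    """Full single-procedure analysis.

    Returns performance counts/rates, per-cell dwell seconds (both hands),
    per-hand undetected time, and the dominant hand's workflow events with
    per-kind duration statistics.
    """
    meta = session.meta
    grid = grid or make_grid(meta.width_px, meta.height_px)
    series = {
        hand: cell_series(session, grid, hand, landmark_id=landmark_id)
        for hand in (HAND_LEFT, HAND_RIGHT)
    }
    dwell = dwell_times(series[HAND_LEFT], series[HAND_RIGHT], meta)
    events = detect_events(series[dominant_hand], meta, event_config)
    report = PerformanceReport.from_session(session)
    return {
        "procedure_id": meta.procedure_id,
        "performance": report.display(),
        "dwell_s": {int(c): float(v) for c, v in dwell.items()},
        "undetected_s": {
            hand: undetected_time(series[hand], meta) for hand in series
        },
        "events": [
            {
                "kind": ev.kind,
                "hand": ev.hand,
                "start_s": ev.start_s,
                "end_s": ev.end_s,
                "duration_s": ev.duration_s,
            }
            for ev in events
        ],
        "event_stats": {
            kind: {"count": s.count, "mean_s": s.mean_s, "sd_s": s.sd_s}
            for kind, s in event_stats(events).items()
        },
        "_dwell_series": dwell,   # consumed by analyze_batch
        "_event_objects": events,
    }


def analyze_batch(sessions, grid: GridSpec = None, **kwargs) -> dict:
    """Analyze each procedure and aggregate across them.

    The aggregate block (cross-procedure mean/SD dwell, heatmap matrix,
    pooled event statistics) is present when >= 2 procedures are given.
    """
    sessions = list(sessions)
    if not sessions:
        raise ValueError("no sessions to analyze")
    per_proc = [analyze_session(s, grid=grid, **kwargs) for s in sessions]

    result = {"procedures": []}
    all_events = []
    dwell_tables = []
    for block in per_proc:
        dwell_tables.append(block.pop("_dwell_series"))
        all_events.extend(block.pop("_event_objects"))
        result["procedures"].append(block)

    if len(sessions) >= 2:
        agg = aggregate_dwell(dwell_tables)
        result["aggregate"] = {
            "n_procedures": len(sessions),
            "dwell_mean_s": {int(c): float(v) for c, v in agg["mean_s"].items()},
            "dwell_sd_s": {int(c): float(v) for c, v in agg["sd_s"].items()},
            "heatmap": heatmap_matrix(agg).tolist(),
            "event_stats": {
                kind: {"count": s.count, "mean_s": s.mean_s, "sd_s": s.sd_s}
                for kind, s in event_stats(all_events).items()
            },
        }
    return result
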