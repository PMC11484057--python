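"""Workflow-event segmentation from occupancy excursions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from handmotion.events import (
    Event,
    EventConfig,
    EventKind,
    classify_cells,
    detect_events,
    event_stats,
    match_events,
)
from handmotion.grid import CellSeries
from handmotion.session import HAND_RIGHT, SessionMeta


def _series(cells, fps=30.0):
    cells = np.asarray(cells, dtype=np.int16)
    meta = SessionMeta("p", fps=fps, duration_s=len(cells) / fps)
    return CellSeries(HAND_RIGHT, cells), meta


def _make_event(kind, start_s, end_s, fps=30.0):
    return Event(
        kind=kind,
        hand=HAND_RIGHT,
        start_frame=int(start_s * fps),
        end_frame=int(end_s * fps) - 1,
        start_s=start_s,
        end_s=end_s,
    )


def test_constant_center_yields_no_events():
    series, meta = _series([5] * 600)
    assert detect_events(series, meta) == []


def test_single_instrument_excursion():
    # 600 s at the field with one 20 s visit to the instrument table
    fps = 30
    cells = [5] * (100 * fps) + [4] * (20 * fps) + [5] * (480 * fps)
    series, meta = _series(cells)
    events = detect_events(series, meta)
    assert len(events) == 1
    ev = events[0]
    assert ev.kind == EventKind.INSTRUMENT_CHANGE
    assert ev.duration_s == pytest.approx(20.0, abs=1 / fps)
    assert ev.start_s == pytest.approx(100.0, abs=1 / fps)


def test_classification_precedence():
    # reaching the handles sweeps other cells: top row wins
    assert classify_cells({4, 1}) == EventKind.MICROSCOPE_ADJUST
    assert classify_cells({4, 7}) == EventKind.INSTRUMENT_CHANGE
    assert classify_cells({7, 8}) == EventKind.TRASH
    assert classify_cells({6}) == EventKind.OTHER
    assert classify_cells({2}) == EventKind.MICROSCOPE_ADJUST


def test_gap_fill_bridges_short_dropout():
    # a 0.2 s tracking loss inside one table visit must not split it
    fps = 30
    cells = (
        [5] * 60 + [4] * 30 + [0] * 6 + [4] * 30 + [5] * 60
    )
    series, meta = _series(cells, fps)
    events = detect_events(series, meta)
    assert len(events) == 1
    assert events[0].kind == EventKind.INSTRUMENT_CHANGE
    assert events[0].duration_s == pytest.approx((30 + 6 + 30) / fps)


def test_long_gap_not_filled_but_merged_within_merge_gap():
    # a 0.6 s loss exceeds gap_fill (0.5 s) but the two same-kind runs sit
    # within merge_gap (1 s), so they still form one event
    fps = 30
    cells = [5] * 60 + [4] * 30 + [0] * 18 + [4] * 30 + [5] * 60
    series, meta = _series(cells, fps)
    events = detect_events(series, meta)
    assert len(events) == 1

    # separation beyond merge_gap: two events
    cells = [5] * 60 + [4] * 30 + [5] * 45 + [4] * 30 + [5] * 60
    series, meta = _series(cells, fps)
    events = detect_events(series, meta)
    assert len(events) == 2


def test_different_kinds_never_merge():
    fps = 30
    cells = [5] * 30 + [4] * 30 + [5] * 6 + [7] * 30 + [5] * 30
    series, meta = _series(cells, fps)
    events = detect_events(series, meta)
    assert [e.kind for e in events] == [
        EventKind.INSTRUMENT_CHANGE,
        EventKind.TRASH,
    ]


def test_min_duration_drops_blips():
    fps = 30
    cells = [5] * 30 + [4] * 10 + [5] * 30  # 0.33 s blip < 0.5 s
    series, meta = _series(cells, fps)
    assert detect_events(series, meta) == []
    config = EventConfig(min_duration_s=0.0)
    assert len(detect_events(series, meta, config)) == 1


def test_leading_undetected_run_left_alone():
    fps = 30
    cells = [0] * 5 + [5] * 55
    series, meta = _series(cells, fps)
    assert detect_events(series, meta) == []


def test_events_disjoint_ordered_and_deterministic(short_sim):
    from handmotion.grid import cell_series, make_grid

    config, session, _ = short_sim
    g = make_grid(config.width_px, config.height_px)
    series = cell_series(session, g, HAND_RIGHT)
    events = detect_events(series, session.meta)
    again = detect_events(series, session.meta)
    assert events == again  # identical inputs -> identical output
    for prev, nxt in zip(events, events[1:]):
        assert prev.end_frame < nxt.start_frame
        assert prev.start_frame <= prev.end_frame


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    cells=st.lists(
        st.sampled_from([0, 1, 4, 5, 7, 8]), min_size=1, max_size=150
    ),
    min_a=st.floats(0, 2),
    min_b=st.floats(0, 2),
)
def test_min_duration_monotonicity(cells, min_a, min_b):
    # raising min_duration_s never increases the event count
    lo, hi = sorted([min_a, min_b])
    series, meta = _series(cells, fps=10.0)
    n_lo = len(detect_events(series, meta, EventConfig(min_duration_s=lo)))
    n_hi = len(detect_events(series, meta, EventConfig(min_duration_s=hi)))
    assert n_hi <= n_lo


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    cells=st.lists(
        st.sampled_from([0, 1, 4, 5, 7, 8]), min_size=1, max_size=150
    ),
    gap_a=st.floats(0, 3),
    gap_b=st.floats(0, 3),
)
def test_merge_gap_monotonicity(cells, gap_a, gap_b):
    # with the blip filter off, widening merge_gap only merges more
    lo, hi = sorted([gap_a, gap_b])
    series, meta = _series(cells, fps=10.0)
    n_lo = len(
        detect_events(
            series, meta, EventConfig(merge_gap_s=lo, min_duration_s=0.0)
        )
    )
    n_hi = len(
        detect_events(
            series, meta, EventConfig(merge_gap_s=hi, min_duration_s=0.0)
        )
    )
    assert n_hi <= n_lo


def test_event_stats_closed_form():
    events = [
        _make_event(EventKind.INSTRUMENT_CHANGE, 10.0, 30.0),
        _make_event(EventKind.INSTRUMENT_CHANGE, 50.0, 73.0),
    ]
    stats = event_stats(events)
    s = stats[EventKind.INSTRUMENT_CHANGE]
    assert s.count == 2
    assert s.mean_s == pytest.approx(21.5)
    assert s.sd_s == pytest.approx(abs(20.0 - 23.0) / math.sqrt(2))

    single = event_stats(events[:1])[EventKind.INSTRUMENT_CHANGE]
    assert single.count == 1 and math.isnan(single.sd_s)

    empty = event_stats([])
    assert all(s.count == 0 for s in empty.values())
    assert all(math.isnan(s.mean_s) for s in empty.values())


def test_match_identical_events():
    events = [
        _make_event(EventKind.TRASH, 5.0, 9.0),
        _make_event(EventKind.MICROSCOPE_ADJUST, 20.0, 24.0),
    ]
    truth = [(e.kind, e.start_s, e.end_s) for e in events]
    result = match_events(events, truth, tol_s=0.5)
    assert result.precision == 1.0 and result.recall == 1.0
    for _, _, start_err, end_err in result.matches:
        assert start_err == 0.0 and end_err == 0.0


def test_match_empty_detected():
    truth = [(EventKind.TRASH, 5.0, 9.0)]
    result = match_events([], truth, tol_s=0.5)
    assert result.recall == 0.0
    assert math.isnan(result.precision)  # undefined, flagged


def test_match_rejects_negative_tolerance():
    with pytest.raises(ValueError):
        match_events([], [], tol_s=-1.0)


def test_noiseless_recovery(clean_sim):
    # noise-free simulation: every scheduled excursion is recovered with
    # boundary errors bounded by gap_fill + one frame
    from handmotion.grid import cell_series, make_grid

    config, session, truth = clean_sim
    g = make_grid(config.width_px, config.height_px)
    series = cell_series(session, g, HAND_RIGHT)
    events = detect_events(series, session.meta)
    excursions = truth.excursions(HAND_RIGHT)
    assert len(events) == len(excursions)
    result = match_events(events, truth, tol_s=1.0)
    assert result.precision == 1.0 and result.recall == 1.0
    bound = EventConfig().gap_fill_s + 1 / config.fps
    for _, _, start_err, end_err in result.matches:
        assert abs(start_err) <= bound
        assert abs(end_err) <= bound
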