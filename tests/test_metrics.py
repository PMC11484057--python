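"""Detection-performance accounting, dwell times and their invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from handmotion.grid import CellSeries, cell_series, make_grid
from handmotion.metrics import (
    PerformanceReport,
    aggregate_dwell,
    detection_performance,
    detections_per_second,
    dwell_times,
    hand_shares,
    heatmap_matrix,
    occupancy_frame_counts,
    truncate,
    undetected_time,
)
from handmotion.session import (
    HAND_LEFT,
    HAND_RIGHT,
    MIDDLE_FINGERTIP,
    Session,
    SessionMeta,
)
from handmotion.simulate import SimConfig, simulate_session

from conftest import constant_session, session_from_positions


def test_truncation_convention():
    # floored at display precision, never rounded
    assert truncate(51.72, 1) == 51.7
    assert truncate(49.494, 1) == 49.4
    assert truncate(84.87, 1) == 84.8
    assert truncate(39.677, 1) == 39.6
    assert truncate(100.0, 1) == 100.0
    assert truncate(1082.69, 0) == 1082


def test_full_detection_scores_100():
    session = constant_session(60)
    assert detection_performance(session) == 100.0
    assert detections_per_second(session) == 42 * 30  # 1260 records/s


def test_empty_session_performance():
    session = Session(SessionMeta("p", duration_s=1.0))
    assert detection_performance(session) == 0.0
    assert detections_per_second(session) == 0
    with pytest.raises(ValueError):
        hand_shares(session)
    zero = PerformanceReport.from_counts(0, 0, 0, 0, duration_s=0.0)
    with pytest.raises(ValueError):
        zero.performance_pct  # zero frames: performance undefined
    with pytest.raises(ValueError):
        zero.detections_per_second


def test_single_handed_shares():
    session = constant_session(10, hands=(HAND_RIGHT,))
    assert hand_shares(session) == (100.0, 0.0, 0.0)


def test_report_counts_consistency():
    with pytest.raises(ValueError):
        PerformanceReport(
            n_total=10, n_right=5, n_left=4, n_null=0,
            n_frames=10, duration_s=1.0, fps=10.0,
        )


def test_dwell_both_hands_center():
    # both hands in cell 5 all session: dwell = 2 x duration (the cap)
    n = 300
    session = constant_session(n)
    g = make_grid(1920, 1080)
    left = cell_series(session, g, HAND_LEFT)
    right = cell_series(session, g, HAND_RIGHT)
    dwell = dwell_times(left, right, session.meta)
    assert dwell[5] == 2 * session.meta.duration_s == 20.0
    assert dwell.drop(5).sum() == 0.0


def test_dwell_single_hand():
    session = constant_session(90, hands=(HAND_RIGHT,))
    g = make_grid(1920, 1080)
    left = cell_series(session, g, HAND_LEFT)
    right = cell_series(session, g, HAND_RIGHT)
    dwell = dwell_times(left, right, session.meta)
    assert dwell[5] == 3.0  # 90 frames at 30 fps, one hand only
    assert undetected_time(left, session.meta) == 3.0


def test_dwell_length_mismatch():
    meta = SessionMeta("p", fps=30, duration_s=1.0)
    a = CellSeries(HAND_LEFT, np.full(30, 5))
    b = CellSeries(HAND_RIGHT, np.full(29, 5))
    with pytest.raises(ValueError):
        dwell_times(a, b, meta)


def test_dwell_matches_brute_force_recount(short_sim):
    # independent oracle: count landmark-12 cell hits frame by frame
    config, session, _ = short_sim
    g = make_grid(config.width_px, config.height_px)
    left = cell_series(session, g, HAND_LEFT)
    right = cell_series(session, g, HAND_RIGHT)
    dwell = dwell_times(left, right, session.meta)

    brute = {c: 0 for c in range(1, 10)}
    df = session.records
    tips = df[df["landmark_id"] == MIDDLE_FINGERTIP]
    for row in tips.itertuples(index=False):
        col = min(int(row.x_px // (config.width_px / 3)), 2)
        r = min(int(row.y_px // (config.height_px / 3)), 2)
        brute[r * 3 + col + 1] += 1
    for cell in range(1, 10):
        assert dwell[cell] == brute[cell] / config.fps


def test_conservation_on_simulated_sessions():
    # sum of per-cell frames + undetected frames == 2 x n_frames, exactly
    config = SimConfig(duration_s=30.0)
    for seed in (0, 1, 2):
        session, _ = simulate_session(config, seed=seed)
        g = make_grid(config.width_px, config.height_px)
        left = cell_series(session, g, HAND_LEFT)
        right = cell_series(session, g, HAND_RIGHT)
        counts = occupancy_frame_counts(left) + occupancy_frame_counts(right)
        assert counts.sum() == 2 * session.meta.n_frames
        dwell = dwell_times(left, right, session.meta)
        total = dwell.sum() + undetected_time(left, session.meta) + \
            undetected_time(right, session.meta)
        assert total == pytest.approx(2 * config.duration_s, abs=1e-9)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(cells_l=st.lists(st.integers(0, 9), min_size=1, max_size=200))
def test_conservation_property(cells_l):
    n = len(cells_l)
    fps = 10.0
    meta = SessionMeta("p", fps=fps, duration_s=n / fps)
    left = CellSeries(HAND_LEFT, np.array(cells_l))
    right = CellSeries(HAND_RIGHT, np.array(cells_l[::-1]))
    counts = occupancy_frame_counts(left) + occupancy_frame_counts(right)
    assert counts.sum() == 2 * n


def test_detection_performance_tracks_dropout_rate():
    # constant dropout p: performance/100 -> (1-p) within 3 binomial SE
    p = 0.1
    config = SimConfig(
        duration_s=600.0, dropout_p0=p, dropout_p1=0.0, p_null=0.0
    )
    session, _ = simulate_session(config, seed=5)
    perf = PerformanceReport.from_session(session).performance_pct
    n_hand_frames = 2 * session.meta.n_frames
    se = 100 * math.sqrt(p * (1 - p) / n_hand_frames)
    assert abs(perf - 90.0) < 3 * se


def test_aggregate_dwell():
    import pandas as pd

    cells = list(range(1, 10))
    t1 = pd.Series([0.0] * 8 + [100.0], index=cells)
    agg = aggregate_dwell([t1, t1, t1])
    assert (agg["sd_s"] == 0).all()

    # illustrative mean: (900 + 1000 + 1061.3)/3 = 987.1
    vals = [900.0, 1000.0, 1061.3]
    tables = [pd.Series([v] + [0.0] * 8, index=cells) for v in vals]
    agg = aggregate_dwell(tables)
    assert agg.loc[1, "mean_s"] == pytest.approx(987.1, abs=1e-9)

    # two procedures: SD = |a-b| / sqrt(2)
    agg2 = aggregate_dwell(tables[:2])
    assert agg2.loc[1, "sd_s"] == pytest.approx(100 / math.sqrt(2))

    with pytest.raises(ValueError):
        aggregate_dwell([t1])


def test_heatmap_matrix():
    import pandas as pd

    cells = list(range(1, 10))
    agg = aggregate_dwell(
        [pd.Series([0.0] * 4 + [50.0] + [0.0] * 4, index=cells)] * 2
    )
    m = heatmap_matrix(agg)
    assert m.shape == (3, 3)
    assert m[1, 1] == 50.0 and m.sum() == 50.0
    assert m.sum() == pytest.approx(agg["mean_s"].sum())
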