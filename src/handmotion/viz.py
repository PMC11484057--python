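"""Tracking plots, the 3x3 dwell heatmap and the consolidated report.

Vertical tracking plots invert the y axis so 0 px renders at the top of the
figure, matching the image convention: reaches to the microscope handles
appear as upward spikes toward 0. Tracking loss is drawn as line breaks,
never interpolated, so dropout stays visible.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .events import EventKind
from .session import HAND_LEFT, HAND_RIGHT, MIDDLE_FINGERTIP, Session

HORIZONTAL = "horizontal"
VERTICAL = "vertical"

_EVENT_COLORS = {
    EventKind.INSTRUMENT_CHANGE: "tab:orange",
    EventKind.MICROSCOPE_ADJUST: "tab:red",
    EventKind.TRASH: "tab:green",
    EventKind.OTHER: "tab:gray",
}


def _coordinate_trace(session: Session, hand: str, axis: str, landmark_id: int):
    """Per-frame coordinate of one hand's landmark, NaN where undetected."""
    df = session.records
    sub = df[(df["hand"] == hand) & (df["landmark_id"] == landmark_id)]
    values = np.full(session.meta.n_frames, np.nan)
    col = "x_px" if axis == HORIZONTAL else "y_px"
    values[sub["frame_index"].to_numpy()] = sub[col].to_numpy()
    return values


def tracking_plot(
    session: Session,
    hands=(HAND_RIGHT, HAND_LEFT),
    axis: str = HORIZONTAL,
    events=None,
    out=None,
    landmark_id: int = MIDDLE_FINGERTIP,
):
    """Time-vs-coordinate line plot; returns the matplotlib Figure.

    UNDETECTED frames break the line; supplied events are shaded and
    labelled by kind; vertical plots put 0 px at the top.
    """
    if axis not in (HORIZONTAL, VERTICAL):
        raise ValueError(f"axis must be horizontal|vertical, got {axis!r}")
    if isinstance(hands, str):
        hands = (hands,)
    meta = session.meta
    times = np.arange(meta.n_frames) / meta.fps

    fig, ax = plt.subplots(figsize=(10, 3.2))
    for hand in hands:
        trace = _coordinate_trace(session, hand, axis, landmark_id)
        ax.plot(times, trace, lw=0.7, label=f"{hand} hand")
    seen = set()
    for ev in events or ():
        color = _EVENT_COLORS[ev.kind]
        label = ev.kind.value if ev.kind not in seen else None
        seen.add(ev.kind)
        ax.axvspan(ev.start_s, ev.end_s, alpha=0.25, color=color, label=label)
    ax.set_xlabel("time (s)")
    ax.set_ylabel(f"{axis} position (px)")
    if axis == VERTICAL:
        ax.set_ylim(meta.height_px, 0)  # 0 px at the top of the image
    else:
        ax.set_ylim(0, meta.width_px)
    ax.set_xlim(0, meta.duration_s)
    if meta.n_frames or events:
        ax.legend(loc="upper right", fontsize=8)
    ax.set_title(f"{axis} motion, {meta.procedure_id}")
    fig.tight_layout()
    if out is not None:
        fig.savefig(Path(out), dpi=110)
        plt.close(fig)
    return fig


def heatmap_plot(matrix, out=None):
    """3x3 color-mapped dwell heatmap with one-decimal second annotations.

    Annotations are taken verbatim from ``matrix`` (no recomputation), so
    they are numerically identical to the aggregate dwell means.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (3, 3):
        raise ValueError(f"expected a 3x3 matrix, got shape {matrix.shape}")
    fig, ax = plt.subplots(figsize=(4.6, 4.2))
    im = ax.imshow(matrix, cmap="viridis")
    for r in range(3):
        for c in range(3):
            ax.text(
                c,
                r,
                f"{matrix[r, c]:.1f}",
                ha="center",
                va="center",
                color="white",
                fontsize=11,
                path_effects=None,
            )
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title("mean dwell per cell (s)")
    fig.colorbar(im, ax=ax, shrink=0.85)
    fig.tight_layout()
    if out is not None:
        fig.savefig(Path(out), dpi=110)
        plt.close(fig)
    return fig


def build_report(analyses: dict, out, fmt: str = "json") -> dict:
    """Bundle a batch analysis (see :func:`handmotion.pipeline.analyze_batch`)
    into a single report file; returns the JSON-ready structure.

    Raises on an empty analysis set or duplicated procedure ids.
    """
    procedures = analyses.get("procedures") or []
    if not procedures:
        raise ValueError("cannot build a report from an empty analysis set")
    ids = [p["procedure_id"] for p in procedures]
    if len(set(ids)) != len(ids):
        raise ValueError(f"inconsistent session ids: duplicates in {ids}")
    payload = _jsonify(analyses)
    out = Path(out)
    if fmt == "json":
        out.write_text(json.dumps(payload, indent=2))
    elif fmt == "html":
        body = json.dumps(payload, indent=2)
        out.write_text(
            "<html><head><title>hand-motion report</title></head>"
            f"<body><pre>{body}</pre></body></html>"
        )
    else:
        raise ValueError(f"unknown report format {fmt!r}")
    return payload


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(_plain(k)): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return _plain(obj)


def _plain(v):
    if isinstance(v, EventKind):
        return v.value
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating, float)):
        v = float(v)
        return None if np.isnan(v) else v
    if isinstance(v, np.ndarray):
        return _jsonify(v.tolist())
    return v
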