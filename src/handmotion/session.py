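"""Session container and file formats for hand-landmark streams.

A *session* is the output of a 21-keypoint hand-pose detector run over one
recorded procedure: for every video frame and each detected hand, up to 21
``(x, y)`` pixel positions (digit joints and wrist), plus occasional "null
detection" records where the detector fired without resolving handedness.

Conventions
-----------
* Frames are 0-based; the time of frame ``i`` is the half-open interval
  ``[i/fps, (i+1)/fps)``.
* Pixel origin is the top-left corner; ``y`` increases downward, so a hand
  reaching toward the top of the image approaches ``y = 0``.
* A hand absent from a frame (tracking loss) is represented by the absence
  of records; a null detection is an explicit record with ``hand == "none"``
  carrying no landmark id or coordinates.
* Coordinates are stored and written with two-decimal pixel precision.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

HAND_LEFT = "left"
HAND_RIGHT = "right"
HAND_NONE = "none"
HANDS = (HAND_LEFT, HAND_NONE, HAND_RIGHT)  # sort order used throughout

N_LANDMARKS = 21
#: landmark id of the tip of the third (middle) digit, the occupancy proxy
MIDDLE_FINGERTIP = 12

#: sentinel landmark id stored for null-detection records
NULL_LANDMARK_ID = -1

RECORD_COLUMNS = ("frame_index", "hand", "landmark_id", "x_px", "y_px")

_META_KEYS = ("procedure_id", "fps", "width_px", "height_px", "duration_s")


class SessionFormatError(ValueError):
    """Raised when a session file does not conform to the on-disk schema."""


class SessionValidationError(ValueError):
    """Raised when session content violates the record invariants."""


@dataclass(frozen=True)
class SessionMeta:
    """Recording metadata for one procedure.

    ``n_frames`` is derived as ``round(duration_s * fps)`` when not given and
    must satisfy that identity when it is.
    """

    procedure_id: str
    fps: float = 30.0
    width_px: int = 1920
    height_px: int = 1080
    duration_s: float = 600.0
    n_frames: int = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.fps <= 0:
            raise SessionValidationError(f"fps must be > 0, got {self.fps}")
        if self.width_px <= 0 or self.height_px <= 0:
            raise SessionValidationError(
                f"frame dimensions must be positive, got "
                f"{self.width_px}x{self.height_px}"
            )
        if self.duration_s < 0:
            raise SessionValidationError("duration_s must be >= 0")
        expected = int(round(self.duration_s * self.fps))
        if self.n_frames is None:
            object.__setattr__(self, "n_frames", expected)
        elif self.n_frames != expected:
            raise SessionValidationError(
                f"n_frames={self.n_frames} inconsistent with "
                f"round(duration_s*fps)={expected}"
            )

    def to_dict(self) -> dict:
        return {
            "procedure_id": self.procedure_id,
            "fps": self.fps,
            "width_px": self.width_px,
            "height_px": self.height_px,
            "duration_s": self.duration_s,
            "n_frames": self.n_frames,
        }


def _empty_records() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "frame_index": pd.Series(dtype=np.int64),
            "hand": pd.Series(dtype=object),
            "landmark_id": pd.Series(dtype=np.int64),
            "x_px": pd.Series(dtype=float),
            "y_px": pd.Series(dtype=float),
        }
    )


def _normalize_records(records: pd.DataFrame) -> pd.DataFrame:
    if records is None or len(records) == 0:
        return _empty_records()
    df = records.loc[:, list(RECORD_COLUMNS)].copy()
    df["frame_index"] = df["frame_index"].astype(np.int64)
    df["landmark_id"] = (
        df["landmark_id"].fillna(NULL_LANDMARK_ID).astype(np.int64)
    )
    df["hand"] = df["hand"].astype(object)
    df["x_px"] = df["x_px"].astype(float)
    df["y_px"] = df["y_px"].astype(float)
    df = df.sort_values(
        ["frame_index", "hand", "landmark_id"], kind="mergesort"
    ).reset_index(drop=True)
    return df


@dataclass(eq=False)
class Session:
    """One procedure's landmark stream: metadata plus a sorted record table.

    ``records`` columns: ``frame_index, hand, landmark_id, x_px, y_px``.
    Null-detection rows carry ``hand == "none"``, ``landmark_id == -1`` and
    NaN coordinates.
    """

    meta: SessionMeta
    records: pd.DataFrame = field(default_factory=_empty_records)

    def __post_init__(self):
        self.records = _normalize_records(self.records)

    @property
    def n_records(self) -> int:
        return len(self.records)

    def equals(self, other: "Session") -> bool:
        return self.meta == other.meta and self.records.equals(other.records)

    def validate(self) -> "Session":
        """Check all record invariants; raise :class:`SessionValidationError`."""
        df = self.records
        if len(df) == 0:
            return self

        bad_hand = ~df["hand"].isin(HANDS)
        if bad_hand.any():
            raise SessionValidationError(
                f"unknown hand label(s) {sorted(df.loc[bad_hand, 'hand'].unique())} "
                f"first at row {int(np.flatnonzero(bad_hand)[0])}"
            )
        if (df["frame_index"] < 0).any() or (
            df["frame_index"] >= self.meta.n_frames
        ).any():
            bad = df[
                (df["frame_index"] < 0)
                | (df["frame_index"] >= self.meta.n_frames)
            ]
            raise SessionValidationError(
                f"frame_index outside [0, {self.meta.n_frames}) "
                f"first at row {int(bad.index[0])}"
            )

        handed = df[df["hand"] != HAND_NONE]
        if len(handed):
            bad_id = (handed["landmark_id"] < 0) | (
                handed["landmark_id"] >= N_LANDMARKS
            )
            if bad_id.any():
                raise SessionValidationError(
                    f"landmark_id outside 0..{N_LANDMARKS - 1} "
                    f"first at row {int(handed.index[bad_id][0])}"
                )
            if not np.isfinite(handed[["x_px", "y_px"]].to_numpy()).all():
                raise SessionValidationError(
                    "non-finite coordinates on a detected-hand record"
                )
            # all-or-none: each (frame, hand) group carries all 21 landmarks
            sizes = handed.groupby(["frame_index", "hand"], sort=False)[
                "landmark_id"
            ].agg(["size", "nunique"])
            bad_groups = sizes[
                (sizes["size"] != N_LANDMARKS)
                | (sizes["nunique"] != N_LANDMARKS)
            ]
            if len(bad_groups):
                frame, hand = bad_groups.index[0]
                raise SessionValidationError(
                    f"frame {frame} hand '{hand}' carries "
                    f"{int(bad_groups['size'].iloc[0])} landmark records; "
                    f"a detected hand must carry all {N_LANDMARKS} or none"
                )

        nulls = df[df["hand"] == HAND_NONE]
        if len(nulls):
            if (nulls["landmark_id"] != NULL_LANDMARK_ID).any():
                raise SessionValidationError(
                    "null-detection records must not carry a landmark_id"
                )
            if np.isfinite(nulls[["x_px", "y_px"]].to_numpy()).any():
                raise SessionValidationError(
                    "null-detection records must not carry coordinates"
                )
        return self


def frame_time(frame_index: int, meta: SessionMeta) -> float:
    """Seconds elapsed at the start of ``frame_index`` (= index / fps)."""
    if not 0 <= frame_index < meta.n_frames:
        raise ValueError(
            f"frame_index {frame_index} outside [0, {meta.n_frames})"
        )
    return frame_index / meta.fps


# ---------------------------------------------------------------------------
# on-disk formats
# ---------------------------------------------------------------------------

def _meta_value(key: str, raw: str):
    if key == "procedure_id":
        return raw
    if key in ("width_px", "height_px"):
        return int(raw)
    return float(raw)


def _fmt_num(x: float) -> str:
    return f"{int(x)}" if float(x) == int(x) else repr(float(x))


def _coords_to_text(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    is_null = out["hand"] == HAND_NONE
    for col in ("x_px", "y_px"):
        vals = out[col].map(lambda v: f"{v:.2f}")
        vals[is_null] = ""
        out[col] = vals
    lm = out["landmark_id"].astype(str)
    lm[is_null] = ""
    out["landmark_id"] = lm
    return out


def write_session(session: Session, path, format: str = "csv") -> Path:
    """Write ``session`` to ``path`` in CSV or JSON form.

    Coordinates are emitted at two-decimal precision; a session whose
    coordinates are already quantized round-trips bit-exactly.
    """
    path = Path(path)
    fmt = format.lower()
    meta = session.meta
    if fmt == "csv":
        buf = io.StringIO()
        buf.write(f"#procedure_id={meta.procedure_id}\n")
        buf.write(f"#fps={_fmt_num(meta.fps)}\n")
        buf.write(f"#width_px={meta.width_px}\n")
        buf.write(f"#height_px={meta.height_px}\n")
        buf.write(f"#duration_s={_fmt_num(meta.duration_s)}\n")
        buf.write(",".join(RECORD_COLUMNS) + "\n")
        if session.n_records:
            _coords_to_text(session.records).to_csv(
                buf, index=False, header=False
            )
        path.write_text(buf.getvalue())
    elif fmt == "json":
        recs = []
        for row in session.records.itertuples(index=False):
            null = row.hand == HAND_NONE
            recs.append(
                {
                    "frame_index": int(row.frame_index),
                    "hand": row.hand,
                    "landmark_id": None if null else int(row.landmark_id),
                    "x_px": None if null else round(float(row.x_px), 2),
                    "y_px": None if null else round(float(row.y_px), 2),
                }
            )
        path.write_text(
            json.dumps({"meta": meta.to_dict(), "records": recs}, indent=None)
        )
    else:
        raise ValueError(f"unknown session format {format!r}")
    return path


def _read_csv(path: Path) -> Session:
    meta_kv = {}
    with open(path) as fh:
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            if "=" not in line:
                raise SessionFormatError(
                    f"{path}: malformed meta line {line.strip()!r}"
                )
            key, _, raw = line[1:].strip().partition("=")
            meta_kv[key] = raw
        missing = [k for k in _META_KEYS if k not in meta_kv]
        if missing:
            raise SessionFormatError(
                f"{path}: missing meta header line(s) for {missing}"
            )
        try:
            df = pd.read_csv(fh, dtype={"hand": object})
        except Exception as exc:  # pandas names the offending line
            raise SessionFormatError(f"{path}: {exc}") from exc
    if list(df.columns) != list(RECORD_COLUMNS):
        raise SessionFormatError(
            f"{path}: expected columns {list(RECORD_COLUMNS)}, "
            f"got {list(df.columns)}"
        )
    for col in ("frame_index", "landmark_id", "x_px", "y_px"):
        if len(df) and not pd.api.types.is_numeric_dtype(df[col]):
            bad = pd.to_numeric(df[col], errors="coerce")
            row = int(np.flatnonzero(bad.isna() & df[col].notna())[0])
            raise SessionValidationError(
                f"{path}: non-numeric value in column {col!r} at data row {row}"
            )
    meta = SessionMeta(**{k: _meta_value(k, v) for k, v in meta_kv.items()})
    return Session(meta, df)


def _read_json(path: Path) -> Session:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SessionFormatError(f"{path}: invalid JSON ({exc})") from exc
    if "meta" not in payload or "records" not in payload:
        raise SessionFormatError(f"{path}: missing 'meta' or 'records'")
    meta_kv = payload["meta"]
    missing = [k for k in _META_KEYS if k not in meta_kv]
    if missing:
        raise SessionFormatError(f"{path}: meta missing {missing}")
    meta = SessionMeta(
        procedure_id=str(meta_kv["procedure_id"]),
        fps=float(meta_kv["fps"]),
        width_px=int(meta_kv["width_px"]),
        height_px=int(meta_kv["height_px"]),
        duration_s=float(meta_kv["duration_s"]),
    )
    if payload["records"]:
        df = pd.DataFrame(payload["records"])
    else:
        df = _empty_records()
    return Session(meta, df)


def read_session(path, format: str = None) -> Session:
    """Read and validate a session file (CSV or JSON).

    ``format`` defaults to the file suffix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        session = _read_csv(path)
    elif fmt == "json":
        session = _read_json(path)
    else:
        raise ValueError(f"unknown session format {fmt!r}")
    return session.validate()
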