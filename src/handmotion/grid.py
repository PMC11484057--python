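"""Calibration grid and per-frame cell occupancy.

The camera frame is partitioned into a 3x3 grid of cells numbered 1-9 in
row-major order (1-3 top row, 4-6 middle, 7-9 bottom). Cell semantics in the
recording setup: the surgical field sits in the center cell (5), the
instrument table in the middle-left cell (4), the microscope handles across
the top row (1-3), the trash bin in the bottom-left cell (7) and the
picture-in-picture microsurgical feed in the bottom-right cell (9).

Bins are half-open ``[edge_i, edge_{i+1})``; points exactly on the right or
bottom frame edge belong to the last column/row, so every in-frame point
maps to exactly one cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .session import MIDDLE_FINGERTIP, N_LANDMARKS, Session

#: cell-series value for frames where the hand yielded no landmark
UNDETECTED = 0
#: assign_cell sentinel for points outside the frame (UNDETECTED downstream)
OUT_OF_FRAME = -1

CELL_IDS = tuple(range(1, 10))


@dataclass(frozen=True)
class GridSpec:
    """3x3 cell geometry over a ``width_px`` x ``height_px`` frame."""

    width_px: float
    height_px: float
    x_edges: tuple = None  # type: ignore[assignment]
    y_edges: tuple = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("grid dimensions must be positive")
        for name, edges, limit in (
            ("x_edges", self.x_edges, self.width_px),
            ("y_edges", self.y_edges, self.height_px),
        ):
            if edges is None:
                thirds = (0.0, limit / 3.0, 2.0 * limit / 3.0, float(limit))
                object.__setattr__(self, name, thirds)
            else:
                edges = tuple(float(e) for e in edges)
                if len(edges) != 4 or any(np.diff(edges) <= 0):
                    raise ValueError(
                        f"{name} must be 4 strictly ascending bounds"
                    )
                if edges[0] != 0 or edges[3] != limit:
                    raise ValueError(
                        f"{name} must span [0, {limit}], got {edges}"
                    )
                object.__setattr__(self, name, edges)

    def cell_center(self, cell: int) -> tuple:
        """Pixel center of ``cell`` (1-9, row-major)."""
        if cell not in CELL_IDS:
            raise ValueError(f"cell must be 1..9, got {cell}")
        r, c = divmod(cell - 1, 3)
        return (
            0.5 * (self.x_edges[c] + self.x_edges[c + 1]),
            0.5 * (self.y_edges[r] + self.y_edges[r + 1]),
        )


def make_grid(width_px, height_px, x_edges=None, y_edges=None) -> GridSpec:
    """Equal-thirds 3x3 grid over the frame; edges overridable for
    calibrations that were not drawn at exact thirds."""
    return GridSpec(width_px, height_px, x_edges, y_edges)


def assign_cells(x_px, y_px, grid: GridSpec) -> np.ndarray:
    """Vectorized cell assignment; OUT_OF_FRAME for points off the frame.

    Points on the right/bottom frame edge are folded into the last
    column/row.
    """
    x = np.asarray(x_px, dtype=float)
    y = np.asarray(y_px, dtype=float)
    col = np.searchsorted(np.asarray(grid.x_edges[1:3]), x, side="right")
    row = np.searchsorted(np.asarray(grid.y_edges[1:3]), y, side="right")
    cells = (row * 3 + col + 1).astype(np.int64)
    out = (
        (x < 0) | (x > grid.width_px) | (y < 0) | (y > grid.height_px)
        | ~np.isfinite(x) | ~np.isfinite(y)
    )
    cells = np.where(out, OUT_OF_FRAME, cells)
    return cells


def assign_cell(x_px: float, y_px: float, grid: GridSpec) -> int:
    """Cell id 1-9 of one point, or OUT_OF_FRAME."""
    return int(assign_cells(x_px, y_px, grid))


@dataclass
class CellSeries:
    """Per-frame cell occupancy of one hand.

    ``cells[i]`` is the grid cell (1-9) of the occupancy landmark at frame
    ``i``, or UNDETECTED (0) when the hand yielded no landmark there.
    """

    hand: str
    cells: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.cells = np.asarray(self.cells, dtype=np.int16)
        bad = ~np.isin(self.cells, (UNDETECTED,) + CELL_IDS)
        if bad.any():
            raise ValueError(
                f"cell values must be 0..9, got {self.cells[bad][0]}"
            )

    def __len__(self) -> int:
        return len(self.cells)


def cell_series(
    session: Session,
    grid: GridSpec,
    hand: str,
    landmark_id: int = MIDDLE_FINGERTIP,
) -> CellSeries:
    """Occupancy series of ``hand`` from one landmark (default: landmark 12,
    the middle fingertip, the cell-timing proxy).

    Frames where the hand has no records — and frames whose landmark falls
    outside the frame — are UNDETECTED.
    """
    if not 0 <= landmark_id < N_LANDMARKS:
        raise ValueError(f"landmark_id must be 0..{N_LANDMARKS - 1}")
    df = session.records
    sub = df[(df["hand"] == hand) & (df["landmark_id"] == landmark_id)]
    cells = np.full(session.meta.n_frames, UNDETECTED, dtype=np.int16)
    if len(sub):
        assigned = assign_cells(
            sub["x_px"].to_numpy(), sub["y_px"].to_numpy(), grid
        )
        assigned[assigned == OUT_OF_FRAME] = UNDETECTED
        cells[sub["frame_index"].to_numpy()] = assigned
    return CellSeries(hand=hand, cells=cells)
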