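"""The 16x9 AOI mesh: pixel coordinates -> AOI labels -> image halves.

The display is tiled by a regular mesh of Areas Of Interest (AOIs),
144 cells of 100x100 px on the default 1600x900 screen.  Labels are
1-based: the left half is numbered 1..72 and the right half 73..144,
row-major within each half (left-to-right within a row, rows
top-to-bottom, y increasing downward).  Which half is "Green" on a given
trial comes from the trial layout, so AOI -> condition is a per-trial
lookup, not a property of the mesh.

All half-level and trial-level metrics downstream are invariant to the
numbering convention within a half; row-major is simply stated once and
used everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

from .io_model import ScanPath

logger = logging.getLogger(__name__)

LEFT = "left"
RIGHT = "right"
GREEN = "green"
NORMAL = "normal"


@dataclass(frozen=True)
class AOIGrid:
    """Regular AOI mesh over the display.

    Defaults give the study geometry: 1600x900 px split into 16x9 cells
    of exactly 100x100 px, 144 AOIs, half-split at column 8.
    """

    screen_w_px: int = 1600
    screen_h_px: int = 900
    n_cols: int = 16
    n_rows: int = 9

    def __post_init__(self) -> None:
        if self.n_cols <= 0 or self.n_rows <= 0:
            raise ValueError("mesh dimensions must be positive")
        if self.screen_w_px % self.n_cols:
            raise ValueError(
                f"screen width {self.screen_w_px} not divisible by "
                f"n_cols {self.n_cols}")
        if self.screen_h_px % self.n_rows:
            raise ValueError(
                f"screen height {self.screen_h_px} not divisible by "
                f"n_rows {self.n_rows}")
        if self.n_cols % 2:
            raise ValueError("n_cols must be even so the screen splits into "
                             "two equal image halves")

    @property
    def cell_w_px(self) -> int:
        return self.screen_w_px // self.n_cols

    @property
    def cell_h_px(self) -> int:
        return self.screen_h_px // self.n_rows

    @property
    def n_aois(self) -> int:
        return self.n_cols * self.n_rows

    @property
    def half_cols(self) -> int:
        return self.n_cols // 2


class AOIEntry(NamedTuple):
    """A fixation mapped onto the mesh."""

    aoi_id: int
    onset_ms: float
    duration_ms: float


def point_to_aoi(x_px: float, y_px: float, grid: AOIGrid = AOIGrid()) -> int | None:
    """Map a screen point to its 1-based AOI label, or None if off-screen.

    Cells are half-open ``[x0, x0+cell_w) x [y0, y0+cell_h)`` with the
    right and bottom screen edges closed, so every on-screen point lies in
    exactly one cell.  Left half -> 1..n_aois/2, right half ->
    n_aois/2+1..n_aois, row-major within each half.
    """
    if not (0 <= x_px <= grid.screen_w_px and 0 <= y_px <= grid.screen_h_px):
        return None
    col = min(int(x_px // grid.cell_w_px), grid.n_cols - 1)
    row = min(int(y_px // grid.cell_h_px), grid.n_rows - 1)
    half = grid.half_cols
    if col < half:  # left half
        return row * half + col + 1
    return grid.n_aois // 2 + row * half + (col - half) + 1


def aoi_half(aoi_id: int, grid: AOIGrid = AOIGrid()) -> str:
    """Which image half an AOI belongs to: 'left' iff aoi_id <= n_aois/2."""
    if not 1 <= aoi_id <= grid.n_aois:
        raise ValueError(f"AOI id {aoi_id} outside 1..{grid.n_aois}")
    return LEFT if aoi_id <= grid.n_aois // 2 else RIGHT


def aoi_condition(aoi_id: int, scanpath: ScanPath | str,
                  grid: AOIGrid = AOIGrid()) -> str:
    """Label an AOI 'green' or 'normal' for a trial.

    ``scanpath`` may be a ScanPath (its ``green_side`` is used) or the
    side string itself.
    """
    green_side = scanpath if isinstance(scanpath, str) else scanpath.green_side
    return GREEN if aoi_half(aoi_id, grid) == green_side else NORMAL


def map_scanpath_to_aois(scanpath: ScanPath,
                         grid: AOIGrid = AOIGrid()) -> list[AOIEntry]:
    """Map each fixation onto its AOI, preserving order.

    Off-screen fixations are dropped (with a logged count); they take no
    part in any AOI-based metric.
    """
    out: list[AOIEntry] = []
    dropped = 0
    for fx in scanpath.fixations:
        aoi = point_to_aoi(fx.x_px, fx.y_px, grid)
        if aoi is None:
            dropped += 1
        else:
            out.append(AOIEntry(aoi, fx.onset_ms, fx.duration_ms))
    if dropped:
        logger.info("participant %s trial %d: %d off-screen fixation(s) "
                    "excluded from AOI mapping",
                    scanpath.participant_id, scanpath.trial_id, dropped)
    return out


def count_offscreen(scanpath: ScanPath, grid: AOIGrid = AOIGrid()) -> int:
    """Number of fixations in the path that lie outside the display."""
    return sum(point_to_aoi(fx.x_px, fx.y_px, grid) is None
               for fx in scanpath.fixations)
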