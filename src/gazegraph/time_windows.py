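"""Early / late viewing-phase windows over a scan path.

Scene viewing is analyzed in three slices of the 10 s trial: the full
view [0, 10 s), the early phase [0, 2 s) where stimulus-driven (ambient)
behaviour dominates, and the late phase [4, 6 s) where goal-driven
(focal) behaviour dominates.  The 2-4 s transition is deliberately
disregarded.

Window membership is decided by fixation onset alone, half-open on
[start, end): a fixation that begins inside the window but outlasts it is
included with its full duration.  Transitions for a windowed graph are
counted only between consecutive included fixations, so the windowed
graph is computable from the windowed path alone.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .io_model import ScanPath

FULL = "full"
EARLY = "early"
LATE = "late"


@dataclass(frozen=True)
class TimeWindow:
    """Half-open analysis window [start_ms, end_ms) over trial time."""

    label: str
    start_ms: float
    end_ms: float

    def __post_init__(self) -> None:
        if not self.start_ms < self.end_ms:
            raise ValueError(
                f"window {self.label!r}: start {self.start_ms} must be "
                f"< end {self.end_ms}")

    def contains(self, onset_ms: float) -> bool:
        return self.start_ms <= onset_ms < self.end_ms


#: The three default analysis windows.
DEFAULT_WINDOWS: dict[str, TimeWindow] = {
    FULL: TimeWindow(FULL, 0.0, 10000.0),
    EARLY: TimeWindow(EARLY, 0.0, 2000.0),
    LATE: TimeWindow(LATE, 4000.0, 6000.0),
}


def slice_scanpath(scanpath: ScanPath, window: TimeWindow) -> ScanPath:
    """Restrict a scan path to the fixations beginning inside a window.

    Inclusion is by onset only (``start <= onset < end``); durations are
    never clipped, so a fixation straddling the window's end keeps its
    full length.  Order is preserved.  Fixations with onset before trial
    start (negative onset carryover) can never satisfy the onset rule for
    the default windows and are therefore excluded.
    """
    kept = [fx for fx in scanpath.fixations if window.contains(fx.onset_ms)]
    return replace(scanpath, fixations=kept)
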