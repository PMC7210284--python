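"""Fixation data model and tabular I/O.

The unit record of the pipeline is a detected fixation: who looked, in
which trial, when (milliseconds from stimulus onset), for how long, and
where on the screen (pixels).  Fixations arrive pre-detected, in the shape
of a vendor fixation-event export (one CSV row per fixation); saccades are
only implicit as the transition between consecutive fixations.

A second small CSV — the trial layout table — states for every
(participant, trial) which screen half carried the color-quantized
("Green") image.  The side is data, not a constant: counterbalancing is an
experimental choice that must travel with the fixation report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical column order of the fixation report dialect.
FIXATION_COLUMNS = ("participant", "trial", "onset_ms", "duration_ms", "x", "y")

#: Canonical columns of the trial layout table.
LAYOUT_COLUMNS = ("participant", "trial", "green_side")

#: Ordered age-group labels, binned half-open: [4, 6), [6, 8), [8, 10].
AGE_GROUPS = ("4-6", "6-8", "8-10")

SIDES = ("left", "right")


@dataclass(frozen=True)
class FixationEvent:
    """One detected fixation.

    Coordinates may lie outside the display (tracker noise); such events
    are kept in the raw model and flagged downstream when mapped to AOIs.
    """

    participant_id: str
    trial_id: int
    onset_ms: float
    duration_ms: float
    x_px: float
    y_px: float

    @property
    def offset_ms(self) -> float:
        """End time of the fixation (onset + duration)."""
        return self.onset_ms + self.duration_ms


@dataclass
class ScanPath:
    """Time-ordered fixation sequence for one participant x trial.

    ``green_side`` records which screen half ('left'/'right') showed the
    Green image on this trial.
    """

    participant_id: str
    trial_id: int
    fixations: list[FixationEvent] = field(default_factory=list)
    green_side: str = "left"
    trial_duration_ms: float = 10000.0

    def __len__(self) -> int:
        return len(self.fixations)

    def __iter__(self):
        return iter(self.fixations)


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_scanpath`."""

    index: int
    field: str
    message: str


class FormatError(ValueError):
    """Raised when a tabular input is structurally malformed."""


def validate_scanpath(scanpath: ScanPath) -> list[Violation]:
    """Check ScanPath invariants; return every violation (never raises).

    Checks: positive durations, non-negative onsets, temporal ordering,
    no overlap between successive fixations, and a defined green side.
    """
    out: list[Violation] = []
    if scanpath.green_side not in SIDES:
        out.append(Violation(-1, "green_side",
                             f"green_side must be one of {SIDES}, "
                             f"got {scanpath.green_side!r}"))
    prev_end = None
    prev_onset = None
    for i, fx in enumerate(scanpath.fixations):
        if fx.duration_ms <= 0:
            out.append(Violation(i, "duration_ms",
                                 f"duration_ms must be > 0, got {fx.duration_ms}"))
        if fx.onset_ms < 0:
            out.append(Violation(i, "onset_ms",
                                 f"onset_ms must be >= 0, got {fx.onset_ms}"))
        if prev_onset is not None and fx.onset_ms < prev_onset:
            out.append(Violation(i, "onset_ms",
                                 "fixations not sorted by onset "
                                 f"({fx.onset_ms} < {prev_onset})"))
        if prev_end is not None and fx.onset_ms < prev_end:
            out.append(Violation(i, "onset_ms",
                                 "fixation overlaps the previous one "
                                 f"(onset {fx.onset_ms} < previous end {prev_end})"))
        prev_onset = fx.onset_ms
        prev_end = fx.offset_ms
    return out


def _apply_column_map(df: pd.DataFrame,
                      column_map: Mapping[str, str] | None) -> pd.DataFrame:
    if column_map:
        df = df.rename(columns={src: dst for dst, src in column_map.items()})
    return df


def read_trial_layout(path: str | Path) -> pd.DataFrame:
    """Read the trial layout CSV (participant, trial, green_side)."""
    df = pd.read_csv(path, dtype={"participant": str})
    missing = [c for c in LAYOUT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"layout table missing column(s): {', '.join(missing)}")
    bad = ~df["green_side"].isin(SIDES)
    if bad.any():
        raise FormatError(
            f"layout table has invalid green_side value(s): "
            f"{sorted(df.loc[bad, 'green_side'].unique())}")
    return df


def read_fixation_report(
    path: str | Path,
    layout: str | Path | pd.DataFrame,
    *,
    column_map: Mapping[str, str] | None = None,
    screen_size: tuple[float, float] = (1600.0, 900.0),
    trial_duration_ms: float = 10000.0,
) -> list[ScanPath]:
    """Read a fixation-event CSV into one ScanPath per (participant, trial).

    Parameters
    ----------
    path
        CSV with header ``participant,trial,onset_ms,duration_ms,x,y``.
        ``column_map`` maps canonical names to the file's actual column
        names (``{"onset_ms": "Event Start Trial Time [ms]", ...}``) so
        real vendor exports can be adapted without rewriting them.
    layout
        Trial layout table (path or DataFrame) giving ``green_side`` for
        every trial present in the report.  A trial absent from the layout
        is an error: the Green/Normal assignment cannot be guessed.
    screen_size
        Display bounds used only to count (and log) off-screen fixations;
        the events themselves are retained.

    Rows that are not time-sorted within a trial are sorted, with a logged
    notice.  Returns ScanPaths sorted by (participant, trial).
    """
    df = pd.read_csv(path, dtype={"participant": str},
                     float_precision="round_trip")
    df = _apply_column_map(df, column_map)
    missing = [c for c in FIXATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"fixation report missing column(s): {', '.join(missing)}")

    if isinstance(layout, (str, Path)):
        layout = read_trial_layout(layout)
    layout_key = {(str(p), int(t)): s for p, t, s in
                  zip(layout["participant"], layout["trial"], layout["green_side"])}

    w, h = screen_size
    n_offscreen = int((~((df["x"] >= 0) & (df["x"] <= w)
                         & (df["y"] >= 0) & (df["y"] <= h))).sum())
    if n_offscreen:
        logger.info("fixation report: %d of %d fixations fall outside the "
                    "%gx%g display (flagged, retained)",
                    n_offscreen, len(df), w, h)

    paths: list[ScanPath] = []
    for (pid, tid), sub in df.groupby(["participant", "trial"], sort=True):
        pid, tid = str(pid), int(tid)
        if (pid, tid) not in layout_key:
            raise FormatError(
                f"trial (participant={pid}, trial={tid}) missing from layout table")
        if not sub["onset_ms"].is_monotonic_increasing:
            logger.info("participant %s trial %d: rows not time-sorted; sorting",
                        pid, tid)
            sub = sub.sort_values("onset_ms", kind="stable")
        fixations = [
            FixationEvent(pid, tid, float(r.onset_ms), float(r.duration_ms),
                          float(r.x), float(r.y))
            for r in sub.itertuples()
        ]
        paths.append(ScanPath(pid, tid, fixations,
                              green_side=layout_key[(pid, tid)],
                              trial_duration_ms=trial_duration_ms))
    return paths


def write_fixation_report(scanpaths: Iterable[ScanPath], path: str | Path) -> None:
    """Write scan paths back to the canonical fixation-report CSV.

    Round-trips with :func:`read_fixation_report` field-for-field.
    """
    rows = [
        (sp.participant_id, sp.trial_id, fx.onset_ms, fx.duration_ms,
         fx.x_px, fx.y_px)
        for sp in scanpaths for fx in sp.fixations
    ]
    pd.DataFrame(rows, columns=FIXATION_COLUMNS).to_csv(path, index=False)


def write_trial_layout(scanpaths: Iterable[ScanPath], path: str | Path) -> None:
    """Write the trial layout CSV implied by the scan paths' green sides."""
    rows = [(sp.participant_id, sp.trial_id, sp.green_side) for sp in scanpaths]
    pd.DataFrame(rows, columns=LAYOUT_COLUMNS).to_csv(path, index=False)


def assign_age_group(age_years: float) -> str:
    """Bin a continuous age into the study's groups: [4,6), [6,8), [8,10]."""
    if 4 <= age_years < 6:
        return AGE_GROUPS[0]
    if 6 <= age_years < 8:
        return AGE_GROUPS[1]
    if 8 <= age_years <= 10:
        return AGE_GROUPS[2]
    raise ValueError(f"age {age_years} outside the studied range [4, 10]")


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read the cohort CSV (participant_id, age_years, age_group)."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in ("participant_id", "age_years", "age_group")
               if c not in df.columns]
    if missing:
        raise FormatError(f"cohort table missing column(s): {', '.join(missing)}")
    mismatch = [
        (p, a, g) for p, a, g in
        zip(df["participant_id"], df["age_years"], df["age_group"])
        if assign_age_group(float(a)) != g
    ]
    if mismatch:
        raise FormatError(
            f"cohort table: age_group inconsistent with age_years for "
            f"{[m[0] for m in mismatch]}")
    return df


def sort_fixations(scanpath: ScanPath) -> ScanPath:
    """Return a copy with fixations sorted by onset (stable)."""
    return replace(scanpath,
                   fixations=sorted(scanpath.fixations, key=lambda f: f.onset_ms))
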