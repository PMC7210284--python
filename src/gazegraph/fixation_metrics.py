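"""Per-AOI fixation time — the traditional counterpart to centrality.

Each fixation's whole duration is credited to the single AOI containing
its centroid; the trial statistic is the sum over the 144 AOIs, split
into Green/Normal halves, and the participant statistic is the mean of
trial totals.  Both metrics consume the identical AOI mapping, so their
condition labels can never disagree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .aoi_grid import AOIEntry, AOIGrid, aoi_condition, GREEN
from .io_model import ScanPath


@dataclass
class FixationTimeResult:
    """Summed fixation durations per AOI for one trial (ms).

    ``per_aoi[k]`` is the dwell in 1-based AOI k+1;
    trial_total_ms == per_aoi.sum() == green_ms + normal_ms.
    """

    per_aoi: np.ndarray
    trial_total_ms: float
    green_ms: float
    normal_ms: float


def fixation_time(scanpath_aois: Sequence[AOIEntry], grid: AOIGrid,
                  scanpath: ScanPath | str) -> FixationTimeResult:
    """Accumulate fixation durations into their AOIs.

    ``scanpath_aois`` is the output of
    :func:`gazegraph.aoi_grid.map_scanpath_to_aois` (off-screen fixations
    already excluded); ``scanpath`` supplies the trial's green side (a
    ScanPath or the side string).
    """
    per_aoi = np.zeros(grid.n_aois)
    for entry in scanpath_aois:
        per_aoi[entry.aoi_id - 1] += entry.duration_ms
    green = 0.0
    for aoi in range(1, grid.n_aois + 1):
        if aoi_condition(aoi, scanpath, grid) == GREEN:
            green += per_aoi[aoi - 1]
    total = float(per_aoi.sum())
    return FixationTimeResult(per_aoi=per_aoi, trial_total_ms=total,
                              green_ms=green, normal_ms=total - green)


def participant_fixation_time(trial_totals: Sequence[float]) -> float:
    """Participant-level fixation time: mean of trial totals.

    Trials with zero on-screen fixations contribute 0 (they stay in the
    denominator); zero trials is an error.
    """
    if len(trial_totals) == 0:
        raise ValueError("participant has no trials to average")
    return float(np.mean(trial_totals))
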