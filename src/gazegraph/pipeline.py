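"""End-to-end analysis: scan paths -> tidy participant metric table.

For every trial and every analysis window the pipeline maps fixations
onto the AOI mesh once, then computes both metrics from that single
mapping: the transition-graph centrality sum and the fixation-time
total, each split into general / Green-half / Normal-half.  Trial values
are then averaged into one row per participant x window x condition x
metric — the table every statistical comparison consumes.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .aoi_grid import AOIGrid, map_scanpath_to_aois
from .fixation_metrics import fixation_time
from .graph_centrality import build_graph, degree_centrality, half_centrality
from .io_model import ScanPath
from .time_windows import DEFAULT_WINDOWS, TimeWindow, slice_scanpath

logger = logging.getLogger(__name__)

CONDITIONS = ("general", "green", "normal")
METRICS = ("centrality", "fixation_time_ms")

#: Column order of the tidy metric table.
METRIC_TABLE_COLUMNS = ("participant_id", "age_years", "age_group",
                        "window", "condition", "metric", "value")


def trial_metrics(scanpath: ScanPath,
                  grid: AOIGrid = AOIGrid(),
                  windows: Mapping[str, TimeWindow] = DEFAULT_WINDOWS,
                  ) -> list[dict]:
    """Compute both metrics for one trial, per window and condition.

    Returns one record per window x condition x metric with keys
    (trial_id, window, condition, metric, value).  Windows with fewer
    than two on-screen fixations yield a zero-link graph and centrality
    0 — degenerate, not missing.
    """
    rows: list[dict] = []
    for label, window in windows.items():
        sliced = slice_scanpath(scanpath, window)
        entries = map_scanpath_to_aois(sliced, grid)
        graph = build_graph([e.aoi_id for e in entries], grid.n_aois)
        cres = degree_centrality(graph)
        green_c, normal_c = half_centrality(cres, grid, scanpath)
        ft = fixation_time(entries, grid, scanpath)
        values = {
            ("general", "centrality"): cres.trial_sum,
            ("green", "centrality"): green_c,
            ("normal", "centrality"): normal_c,
            ("general", "fixation_time_ms"): ft.trial_total_ms,
            ("green", "fixation_time_ms"): ft.green_ms,
            ("normal", "fixation_time_ms"): ft.normal_ms,
        }
        for (condition, metric), value in values.items():
            rows.append({"trial_id": scanpath.trial_id, "window": label,
                         "condition": condition, "metric": metric,
                         "value": float(value)})
    return rows


def cohort_metrics(scanpaths: Iterable[ScanPath],
                   cohort: pd.DataFrame,
                   grid: AOIGrid = AOIGrid(),
                   windows: Mapping[str, TimeWindow] = DEFAULT_WINDOWS,
                   ) -> pd.DataFrame:
    """Run the pipeline over a cohort and aggregate to participant level.

    ``cohort`` holds (participant_id, age_years, age_group).  Per-trial
    values are averaged over each participant's available trials (zero
    trials for a participant present in the cohort table is an error).
    Returns the tidy table with :data:`METRIC_TABLE_COLUMNS`.
    """
    per_trial: list[dict] = []
    for sp in scanpaths:
        for row in trial_metrics(sp, grid, windows):
            row["participant_id"] = sp.participant_id
            per_trial.append(row)
    if not per_trial:
        raise ValueError("no scan paths to analyze")
    df = pd.DataFrame(per_trial)

    known = set(cohort["participant_id"])
    seen = set(df["participant_id"])
    missing = sorted(known - seen)
    if missing:
        raise ValueError(f"cohort participants with no scan paths: {missing}")
    extra = sorted(seen - known)
    if extra:
        raise ValueError(f"scan paths for unknown participants: {extra}")

    agg = (df.groupby(["participant_id", "window", "condition", "metric"],
                      sort=True, as_index=False)["value"].mean())
    out = agg.merge(cohort, on="participant_id", how="left")
    return out[list(METRIC_TABLE_COLUMNS)]
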