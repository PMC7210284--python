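"""Group-comparison statistics on the tidy metric table.

The battery mirrors a standard developmental eye-tracking analysis:
Pearson correlations of participant metrics with continuous age, a
3 (age group) x 2 (viewing phase) mixed-design ANOVA (between = group,
within = phase), post-hoc pairwise t-tests (independent between groups,
paired between phases or conditions), and a group-means report table.

Degrees of freedom are always computed from the data actually supplied,
never imitated from any external report.  Post-hoc p-values are reported
uncorrected by default (flagged as such); Holm correction is available
on request.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_model import AGE_GROUPS
from .pipeline import CONDITIONS, METRICS

PHASES = ("early", "late")


@dataclass(frozen=True)
class AnovaResult:
    """One effect of the mixed ANOVA."""

    effect: str  # 'group', 'phase' or 'interaction'
    F: float
    df_num: int
    df_den: int
    p: float


def _cell(table: pd.DataFrame, metric: str, window: str | None = None,
          condition: str | None = None) -> pd.DataFrame:
    sel = table["metric"] == metric
    if window is not None:
        sel &= table["window"] == window
    if condition is not None:
        sel &= table["condition"] == condition
    return table[sel]


def correlate_with_age(table: pd.DataFrame, metric: str, window: str,
                       condition: str) -> tuple[float, float]:
    """Pearson correlation of participant metric values with continuous age.

    Returns (r, two-sided p).  Requires >= 3 participants; a zero-variance
    variable is an error naming the degenerate side.
    """
    cell = _cell(table, metric, window, condition)
    age = cell["age_years"].to_numpy(dtype=float)
    val = cell["value"].to_numpy(dtype=float)
    if len(cell) < 3:
        raise ValueError(
            f"correlation needs >= 3 participants, got {len(cell)}")
    if np.ptp(age) == 0:
        raise ValueError("age_years has zero variance")
    if np.ptp(val) == 0:
        raise ValueError(f"metric {metric!r} has zero variance in "
                         f"window={window!r}, condition={condition!r}")
    r, p = sps.pearsonr(age, val)
    return float(r), float(p)


def mixed_anova(table: pd.DataFrame, metric: str,
                condition: str) -> list[AnovaResult]:
    """3 (age group) x 2 (early/late phase) mixed-design ANOVA.

    Between factor = age_group, within factor = viewing phase.  Every
    participant must contribute exactly one value per phase; otherwise
    the offending participants are listed.  Returns the group, phase and
    interaction effects.  Degenerate cells are resolved by convention:
    a zero effect over a zero error is F = 0 (p = 1); a positive effect
    over a zero error is F = inf (p = 0).
    """
    import pingouin as pg

    cell = _cell(table, metric, condition=condition)
    cell = cell[cell["window"].isin(PHASES)]
    counts = cell.groupby("participant_id")["window"].nunique()
    bad = sorted(counts[counts != len(PHASES)].index)
    n_rows = cell.groupby("participant_id").size()
    bad = sorted(set(bad) | set(n_rows[n_rows != len(PHASES)].index))
    if bad:
        raise ValueError(
            f"participants without exactly one value per phase: {bad}")
    if cell.empty:
        raise ValueError("no data for the requested metric/condition")

    with np.errstate(divide="ignore", invalid="ignore"):
        aov = pg.mixed_anova(data=cell, dv="value", within="window",
                             subject="participant_id", between="age_group")
    name_map = {"age_group": "group", "window": "phase",
                "Interaction": "interaction"}
    out: list[AnovaResult] = []
    for row in aov.itertuples():
        effect = name_map.get(row.Source, row.Source)
        # pingouin omits F/p-unc entirely when the data are constant
        F = float(getattr(row, "F", float("nan")))
        p = float(getattr(row, "p_unc", float("nan")))
        if math.isnan(F):  # 0/0: no effect over no error
            F, p = 0.0, 1.0
        elif math.isinf(F):
            p = 0.0
        out.append(AnovaResult(effect, F, int(row.DF1), int(row.DF2), p))
    return out


def _check_groups(a: np.ndarray, b: np.ndarray) -> None:
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 participants")
    pooled = ((len(a) - 1) * np.var(a, ddof=1)
              + (len(b) - 1) * np.var(b, ddof=1))
    if pooled == 0:
        raise ValueError("degenerate (zero) within-group variance")


def pairwise_t(table: pd.DataFrame, metric: str, group_a: str, group_b: str,
               window: str, condition: str) -> tuple[float, int, float]:
    """Independent two-sample pooled-variance t-test between two age groups
    on one (window, condition, metric) cell.  Returns (t, df, p)."""
    cell = _cell(table, metric, window, condition)
    a = cell.loc[cell["age_group"] == group_a, "value"].to_numpy(dtype=float)
    b = cell.loc[cell["age_group"] == group_b, "value"].to_numpy(dtype=float)
    _check_groups(a, b)
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), len(a) + len(b) - 2, float(p)


def paired_phase_t(table: pd.DataFrame, metric: str, group: str,
                   condition: str) -> tuple[float, int, float]:
    """Paired t-test early vs late phase within one age group.
    Returns (t, df, p) with df = n - 1."""
    cell = _cell(table, metric, condition=condition)
    cell = cell[cell["age_group"] == group]
    wide = cell.pivot(index="participant_id", columns="window", values="value")
    for phase in PHASES:
        if phase not in wide.columns or wide[phase].isna().any():
            raise ValueError(f"group {group!r}: missing {phase!r} values")
    early = wide["early"].to_numpy(dtype=float)
    late = wide["late"].to_numpy(dtype=float)
    if len(early) < 2:
        raise ValueError("paired test needs >= 2 participants")
    if np.ptp(early - late) == 0 and (early - late).sum() == 0:
        return 0.0, len(early) - 1, 1.0
    t, p = sps.ttest_rel(early, late)
    return float(t), len(early) - 1, float(p)


def paired_condition_t(table: pd.DataFrame, metric: str,
                       window: str) -> tuple[float, int, float]:
    """Paired t-test Green vs Normal half across all participants in one
    window.  Returns (t, df, p); positive t means Green > Normal."""
    cell = _cell(table, metric, window=window)
    cell = cell[cell["condition"].isin(("green", "normal"))]
    wide = cell.pivot(index="participant_id", columns="condition",
                      values="value")
    if wide.isna().any().any() or len(wide) < 2:
        raise ValueError("green/normal values missing for some participants")
    t, p = sps.ttest_rel(wide["green"].to_numpy(dtype=float),
                         wide["normal"].to_numpy(dtype=float))
    return float(t), len(wide) - 1, float(p)


def report_tables(table: pd.DataFrame) -> pd.DataFrame:
    """Group-means report: mean and n per group x window x condition x
    metric.

    The full factorial of levels observed in the table is reported in a
    deterministic order; a cell with no data appears with n = 0 and a
    missing mean (never a fabricated zero).
    """
    groups = [g for g in AGE_GROUPS if g in set(table["age_group"])]
    windows = sorted(set(table["window"]))
    conditions = [c for c in CONDITIONS if c in set(table["condition"])]
    metrics = [m for m in METRICS if m in set(table["metric"])]

    agg = table.groupby(["age_group", "window", "condition", "metric"],
                        sort=False)["value"].agg(["mean", "size"])
    rows = []
    for g in groups:
        for w in windows:
            for c in conditions:
                for m in metrics:
                    try:
                        mean, n = agg.loc[(g, w, c, m)]
                        rows.append((g, w, c, m, float(mean), int(n)))
                    except KeyError:
                        rows.append((g, w, c, m, float("nan"), 0))
    return pd.DataFrame(rows, columns=["age_group", "window", "condition",
                                       "metric", "mean", "n"])


def report_posthoc(table: pd.DataFrame, metric: str, window: str,
                   condition: str, correction: str | None = None,
                   ) -> pd.DataFrame:
    """All pairwise between-group t-tests on one cell.

    ``p`` is uncorrected (flagged in the ``p_kind`` column); pass
    ``correction='holm'`` to add Holm-adjusted p-values.
    """
    groups = [g for g in AGE_GROUPS if g in set(table["age_group"])]
    rows = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            t, df, p = pairwise_t(table, metric, ga, gb, window, condition)
            rows.append({"group_a": ga, "group_b": gb, "t": t, "df": df,
                         "p": p, "p_kind": "uncorrected"})
    out = pd.DataFrame(rows)
    if correction == "holm" and len(out):
        from statsmodels.stats.multitest import multipletests
        out["p_holm"] = multipletests(out["p"], method="holm")[1]
    elif correction not in (None, "holm"):
        raise ValueError(f"unknown correction {correction!r}")
    return out
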