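"""Synthetic free-viewing scan paths with the structure the analysis assumes.

The original study design — 60 typically developing children in three age
groups (4-6, 6-8, 8-10 y), 48 trials of 10 s free viewing on a 1600x900
display, each trial pairing a Normal photograph with its color-quantized
"Green" twin on opposite screen halves — was never deposited, so this
module generates cohorts with the same design and the statistical
regularities the method is meant to detect:

* **Two attentional modes.**  Viewing alternates between an *ambient*
  mode (short fixations, median 120 ms, with large exploratory
  relocations) dominant in the first 2 s, and a *focal* mode (long
  fixations, median 300 ms, small local saccades, mean 2.5 deg)
  dominant later.  Ambient saccades are modelled as relocations to a
  fresh landing point in a chosen image half; their amplitudes are
  therefore emergent from display geometry (mean ~15 deg, comfortably
  above the 5 deg ambient threshold), while focal amplitudes follow the
  configured gamma distribution.  Relocations, rather than a directed
  random walk, are what make the late viewing phase forget which half
  attracted the gaze early on — a memory the walk formulation retains
  long enough to contaminate the late-phase Green/Normal contrast.

* **Development.**  Fixation durations scale up with age
  (``group_dur_scale``); off-task time between fixations (blinks, track
  loss, looks away — common in younger children) scales down with age
  (``group_gap_ms``); and the propensity for ambient exploration scales
  up with age (``group_ambient_scale``), in line with the late-maturing
  dorsal pathway that ambient viewing is attributed to.  Together these
  make mean fixation duration, fixation count and transition-graph
  centrality all increase across groups.

* **Time-on-task decay and re-entries.**  Off-task gaps are short early
  in the trial and longer later (``gap_factor_early/late``), so early
  windows hold more fixation time and more transitions than late
  windows.  A gap longer than ``reentry_gap_ms`` breaks scan-path
  continuity: the next fixation is a fresh landing concentrated near an
  image centre, not a continuation of the pre-gap walk — without this,
  long gaps act as a delay line that carries early, salience-biased
  positions straight into the late analysis window.

* **Saliency anchoring.**  Relocations land in the Green half with a
  probability that ramps from ``green_bias_early`` (default 0.65) at
  stimulus onset down to an unbiased 0.5 at 2 s, mirroring the fast
  waning of low-level-feature capture over the first fixations.
  Setting the early bias to 0.5 removes the effect entirely — the
  generator's null condition.

Participant-level log-normal random effects on durations and gaps, and a
small Gaussian jitter on saliency susceptibility, provide realistic
inter-individual variation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .aoi_grid import AOIGrid
from .io_model import FixationEvent, ScanPath, assign_age_group

#: Age-group bins in years, half-open except the last: [4,6), [6,8), [8,10].
AGE_BINS = ((4.0, 6.0), (6.0, 8.0), (8.0, 10.0))


@dataclass(frozen=True)
class ModeParams:
    """One attentional mode: a fixation-duration and saccade-amplitude law.

    Durations are log-normal (``median_dur_ms`` with log-scale dispersion
    ``dur_sigma``); amplitudes are gamma with mean ``mean_amp_deg`` and
    shape ``amp_shape``.
    """

    name: str
    median_dur_ms: float
    dur_sigma: float
    mean_amp_deg: float
    amp_shape: float = 2.0


#: Default ambient mode: short fixations, large exploratory saccades.
AMBIENT = ModeParams("ambient", median_dur_ms=120.0, dur_sigma=0.35,
                     mean_amp_deg=7.0)
#: Default focal mode: long fixations, small local saccades.
FOCAL = ModeParams("focal", median_dur_ms=300.0, dur_sigma=0.35,
                   mean_amp_deg=2.5)


@dataclass
class SimulationConfig:
    """Study-design and generative parameters for a simulated cohort.

    Defaults reproduce the companion study's design: 3 age groups x
    ``n_per_group`` children, 48 trials of 10 s each on a 1600x900
    display.  ``px_per_deg`` = 35 corresponds to roughly 60 cm viewing of
    a 22-inch display and is an explicit constant, not a hidden one.
    """

    n_per_group: int = 20
    trials_per_participant: int = 48
    trial_ms: float = 10000.0
    grid: AOIGrid = field(default_factory=AOIGrid)
    px_per_deg: float = 35.0

    ambient: ModeParams = AMBIENT
    focal: ModeParams = FOCAL
    #: P(ambient mode) before / after the mode switch time.
    ambient_p_early: float = 0.8
    ambient_p_late: float = 0.2
    mode_switch_ms: float = 2000.0

    #: P(an ambient relocation lands in the Green half), early vs late.
    green_bias_early: float = 0.65
    green_bias_late: float = 0.5

    #: Multiplicative fixation-duration factor per age group (young->old).
    group_dur_scale: tuple[float, float, float] = (1.0, 1.35, 1.7)
    #: Multiplier on the ambient-mode probability per age group
    #: (young->old).  Exploratory (ambient, dorsal-pathway) viewing
    #: strengthens with age, which is what drives the developmental rise
    #: in transition-graph centrality.
    group_ambient_scale: tuple[float, float, float] = (0.6, 1.0, 1.5)
    #: Mean off-task gap between fixations per age group, ms (young->old).
    group_gap_ms: tuple[float, float, float] = (380.0, 180.0, 80.0)
    #: Gap multiplier before / after the mode switch (time-on-task decay).
    gap_factor_early: float = 0.25
    gap_factor_late: float = 3.0

    #: P(a focal saccade is aimed at the screen centre) — central bias.
    central_bias: float = 0.3

    #: Off-task gaps longer than this break scan-path continuity: the
    #: next fixation is a fresh re-entry landing rather than a
    #: continuation of the walk (blinks and looks away do not preserve
    #: the pre-gap locus).
    reentry_gap_ms: float = 300.0
    #: Spread of re-entry landings around the centre of the chosen image
    #: half.  Re-entries home in on the image, unlike ambient exploration
    #: which samples the half broadly.
    reentry_sigma_px: float = 90.0

    #: Log-scale SDs of participant random effects; SD of the per-child
    #: jitter on the early Green bias.
    participant_dur_sd: float = 0.12
    participant_gap_sd: float = 0.20
    participant_bias_sd: float = 0.03

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ambient_p_early", "ambient_p_late",
                     "green_bias_early", "green_bias_late", "central_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_per_group < 1 or self.trials_per_participant < 1:
            raise ValueError("n_per_group and trials_per_participant must be >= 1")
        if self.trial_ms <= 0:
            raise ValueError("trial_ms must be positive")
        if len(self.group_dur_scale) != 3 or len(self.group_gap_ms) != 3 \
                or len(self.group_ambient_scale) != 3:
            raise ValueError("group parameters must have one entry per age group")
        if not (self.group_dur_scale[0] < self.group_dur_scale[1]
                < self.group_dur_scale[2]):
            raise ValueError("group_dur_scale must be strictly increasing "
                             "with age")
        # the ambient/focal taxonomy (180 ms, 5 deg) must hold for the modes
        if not (self.ambient.median_dur_ms < 180.0
                and self.ambient.mean_amp_deg > 5.0):
            raise ValueError("ambient mode must have median duration < 180 ms "
                             "and mean amplitude > 5 deg")
        if not (self.focal.median_dur_ms > 180.0
                and self.focal.mean_amp_deg < 5.0):
            raise ValueError("focal mode must have median duration > 180 ms "
                             "and mean amplitude < 5 deg")

    def ambient_prob(self, t_ms: float) -> float:
        """P(ambient mode) at trial time t."""
        return self.ambient_p_early if t_ms < self.mode_switch_ms \
            else self.ambient_p_late

    def green_bias(self, t_ms: float) -> float:
        """P(an ambient relocation targets the Green half) at trial time t.

        Salience capture is strongest immediately after stimulus onset
        and wanes over the first fixations: the bias ramps linearly from
        ``green_bias_early`` at t = 0 down to 0.5 at the mode switch,
        then stays at ``green_bias_late``.
        """
        if t_ms >= self.mode_switch_ms:
            return self.green_bias_late
        ramp = 1.0 - t_ms / self.mode_switch_ms
        return 0.5 + (self.green_bias_early - 0.5) * ramp


class SimulatedCohort(NamedTuple):
    """Output of :func:`simulate_cohort`: unpacks as (paths, cohort, layout)."""

    scanpaths: list[ScanPath]
    cohort: pd.DataFrame  # participant_id, age_years, age_group
    layout: pd.DataFrame  # participant, trial, green_side


def _reflect(v: float, lo: float, hi: float) -> float:
    """Fold a coordinate back into [lo, hi] by reflection at the edges."""
    span = hi - lo
    v = (v - lo) % (2.0 * span)
    if v > span:
        v = 2.0 * span - v
    return lo + v


def simulate_scanpath(
    config: SimulationConfig,
    group: int,
    rng: np.random.Generator,
    *,
    participant_id: str = "P000",
    trial_id: int = 1,
    green_side: str | None = None,
    dur_factor: float = 1.0,
    gap_factor: float = 1.0,
    bias_offset: float = 0.0,
) -> ScanPath:
    """Simulate one trial's scan path as a fixation/saccade renewal process.

    ``group`` indexes the age group (0, 1, 2 = young to old) and selects
    the duration and gap scales.  ``dur_factor``/``gap_factor``/
    ``bias_offset`` carry participant-level random effects (1/1/0 for a
    generic child).  ``green_side`` is drawn from the rng when not given.

    Each cycle draws the attentional mode from the group-scaled
    ``ambient_prob(t)``, a log-normal fixation duration (group and
    participant scaled), an exponential off-task gap (group- and
    phase-scaled), and then the next landing point: after a long gap
    (> ``reentry_gap_ms``) a fresh re-entry landing near the centre of
    the half chosen by the salience bias at re-entry time; otherwise
    ambient -> exploratory relocation uniform in the half chosen by
    ``green_bias(t)`` (+ participant offset while the bias is active),
    focal -> gamma-amplitude step in a uniform direction (aimed at the
    screen centre with probability ``central_bias``), reflected at the
    display edges.  The final fixation is clipped at the trial end, as a
    vendor export would clip it.
    """
    grid = config.grid
    w, h = float(grid.screen_w_px), float(grid.screen_h_px)
    if green_side is None:
        green_side = "left" if rng.random() < 0.5 else "right"
    dur_scale = config.group_dur_scale[group] * dur_factor
    gap_scale = config.group_gap_ms[group] * gap_factor

    margin = 30.0
    x = min(max(w / 2.0 + rng.normal(0.0, 100.0), margin), w - margin)
    y = min(max(h / 2.0 + rng.normal(0.0, 80.0), margin), h - margin)

    def salience_bias(at_ms: float) -> float:
        # participant susceptibility shifts the pre-ramp bias, so it
        # vanishes along with the salience effect itself
        if at_ms >= config.mode_switch_ms:
            return config.green_bias_late
        ramp = 1.0 - at_ms / config.mode_switch_ms
        return 0.5 + (config.green_bias_early + bias_offset - 0.5) * ramp

    def relocate(bias: float, concentrated: bool = False) -> tuple[float, float]:
        to_green = rng.random() < min(max(bias, 0.0), 1.0)
        target_half = green_side if to_green else \
            ("right" if green_side == "left" else "left")
        if target_half == "left":
            lo, hi = margin, w / 2.0 - margin
        else:
            lo, hi = w / 2.0 + margin, w - margin
        if concentrated:  # re-entries home in on the image centre
            s = config.reentry_sigma_px
            tx = min(max((lo + hi) / 2.0 + rng.normal(0.0, s), lo), hi)
            ty = min(max(h / 2.0 + rng.normal(0.0, s), margin), h - margin)
        else:  # ambient exploration samples the half broadly
            tx = rng.uniform(lo, hi)
            ty = rng.uniform(margin, h - margin)
        return tx, ty

    fixations: list[FixationEvent] = []
    t = rng.uniform(100.0, 250.0)  # saccade latency from stimulus onset
    ambient_scale = config.group_ambient_scale[group]
    while t < config.trial_ms:
        ambient = rng.random() < min(config.ambient_prob(t) * ambient_scale, 1.0)
        mode = config.ambient if ambient else config.focal
        dur = math.exp(rng.normal(math.log(mode.median_dur_ms * dur_scale),
                                  mode.dur_sigma))
        dur = min(dur, config.trial_ms - t)
        fixations.append(FixationEvent(participant_id, trial_id, t, dur, x, y))
        t_end = t + dur
        if t_end >= config.trial_ms:
            break

        gap_ms = rng.exponential(gap_scale * (
            config.gap_factor_early if t_end < config.mode_switch_ms
            else config.gap_factor_late))

        if gap_ms > config.reentry_gap_ms:
            # off-task interval (blink / look away / track loss): scan-path
            # continuity is broken; the next fixation is a fresh landing,
            # guided by whatever salience bias holds at re-entry time
            nx, ny = relocate(salience_bias(t_end + gap_ms), concentrated=True)
            saccade_ms = 0.0  # the movement hides inside the gap
        elif ambient:
            nx, ny = relocate(salience_bias(t_end))
            amp_deg = math.hypot(nx - x, ny - y) / config.px_per_deg
            saccade_ms = 20.0 + 2.0 * amp_deg  # main-sequence ballpark
        else:
            amp_deg = rng.gamma(mode.amp_shape,
                                mode.mean_amp_deg / mode.amp_shape)
            amp_px = amp_deg * config.px_per_deg
            if rng.random() < config.central_bias:
                theta = math.atan2(h / 2.0 - y, w / 2.0 - x)
            else:
                theta = rng.uniform(0.0, 2.0 * math.pi)
            nx = _reflect(x + amp_px * math.cos(theta), 0.0, w - 1.0)
            ny = _reflect(y + amp_px * math.sin(theta), 0.0, h - 1.0)
            saccade_ms = 20.0 + 2.0 * amp_deg

        t = t_end + saccade_ms + gap_ms
        x, y = nx, ny

    return ScanPath(participant_id, trial_id, fixations,
                    green_side=green_side, trial_duration_ms=config.trial_ms)


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Simulate the full developmental cohort.

    3 x ``n_per_group`` participants with ages uniform within their group
    bins, ``trials_per_participant`` trials each; per-participant rng
    streams are spawned from the config seed, so output is reproducible
    and parallelizable by participant.
    """
    n_participants = 3 * config.n_per_group
    seeds = np.random.SeedSequence(config.seed).spawn(n_participants)

    scanpaths: list[ScanPath] = []
    cohort_rows = []
    idx = 0
    for group, (lo, hi) in enumerate(AGE_BINS):
        for _ in range(config.n_per_group):
            rng = np.random.default_rng(seeds[idx])
            pid = f"P{idx + 1:03d}"
            age = rng.uniform(lo, hi)
            dur_factor = math.exp(rng.normal(0.0, config.participant_dur_sd))
            gap_factor = math.exp(rng.normal(0.0, config.participant_gap_sd))
            bias_offset = rng.normal(0.0, config.participant_bias_sd)
            cohort_rows.append((pid, round(age, 3), assign_age_group(age)))
            for trial in range(1, config.trials_per_participant + 1):
                scanpaths.append(simulate_scanpath(
                    config, group, rng,
                    participant_id=pid, trial_id=trial,
                    dur_factor=dur_factor, gap_factor=gap_factor,
                    bias_offset=bias_offset))
            idx += 1

    cohort = pd.DataFrame(cohort_rows,
                          columns=["participant_id", "age_years", "age_group"])
    layout = pd.DataFrame(
        [(sp.participant_id, sp.trial_id, sp.green_side) for sp in scanpaths],
        columns=["participant", "trial", "green_side"])
    return SimulatedCohort(scanpaths, cohort, layout)
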