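# gazegraph

Graph-based analysis of visual scanning patterns in eye-tracking data,
built for developmental free-viewing studies in which a color-quantized
("Green") image and its Normal original compete for attention on opposite
halves of the screen.

Classical fixation-time analysis is static: it tells you *where* gaze
dwelt, not how it *moved*. `gazegraph` represents each trial's scan path
as a weighted undirected transition graph over a 16 × 9 mesh of 144 Areas
Of Interest (AOIs) tiling a 1600 × 900 display (100 × 100 px cells; left
half A1–A72, right half A73–A144) and scores every AOI with a
standardized weighted degree centrality, alongside the traditional
per-AOI fixation time computed from the identical AOI mapping. Metrics
are sliced by viewing phase — early (0–2 s), late (4–6 s), full (0–10 s),
with 2–4 s deliberately disregarded as a transition period — and by image
condition (Green half, Normal half, whole screen), then fed to the
group-comparison statistics a developmental study needs.

## The model

A trial's fixation sequence, mapped to AOIs, induces the symmetric
adjacency matrix

```
M_ij = w   if AOI i and AOI j are linked,   M_ij = 0 otherwise,
```

where the weight *w* counts gaze transitions between the two AOIs
(consecutive refixations within one AOI create no link; dwell is the
fixation-time metric's job). Each node is scored with the
tuning-parameter (Opsahl-style) standardized weighted degree centrality

```
C_D^W(i) = C_D(i) / max C_D  ×  w(i) / max W  ×  100,
```

with `C_D(i)` the number of distinct neighbours of node *i*, `w(i)` its
strength (summed link weights), and the maxima taken over the same graph.
Values lie in [0, 100]; a node attaining both maxima scores exactly 100.
The trial statistic is the sum over all 144 nodes; the participant
statistic is the mean over the participant's trials. An AOI (or image
half) with high centrality acts as an *anchor* of the scan pattern.

Because the child cohort this design comes from was never deposited, the
package ships a first-class synthetic scan-path simulator
(`gazegraph.synthetic_scanpaths`) that emulates the study: 3 age groups
(4–6, 6–8, 8–10 y) × 20 children × 48 trials of 10 s, an ambient → focal
attentional-mode mixture over the trial, age-scaled fixation durations,
off-task gaps and exploration propensity, and an early-phase salience
bias toward the Green half that decays to chance by 2 s. See
`docs/methods.md` for the generative model and its limitations.

## Worked example

Simulate a reduced cohort (10 children per group, 24 trials), run the
pipeline, and compute the statistics:

```bash
gazegraph simulate --out-dir data --seed 7 --n-per-group 10 --trials 24
gazegraph analyze --fixations data/fixations.csv --layout data/layout.csv \
                  --cohort data/cohort.csv --out results.csv
gazegraph report --results results.csv --out report
```

`report/group_means.csv` (centrality, whole screen) shows both the
developmental rise and the early-to-late drop:

```
age_group window condition     metric  mean  n
      4-6  early   general centrality 330.6 10
      4-6   full   general centrality 621.9 10
      4-6   late   general centrality  73.1 10
      6-8  early   general centrality 428.5 10
      6-8   full   general centrality 728.0 10
      6-8   late   general centrality 118.5 10
     8-10  early   general centrality 482.5 10
     8-10   full   general centrality 835.1 10
     8-10   late   general centrality 166.7 10
```

`report/green_vs_normal.csv` (paired t across participants) shows the
salience anchoring: the Green half out-scores the Normal half early, and
the two are indistinguishable by the late phase:

```
    metric window       t  df      p  significant
centrality  early  7.5697  29 0.0000         True
centrality   full  3.2463  29 0.0029         True
centrality   late -0.7723  29 0.4462        False
```

(The full-window contrast still carries the early anchoring inside it;
the phase-resolved rows are the informative ones.)

`report/age_correlations.csv` and `report/mixed_anova.csv` complete the
battery — Pearson correlations of participant centrality with continuous
age (here r = 0.73–0.79, p < 0.001) and the 3 (age group) × 2 (phase)
mixed ANOVA with group, phase and interaction effects.

The same numbers are available programmatically:

```python
from gazegraph import (SimulationConfig, simulate_cohort, cohort_metrics,
                       report_tables, paired_condition_t)

paths, cohort, layout = simulate_cohort(SimulationConfig(seed=7))
table = cohort_metrics(paths, cohort)     # tidy participant metric table
report_tables(table)                      # group means per cell
paired_condition_t(table, "centrality", "early")  # Green vs Normal
```

To analyze real data, provide the fixation report
(`participant,trial,onset_ms,duration_ms,x,y`; a `column_map` in the
config adapts other exports) plus the trial layout table
(`participant,trial,green_side`) stating which half showed the Green
image on each trial.

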