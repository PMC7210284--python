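# Methods

## Scope and data model

The pipeline consumes detected fixation events (participant, trial,
onset in ms from stimulus onset, duration in ms, screen x/y in pixels),
the shape of a vendor fixation export. Event detection, calibration and
saccade/blink parsing are out of scope; saccades exist only implicitly
as transitions between consecutive fixations. A trial layout table
supplies, per (participant, trial), which screen half carried the Green
image — the package never assumes a counterbalancing scheme.

Off-screen fixations (tracker noise) are retained in the raw model,
counted in logs, and excluded from every AOI-based metric, which keeps
the 144-cell partition exhaustive for everything downstream.

## AOI mesh

The display (1600 × 900 px by default) is tiled by a 16 × 9 mesh of
144 AOIs of exactly 100 × 100 px. Cells are half-open
`[x0, x0+w) × [y0, y0+h)` with the right/bottom screen edges closed, so
every on-screen point lies in exactly one cell. Labels are 1-based:
left half 1–72, right half 73–144, row-major within each half (rows
top-to-bottom, y downward). Row-major is a convention stated once; all
half-level and trial-level metrics are invariant to any relabeling
within a half (property-tested). The 1 cm physical gap and gray
background between the two photographs are not modelled as separate
regions: the halves proxy the images, exactly as the A1–A72 / A73–A144
coding implies. An optional rectangular mask for the photo region is
deliberately not implemented; the whole-half coding is the default and
only mode.

## Transition graph and centrality

Consecutive on-screen fixations in distinct AOIs add one undirected
transition; the symmetric adjacency matrix M (zero diagonal,
non-negative integer entries) stores the counts. Refixations within an
AOI create no link — dwell belongs to the fixation-time metric.
Directed variants are out of scope.

Standardized weighted degree centrality:
`C_D^W(i) = C_D(i)/max C_D × w(i)/max W × 100`, with degree = distinct
neighbours, strength = summed incident weights, and both maxima taken
over the *same analyzed graph* (per trial × window). Per-graph maxima
are what make values comparable across trials and participants; they
also mean the measure is scale-invariant in the weights (multiplying M
by k changes nothing — property-tested). Degenerate windows (fewer than
two fixations, hence no links) score 0 rather than NaN, so participant
means stay defined for sparse early windows in young children; the
pipeline records such trials as zeros.

Per-half ("per-image") centrality defaults to partitioning the
full-graph per-node values by half, preserving the identity
green + normal = total. The alternative reading — per-half subgraphs
with per-half maxima, dropping cross-half links — is provided as
`subgraph_half_centrality` but is not the default, because it destroys
the conservation identity and discards cross-half structure.

## Fixation time

A fixation's entire duration is credited to the single AOI containing
its centroid; no spatial splitting across cell borders (the input is
fixation points, not gaze samples). Trial total = sum over 144 AOIs;
participant value = mean over trials, zero-fixation trials included at 0
(same policy as centrality). Both metrics consume the identical AOI
mapping, so condition labels can never disagree between them.

## Viewing-phase windows

Early = [0, 2000) ms, late = [4000, 6000) ms, full = [0, 10000) ms;
2–4 s is disregarded as a gradual transition (6–10 s is likewise not
analyzed by default; any custom window can be configured). Membership
is decided by onset alone, and an included fixation keeps its full
duration even when it outlasts the window. Transitions are counted only
between consecutive *included* fixations, so a windowed graph is
computable from the windowed path alone. Fixations with negative onset
(pre-stimulus carryover, should an export contain them) can never
satisfy the onset rule and are thereby excluded.

## Statistics

Between factor = age group (4–6, 6–8, 8–10 y), within factor = viewing
phase (early/late). The battery: Pearson correlation of participant
metrics with continuous age (not group codes); a 3 × 2 mixed-design
ANOVA (pingouin backend, cross-checked in the test suite against a
from-scratch sums-of-squares oracle on balanced designs, and against
the F = t² identity for two groups); independent pooled-variance
t-tests between groups; paired t-tests between phases within a group
and between Green/Normal halves across participants. Degrees of freedom
are always computed from the data supplied. Post-hoc p-values are
reported uncorrected and flagged as such, with Holm correction
available on request (off by default). Degenerate ANOVA cells follow
the convention 0/0 → F = 0 (p = 1) and positive/0 → F = ∞ (p = 0).

## Synthetic cohort generator

The generator emulates the study design the analysis was built for:
3 age groups × `n_per_group` (default 20) children, ages uniform within
half-open bins, 48 trials of 10 s on the 1600 × 900 display, Green side
drawn per trial. Each trial is an alternating fixation/gap renewal
process; all randomness flows from one seed through per-participant
spawned streams, so cohorts are byte-reproducible and parallelizable.

Structure it generates, and why:

* **Attentional modes.** Each fixation is ambient or focal. Ambient:
  log-normal durations (median 120 ms, σ = 0.35) followed by an
  exploratory relocation — a fresh landing point sampled broadly in a
  chosen image half (amplitude emergent from display geometry, ≈ 15°).
  Focal: log-normal durations (median 300 ms) followed by a small local
  step (gamma amplitude, mean 2.5°, aimed at the screen centre with
  probability 0.3 — the classical central fixation bias — and reflected
  at the display edges). P(ambient) is 0.8 before 2 s and 0.2 after
  (step at the mode switch), scaled per age group. Each mode in
  isolation satisfies the standard taxonomy (ambient: fixations
  < 180 ms, saccades > 5°; focal: the reverse), which the test suite
  checks empirically at n ≥ 2000. Modelling ambient saccades as
  relocations rather than as an amplitude-and-direction random walk is
  a deliberate choice: a biased walk preserves the early Green-side
  position into the late window (long off-task gaps act as a delay
  line), producing a spurious late-phase Green/Normal difference that
  the analysis must *not* find when the salience effect is truly
  short-lived.

* **Off-task gaps and re-entries.** Inter-fixation gaps are
  exponential, with a mean that falls with age (young children blink,
  look away and lose tracking more) and grows within the trial
  (time-on-task decay: factor 0.25 before 2 s, 3.0 after). A gap longer
  than 300 ms breaks scan-path continuity: the next fixation is a fresh
  re-entry landing near the centre of a chosen half (σ = 90 px) — after
  a blink or a look away, gaze does not resume the pre-gap locus.

* **Development.** Three group-level dials, all increasing or
  decreasing monotonically with age: fixation-duration scale (1.0,
  1.35, 1.7), mean off-task gap (380, 180, 80 ms), and ambient
  propensity scale (0.6, 1.0, 1.5). The last one reflects the
  developmental account in which exploratory (ambient, dorsal-pathway)
  viewing matures late, and is what drives the rise of transition-graph
  centrality with age: older children make more, and more distinct,
  transitions. Participant-level log-normal random effects on durations
  (σ = 0.12) and gaps (σ = 0.20) provide inter-individual variation.

* **Salience anchoring.** Relocations choose the Green half with a
  probability that ramps linearly from `green_bias_early` (0.65) at
  stimulus onset to 0.5 at 2 s and stays at 0.5 afterwards — salience
  capture is strongest immediately after onset and wanes within the
  first fixations. A small per-child susceptibility jitter (σ = 0.03)
  scales with the same ramp, so it vanishes when and where the salience
  effect does. Setting `green_bias_early = 0.5` is the generator's null
  condition: Green and Normal become exchangeable by construction
  (verified empirically on 720 null participants).

Default magnitudes were chosen once to realize the qualitative pattern
the generator is documented to produce — metrics rising with age,
early > late, an early-only Green anchor — at the study's sample size;
no quantitative effect sizes exist to calibrate against, so the sign
pattern, not any printed value, is the target.

What the generator does *not* emulate: image content (no saliency maps,
no objects — relocation targets are geometric, not semantic), tracker
noise and off-screen fixations (all landings are on-screen by
construction; the reader's off-screen handling is exercised by
hand-built fixtures instead), pupil/vergence physiology, and any
left/right population bias. Consequently, passing recovery tests show
that the *pipeline* detects the structure the generator puts in; they
cannot certify effect sizes on real children.

## Numerical and policy choices

* Windows half-open on onsets; durations never clipped by windows; the
  final simulated fixation is clipped at the trial end (as a vendor
  export clips it).
* `px_per_deg = 35` (≈ 60 cm viewing of a 22-inch display) converts
  saccade amplitudes; the viewing distance is not part of the original
  design record, so the constant is explicit and configurable.
* Pipeline aggregation averages trial values over all of a
  participant's available trials; missing trials shrink the
  denominator, zero-fixation trials do not.
* CSV round-trips use `float_precision="round_trip"` parsing so that
  write → read is the identity on every field.
* Phase-level group means are participant-level means of trial sums
  (matching the aggregation that defines the participant statistic),
  not pooled trial-level values.

## Known limitations

* The full-window (0–10 s) Green/Normal contrast retains part of the
  early anchoring and can reach significance on synthetic cohorts even
  though the phase-resolved late contrast is null; with real,
  content-driven viewing the early contribution dilutes further. The
  phase-resolved contrasts are the informative ones.
* Centrality of near-empty windows is 0 by convention, which slightly
  compresses group differences in sparse cells (young children, late
  phase).
* The mixed ANOVA requires complete early/late cells per participant;
  participants with missing phases must be excluded by the caller (the
  error lists them).
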