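# Methods

This note documents the models, conventions and numerical choices behind each
analysis stage, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Coordinate and timing conventions

All positions live in video pixel space: origin top-left, x rightward,
y downward, 0-based frame indices, time = frame / fps. Typical sessions are
filmed at 25 fps (chemogenetic experiments) or 60 fps (photometry
experiments). Photometry and behavior are assumed to start on a common
hardware trigger; a constant offset can be applied at ingestion if a rig
introduces one. Low-confidence pose samples (tracker likelihood < 0.6 by
default) are linearly interpolated between neighboring valid frames,
leading/trailing gaps held at the nearest valid sample; the interpolated
fraction is reported as a per-session QC metric, and interpolated frames
participate in zone assignment.

## Zone assignment and behavioral indices

Two zone geometries are supported because the two tracking pipelines used in
this kind of experiment define interaction differently: a radial rule (nose
within 100 px of the chamber center for social tests, 50 px for object tests)
and an annulus rule (between the chamber edge and 3 cm beyond it). Both use
strict inequality at the outer boundary, so a frame exactly on the boundary is
outside; a frame inside several candidate zones goes to the nearest center,
and an exact distance tie assigns no zone rather than double-counting.
Interaction time counts whole frames (frames / fps) without sub-frame
interpolation, matching frame-based tracking.

The sociability and discrimination indices are ratios of interaction times and
are undefined (returned as `None`, never 0) when both contributing times are
zero. The exclusion rule removes subjects whose saline-treatment
discrimination index is below 0.5; exactly 0.5 is retained (the rule is a
strict `<`).

## Photometry conditioning and event detection

The conditioning chain is: zero-phase 4th-order Butterworth low-pass at 40 Hz
(applied forward–backward so transients are not delayed against the behavioral
clock), z-score of the calcium-dependent channel, down-sampling onto the
60 Hz behavioral grid (anti-alias low-pass at 0.45× the target rate, then
linear interpolation onto t = k/60). The z-score baseline is the whole session
by default; a restricted baseline window (≥ 10 s) is available. Isosbestic
regression (least-squares fit of the 415 nm channel onto the 470 nm channel,
subtracted before z-scoring) is provided but off by default: lock-in
acquisition already separates the channels, and motion correction should be a
deliberate choice.

A calcium event is the onset of an upward threshold crossing,
`z[i-1] <= θ < z[i]`, with θ = 2.58 (the two-sided 1% normal quantile; the
threshold is a parameter). Crossing onsets, not suprathreshold samples, are
counted because downstream analyses use event *numbers*. Two guards are
exposed and default off, keeping the pure rising-edge semantics: a refractory
period, and a hysteresis re-arm level (the detector ignores further crossings
until z falls below the re-arm value). With a ~1 s decay transient riding on
band-limited noise, the trace hovers near threshold while decaying and plain
rising-edge detection re-triggers several times per transient; the pipeline
analyses therefore run with `rearm_z = 1.0` (a level the transient has clearly
decayed through). Detection necessarily lags the true transient onset by the
kernel's rise-to-threshold time — tens of milliseconds, i.e. a few frames at
60 fps — and jitters by a couple of frames where transient tails overlap. At
an ordinary walking speed this displaces the attributed position by well under
one 50 px spatial bin, which is why event-to-position mapping uses the nearest
behavioral frame without latency compensation.

## Spatial maps

Heatmaps accumulate over square bins (default 50 px), half-open
`[k·bin, (k+1)·bin)`, with points on the far arena edge falling into the last
bin; points up to 1 px outside the arena are clamped into the edge bin and
counted in a QC flag. Occupancy maps accumulate integer frame counts and scale
once by 1/fps, so mass conservation (total = duration; total = event count) is
exact to float rounding. A "column" of the map is a constant-x strip (the
orientation is configurable); columns where either map has zero variance give
an undefined correlation and are excluded from the count rather than set to 0.
Zone event ratios return `inf` when the denominator zone has no events and
`nan` when neither has any; cohort-level correlation excludes these markers
and reports how many were excluded.

## Freezing

Both comparisons in the freezing rule are strict: a frame is motionless when
its changed-pixel fraction is < 0.1%, and a run becomes a bout only when
strictly longer than 1 s (a 25-frame run at 25 fps is not a bout). Bout bounds
in seconds are `[first_frame/fps, (last_frame+1)/fps)`. The module consumes
precomputed per-frame changed-pixel fractions; computing them from raw video
(binarizing |Δintensity| per pixel) happens upstream in the tracking software
and is out of scope.

## Tracing quantification

Normalized fractions divide each region's count by the per-subject sum over a
reference region set (all table regions by default), controlling for
injection-to-injection transfection variability; medians are taken across
subjects and rounded to 2 decimals only for display. Axis distributions use
half-open 1 mm bins aligned to integer millimeters, anterior-positive
coordinates relative to bregma; a coordinate exactly at the split (0 mm)
counts as posterior. Fluorescence laminar profiles arrive
background-subtracted (the subtraction method is acquisition-specific), are
normalized by the distal-subregion maximum, and AUCs use the trapezoid rule.

## Slice electrophysiology

Responses are classified on the averaged trace (3–6 sweeps), never per sweep.
The baseline window defaults to the 100 ms before stimulus onset; the response
window is onset → 50 ms. The criterion statistic defaults to the window
extremum in the expected polarity (EPSC negative at −70 mV, IPSC positive at
+12 mV; unsigned search available). A response smaller than k = 2 baseline
SDs is a zero response and contributes amplitude 0. Note an inherent property
of extremum-based criteria: the extremum of a broadband-noise window exceeds
2 SD with high probability regardless of any true response (an extreme-value
effect), so the extremum mode is anticonservative on noise-only traces; a
window-mean mode with far better null specificity (≥ 97% measured on
simulated nulls) is exposed via `criterion_on="mean"`. Per-slice
normalization divides each neuron's amplitude by the slice *mean* (so
normalized values average to 1 within a slice, letting slices with different
expression levels be pooled); a slice-sum mode is available. "IPSC dominance"
means |IPSC| > |EPSC| strictly; a cell on the unitary line is not dominant.

## Statistics

Paired comparisons use the Wilcoxon signed-rank test, two-sided, zeros
dropped, requiring ≥ 5 nonzero pairs. For n ≤ 25 the p-value is exact,
computed by dynamic programming over the sign-flip null with midranks (this
reduces to the classical exact distribution when |differences| are untied and
remains exact under ties, where the textbook tables do not apply); larger n
uses the tie-corrected normal approximation. Unpaired comparisons use the
rank-sum test. Multi-group comparisons run a one-way ANOVA omnibus with
Tukey–Kramer pairwise comparisons by default, or pairwise rank-sum with Holm
correction as the rank-based post hoc. Correlations are Pearson with two-sided
p. A two-sided single-outlier Grubbs screen (α = 0.05) is available as an
optional pre-filter, off by default. Note the discreteness of the exact
signed-rank test: at n = 10 the largest achievable level below 5% is 4.88%,
which is what a well-calibrated implementation should produce under the null.

## The synthetic-data generator

The generator exists so every downstream stage can be tested against known
ground truth; all generators are pure functions of (parameters, seed), with
one global seed expanding into per-component substreams via
`numpy.random.SeedSequence.spawn` in a documented order.

**Trajectory.** A reflecting Gaussian random walk (step SD 1.5 px/frame at
60 fps in a 500 px ≙ 50 cm arena, ~11 cm/s mean speed) that switches between
a free state and attraction to a chamber. Transitions are position-independent
(geometric dwell times: entry 0.01/frame, persistence 0.995/frame ≙ ~3 s
attraction bouts); while attracted, a drift of gain × step SD points at the
chamber center, and chambers are chosen with probability proportional to their
attraction gains. Zone occupancy therefore increases monotonically with gain,
and a 2:1 gain ratio yields discrimination indices around 0.7. The
state-switching design (rather than a potential well) keeps dwell-time
distributions analytically simple. Real trajectories have directed runs,
thigmotaxis and grooming pauses that this walk does not reproduce; passing
tests demonstrate correct accounting, not behavioral realism.

**Photometry.** Events are an inhomogeneous Poisson process (baseline
0.05 events/s — sparse population transients — multiplied inside chosen
zones), thinned per sample at 120 Hz. Each event adds a peak-normalized
double-exponential transient (rise 0.05 s, decay 1 s, amplitude 4) to white
channel noise (SD 0.35); the isosbestic channel is noise only. After the
40 Hz filter the transient-to-noise ratio is ~10–15, typical of population
calcium recordings, and the transient peak lands near 4 on the whole-session
z-score. Two accounting effects follow from the physics and are visible in
recovery tests: detection lags onsets by the rise-to-threshold time, and
transients closer together than the hysteresis re-arm window merge, so event
counts under-recover by ~10–20% in high-rate zones and the recovered zone-rate
ratio for a programmed 3× multiplier centers near 2.5–2.9 (within the 25%
recovery band asserted in the acceptance tests). Photobleaching, motion
artifacts and hemodynamic contamination are not simulated.

**Pixel change, counts, sweeps.** The freezing series draws frames around a
moving level (2%) or a frozen level (0.02%) with small Gaussian noise, clipped
to [0, 1] — noiseless settings make bout recovery exact. Count tables are
negative-binomial per region × subject (Poisson in the infinite-dispersion
limit), emulating overdispersed between-animal variability. Ephys sweeps are
Gaussian baseline noise plus an instant-rise/exponential-decay response
template.

## Problem sizes used in the shipped checks

The acceptance tests run 100 seeded cohort replicates of 8 subjects × 600 s at
60 fps through the full pipeline (~1 minute), 1 000 random traces for
detection-oracle equivalence, 10⁴ null replicates for each statistical
calibration, and 1 000 simulated nulls for ephys specificity. The acceptance
script uses 10 cohort replicates. These sizes give Monte-Carlo error well
inside every asserted tolerance.

## Known limitations

- The pipeline consumes tracker and photometry exports; it does not decode
  video, train pose models, or register sections to an atlas.
- Event detection is threshold-based, not deconvolution; event counts are
  rate-biased downward where transients overlap (dead time), which matters for
  absolute rates but largely cancels in within-session comparisons.
- The 2-SD extremum criterion for slice responses is anticonservative on pure
  noise (see above); conclusions about connection probability should prefer
  the mean-mode criterion or larger k when baseline noise is broadband.
- The column correlation treats the arena grid as independent columns; no
  spatial smoothing or information-theoretic place metrics are computed.
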