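# Methods

## Signal model

Evoked responses are modeled per channel as a sum of three parts, all in µV
at 25 kHz:

- **fPSP carrier**: an alpha kernel `A · (t/τ) · e^(1−t/τ)` starting a fixed
  synaptic onset delay (default 2 ms) after the stimulus; negative on
  dendritic-layer channels, positive (scaled by `pos_neg_ratio`, default
  0.6) on axonal-layer channels.  The alpha kernel is an analytic
  convenience, not a biophysical claim: it has a single extremum of known
  value `A` at `t = τ` and a closed-form falling phase, so every feature the
  pipeline extracts has a computable truth value.
- **Population spike**: a Gaussian transient `a_PS · exp(−(t−t_PS)²/2σ²)`
  of opposite sign to its carrier (default latency 6 ms, σ 0.6 ms),
  superimposed on axonal channels when the slice's Bernoulli draw for that
  intensity succeeds.
- **Stimulation artifact**: `−A_art · e^(−t/τ_art)` at both pulse onsets on
  all channels (default 5 mV, τ 0.25 ms), so that the default 1.5 ms
  blanking window leaves a residual below the artifact-quality screen.

Gaussian white noise (default SD 10 µV, a typical planar-MEA noise floor) is
added last, and voltage is quantized to the container's int16 grid
(0.2 µV/LSB) so that write→read round trips are bit exact.

Spatially, the fPSP amplitude decays as a Gaussian (σ 300 µm) and the PS
amplitude as an exponential with decay length `spatial_spread_um` around a
dipole center placed slightly off-grid (55, 35) µm from the focus electrode;
weights are renormalized so the focus electrode carries the slice's nominal
amplitude.  The off-grid center keeps nearest/second-nearest channels unique,
as in real slices where current sources are not aligned to electrodes.

## Intensity–response and cohort structure

Within the tested range the fPSP1 slope is linear in the intensity step
index `s` (steps of 250 mV from 500 to 3500 mV):

    slope1 = β₀ + β₁·s,   slope2 = PPR · slope1

with group-level gains β₁ = 0.038 (IHKA) and 0.023 (control) mV/ms per step,
paired-pulse ratio 0.89 vs 1.30, and PS occurrence
`P(PS at s) = logistic(a + b·s)` calibrated so maximal-intensity PS1
prevalence is ≈ 0.72 (IHKA) vs ≈ 0.18 (control); PS amplitude grows by
0.078/0.109 mV per step (IHKA PS1/PS2) and 0.012/0.047 (control).  These
group-level values are the literature-anchored conditions of the study the
generator emulates.

The slope intercept (0.08 mV/ms at 500 mV) and all variance components are
generator assumptions, chosen once as realistic for slice electrophysiology
and so that the linear Gaussian model holds without truncation over the
range: slice-level SDs 0.03 (intercept) and 0.006 (gain), animal-level
intercept SD 0.015, animal-level gain SD 0 by default (animal clustering
enters through the intercept and the PS-logit offsets; a nonzero animal gain
SD is configurable, but with three slices per animal a three-level slope
decomposition is not identifiable, and the analysis model varies the slope
between slices).  PS logit offsets: SD 0.3 at each level.  Per-measurement
noise: 0.03 mV/ms on slopes, 0.05 mV on PS amplitudes.

Randomness is hierarchical and piecewise reproducible:
`SeedSequence(master, spawn_key=(group, animal))` draws animal effects,
`spawn_key=(group, animal, slice)` drives each slice, so any slice can be
regenerated without its cohort.  `sample_cohort_features` draws the
per-slice × intensity feature table from the same distributions without
waveform rendering; the statistical replicate studies (recovery, power,
type-I error) run on this route, since rendering 25 kHz voltage for
hundreds of cohorts adds nothing to a test of the statistical models.

## Feature definitions and numerical choices

- **Slope**: the trace (µV, blanked, baseline-corrected) is referenced to
  its first post-blank sample (making the fit window invariant to DC
  offsets), the negative extremum located, and an ordinary least-squares
  line fitted over the falling phase between the exact 20 % and 80 %
  crossings of the extremum.  Crossing times are interpolated between
  samples and the fit runs on the interpolated segment, which removes the
  sample-quantization of the window (≤ 0.1 % deviation from the dense-grid
  construction at 25 kHz, versus ≈ 1.5 % with sample-snapped windows at
  τ = 2 ms).  Output is |slope| in mV/ms with the signed value, window, R²
  and a quality flag in the diagnostics.
- **PS amplitude**: vertical distance between a local trough and the
  straight line connecting its nearest flanking local maxima, maximized
  over candidate troughs in a 0.3–8 ms window after blanking; present iff
  ≥ 30 µV.  The *nearest*-flank rule matters: a chord between distant peaks
  arcs far above a curved carrier and would turn noise troughs on the decay
  tail into spurious tens-of-µV "spikes".  On noiseless single-PS traces
  the construction coincides with exhaustive triple search.  On noisy
  single repeats the pipeline additionally applies a 0.2 ms boxcar and a
  10 µV prominence floor on extrema so a noise wiggle inside the PS notch
  cannot act as a flanking peak; both are off in the bare API.
- **Positive fPSP**: maximum positive deflection after blanking, present
  iff ≥ 50 µV.  QC requires > 250 µV (strict) on ≥ 4 dendritic channels.
- **Averaging**: parameters are computed per repeat and then averaged per
  intensity (never average-waveform-then-parameter).  Binary PS presence
  aggregates by majority (≥ 2 of 3; exact ties count as present); PS
  amplitude averages over the present repeats only.
- **PPR**: slope2/slope1, undefined (NaN, flagged) when slope1 < 0.01 mV/ms.
- **Pulse-2 tail**: by default the second response is measured on the raw
  trace; a config switch subtracts an exponential fit to the late pulse-1
  decay extrapolated under the pulse-2 window.
- **Channel selection**: at the 2000 mV reference intensity (the
  optimal-site search pulse); ties break to the lowest channel id.  The
  "no superimposed PS" rule uses the same peak-trough-peak construction on
  the inverted trace, so a nominal reflection whose *measured* amplitude
  falls below 30 µV (carrier sag eats into the chord) does not disqualify
  a channel.

## Statistical models

Continuous responses (slope1, slope2, PPR, PS1/PS2 amplitude) are fitted as

    y ~ group + step + group:step
    + (1 | animal) + (1 | slice:animal) + (0 + step | slice:animal)

via statsmodels MixedLM (variance components for the slice terms,
independent intercept and slope), REML estimation, Wald CIs/p-values,
two-tailed α = 0.05, no multiple-testing correction across the five
responses.  AIC is computed as −2·llf + 2·k (k = fixed + covariance
parameters) and compared against a random-intercept-only refit with the
same fixed effects; with slice-level gain variance in the data the full
model wins.  Degenerate inputs with zero residual variance fall back to OLS
with a flag; non-convergence falls back to the reduced random structure.
At the default study size the interaction test is calibrated: empirical SD
of the estimate equals the model SE (0.00135 vs 0.00134 mV/ms per step),
95 % of estimates fall within 2 SE of the true 0.015, and the null rejects
at 4–7 %.

Dichotomous PS occurrence is aggregated to binomial trials/events — slices
per animal (input–output analysis) or positive-fPSP channels per slice
(spatial analysis) — expanded to Bernoulli rows (identical likelihood), and
fitted with GEE logistic regression: `ps ~ group * step`, clusters as
subjects, exchangeable working correlation (independence available as a
sensitivity switch), robust SEs.  Complete separation is flagged, not
silently fitted.

## Problem sizes

Replicate studies use the study's own design — 15 animals × 3 slices per
group × 13 intensities — with 100 recovery and 200 null replicates for the
LMM and 100 + 100 for the GEE in the test suite (40/60 in the acceptance
script, whose numbers are therefore slightly coarser); oracle checks use
500 randomized noiseless epochs; selection accuracy uses 100 designed
single-slice dipoles; prevalence summaries use 60 animals × 3 slices.
Waveform-level simulations in tests use compact recordings (60 ms event
spacing rather than the 10 s interstep wall-clock of an acquisition
session; the protocol metadata still records 10 s).

## What passing tests do and do not show

The generator reproduces the *statistical shape* of the data the analysis
assumes: dipole-consistent waveforms, linear input–output curves, logistic
PS recruitment, nested variability.  It does not emulate biophysics
(conductance dynamics, mossy-fiber sprouting mechanisms), realistic artifact
shapes beyond an exponential, non-stationary noise, slice drift, or
electrode failure.  Passing recovery tests therefore validates the pipeline
— extraction, selection, aggregation, and inference are correct when their
assumptions hold — not the assumptions themselves on any particular real
recording.  Real data enter through the same HDF5/CSV container interface
with manually annotated layouts.

## Known limitations

- The tangent-fit window rule (20–80 %) is a standard convention; acquired
  datasets fitted with a different window will give shifted absolute
  slopes (group contrasts are much less sensitive).  The window is
  configurable.
- PS detection near the 30 µV level on single noisy repeats is inherently
  flaky (noise SD 10 µV); the majority rule over repeats absorbs most of
  it, but prevalence at low intensities is detection-limited for
  small-amplitude groups.
- MixedLM offers Wald inference only; with very few animals per group,
  p-values for variance-component-heavy designs become approximate.
- The spatial trials gate (positive fPSP ≥ 50 µV) interacts with PS
  amplitude when the PS overlaps the carrier peak; event counts are
  strictly monotone in spread only when the PS is clear of the carrier
  maximum.
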