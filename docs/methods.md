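# Methods

This note documents the models and procedures implemented in `fiberphot`, the
assumptions behind them, the parameters that matter, and what the synthetic
data can and cannot establish.

## Photometry processing model

The recording scheme interleaves two excitation wavelengths on one camera:
473 nm drives calcium-dependent GCaMP fluorescence, while 405 nm — the
isosbestic point of GCaMP — drives calcium-*independent* fluorescence. The two
lasers are multiplexed at 10 or 15 Hz per channel (a 20 or 30 Hz frame train).
A second fiber sits in a dye tube and reports only laser-power fluctuation.

Let `s473(t)` and `s405(t)` be the background-subtracted signal-fiber series
and `c473(t)`, `c405(t)` the matching control-fiber series. Processing is:

1. **Demultiplex.** Each 473 frame is paired with the immediately preceding
   405 frame; the pair carries the 473 frame's timestamp. Pairing (rather than
   resampling/interpolation) preserves causality and the sample count; at
   10–15 Hz per channel the half-frame offset between the paired samples is
   33–50 ms, short relative to GCaMP6s kinetics. Unpaired boundary frames are
   dropped and counted. Non-alternating laser-on frames are an error, not a
   warning: they indicate a hardware fault that silently corrupts pairing.
2. **Background subtraction.** The mean intensity over laser-off frames is
   subtracted per fiber. Negative values are allowed (noise around a small
   signal) with a warning.
3. **Control-fiber regression.** `s473 ~ a + b*c473` and `s405 ~ a + b*c405`
   by ordinary least squares; the residuals replace the series. This removes
   the component explained by laser-power fluctuation.
4. **Isosbestic regression.** The 473 residuals are regressed on the 405
   residuals; the residual of this second fit is the artifact-corrected
   calcium signal, because motion and other calcium-independent contributions
   appear in both excitation channels while the transient appears only at
   473 nm.
5. **Session z-score.** The final residual is standardized over the whole
   session: `z = (x - mean) / sd`. Residuals have mean zero by construction
   but not unit variance; the explicit standardization puts every session on
   the same dimensionless scale.

Both regressions include an intercept. That choice is load-bearing: the
intercept absorbs static offsets so that slow bleaching and baseline
differences do not force the slope away from the artifact-matching value.
Bleaching itself is handled implicitly — it is shared by the 405 and 473
channels and is largely removed by the isosbestic regression; an optional
single-exponential pre-detrend exists (`process_session(..., detrend=True)`)
but defaults off because the standard chain does not include it.

**Known limitation (finite-sample slope bias).** The isosbestic slope is
estimated from the data, so chance covariance between the calcium signal and
the artifact biases it away from 1, leaving a proportional artifact copy in
the residual. The bias shrinks with the number of independent artifact
fluctuations in the session; at the 30 min sessions and artifact spectra the
generator emulates, the median residual-artifact correlation across seeds is
a few hundredths. Very short sessions, or sessions whose artifact varies on
the same timescale as the whole recording, will correct less completely. This
is a property of the regression approach itself, not of this implementation.

Degenerate inputs fail loudly: zero-variance control or isosbestic series and
constant residuals raise errors rather than returning zeros. A constant
control series can be tolerated explicitly with `allow_constant_control=True`
(mean-subtraction fallback), which exists mainly for noiseless synthetic
sessions.

## Peri-event analysis

* **Alignment.** Event times snap to the nearest trace sample, ties toward
  the earlier sample. Rows span `[-pre, +post]`; events whose window leaves
  the session are dropped and counted, and alignment is shift-equivariant.
* **Window statistic.** The comparison unit is the mean z over three
  consecutive samples (0.2 s at 15 Hz) centered on the target lag. Centered
  placement is symmetric in time; `leading`/`trailing` variants are exposed
  because the placement convention is not universal.
* **AUC.** Trapezoidal integral of z between the samples nearest the bounds,
  in z·seconds. Snapping bounds to samples makes AUC exactly additive over
  adjacent intervals.
* **Count standardization.** When categories with different trial counts are
  compared, each group is subsampled without replacement to the smallest
  group's size with a seeded generator, so averages are built from equal
  numbers of events per category.
* **Correlation.** Pearson r with a two-sided p-value and a Fisher-z 95%
  confidence interval (`tanh(atanh(r) ± 1.96/sqrt(n-3))`); requires n ≥ 4.

## Behavioral parsing

Fixed-ratio schedules are named `FR<N>-NTL` or `FR<N>-<limit>s`; the response
clock starts at lever extension. Outcomes partition trials exactly:
*completed* (≥ N presses within the limit), *incomplete* (1..N-1 presses),
*omission* (no press). Omission is defined as the forced complement of the
other two classes. Initiation latency is first press minus extension;
retrieval latency is first head entry after pellet delivery minus the
delivery time, with delivery chosen as the causal anchor for "retrieval".
Schedule advancement uses the ≥ 30 completed trials in two consecutive
sessions rule.

Lick bouts are maximal runs of ≥ 2 licks with every inter-lick interval
strictly under 2 s; an interval of exactly 2 s splits a run. Movement epochs
use hysteresis thresholding of smoothed speed (defaults: on 2 cm/s, off
1 cm/s, minimum duration 0.5 s, 0.25 s boxcar) — the thresholds are
conventions, exposed as parameters, since tracking software defaults vary.
Approach events are outside-to-inside crossings of a 5 cm radius around a
target; dwelling inside yields one event and re-entry requires a prior exit.

## Intrinsic electrophysiology

Spikes are peaks above −10 mV separated by ≥ 2 ms and preceded within 3 ms by
a depolarization rate ≥ 20 mV/ms; the same dV/dt criterion defines the AP
threshold (membrane potential at the first sample reaching 20 mV/ms before
the peak). The 20 mV/ms value is a common operational choice and is
configurable. Features:

* **Maximum firing rate** = `5 / (t6 - t1)` Hz from the first six APs of the
  0.5 s step with the most APs; undefined (flagged) with fewer than six.
* **Accommodation index** over the maximum-firing step:
  `A = (1/(N-1)) * Σ (ISI_i - ISI_{i-1}) / (ISI_i + ISI_{i-1})` — the mean
  local contrast of successive inter-spike intervals; positive for adapting
  trains, zero for constant intervals, antisymmetric under time reversal.
  Requires ≥ 3 ISIs. Sweeps that fall into depolarization block (no spikes in
  the final quarter of the step while the membrane stays above −45 mV) are
  excluded from this analysis; the formula is isolated behind one function so
  an alternative definition can be swapped in.
* **Input resistance** from a −140 pA hyperpolarizing step:
  `|ΔV_ss| / 0.14 nA` in MΩ, with the steady state taken as the mean over the
  last 20% of the step against a 100 ms pre-step baseline.
* **Rebound burst**: APs within 300 ms (inclusive) after step offset, with
  their mean inter-spike interval. The window length is a convention,
  configurable.

## Tracing quantification

Labeled cells are counted per coronal slice in CM, ipsilateral CL and
contralateral CL with the section area. Densities (count/area) form two
ratios per slice — CM : ipsi CL and ipsi CL : contra CL — averaged first
across slices within a case, then across cases per afferent, following that
order literally. A comparison is *strong* when the compartments differ by at
least 40% of the larger value: `min(d1, d2) / max(d1, d2) ≤ 0.6`, boundary
inclusive, direction-agnostic. The larger value is used as the denominator of
the percentage-difference because "X% fewer" is read against the larger
count; with the smaller value as reference the boundary ratio would be 1.4
rather than 5/3. Slices with a zero denominator density are excluded with a
warning; a case with no usable slice is an error.

## Synthetic-data generator

The generator produces every input with known ground truth. What it emulates,
and the defaults:

* **Photometry.** Transients are a difference-of-exponentials kernel (rise
  0.2 s, decay 1.5 s — GCaMP6s-like), unit peak, convolved with the event
  train and scaled by `transient_amplitude` (default 5 fluorescence units on
  a base of 100). Bleaching is a multiplicative single exponential (default
  tau 600 s). The motion artifact (default for test sessions: a 0.1 Hz
  sinusoid of amplitude 2 plus a Gaussian random walk, step sd 0.05) is added
  *identically* to both excitation channels, and the laser drift (±2%
  sinusoid around 1) multiplies all laser-driven fluorescence including the
  control fiber. Bleach, drift and artifact are evaluated once per 405/473
  frame pair so the isosbestic contract (no transient energy at 405 nm, and
  sample-for-sample artifact identity) holds exactly at zero noise. A ≥ 1 s
  block of laser-off frames at the background level leads the session.
  Default test sessions are 1800 s (a 30 min recording) with 100 transients.
* **Operant sessions.** Per trial: 3 s ITI, lever extension, presses with
  exponential inter-press intervals at `press_rate_hz` when the trial is
  engaged (probability `p_engage`, shifted by `light_effect` on light
  trials), pellet delivery at the ratio-th press within the limit, head entry
  an exponential (mean 1 s) later, retraction at retrieval or limit expiry,
  8 s consumption after completed trials. Light trials are an exact
  proportion (default 33% where enabled), pseudo-randomized by seeded
  shuffling of a fixed-proportion label vector. Non-engaged no-time-limit
  trials end at a 60 s cap, since an omission otherwise has no trial end.
  The returned log carries the per-trial ground truth for oracle tests.
* **Lick trains** are deterministic: `n_bouts` bouts of `licks_per_bout`
  licks at the given intra-bout interval, separated by the given gap.
* **Current clamp.** Template APs (2 ms slow foot to a kink 15 mV above the
  local baseline, 0.3 ms upstroke to +90 mV, downstroke to a 5 mV AHP)
  superposed on an Ohmic membrane response with a 20 ms time constant whose
  steady-state deflection is `step_pa × rin_mohm` (in µV), at 10 kHz.
* **Tracing counts** are Poisson draws with mean
  `base_count × ratio × area`, areas uniform in 0.8–1.2 mm².

**What passing tests do and do not show.** The generator's artifact enters
both channels identically and its control-fiber drift is exactly the drift in
the signal fiber — wavelength-dependent artifacts, hemodynamic contamination,
fiber autofluorescence with its own bleaching time course, and nonlinear
motion coupling are not modeled, so the denoising results bound performance
under the model's own assumptions only. Spike shapes are a fixed template:
spike-detection results say nothing about waveform diversity or bursting
collisions. Behavioral timing uses exponential intervals, which have no
within-trial rate modulation. No video, images, or raw photometry pixels are
simulated; counts, trajectories and per-frame means are taken as given.

## Problem sizes and determinism

Every stochastic component consumes a `numpy` `Generator` seed; identical
configs and seeds give byte-identical outputs. The test suite and the
acceptance script run at deliberately modest sizes — 20 × 30 min photometry
sessions, 1000-trial operant oracles, 1000 random lick trains, 50 simulated
cells, 100 tracing seeds — chosen so the whole battery completes in seconds
while keeping every estimate's sampling error far from its decision
boundary.
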