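# Methods

This note documents the models, estimators and numerical choices behind
each stage, what the synthetic generators do and do not emulate, and the
known limitations.

## Signal model and filters

A `Trace` is a uniformly sampled scalar signal; sample *i* sits at
`t0 + i/fs` (sample-centred, 0-based, seconds). Two filters are used:

* **Gaussian smoothing** (spike pre-processing): unit-area kernel with
  σ = 1.5 ms by default, truncated at ±4σ (mass loss < 0.01 %),
  reflect-padded. DC gain is exactly 1, and the operation is linear and
  shift-equivariant away from the padded edges.
* **Chebyshev type-I low-pass** (LFP band): 150 Hz cutoff, 4th order,
  0.5 dB passband ripple, applied forward–backward (`filtfilt`) so the
  phase is zero and event timing is preserved. The ripple value is a
  package default (the recording workflow this mirrors does not fix one);
  note that an even-order Chebyshev-I sits at its ripple floor at DC, so
  the squared (two-pass) DC gain is 10^(−1/20) ≈ 0.891 — irrelevant for
  event detection, which is threshold-relative.

## Extracellular stage

**Spike detection.** σ is the standard deviation of the *entire* smoothed
trace, spikes included (a median-absolute-deviation alternative is
available via `robust_sigma=True` but is not the default). Threshold
crossings beyond ±k·σ (k = 4.5) are grouped into suprathreshold
excursions, one spike per excursion at the extremum; any spike within the
refractory window (1.5 ms) after an accepted spike is discarded, keeping
the earlier one. Detection is scale-invariant by construction. A burst
requires at least two spikes (an ISI needs two spikes) and all successive
ISIs strictly below 10 ms.

**LFP events.** Detected on the low-passed signal at ±4σ; peaks closer
than the 200 ms analysis window are merged (largest deviation wins), and
events whose peak falls within one window of either trace edge are
discarded — they are dominated by the `filtfilt` edge transient and their
amplitude window would be truncated.

**LFP duration.** The duration of an event is the maximal contiguous run
of significant samples containing the peak, within ±200 ms, at
α = 0.001 against a bootstrap null (10,000 i.i.d. draws from event-free
baseline samples; empirical p = (1 + #{null ≥ obs})/(n_boot + 1);
deterministic given `rng_seed`). The tested per-sample statistic is the
**fluctuation amplitude**: the magnitude of the analytic signal (Hilbert
transform) of the filtered trace, averaged over a 5 ms moving window, with
a one-sided p-value. A literal two-sided test on the signed filtered
sample is available (`statistic="signed"`) but is degenerate for any
oscillatory event: the signed signal crosses zero once per half carrier
period, so the contiguous significant run containing the peak can never
exceed about half a period (tens of ms for a 100 ms transient) regardless
of SNR. The envelope statistic makes "interval of significant fluctuation"
well defined for oscillations; the 5 ms averaging window suppresses
single-sample dropouts that would otherwise truncate the run, while
leaving noise-only peaks non-significant (duration 0).

With 100 ms Hann-windowed transients at 8× the raw noise SD, the
recovered duration concentrates at 84–90 ms: the Hann edges taper below
the α-quantile of the baseline envelope, so a mild underestimate of the
full window support is intrinsic to any significance-interval definition
of duration.

## Intracellular stage

* **Input resistance**: ΔV = (mean over the last 25 % of the step) −
  (baseline mean over the 100 ms before the step); OLS slope of ΔV (mV)
  against I (pA), ×1000 → MΩ. Sweeps with an AP inside the step are
  excluded (not truncated), with a warning; fewer than three usable sweeps
  is an error. Using ΔV rather than absolute V changes only the intercept.
* **AP detection**: an AP is a contiguous excursion of V above −10 mV
  whose rise reaches 10 mV/ms (checked from 2 ms before the excursion
  onset); one detection per excursion at the voltage maximum.
* **AP threshold**: V at the argmax of d²V/dt² (first differences twice)
  within the rise window, which runs from the last dV/dt crossing of
  10 mV/ms before the peak to the peak. The 10 mV/ms delimiter is a
  package default; it only defines the search window. On waveforms with an
  interior curvature maximum the estimator is exact: the piecewise-linear
  test AP (kink at −45 mV, rise 100 mV/ms, peak +40 mV) returns threshold
  −45 mV, amplitude 85 mV, FWHM 0.85 ms and max dV/dt 100 mV/ms to grid
  resolution at 100 kHz. On a truncated-exponential upswing (the AdEx
  generator) curvature increases monotonically to the peak, so no
  algorithm of this family can recover the nominal V_T there; the tests
  assert only that the estimate brackets the rise. Real APs have
  sigmoidal upstrokes and are the intended regime.
* **FWHM**: crossings of (threshold + peak)/2 located by linear
  interpolation between samples; a missing falling crossing within 10 ms
  of the peak is a malformed-AP error.
* **mAHP**: baseline mean (first 100 ms of the sweep) minus the voltage
  minimum within 500 ms after the end of spikes; positive =
  hyperpolarized below baseline. "End of spikes" defaults to the last
  detected AP peak; a stimulus-offset convention can be used by passing
  that time instead.
* **Tonic shift**: mean(pre-window) − mean(post-window) with a
  configurable 1 s guard gap around the application time; the sign follows
  the direction of displacement.

## Behavioral scores

The susceptibility score is Σ w_s / t_s with w = (0.2, 0.3, 0.5) over
stage latencies in seconds; an unreached stage contributes 0, the
continuous limit of 1/t as t → ∞, keeping scores finite and the score
strictly decreasing in each latency. A stage-4 death category is carried
as a categorical final stage with no latency arithmetic. PPI is the
printed formula, exactly; it is invariant to rescaling both response sets.

## Proteomics

Welch's t runs on log2 abundances (variance stabilization standard for
isobaric-label intensities); fold change is the ratio of linear-scale
group means. Differential calls default to p-only (p < 0.05) because
biologically important hits can sit below the 1.5× gate; the gate is an
explicit flag used for volcano highlighting. No multiple-testing
correction is applied by default (Benjamini–Hochberg available by flag).
The pre-ranked metric is signed log2FC × (1/p) — the sign keeps the two
regulation directions at opposite ends of the ranking, which a raw ratio
(directionless below 1) would not; ties break lexicographically by id so
rankings are reproducible. p = 0 is rejected with a hint to apply a p
floor.

**Calibration.** At the n = 3-per-group design, Welch's test is
intrinsically conservative: the Satterthwaite df is itself an estimate,
and the null rejection rate at nominal 0.05 is ≈ 0.036 (reproduced
independently by simulating plain normal triplets through
`scipy.stats.ttest_ind(equal_var=False)`). The null-table benchmark
therefore reports a fraction near 0.036, not 0.05; the suite pins the
pipeline to the independent simulation rather than to nominal uniformity.
Power at the planted fold change 2 with 10 % CV is essentially 1
(recall ≥ 0.9 required, 1.0 observed).

## Statistical dispatch

Normality must hold in *both* groups for a t-family test; either rejection
routes to Mann–Whitney. The equal-variance check is a two-sided F test at
0.05 — the variance test is not pinned by the upstream workflow, and F
matches the conventional Prism-style pipeline; it is a configurable
choice. Constant samples defeat the normality tests and fall back to
Mann–Whitney with a warning. Under the full dispatch with normal n = 20
groups, the empirical type-I error at nominal 0.05 stays within
[0.03, 0.07] (2000-rep Monte Carlo in the benchmark suite).

## Synthetic generators

* **AdEx neuron**: C V̇ = −g_L(V−E_L) + g_L Δ_T exp((V−V_T)/Δ_T) + I + ξ − w,
  τ_w ẇ = a(V−E_L) − w, spike-and-reset at V ≥ V_peak with w ← w + b.
  Forward Euler at dt = 1/fs (default 20 kHz; 100 kHz for waveform tests);
  the exponential argument is clamped at 30 to avoid overflow one step
  before reset. Defaults: C = 150 pF, g_L = 10 nS (R_in = 100 MΩ),
  E_L = −70 mV, Δ_T = 2 mV, V_T = −50 mV, V_reset = −55 mV,
  V_peak = 20 mV, τ_w = 150 ms, a = 0, b = 60 pA. Subthreshold adaptation
  is off (a = 0) so the passive I–V slope is exactly 1/g_L and the AHP is
  purely spike-triggered; note that during *sustained* firing adaptation
  self-limits (mean w ≈ I − I_rheobase independent of b), so
  b-monotonicity of the mAHP is demonstrated with short trains and slow
  τ_w, where w_end ≈ n·b.
* **Extracellular scenes**: stationary Gaussian noise plus biphasic
  templates (one Hann-windowed sine cycle, 6 ms wide, repolarization lobe
  scaled to 10 % of the main lobe) at Poisson background times, planted
  burst clusters (default 8 ms intra-burst ISI: below the 10 ms burst
  criterion, above the template lobe width so planted spikes remain
  separable), and Hann-windowed sinusoidal LFP transients (default carrier
  40 Hz — inside the 150 Hz LFP band and fast enough that the analytic
  envelope tracks the Hann window). Template and transient peaks are
  expressed in multiples of the raw noise SD; the default spike peak
  (10σ) puts the detector comfortably at its design point after the 1.5 ms
  smoothing (which attenuates a 6 ms template ~3.5× but white noise ~10×).
  The 10 % repolarization lobe keeps the secondary phase below the ±4.5σ
  threshold at design SNR, as in real smoothed waveforms where only the
  dominant phase triggers.
* **Proteome tables**: per-protein base abundance log-normal(ln 10⁶, 1);
  replicate noise log-normal with σ² = ln(1 + CV²) so the requested CV is
  exact; planted rows scaled by the fold change in the cKO group.
* **Seizure cohorts**: stage latencies are cumulative sums of exponential
  stage-to-stage gaps (rates 1/120, 1/180, 1/300 s⁻¹), guaranteeing
  monotone stage latencies; the shifted group's rates are multiplied by
  the rate shift; stages arriving after the 30 min observation window are
  censored. Stage-2 events are uniform onsets with exponential durations.

**What the generators do not emulate** — and hence what passing tests do
not show about real data: electrode drift and line noise; overlapping
spikes from multiple units (no spike sorting is attempted); bursts with
accelerating/decelerating ISIs; LFP events with asymmetric envelopes or
mixed frequency content; channel crosstalk; patch-electrode access
resistance and bridge-balance errors; proteome missing values,
batch/plex effects and normalization artifacts; seizure-stage
misclassification. Benchmarks on this synthetic data certify the
*estimators*, not the biology.

## Benchmark problem sizes

The reproduction script (`scripts/acceptance.py`) uses: 20 scenes × 10 s ×
20 kHz for spike F1 (plus 5 one-second scenes for brute-force agreement);
1000 fuzzed trains for burst exactness; 50 trials × 3 s for LFP duration
(n_boot = 10,000); an 11-step subthreshold ladder for R_in; 2000
Monte-Carlo reps at n = 20 for dispatch calibration; and a 10,000-row null
table for the proteomics size check. These sizes give binomial/Monte-Carlo
standard errors well inside the asserted tolerances.
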