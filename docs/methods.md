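# Methods

This note documents the models, the synthetic data they are exercised
on, the tunable parameters, and the numerical choices, in the package's
own terms. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Walking Performance Index

Four trial-level gait metrics enter the index: mean stride velocity
(m/s), mean arm-swing amplitude (m, anteroposterior wrist excursion
range per cycle averaged over both arms), and the coefficients of
variation of step length and step time (sample SD over mean, ddof = 1,
over all individual steps of the retained strides). Each metric is
min–max scaled to [0, 1] *within a visit* (the minimal scheme that makes
components comparable across metrics and oriented "higher = better"
after the `1 − x` flip of the variability terms), combined with equal
weights, and divided by the same-visit clinical-setting trial's value.
A metric constant across a visit carries no ranking information and is
set to the uninformative midpoint 0.5. Rank ties break stably by trial
order and are logged.

Consequences worth knowing: min–max normalization makes the raw WPI a
*per-visit relative* quantity — a visit whose settings all walk equally
well still spreads its components over [0, 1]. Baseline normalization
restores cross-visit comparability only to the extent the clinical
setting is stable.

Gait events come primarily from footswitch (FSR) threshold crossings
(threshold = 10% of the channel's trial maximum, 50 ms debounce; toe
off = deactivation of the union of forefoot channels, i.e. the
last-active sensor). When a heel channel is flat (e.g. toe walking) a
goniometer fallback uses the dorsiflexion maximum for heel strike and
the peak plantarflexion velocity for toe off; both are approximate
kinematic surrogates and flagged as such. Cycles whose cumulative
heading change exceeds 45° are turns and are excluded from all metrics.
Intervals are half-open `[start, end)`, times in seconds, samples
0-based.

## Gaussian-process optimization

Inputs stay in raw device units (mA, Hz, μs) so the anisotropic Matérn
length scales are interpretable on the device's own axes; targets are
centered by their mean before fitting. Kernel: signal variance ×
Matérn(ν = 3/2) + white noise, all hyperparameters fitted by L-BFGS
restarts (default 40 in `GPRConfig`; the simulation studies in the test
suite use 3–8 restarts to keep Monte-Carlo loops affordable — the
achieved log-marginal likelihood is monotone in the number of restarts,
which a test asserts). Length-scale bounds default to device-plausible
ranges ((0.1, 50) mA, (2, 1000) Hz, (2, 1000) μs); the noise variance is
bounded below at 1e-6.

The proposal policy is pure exploitation of both posterior-mean tails:
argmax ("best") and argmin ("worst") over a programming-resolution grid
(0.1 mA × 5 Hz × 10 μs), exact ties resolving toward lower amplitude
then lower frequency. Each loop iteration tests best, worst, and the
clinical setting — the worst/clinical tests validate the model the way
a programming session would, at the cost of two-thirds of each
iteration's budget. The canonical initial design
(`gpr.initial_design`) is the 7-point one-axis-at-a-time variation
around the clinical setting (amplitude extremes; 60 Hz and the high
frequency; both pulse-width limits) plus 4 seeded Latin-hypercube
interior points — 11 settings, the number typically accumulated in
clinic before model-guided proposals start.

**Operating regime.** The simulated programming problem gives each
evaluation (one walking bout) a WPI noise of sd 0.04, about 10% of the
response surface's dynamic range, and a budget of 15 evaluations over a
3-D box. Under these conditions, locating a setting whose true value is
within 5% of the surface peak is noise-limited: a GP given the *true*
surface hyperparameters and an optimal static design succeeds in only
about half of random surfaces, because the required precision equals
one evaluation-noise SD. The implemented loop performs at that
information ceiling (the noise-free version recovers the optimum within
programming resolution, which the acceptance suite asserts); reliably
exceeding it would require replicate bouts per setting or a larger
budget, not a different estimator.

## Synthetic cohort generator

The generator's purpose is closure: every downstream stage can be
tested against known truth.

* **Response surface:** a Gaussian bump over the subject's safe box;
  optimum drawn in the central 60% of each axis, widths 25–60% of the
  axis, baseline WPI 0.30–0.45, peak 0.35–0.50 above baseline, trial
  observation noise sd 0.04 (chosen as a realistic bout-to-bout
  repeatability for a ~100-stride overground walk; see operating-regime
  note above).
* **Kinematics:** stride period ~1.1 s, shortened up to 25% as
  performance rises; step-time jitter and per-step length noise are set
  so the measured CVs match linear-in-performance targets
  (VST: 0.10 → 0.02, VSL: 0.13 → 0.03 across the performance range);
  stride velocity 0.55–1.4 m/s and arm swing 0.4–1.35 m likewise linear
  in performance, so that per-visit min–max scoring recovers the
  normalized truth by construction. A 6 m back-and-forth course is
  emulated by a 180° heading reversal every 5 strides, alternating
  direction; turn cycles are ground-truth flagged. Wearable kinematics
  are sampled at 100 Hz (the device rates 500 Hz neural / 64 Hz
  accelerometer are fixed).
* **Neural channels:** 1/f background plus narrowband oscillations at
  3/6/10/20 Hz with wandering carrier phase and lognormal slow amplitude
  modulation. Per-trial band power carries a lognormal physiological
  gain (log-SD 1.15), which sets the between-trial feature variance and
  hence the effect-size regime of the biomarker regressions (group-model
  standard errors land near 0.06–0.08 at ~70 observations). Requested
  biomarker slopes (z-units per baseline-normalized WPI unit) are
  applied as log-linear power modulation gated on the phase intervals;
  the per-phase conversion constants (7.9 for the short double-support
  phases, 6.0 for the swing phases) were calibrated once against the
  full extraction pipeline — short phases need larger constants because
  the wavelet's time resolution smears their contrast into neighbours.
  The modulation covariate is the visit-level baseline-normalized
  min–max performance scale, i.e. the same scale the WPI analysis
  regresses on. Cortical channels share 60% of the pallidal beta
  component, producing elevated cortico-pallidal beta coherence.
* **Device clock:** neural and device-accelerometer streams live on a
  clock offset from the wearables (defaults −0.9 to −2.3 s per
  subject); chest and device accelerometers share heel-strike impulse
  anchors.
* **Artifacts** (opt-in per cohort): stimulation tone at the setting
  frequency and a half-frequency subharmonic; gamma bursts specified in
  detection-domain z-units (the injector pre-compensates the variance
  the bursts themselves add to the per-trial z denominator, so the
  requested z is what the detector sees); ~1.1 Hz EKG-like biphasic
  spikes, by default small enough not to trip the 8-z detector and
  deliberately *not* removed by the pipeline; packet loss as
  repeated-sample runs.

What the generator does **not** emulate: medication state and washout,
freezing-of-gait or festination episodes, nonstationary stride-length
drift within a bout, realistic electrode geometry, or volume-conducted
cross-channel artifacts. Passing tests therefore demonstrate the
pipeline's internal consistency and statistical calibration under the
stated structure, not clinical validity on real recordings.

## Neural preprocessing

The detection chain for gamma-range transients is separate from the
analysis signal: zero-phase 4 Hz order-4 Butterworth high-pass, then a
75–150 Hz band-pass, per-sample z-scores over the whole trial (per-trial
scope; configurable), strictly-greater-than-8 flagging, 200 ms dilation
on each side of every flagged run, merge, and NaN blanking. All main
filtering is zero-phase (forward–backward), which doubles the effective
order; the 1 Hz analysis high-pass is Butterworth order 4. Filtering
restarts per contiguous finite segment so NaN gaps do not leak
transients. Packet loss is operationalized as runs (≥ 50 ms) of exactly
repeated or zero samples, with sub-50 ms gaps merged — an
interpretation, since streaming firmware repeats the last sample across
a dropout. A gait cycle is excluded when packet loss overlaps it at all
or when more than half of any single phase is blanked.

Clock sync: acceleration peaks (≥ 0.35 s apart, prominence 0.5 SD) from
the device and chest streams become impulse trains on a 1 ms grid,
smoothed (σ = 30 ms) and cross-correlated over ±10 s; the offset is
refined by the median nearest-peak residual. Recovery is asserted to
within 2 device samples (1/32 s) across random offsets in ±5 s.

## Spectral features

Complex Morlet wavelet (`cmor1.5-1.0`), 10 voices per octave (a
portable analytic-wavelet choice; configurable), log frequency grid
from 1 to 30 Hz — rows below 2 Hz are computed but belong to no band.
Missing samples invalidate output cells with a one-wavelet-period
margin per row. Wavelet coherence smooths the cross- and auto-spectra
with a scale-dependent Gaussian time window (one period per scale) and
a 0.6-octave boxcar across scales, then clips the ratio to [0, 1] —
conventional practice for this estimator. z-normalization is per
frequency row over all non-missing samples pooled across a visit's
trials, per hemisphere and channel; constant rows yield zeros plus a
flag. Band averages are unweighted means over grid rows with
`lower ≤ f < upper`; phase features are means over each phase interval,
missing when more than half the samples are blanked, and per-trial
features average the usable cycles.

## Statistics

Benjamini–Hochberg is the step-up procedure (sort, scale by m/i,
reverse cumulative minimum, cap at 1); the family for each
person-specific model is its four phase p-values. Group models are
random-intercept linear mixed models fitted by REML for reported
estimates, refitted by ML for likelihood-ratio tests and AIC
comparisons (including the feature × hemisphere interaction check,
ΔAIC = AIC(interaction) − AIC(main)); the optimizer retries
L-BFGS → Powell → CG and keeps the best finite likelihood. Wald t uses
residual degrees of freedom (n − p). A singular random-effect fit falls
back to OLS with a flag. Residual diagnostics report Shapiro–Wilk p,
sample skewness, and Pearson (non-excess) kurtosis. Backward selection
eliminates fixed effects by ML likelihood-ratio tests at α = 0.05.

## Problem sizes used by the test and acceptance suites

Simulation studies run at reduced but statistically adequate scale:
24-stride trials and 2 visits × 7 settings × 3 subjects (~70
observations, matching the group analysis's reported degrees of
freedom) for biomarker recovery; 100 seeds for the slope-recovery and
optimizer Monte-Carlos; 500 replicates for the type-I-error and FDR
calibrations; 40-stride trials for the artifact operating point (burst
z-levels are only realizable when bursts occupy a small fraction of the
trial). The pipeline determinism check uses 3 subjects at 20 strides
per trial. These sizes are the package's standing choices and are
encoded in the tests themselves.
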