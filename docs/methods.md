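# Methods

`hypercoh` analyzes simultaneous two-person (hyperscanning) fNIRS
recordings of naturalistic interaction.  Its question is twofold: do two
interacting brains synchronize more during cooperation than during solo
work, and can moments of synchrony be attributed to concrete social
behaviors — here, raising the face toward the partner?  The pipeline has
four stages: signal conditioning, wavelet-coherence estimation with group
statistics, automated behavioral event classification, and an
event-related generalized linear model.  This note documents the models,
the defaults and the numerical choices, and what the synthetic-data
generator does and does not emulate.

## Signal conditioning

**Modified Beer–Lambert law.** Optical-density changes at 695 and 830 nm
are inverted per sample through the 2×2 extinction system
ΔOD(λ) = [ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR]·d·DPF(λ).  Default extinction
coefficients are the standard compiled molar spectra at those
wavelengths; with the default DPF = 1 (continuous-wave topography
convention) outputs are relative concentrations in mM·mm.  A condition
number above 10⁶ on the extinction matrix is rejected as singular.

**Hemodynamic modality separation (HDMS).** Each oxy/deoxy pair is
decomposed into a functional component with deoxy = k_f·oxy (k_f < 0:
cortical activation raises oxy-Hb and lowers deoxy-Hb) and a systemic
component with deoxy = k_s·oxy (k_s > 0: superficial blood-volume
changes, e.g. skin flow driven by movement or arousal, move both
together).  The decomposition is the exact per-sample solve of
oxy = F + S, deoxy = k_f·F + k_s·S.  Defaults k_f = −0.6, k_s = +0.5
encode only the sign structure the method assumes; both are
configuration keys (`preprocess.hdms.k_f/k_s`) because the appropriate
ratios depend on optode geometry and population.  Only the functional
component feeds coherence analysis.

**AR pre-whitening.** Each channel is de-meaned and filtered to the
one-step-ahead residuals of an AR(50) model — 5 s of history at the
10 Hz sampling rate — fitted per channel by Yule–Walker
(Levinson–Durbin on the sample autocovariance, MLE-style denominator
for stability at high order).  Pre-whitening removes serial correlation,
which also statistically suppresses motion transients shared between
participants.  Residual series are shorter by the AR order; all channels
of a session are left-trimmed identically so cross-participant alignment
survives.  Fits are per channel; a common filter across channels would
also be defensible but couples channels through the filter estimate.

## Wavelet coherence

The continuous wavelet transform uses a Morlet mother wavelet with
wavenumber ω₀ = 6 — six carrier cycles per envelope, the common
compromise between time and frequency resolution.  Scale and frequency
are related by the Morlet Fourier factor λ = s·4π/(ω₀+√(2+ω₀²)), so the
analysis grid is specified in frequency directly: f_k = f_min·2^(k/10),
a 1/10-octave geometric ladder anchored at the printed band edges
0.0072–3.68 Hz, giving exactly 91 bands (the top band, 0.0072·2⁹ =
3.6864 Hz, rounds to the printed 3.68).  The transform is FFT-based with
zero padding to the next power of two; the cone of influence (COI)
excludes all points within √2·s of either session edge, and excluded
points never enter any statistic.

Squared coherence follows the standard smoothed-cross-spectrum
estimator,

    R²_k(t) = |S(W_xy/s)|² / ( S(|W_x|²/s) · S(|W_y|²/s) ),

with S a Gaussian in time of SD equal to the scale, then a boxcar across
scale spanning 0.6 octaves (three bands at this resolution; edge bands
renormalize over the truncated window).  Time smoothing is implemented
as multiplication with the analytic Gaussian transfer function on a
zero-padded FFT grid; the padding leaves a ≤ 2·10⁻⁴ wrap-around residue
at the largest scales, orders of magnitude below the estimator's
sampling noise and identical in numerator and denominator.  Coherence of
a series with itself is exactly 1 by construction.  Values are clipped
to [0, 1].

**Channel pairs.** With 20 channels per participant there are 20
identical-channel and 190 different-channel unordered between-brain
pairs (210 total → 210×91 = 19,110 cells); within-brain connectivity
uses the 190 different pairs of one head (17,290 cells).  A
different-channel pair has two orientations, (A_i, B_j) and (A_j, B_i);
since the family counts unordered pairs, the two orientation coherence
matrices are averaged by default (a `keep-both` policy returns both).
This averaging rule is a package decision — no convention exists for it.

## Group statistics

Per cell (pair × band), each dyad contributes the in-COI mean coherence
of its cooperative (COOP) and independent (IND) sessions.  Cells are
contrasted with a two-tailed t-test, paired across dyads by default
(each dyad provides both conditions; an unpaired mode is available).
Cells with fewer than three complete dyads are flagged untested.  A cell
whose per-dyad differences are identically zero is the exact null
(t = 0, p = 1) rather than 0/0.

Multiplicity over the ~19k-cell family is controlled with Storey's
positive-FDR q-values: π₀ = #{p > λ}/(m(1−λ)) at fixed λ = 0.5, clipped
to (0, 1], with the step-up minimum of π₀·m·p/rank over the sorted
family.  The fixed-λ estimator (rather than the spline-tuned variant)
keeps the procedure transparent; λ is a configuration key.  Between- and
within-brain families are corrected separately.

One representative band per channel pair — the band with the smallest
p-value, ties broken toward the lower band index — summarizes each pair,
because adjacent bands of a geometric grid are strongly correlated.
Candidates for the event-related stage are cells with COOP > IND,
p < 0.001, inside 0.03–0.1 Hz (the band where interaction-scale dynamics
live, above the very-low-frequency drift and below respiratory
artifacts), reduced to one representative band per pair.

## Face-up events

Head pitch (OpenFace-style `pose_Rx`, radians) is z-scored per
participant per session — removing seating-height and camera-angle
offsets, with session scope chosen to also absorb slow posture drift —
and a sample is face-up when z > +2.  On Gaussian noise this threshold
marks the one-tailed 2.28% tail, matching the intentionally strict
classification rate of a few percent.  Invalid tracking frames are
excluded from the moments and never classified up; tracking gaps of at
most 0.5 s are linearly interpolated on read.

Before labeling, each binary track is cleaned morphologically: gaps
shorter than 0.2 s are bridged and runs shorter than 0.3 s dropped
(single-frame tracker jitter; both default to configurable values and 0
disables them).  Labels are then sample-wise and mutually exclusive:
both-up (A ∧ B), self-up-A (A ∧ ¬B), self-up-B (B ∧ ¬A).  Self-up of one
participant is other-up of the partner, so the two merge into
"either-up" at the group stage.

An inherent constraint worth knowing: the 2 SD rule can only detect
events whose total duty cycle is modest.  If a participant's face is up
a fraction f of the session, the up-plateau sits at z ≈ √((1−f)/f)
asymptotically, which crosses 2 only for f < 20%; reliable detection
needs f ≲ 15%.  The threshold is thus a *rare-event* classifier by
design, consistent with the few-percent rates it is meant to produce.

## Event-related GLM

For each candidate cell, the behavioral tracks are down-sampled to the
10 Hz coherence rate by nearest-sample selection (regressors stay
binary) and shifted **forward** by 5 s: the regressor at response time t
is the behavioral state at t − 5 s, absorbing the delay-of-peak between
an event and its hemodynamic response.  Early samples without a defined
regressor, and samples outside the COI at the candidate band, are
dropped.  The per-dyad model is a GLM with gamma error and log link —
coherence is positive and right-skewed — fitted by iteratively
reweighted least squares (statsmodels); responses at or below zero are
clipped to 10⁻⁶ and counted, and samples numerically at 1 are nudged to
1−10⁻⁹ (gamma support is open at both relevant boundaries).  All-zero
regressors yield a missing β; non-converged fits are excluded.

For a different-channel pair the GLM runs once per orientation;
β_either = mean(β_self, β_other) within each fit (a missing component
propagates as the other alone), then averaged across orientations.
Dyads with no usable events contribute no β and are excluded pairwise —
group n at this stage is typically below the number of recorded dyads.
Group inference is a paired two-tailed t-test of β_both − β_either
across dyads per candidate, Bonferroni-corrected over the number of
candidates (α = 0.05/n_candidates).

`event_locked_wtc` additionally averages coherence segments around event
onsets or offsets for visualization, against the all-pair grand-mean
baseline at the band; events whose windows leave the session are
excluded and counted.

## Synthetic data

The generator produces what the analysis assumes, not physiology.  Per
channel: unit-SD 1/f background (spectral shaping of white noise,
exponent 1) plus white noise (SD 0.3).  Per participant: one shared
systemic trace (1/f^1.5, amplitude 0.3) entering all channels with
oxy/deoxy ratio +0.5, while functional content carries ratio −0.6 — so
modality separation has exactly the structure it expects.  Coupled
channel pairs share a sinusoid with slowly drifting phase (random-walk
phase, 0.01 rad/sample SD), gated by behavioral epochs with 1 s
raised-cosine ramps and delayed by the 5 s hemodynamic lag the GLM later
corrects.  Face-up events arrive sequentially (exponential gaps, 0.9/min
pooled rate, uniform 15–25 s durations, 30% both-up) — roughly 20% of a
session has at least one face up, keeping each participant's duty near
13%, inside the detectability ceiling above.  Pose traces are Gaussian
pitch noise (SD 0.05 rad) with plateau excursions of 12 baseline SDs
during up-epochs: a deliberate posture change is an order of magnitude
larger than tracker jitter.

Not emulated: realistic neurovascular impulse responses, motion
artifacts with video-correlated structure, optode geometry, respiratory
and cardiac bands, non-stationary noise.  Passing tests therefore show
that the *statistics* behave as designed under their own assumptions,
not that real recordings satisfy those assumptions.

## Verification scale

The end-to-end recovery experiment injects coupling at one channel pair
(0.09 Hz) only during either-up epochs and asks the full pipeline —
conditioning, coherence, candidate selection, GLM, group contrast — to
report β_either > β_both with Bonferroni significance at that pair.  It
runs 20 dyads with 10-minute sessions, 25 replicates, with 2 channels
per participant (6-cell × 91-band family); the channel count is the
package's scaling choice to keep the whole verification suite fast while
preserving every stage, including orientation handling for
different-channel pairs.  The matching null experiment (coupling
amplitude 0, 10 dyads, 5-minute sessions, 50 replicates) requires a
median of zero significant contrasts.  A demo-sized experiment (6 dyads,
5-minute sessions) reliably flags the injected pair at the candidate
stage but cannot clear a df ≤ 5 Bonferroni group test; the recovery
claim belongs to the 20-dyad scale.

## Known limitations

- HDMS ratios and DPFs are conventions, not calibrations; absolute Hb
  units require instrument-specific values.
- The coherence null level depends on the smoothing operator; compare
  conditions, not raw coherence values, across implementations.
- The fixed-λ π₀ estimate is slightly conservative for very small
  families.
- Orientation averaging discards any directional asymmetry between
  (A_i, B_j) and (A_j, B_i).
- The 5 s delay is a constant; true delay-of-peak varies by region and
  person.
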