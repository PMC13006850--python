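# Methods

This note documents the models, parameter defaults, numerical choices and
known limitations of the pipeline. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Preprocessing

Signals are handled in physical microvolts throughout. The chain is: select
the best of four frontal-occipital candidate derivations by its
scoreable-data fraction (ties break in candidate order; a night with no
candidate at or above 50% is discarded); bandpass 0.3–40 Hz with a
300th-order Hamming-window FIR applied forward-backward (zero phase, so
event onsets feed timing metrics unshifted); cut into 30-s epochs anchored
at recording start on half-open intervals [t, t+30); demean each epoch and
reject any whose |sample| exceeds 200 μV. Detection runs only on usable
(artifact-free N2/N3) epochs, and events must lie wholly inside them —
events straddling a masked boundary are discarded.

Two deliberate consequences of the 300th-order prefilter are documented
rather than hidden. First, a 301-tap FIR at 250 Hz has a transition width of
roughly 2 Hz, so sub-0.3 Hz drift is only partly removed (forward-backward
gain ≈ 0.4 at 0.05 Hz); the per-epoch demeaning and the slow-oscillation
band filter absorb most of the residual. The test suite demonstrates the
full attenuation property at an adequate filter length (8192 taps) and the
passband property at the 300-order default. Second, the prefilter attenuates
~1 Hz content by about 30% (forward-backward), which biases amplitudes
measured on the detection trace; see the amplitude calibration note below.

The amplitude-rejection criterion is interpreted as peak absolute value of
the demeaned trace (not peak-to-peak); this is a configuration-visible
choice (`preprocess.reject_uV`).

## Slow-oscillation detection

Candidates are negative-then-positive half-wave pairs delimited by zero
crossings (sign changes of the 0.3–4 Hz trace, crossing times linearly
interpolated; samples exactly at zero join the following excursion). A
candidate is accepted iff trough magnitude ≥ 33 μV, trough-to-following-peak
≥ 61 μV, negative half-wave duration in [125, 1500] ms and positive
half-wave ≤ 1000 ms. No total-duration cap is applied, and the amplitude
criteria are treated as minima. Events are non-overlapping by construction
and sorted by onset.

The 0.3–4 Hz detection band uses a zero-phase 4th-order Butterworth rather
than a short FIR: a 301-tap FIR attenuates the band's own passband (~20% at
1 Hz), which would silently tighten the amplitude criteria; an IIR applied
forward-backward has unit passband gain at any order. The broadband
prefilter remains FIR as specified for acquisition fidelity.

## Spindle detection

A sliding window of 0.3 s advancing by 0.1 s computes three features on the
sigma (11–16 Hz) and broadband (0.4–30 Hz) traces: (i) relative sigma power,
as the z-score of log10(sigma power / broadband power) against a 30-s moving
baseline, threshold 1.6; (ii) Pearson correlation between the sigma-filtered
and broadband windows, threshold 0.69; (iii) sigma-broadband covariance on a
log10 scale z-scored against the same 30-s baseline, threshold 1.3. A window
is spindle-positive iff all three exceed threshold; consecutive positive
windows merge (no bridging across gaps of one step or more) and merged
candidates are kept iff 0.5–2.5 s long. The absolute-sigma-power criterion of
the original four-feature algorithm is deliberately omitted, reflecting use
on a non-standard frontal-occipital montage. The spindle amplitude is the
mean analytic-signal (Hilbert) envelope of the sigma trace over the event.

The covariance feature floors the raw windowed covariance at 0.1 μV² before
the log: without a floor, rare negative-covariance windows map to extreme
log values that inflate the baseline SD and suppress every z-score.

Because the absolute-power gate is omitted, the detector retains a small
residual false-alarm rate on featureless 1/f noise (measured ≈ 0.05–0.1
events/min at default thresholds, versus a real density scale of
~1.5/min; precision against injected ground truth stays ≥ 0.95 at realistic
densities). This mirrors the documented trade-off of removing that
criterion on non-standard montages.

## Sleep metrics and exclusions

Stage minutes are 0.5 × epoch counts; TST = N1+N2+N3+REM (an exact identity,
asserted per night); WASO counts wake epochs between the first and last
sleep epochs; awakenings are maximal wake runs inside that span; sleep
efficiency is 100·TST/time-in-bed. These conventional definitions are
adopted where the upstream device would normally supply its own. Event
density divides counts by *scored* N2+N3 minutes — the literal definition —
with an artifact-free-denominator variant available
(`metrics.density_denominator`). Exclusions drop nights without a usable
channel first, then participants left with fewer than 4 nights; both steps
emit reason-coded log rows so the accounting reconciles exactly.

## Task scoring

Go/NoGo: mean RT over correct go responses within [200, 900] ms (bounds
strict on the outside, boundary values kept); hit rate over all go trials;
commission rate = responses on no-go trials / all no-go trials (a
correct-go denominator is available, since "relative to correct responses"
admits both readings). Simon switch: cell means over correct responses
within [300, 3000] ms; Simon cost = incongruent − congruent RT; switch cost
= switch − nonswitch RT; accuracy effects default to the orientation in
which an interference cost is negative (incongruent − congruent), with the
literal subtraction order available as `accuracy_sign="literal"`. First
trials of a block carry no switch label and join neither switch cell.
Missing cells or absent valid RTs yield NaN so the day can be dropped
listwise from the relevant model.

## Statistical layer

All mixed models use maximum likelihood (not REML) so the Gaussian and beta
families are comparable. Gaussian random-intercept models are fitted through
statsmodels MixedLM; a profiled-ML fitter (1-D optimization over
θ = σ²_b/σ²_w on the log scale, θ = 0 boundary checked explicitly, GLS
standard errors) computes the identical maximum and powers the simulation
loops — it is cross-checked against MixedLM in the tests, and stands in when
MixedLM's Hessian is singular at a boundary optimum. The zero-inflated beta
model (logit link, constant inflation probability, participant random
intercept) is fitted by ML with 25-node Gauss–Hermite quadrature;
it is cross-checked against R's glmmTMB on the same data in the test suite.

ICC = σ²_b/(σ²_b+σ²_w). For beta-family models, which estimate no residual
variance, the latent ICC σ²_b/(σ²_b+c) is used with c = 1 on the logit
scale by default; c = π²/3 (the logistic latent variance) is offered, as the
two conventions differ materially and neither is universal. Standardized
coefficients come from a z-scored refit (the Wald z statistics are invariant
to this, asserted to 1e-6); Type III tests for continuous predictors reduce
to F = z² with one numerator degree of freedom. Proportions equal to 1 would
be squeezed by (y·(n−1)+0.5)/n before a beta fit; exact zeros belong to the
inflation component, never to a squeeze.

The parametric bootstrap for the ICC simulates from the fitted Gaussian
model over the original design, refits by profiled ML, and takes the 2.5/97.5
percentile interval (the convention of standard mixed-model bootstrap
tooling). At 17 participants this interval undercovers mildly — measured
coverage ≈ 0.89–0.92 against the nominal 0.95 over 100 replications × 200
bootstraps, driven by ML's downward bias in σ²_b — and the acceptance test
asserts coverage within [0.85, 1.0] with that Monte-Carlo resolution.
Bootstrap CIs are offered for Gaussian models only.

Power simulation draws a participant-day predictor with between- and
within-participant spread (defaults on the scale of nightly slow-oscillation
density: mean 4.2, SDs 2.0/2.0), generates outcomes at the study's variance
components, and reports the Wald rejection rate per slope. Outlying nightly
densities can be flagged before modelling by a robust z-rule
(|z| > 3 on median/MAD scaling), replacing by-eye removal with a logged,
reproducible criterion.

## Synthetic-data generator

The generator defines the study conditions under which recovery is tested.

*Hypnograms* come from a five-state Markov chain on 30-s epochs. Stage mean
bout lengths (W 2, N1 1.5, N2 10, N3 8, REM 12 epochs) fix the diagonal;
off-diagonal weights are calibrated by fixed-point iteration so the chain's
stationary distribution exactly matches the configured stage-minute profile
(defaults: W 48.11, N1 34.60, N2 212.04, N3 64.22, REM 106.50 — an
older-adult multi-night cohort scale). Targets and dwells live in the
config, not in code. Default nights are 931 epochs (~7.8 h in bed); tests
and the acceptance script use 240-epoch (2-h) nights to keep runtimes to
seconds per night while preserving per-minute event statistics.

*EEG* is 1/f background (exponent 1, RMS 15 μV) plus extra 0.5–2 Hz power in
N3 (5 μV RMS, faded over 2 s at stage boundaries). Slow oscillations are a
negative then positive half-sine (durations U(0.4, 0.7) s each, 55/45
amplitude split, log-normal ±8% amplitude jitter); spindles are
Hann-windowed sinusoids (13 ± 0.4 Hz clipped to 11–16, U(0.7, 1.1) s,
20 μV peak). Event counts are Poisson at the configured densities
(SO 4.2/min, spindle 1.52/min of N2+N3); placement is uniform over eligible
N2/N3 samples with rejection on overlap (0.25 s guard) and strict
containment in contiguous N2/N3 spans, so every injected event is
recoverable in principle. Infeasible densities raise a generation error
naming the available N2+N3 budget.

The injected SO amplitude default is 120 μV raw peak-to-peak: the observed
~86 μV scale for such cohorts is a *measured* amplitude downstream of an
acquisition-style 0.3–40 Hz chain whose 300-order FIR attenuates ~1 Hz
content by ~30%, and 120 μV raw waves measure ≈ 87 μV on the detection
trace. The device's true noise model is unknown, so the synthetic SNR is a
declared free choice; every recovery figure in the tests and acceptance
report is conditional on it.

*Behavior* is drawn from the random-intercept model itself (Gaussian, or
zero-inflated beta where `var_within` plays the beta precision φ), with
variance-component defaults at the published reaction-time scale
(between 2404.27, within 1440.80). One global seed fans out to per-night
and per-stage substreams via a splitmix-style hash, so nights are mutually
independent but the whole cohort is bit-reproducible.

**What passing recovery tests do and do not show.** The generator emulates
stage-dependent event placement, realistic densities/amplitudes, and 1/f
background — not EMG/EOG contamination, electrode pops, apnea-related
artifacts, inter-individual spindle-morphology differences, or the device's
proprietary staging noise. Recovery ≥ 0.9 under these conditions validates
the detector implementations and thresholds, not their field accuracy on
hard recordings.

## Degenerate inputs and tie-breaks

All-wake hypnograms yield TST = WASO = efficiency 0 rather than errors;
zero N2+N3 minutes make density undefined and the night excludable; an
empty analysis mask returns an empty event list; equal channel qualities
resolve in candidate order; samples exactly at zero join the following
half-wave; correlation of a zero-variance vector is an error, not NaN.

## Known limitations

- No slow/fast spindle subclassification, SO-spindle coupling, or
  topography; hypnograms are consumed, never produced.
- The Wald z tests inherit mild small-sample anti-conservatism for
  predictors whose variance is mostly between-participant (no
  Satterthwaite/Kenward-Roger correction is applied).
- The latent-ICC scale constant is a convention, not an estimate; results
  at c = 1 and c = π²/3 can differ by a factor of ~3 at small σ²_b.
- EDF writing is a minimal 16-bit encoder (1-s records, per-channel
  symmetric physical range) sufficient for round-tripping synthetic nights;
  it is not a general-purpose EDF+ library.
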