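# Methods

This note documents the models, estimators and numerical choices behind
`lidpipe`, the assumptions they rest on, and what the synthetic tests do and
do not demonstrate about real recordings.

## Signal model and spectral chain

LFPs are modelled as an aperiodic 1/f^χ background plus transient narrowband
oscillations. The spectral chain operates on **bipolar** derivations — the
difference of every within-structure electrode pair (all C(n,2) pairs; no
inter-wire distance filter) — which cancels any source common to the wires
of a structure exactly, by construction.

Spectrograms use single-taper 8-s Hann windows with 50% overlap over
0–300 Hz. The native resolution of an 8-s window is 0.125 Hz; output is
reported on a 0.5-Hz grid by averaging four adjacent native bins in linear
power (bins nearest each 0.5-Hz multiple), so the stated window length and
the stated grid are both honored. PSDs use density scaling with the Hann
power correction; the integral of the PSD reproduces the time-domain
variance to better than 1% (tested).

### IRASA aperiodic separation

The fractal component is isolated by irregular resampling: for each factor
h ∈ {1.10, 1.15, …, 1.90} (the method's standard published set;
configurable) the signal is polyphase-resampled by h and 1/h, the two PSDs
are interpolated back to the native grid, their geometric mean taken, and
the median over factors used as the fractal spectrum. Oscillatory power is
the dB difference `normalized = total − fractal` ("dB_fractal").

One statistical subtlety matters: the geometric mean of two *one-window*
PSD estimates is biased low by about 1 dB (E[√X] < √E[X] for chi-squared
power estimates). Session-level decompositions therefore average PSDs
across windows **before** the geometric mean, which removes the bias; the
per-window normalized spectrograms used for peak tracking retain a small
positive baseline offset that the peak model's background terms (D, E)
absorb. On pure power-law input the session-level normalized spectrum is
flat to within ±0.5 dB with <1% of 2–100 Hz bins above +3 dB, and the
fractal log-log slope recovers χ within ±0.1 for χ ∈ {0.5, 1, 2} (tested).

## Parametric peak detection

Per analysis window, the structure-averaged normalized spectrum restricted
to the band is fitted with `y(f) = A·exp(−((f−B)/C)²) + D·f + E` by bounded
trust-region least squares. The objective is multimodal in B, so the fit is
restarted from five B values spread across the band and the lowest-cost
solution kept. Optimizer bounds (A ∈ [0, 200], B inside the band,
C ∈ [0.5, 40], D ∈ [−5, 5], E ∈ [−30, 30]) are deliberately wider than the
detection thresholds so that rejection happens in the threshold logic, not
by clamping. Optimizer failure yields an undetected fit with a diagnostic,
never an exception.

Detection requires R² > 0.2, 2 < A < 100 dB, 1 < C < 20 Hz, −1 < D < 1,
−10 < E < 10 (all strict), with the class assigned by the B interval.
Three band classes are kept separate and configurable — gamma 30–70 Hz,
HFO 115–170 Hz, and the dyskinesia NBG band 65–110 Hz — because the first
two are the printed threshold classes while the NBG band is the range in
which the dyskinesia oscillation is actually described; no attempt is made
to reconcile them. The detection *rate* is defined per analysis window
(fraction of 8-s windows with a positive detection), the only granularity
at which a rate is well defined. Band power is the integral average
(trapezoid) of the normalized spectrum over a 20-Hz band centered on the
session-and-structure median of B.

Cross-structure feature comparisons (peak frequency/height/width) use
Pearson correlation over windows where both structures detect, as 1 − r
distances, with structures below a 5% detection rate excluded exactly.

## Phase-coupling connectivity

Phase analysis uses **monopolar** series — unlike the spectral chain — since
bipolar derivation would cancel precisely the shared oscillation whose phase
consistency is the quantity of interest (this contract is enforced by test).
Series are bandpass filtered ±5 Hz around the recording's median NBG
frequency and Hilbert transformed; the phase difference of each
cross-structure wire pair is summarized by the von Mises concentration
κ = A⁻¹(R̄) via the classical Best–Fisher piecewise approximation, capped at
κ = 1000 for degenerate samples, requiring n ≥ 10. The structure-pair
entry is the median κ over its wire pairs; treatment maps are elementwise
κ differences on the common defined-pair set (missing pairs stay missing).

The filter is a zero-phase (forward–backward) windowed FIR of order 512 by
default. A ±5 Hz passband at a 2 kHz sampling rate needs a transition this
sharp: shorter kernels of the order sometimes quoted for this task (~64
taps) leave less than 6 dB of two-pass attenuation 20 Hz off-center and
therefore cannot isolate the gamma band at all; order 512 achieves >100 dB
there while remaining exactly zero-phase. The order is configurable.

Phase samples are decimated to 10-ms spacing before fitting. This does not
de-bias κ (R̄ is invariant in expectation) but keeps the reported n
meaningful; κ estimated from few effective samples is inflated by the usual
R̄ small-sample bias, which is why κ estimates from short windows should be
compared, not read as absolutes.

σ² = −2 ln R̄ (circular variance) satisfies σ²·κ̂ ≈ 1 within 10% for κ ≥ 4
(tested at κ = 8).

## Behavior

Heading is atan2(front − center) in y-up image coordinates after zero-phase
4th-order Butterworth smoothing at 5 Hz; frames below a tracking confidence
of 0.6 are interpolated first. Rotation counting quantizes the unwrapped
angle into eight 45° sectors (sector 0 centered on 0°) with 5° of
hysteresis at each boundary to suppress jitter-induced crossings; eight
consecutive same-direction crossings register one rotation and reset the
accumulator, any reversal resets it, so incomplete arcs are never counted.
Counter-clockwise is contraversive for a right lesion; the lesion side is a
required input with no default. Counts are binned in non-overlapping
half-open 10-min bins from levodopa administration, with counts/min means
over 40–80 min (peak) and 120–160 min (late).

The ALO global AIMs score is Σ severity×amplitude over the axial, limb and
orolingual subtypes (severity ∈ {0, 1, 2, 2.5}, amplitude ∈ {1, 2, 3, 4}),
bounded [0, 30], one observation per 10-min interval (18 per 180-min
session); off-scale values are rejected naming the offending row.

## Brain-state comparison

State spectra use monopolar electrodes (per the stated method for this
analysis), non-overlapping 4-s windows inside the 40–80 or 120–160 min
period, per-window IRASA with the same factor set (the factors are
dimensionless and need no rescaling for the shorter window), averaging over
windows and sites in linear power, restricted to 1–200 Hz on the native
0.25-Hz grid. Treatments are compared by Pearson r of a session's spectrum
against each reference condition average (dB domain; r is invariant to
constant dB offsets), with a two-sided rank-sum annotation as reporting
plumbing only.

## The synthetic generator

`synth` emulates what the analysis assumes: per-wire independent 1/f^χ
backgrounds (spectral shaping of white noise, amplitude ∝ f^(−χ/2), random
phases — the target spectrum is exact in expectation; the power law is
flattened below 0.5 Hz to keep low-frequency power finite); narrowband
oscillations as complex Gaussian baseband noise with a Gaussian-shaped PSD
(σ_f = bandwidth/2) rotated to a possibly drifting center — stochastic
oscillations, not sinusoids, so peak width is a real recovery target;
schedules gated with 100-ms raised-cosine ramps; a piecewise-linear drug
level (onset 20 min, plateau 40–80 min, decay to 160 min by default);
trajectories tracing an exact number of full revolutions with optional
7/8-turn decoys; and AIMs schedules slaved to the drug level.

Phase coupling is calibrated through the estimator's own link function:
each wire of a coupled group receives the group's shared analytic signal
rotated by an independent smooth Gaussian phase process (4th-order
Butterworth-filtered white noise, 2 Hz bandwidth) with variance
σ² = −ln A(κ_target), so the pairwise phase difference — wrapped normal,
closed under differences — has mean resultant length exactly A(κ_target)
and the recovered κ equals the target in expectation. A von Mises jitter
draw was rejected because i.i.d. draws are spectrally white and would be
smoothed away by the ±5 Hz bandpass, and the difference of two von Mises
variables is not von Mises, making pairwise calibration inexact. κ = 0
requests independent oscillations per wire; κ = None identical ones.

The 2-Hz jitter bandwidth balances two opposing estimator biases measured
numerically: slower jitter leaves too few effective samples (R̄ inflation,
κ̂ biased up), faster jitter is partially removed by the ±5 Hz bandpass
(κ̂ biased up at low κ). With the default, session-level κ recovery is
within 15% of target for κ ∈ {0.5, 2, 8} at oscillation SNR ≈ 1 relative
to the background RMS. In-band background noise adds phase dispersion, so
recovery degrades gracefully as the oscillation amplitude falls — real
recordings sit somewhere on that curve, which is why κ comparisons across
conditions are more trustworthy than absolute κ values.

What the generator does **not** emulate: spikes/units, volume conduction
(backgrounds are wire-independent, so bipolar derivation removes nothing
that was not put in explicitly), line noise and movement artifacts,
non-stationary aperiodic exponents, and amplitude covariation between
oscillations and behavior beyond the shared drug profile. Passing tests
therefore demonstrate estimator correctness under the stated model, not
robustness to every artifact of in-vivo data.

Because no amplitude/SNR for real NBG episodes is established, oscillation
amplitude is a free parameter; tests use an RMS equal to the background
(50 µV on a 50 µV background), at which detection is reliable without being
trivial.

## Problem sizes and runtime

Tests run at desk scale by the package's own choice: sessions of 1.5–5 min
with 1–3 structures and 1–4 wires for estimator checks (the estimators are
window-local, so minutes of data exercise them fully), 20 replicates for
the connectivity contrast, 50 for brain-state discrimination, and a 5-min
3-structure session for end-to-end determinism. A
`SessionConfig.desk_scale()` (11 structures × 4 wires × 30 min) and
`long_session()` (180 min) are provided for full-scale runs. The whole
suite completes in ~2 minutes on one CPU; `scripts/acceptance.py` in a
similar time.

## Known limitations

- Per-window IRASA near a strong narrowband peak depresses the normalized
  baseline on the peak's flanks (the fractal estimate absorbs some peak
  power over f/h…f·h), which tilts the fitted background line; with a
  single bipolar pair this occasionally pushes E below −10 and costs a
  detection. Averaging ≥3 pairs per structure makes this negligible.
- κ from short windows or strongly autocorrelated phases is biased upward;
  compare conditions at matched window lengths.
- The rotation counter assumes a mostly-defined heading (>95% of frames);
  pose dropouts beyond that are refused rather than guessed.
- The brain-state rank-sum annotation treats sessions as exchangeable and
  is reporting plumbing only; no mixed-effects modelling is provided.
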