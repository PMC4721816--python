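# Methods

## The transform

A decimated DWT is a two-channel filter bank: at each level the current
approximation stream is passed through a lowpass (approximation) and a
highpass (details) FIR filter and downsampled by two.  This package's
analog counterpart replaces the z-domain Daubechies pair with s-domain
Butterworth-prototype filters and replaces decimation with a per-level
halving of every cut-off frequency.  The continuous branch outputs are
estimates of the DWT coefficient streams: sampling the (bulk-delayed)
analog line at the decimated coefficient time stamps recovers the digital
coefficients up to the phase mismatch quantified below.

Both halves of the correspondence rest on maximal flatness.  The
Daubechies-N magnitude response is the maximally flat FIR half-band
response (all-zero); the Butterworth response is the maximally flat IIR
response (all-pole).  Concretely:

* **Details.** `|H_hi|` of dbN rolls off at 20·N dB/decade toward DC and
  is fitted by a Butterworth highpass of order N.  Cut-off: `fs/2` for
  db1, `fs/2.34` for db4.
* **Approximation.** `|H_lo|` of dbN is periodic with a null at Nyquist
  and a rising image above it.  Its continuous-time match is therefore a
  band-stop (notch), not a lowpass: transmission zeros at `±jωn` mirror
  the Nyquist null, and the upper passband mirrors the first spectral
  image.  The notch is built by applying
  `p → (ωn/Q)·s / (s² + ωn²)` to the Butterworth lowpass prototype of
  order N/2 (order N for db1, where the prototype is first order), with
  `fn = fs/2, Q = 1/√2` (db1) and `fn = fs/2.12, Q = 0.735` (db4), and
  overall DC gain √2 = Σ lowpass taps.  This construction reproduces all
  printed level-1 notch coefficients of the reference designs within
  their printed precision (0.5 %).

Two published constants are internally inconsistent and resolved as
follows: the prose quality factor "Q = 1/2" for db1 contradicts the
printed denominator (1599 ≈ √2·ωn), which forces Q = 1/√2 — the code uses
1/√2; and the printed fourth-order details function is not the Butterworth
highpass the design text states (its denominator factors into two
identical critically-damped sections near 484 rad/s).  `design` mode
follows the stated parameters; `table2` mode reproduces the printed
functions verbatim; both are first-class.

**Level scaling.** The level-i filter is `H_i(s) = H_1(2^(i−1) s)`, so the
analysed band halves per level.  (Written as a substitution on s the
printed form `s → s/2^(i−1)` would raise the cut-off with level,
contradicting the multi-resolution semantics; the package implements the
direction that halves it.)

**Gain conventions.** Three modes: `normalized` (unit passband gain, the
convention of the published response plots), `literal` (the printed gains,
including the curious 2.25/2.0 high-frequency gains of the printed details
functions), and `fir_matched` for amplitude-commensurate comparison with
the digital transform.  In `fir_matched` mode the approximation filter is
anchored exactly (both the analog DC gain and the FIR tap sum are √2) but
the details filter has no common anchor point — the FIR peaks at Nyquist
where the analog highpass has not yet reached its asymptote — so its gain
is fitted least-squares to the FIR magnitude over [0.05, 0.95]×Nyquist.
For db1 this yields ≈2.19, essentially the printed 2.25 ≈ √2·π/2; the
sign is negative because the alternating-sign highpass construction makes
the FIR Nyquist response −√2 at every order.

## Numerical realization

High-order s-domain polynomials at rad/s scales reach ~10^16 in
coefficient magnitude; filters are therefore carried as zeros/poles/gain
and converted to polynomial form only for display.  Round-tripping through
polynomial coefficients preserves the frequency response to 1e−9 relative
(tested).

Simulation discretizes the controllable-canonical state-space model
exactly for piecewise-linear (first-order-hold) input, via the augmented
matrix exponential, and runs the recursion as a direct-form filter with a
one-sample look-ahead numerator; a correction removes the spurious initial
state the z-domain solution would imply when the first sample is nonzero.
The result agrees with reference continuous-time simulation (`lsim`-style,
linear interpolation) to ~1e−14 and with the closed-form first-order step
response to <1e−6.  Because the discretization is exact for
piecewise-linear input, the only simulation error is input-reconstruction
error; the `oversample` parameter refines the output grid (needed to
grid-search sub-sample alignment delays) but cannot add information
between the given samples.

Group delay is computed analytically: each zero/pole r contributes
`∓Re(r)/|jω − r|²`.  Frequencies coinciding with jω-axis transmission
zeros are excluded (undefined phase slope).  FIR group delay uses the
standard discrete-time computation, converted to seconds.

**Delay equalization.** The residual between an analog and a digital
group-delay curve is summarized after removing one fixed bulk delay d,
chosen to minimize the *peak* of `|τa(f) − τd(f) − d|·f·100` — the error
expressed as a percentage of one cycle at each frequency.  The objective
is a maximum of convex V-shapes in d, hence unimodal; a bounded scalar
minimizer finds it.  Peak (minimax) rather than least-squares matches how
the error levels are quoted.  Evaluation bands (config defaults,
overridable): details [0.05, 0.95]×Nyquist intersected with the filter's
−3 dB passband, falling back to the full span when the cut-off sits at
Nyquist (db1); approximation [0.01·fs, 0.8·fn], clear of DC and of the
notch singularity.  With these defaults at 360 Hz the first-order pair
peaks at ≈1.5 % of a cycle and the fourth-order pair at ≈14.6 %.

## Transient comparison

`adwt_multires` runs the bank with no decimation (level-i filters applied
to the level-(i−1) continuous approximation).  `align_and_compare` then
grid-searches, per branch, a single fixed delay over the oversampled time
base, samples the delayed continuous output at the DWT coefficient time
stamps (linear interpolation), and reports the RMS deviation normalized by
the coefficient RMS.  Delays may be negative and large for mixed-phase FIR
banks (the db4 cascade accumulates ≈0.2 s of bulk delay at level 4 at
360 Hz); candidate delays that would push more than half the coefficients
outside the simulated span are discarded, and deviations are computed over
the coefficients that remain.

The level-1 caveat: the level-1 details branch is the only one whose
filter sees the raw input with no band-limiting in front of it.  In the
deployment scenario — an analog front end processing the continuous
signal — the input carries noise above the digital Nyquist which the
highpass passes straight through, while the digital transform never sees
it; from level 2 on, the approximation filter has imposed band-limiting
and the effect disappears.  The comparison machinery reproduces this by
generating the test ECG on a continuous-time stand-in grid (8× the base
rate) whose noise rolls off gently (2nd order) above fs/4, feeding the
analog bank the continuous signal and the digital transform its
stride-sampled base-rate acquisition.  Under these conditions the
fourth-order bank's level-1 details deviation exceeds its level-2
deviation on every seed tested, while the first-order bank stays well
matched at level 1 — the qualitative contrast reported for the two banks.
When both transforms are fed the identical base-rate samples instead, the
level-1 branch is consistently the best matched and the caveat does not
arise; the deviation ceilings asserted in the tests are pinned from the
package's own verified runs, as no reference numbers exist for this
comparison.

## Synthetic data

The generators are pure functions of their parameter dataclasses
(seed included).

**ECG.** A quasi-periodic train of biphasic beats — two opposed
Gaussian-derivative lobes with millisecond-scale slopes, QRS-like —
at 72 bpm with ±5 % interval jitter, amplitude 1, plus broadband noise of
RMS 0.3 low-passed (2nd order) at fs/4.  The template keeps >99 % of its
energy below fs/4, so the digital level-1 details band carries essentially
only noise; the noise retains genuine content above fs/2 on the continuous
grid (the front-end scenario above).  The noise level is calibrated so
beats are hidden in the raw trace yet recoverable as the largest local
maxima of the level-2 details energy envelope — the demonstration
behaviour the transform exists to support.  Ground-truth beat times are
returned.

**EEG.** Two-channel, two-state (wake/sleep) records at 100 Hz.  A state
track alternates with exponential dwell times (mean 5 min, truncated at
one 30 s epoch); within each state the signal is a sum over the four
0–25 Hz sub-bands (0–3.125, 3.125–6.25, 6.25–12.5, 12.5–25 Hz) of
band-limited Gaussian noise with the state's per-band RMS profile —
sleep delta-dominated (5, 2.5, 1.5, 1), wake dominated by the upper bands
(1, 1.5, 2.5, 3.5).  Bands are partitioned spectrally (FFT masking), so
the realized per-band powers converge to the requested profile without the
cross-band leakage a maximally flat analog shaper would introduce at
one-octave band spacing; within-state realized powers match the profile to
<2 % over a 100-epoch record and the per-epoch band-power rank order
matches the state profile in ≥95 % of epochs.  Epoch labels are assigned
by majority occupancy.  What this generator does *not* emulate: real EEG's
1/f background, artifacts, inter-subject variability, or graded sleep
stages — synthetic separability is by construction, so classification
accuracies on it say nothing about absolute performance on real
recordings; only the *transfer* property (DWT-trained, analog-tested)
is the meaningful read-out.

## Classification experiment

Features: per 30 s non-overlapping epoch, the per-sample mean-square power
of D2, D3, D4 and A4 per channel (8 features; level-1 details excluded per
the caveat above).  Mean square, not sum, keeps decimated coefficient
streams and continuous oversampled streams on one scale; log10 is applied
before standardization because powers span decades.  The classifier is a
feed-forward network — input, three hidden layers (16, 8, 4, logistic
units), output — trained with lbfgs; the original experiment's
scaled-conjugate-gradient backpropagation has no scikit-learn equivalent,
and lbfgs is the closest deterministic batch method.  A logistic-regression
fallback (`algorithm="logistic"`) provides a fully deterministic baseline.
Leave-one-record-out: standardization statistics come from the training
folds only; metrics (sensitivity = 100·TP/(TP+FN), selectivity =
100·TP/(TP+FP), each class in turn treated as positive) are averaged over
the out-of-sample folds.  In the transfer variant only the held-out
record's features are swapped for analog-bank features; training data and
standardization are untouched.  On the default synthetic conditions
(4 records × 100 epochs) the transfer changes every metric by about one
percentage point; the test bound is pinned at five points.  The published
absolute accuracies come from four full-day real recordings and are
deliberately not reproduced.

## Sizes and defaults

| parameter | default | why |
|---|---|---|
| base rate (ECG demos) | 360 Hz | standard ambulatory-ECG rate of the reference recordings |
| base rate (EEG) | 100 Hz | the sleep-EEG rate; makes the four feature bands 0–25 Hz |
| levels | 4 | the analysis depth of both demonstrations |
| oversample | 8 | sub-sample delay-search resolution; simulation itself is exact per grid |
| group-delay grid | 512 points, logarithmic | resolves the band edges without dominating runtime |
| EEG records | 4 × 100 epochs | leave-one-record-out needs ≥2; 100 epochs give stable per-fold confusion counts at desk scale |
| ECG segment | 2.5 s, 3 beats | the transient-comparison demonstration size |

Known limitations: the analog approximation branch is a notch, so input
energy above the final notch frequency leaks into deep approximation
levels where a digital transform would alias it differently — inputs
should be band-limited near the base Nyquist for faithful deep-level
estimates; the fourth-order details branches inherit the ~15 %-of-a-cycle
phase mismatch, visible as waveform distortion of broadband transients;
and reconstruction (inverse transform) is out of scope — the package
analyses signals, it does not resynthesize them.
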