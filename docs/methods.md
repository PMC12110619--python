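# Methods

## Problem and model

Band-average power — the integral of a channel's one-sided power spectral
density over a frequency band, in µV² — is the standard readout for EEG
rhythm strength. The quantity is estimator-dependent: the bandpass filter
that isolates the band leaks, ripples or distorts differently per design.
`bandopt` treats filter choice as a discrete optimization: over a grid of
(family, order) candidates with fixed per-family passbands, select the
stable design that minimizes the band-average power of the zero-phase
filtered signal. Since every candidate is near-unit-gain inside the scored
band by construction, a lower band average means better suppression of
out-of-band power leaking into the band estimate, not attenuation of the
in-band signal.

## Filter materialization and the stability frontier

IIR candidates are materialized as **single transfer-function polynomials**
(numerator/denominator coefficient vectors), not second-order sections, and
the construction runs entirely in the polynomial domain: analog lowpass
prototype (Butterworth or Chebyshev I) → polynomial transfer function →
lowpass-to-bandpass transform → bilinear transform with band-edge
prewarping. This representation is the point, not an implementation detail:
narrowband bandpass polynomials of order 2N are severely ill-conditioned,
and coefficient round-off pushes poles across the unit circle well before
the ideal zero-pole-gain design would destabilize. On the default bands at
500 Hz both IIR families are stable through design order 7 and unstable at
8–9; a cascade (SOS) materialization would be stable far higher and would
not exhibit the frontier this tool screens for. Stability is judged by the
companion-matrix eigenvalues of the denominator: stable iff every pole has
magnitude strictly below 1, with poles on the circle counted unstable
(conservative and deterministic).

Consequences of the polynomial representation, measured and accepted:

- Butterworth cutoff gains are 1/√2 to within 1e-3 at orders 4–6; at order
  7 round-off grows the deviation to ≈2e-3.
- Chebyshev passband ripple is confined to [1−δ, 1] (δ = 0.005) to within
  1e-6 at orders 2–5; orders 6–7 show excursions up to ≈2e-2 from the same
  round-off that destabilizes orders 8–9. Tests pin the exact behavior at
  the numerically faithful orders and tolerate the documented degradation
  above them.

The Chebyshev ripple parameter is specified as an amplitude fraction δ
(passband gain oscillates in [1−δ, 1]) and converted internally to the
decibel form −20·log10(1−δ) ≈ 0.0435 dB for δ = 0.005. FIR candidates are
Hamming-windowed sinc designs whose band edges are −6 dB points; taps are
rescaled post-design to exactly unit gain at the passband midpoint so FIR
and IIR scores are comparable.

## Zero-phase filtering

Candidates are applied forward and backward with odd-reflection edge
padding of length 3×(n_taps − 1). The effective amplitude response is |H|²
and the net phase is zero, so band power of the filtered signal is directly
comparable to the unfiltered reference. Unstable designs are rejected
before application. A subtlety worth documenting: for IIR filters the
forward-backward and backward-forward operator orders differ by edge
transients decaying like max|p|ⁿ; with pole radii ≈0.98 the two agree to
better than 1e-9 only a few thousand samples away from the record edges.
FIR filtering (symmetric taps) commutes with time reversal to machine
precision everywhere.

## Spectral estimation

Welch's method with 2 s Hamming segments (1000 samples at 500 Hz), 50 %
overlap and constant detrending — conventional EEG defaults, exposed in
`WelchParams`. Densities are reported one-sided in µV²/Hz (signals are
stored in volts; 1 V² = 1e12 µV²). Band-average power integrates the
density by the trapezoid rule with band edges included by linear
interpolation of the bounding bins; "average power" therefore has power
units (µV²), not density units. Per-channel power at a single frequency is
the Welch density linearly interpolated at that frequency; scalp maps are
min–max normalized per frequency into [0, 1], with a constant map defined
as all zeros.

## Channel screening

Three rules, a channel being removed iff at least one flags it:

- **Flatline**: some contiguous span longer than 10 s (default) over which
  the channel's max−min stays within 1 µV. The tolerance avoids the
  fragility of exact-equality tests under quantization; the sliding
  max/min is computed exactly with monotonic rolling filters. Invariant to
  constant offsets.
- **High-frequency noise**: score = SD of the residual above a 45 Hz
  lowpass; flagged when the robust z-score across channels — deviation from
  the median in units of 1.4826·MAD — exceeds 4. With zero MAD (all
  channels alike) nothing is flagged. The cap of 4 is a z-score threshold
  on a noise-SD statistic, the established form of this criterion.
- **Neighbor correlation**: on 1–45 Hz bandpassed data split into 5 s
  windows, each channel's window score is its maximum absolute Pearson
  correlation over its 4 nearest montage neighbors; the channel score is
  the median across windows, flagged below 0.7. Max-over-neighbors (rather
  than mean or a regression-based predicted signal) was chosen so that one
  good neighbor suffices to vouch for a channel; this is a design choice
  where the criterion's exact aggregation is genuinely open.

Screening assumes transient artifacts (blinks, movement) have already been
removed upstream, e.g. by ICA-based decomposition — that step is outside
this package. Blink-contaminated recordings will trip the HF-noise rule on
all frontal channels at once, which is detection working as specified on
uncleaned input, not a screening target.

Internal screening filters use SOS filtfilt; the transfer-function
polynomial mandate applies to the candidate bank whose instability is being
screened, not to these utilities.

## Synthetic data

The generator emulates the acquisition setting the tool targets: 64
channels at 500 Hz on a midline + lateral-ring montage, rhythmic activity
concentrated in canonical bands, 1/f background. Oscillations are
fixed-frequency sinusoids with one random phase per oscillation shared
across channels and per-channel amplitude weights — the volume-conduction
signature that makes neighboring electrodes correlated on a real cap, and
the reason a neighbor-correlation screen is meaningful at all. A tone of
RMS r contributes exactly r² µV² of band power, making ground truth
analytic. The background is spectrally shaped white noise (amplitude ∝
f^(−1/2)), split into a cap-wide shared field plus independent per-channel
noise (shared fraction 0.8 of variance) and rescaled to the exact per-channel
RMS. Defaults: 10 µV RMS background, 6 µV beta (20 Hz, frontal-weighted),
8 µV alpha (10 Hz, posterior-weighted) — typical scalp-EEG magnitudes with
beta dominant in its band, matching the attentive-viewing setting.

Artifacts are injected with annotations: blinks as one-sided 300 ms
exponential pulses of ≈0.02 V peak on frontal channels; muscle noise as
45–100 Hz bandpassed noise on temporal channels; flat segments exactly
constant; decorrelated channels replaced wholesale by independent 1/f noise
of matched RMS. What the generator does **not** model: volume-conduction
forward physics, non-stationary rhythm dynamics, electrode drift, line
noise, or ICA-separable source mixing. Passing tests therefore demonstrate
the pipeline's correctness on signals whose spectral and spatial structure
is known exactly, not robustness to every pathology of clinical recordings.

## Problem sizes and determinism

Tests and the acceptance script run on 60 s, 64-channel recordings (30 000
samples per channel) — long enough for ≈59 Welch segments and tight
band-power estimates, small enough to keep the full 115-candidate sweep in
seconds. All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); identical seeds give bit-identical
recordings, reports and selections.

## Known limitations

- Selection minimizes band power only; the per-candidate report includes
  the pole radius but no in-band-flatness statistic, so a user auditing
  the "flat in band" premise should inspect `magnitude_response` on the
  scored band.
- Cutoff frequencies per family are fixed inputs, not optimized.
- EDF/BDF export quantizes to the format's 16-/24-bit integers; the CSV +
  sidecar format is the lossless interchange.
- The optimizer evaluates all FIR orders with no early stopping;
  determinism and a complete report are preferred over speed.
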