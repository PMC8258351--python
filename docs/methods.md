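# Methods

## Scope and structure

`binloud` models categorical loudness scaling (CLS) data of normal-hearing
(NH) and hearing-impaired (HI) listeners. Three layers build on each
other:

1. **Loudness functions** (`loudness_function`): the parametric level-to-CU
   mapping, its fitting procedure, and the CU/sone transforms.
2. **The loudness model** (`excitation`, `stages`, `model`): stimulus to
   internal excitation to binaural internal loudness to CU.
3. **Analyses** (`summation`, `individualization`): binaural summation
   ratios and the data-driven binaural-stage fit; the four-version
   individualization hierarchy with its performance metrics.

A synthetic-listener generator (`synthetic`) closes the loop so every
analysis is exercised end to end without measured data.

## Loudness functions and transforms

The categorical loudness function is two straight lines (slopes `m_lo`,
`m_hi` in CU/dB) joined by a quadratic Bezier arc between 15 and 35 CU
whose control point lies on the line intersection at 25 CU; the hearing
threshold is the 2.5-CU level and anchors the lower branch. Output is
clipped to [0, 50] CU. Fitting minimizes horizontal (level-direction)
residuals with the threshold pinned; if fewer than 5 data points lie in
35-50 CU, the upper slope is fixed (default 0.7 CU/dB, configurable).
Threshold estimation strategies:

- `zero-crossing` (default when 0-CU responses exist): interpolated level
  at which the fraction of "not heard" responses crosses 50 %;
- `extrapolate`: straight-line fit to the pure lower branch solved at
  2.5 CU;
- `least-squares`: the anchor is a third free parameter of the
  level-direction fit. The fitting hierarchy uses this strategy: the
  crossing estimate rests on the few trials near threshold (its standard
  deviation is several dB at 3-CU response noise) and that anchor noise
  would propagate into every post-gain fit.

CU-to-sone conversion is a strictly increasing log10-cubic in (cu - 25)
with five stored coefficients. The shipped default assigns ~1 sone near
19 CU and ~140 sones at 50 CU, with the characteristic steepness at low
categories (low CU categories span a wide sone range). Tests rely only on
monotonicity and round-trip behavior, not on the specific coefficients.

## Excitation front end

The front end is a functional stationary excitation-pattern model; all
individualization stages sit downstream of it and are unchanged by that
choice.

- Third-octave band levels (narrowband noises occupy one band; the
  broadband IF noise follows a shipped female speech-spectrum shape,
  power-normalized to the overall level).
- A fixed filter chain folds the outer/middle-ear transfer and threshold
  correction into one free-field threshold curve, so audiogram values in
  dB HL offset it directly; +/-60 degree azimuths apply a shipped
  frequency-dependent interaural level difference (interaural phase is
  ignored by this energy-based model).
- Excitation spreading along N log-spaced segments (default N = 1000;
  tests and the recovery study use N = 200): 27 dB/oct toward low
  frequencies, level-dependent flattening toward high frequencies (upward
  spread of masking), power summation across bands.
- Per-segment input/output function (dB domain): normal hearing
  compresses at 0.3 dB/dB; OHC loss shifts the threshold and linearizes
  growth (recruitment), rejoining the normal curve at 100 dB sensation
  level. The audiogram is split OHC-first up to the 35-dB cochlear-gain
  cap, remainder IHC; the construction makes the modeled detection
  threshold equal the audiogram at the audiometric frequencies (smooth
  audiograms; strong audiogram notches can be detected off-frequency).
- The IHC attenuation (input-referred dB) is applied ahead of a constant
  internal threshold; everything at or below threshold is zeroed. The
  supra-threshold remainder is compressed with a specific-loudness
  exponent of 0.5 and amplified by the per-frequency post gain. The
  exponent flattens the excitation profile across place so the bandwidth
  estimator cleanly separates narrowband (W ~ 0.15-1) from broadband
  (W ~ 0.7-2.3) excitation; without it, W barely distinguishes the two and
  the bandwidth-gain parameters are practically unidentifiable.
- Stationary stimuli use a steady-state single frame; a first-order
  25-ms integrator resampling to 200-Hz frames is provided for
  time-varying band envelopes, keeping the frame interface open.

A post gain equal to `0.5 * threshold_slope * IHC` exactly opposes the
IHC attenuation at high levels (`counteracting_post_gain_db`), restoring
a normal uncomfortable level while keeping the elevated threshold — the
recruitment configuration.

## Calibration and the NH reference

The internal-loudness-to-sone power law (scale, exponent) is set by
regressing (log-log) the zero-loss model's internal loudness for the
monaural 1-kHz narrowband noise onto the sone values of an analytic NH
anchor (2.5 CU at the free-field threshold, 25 CU at 65 dB SPL, 50 CU at
100 dB SPL). The calibration is deterministic and idempotent; the anchor
only pins scale and overall slope (the calibrated model deviates from the
anchor's exact two-line shape by a few dB rms, which is reported, not
hidden). The average NH reference loudness functions used by the aided
narrowband loudness compensation are then *generated from the calibrated
zero-loss model*, never hand-entered, so all closed-loop checks
(zero-loss model vs. NH reference within 2 dB rmse) are meaningful through
the anchor.

Aided ("loudness-compensated") stimuli apply per-band, level-dependent
gains restoring the listener's band loudness to that NH reference,
capped at 60 dB; NH listeners receive only small corrections.

## Individualization hierarchy

All fits compare measured and modeled loudness functions at the
categories 5-50 CU in the level direction; modeled curves are condensed
into parametric functions with the same estimator that condenses the
measured data, so both sides live in the same space. Broadband functions
are up-weighted by the number of narrowband stimuli (6) so narrowband and
broadband data contribute equally.

1. **Version 1** — per ear and frequency, the OHC share is chosen from a
   small grid (1.0, 0.6, 0.3 of the capped loss; steeper measured lower
   branches favor larger OHC shares) jointly with a fitted post gain; a
   second pass refits the post gains with all neighbors in place (the
   periphery is interpolated across segments, so bands interact).
   Frequencies without a fittable dataset (inaudible conditions) keep the
   counteracting post-gain default. The binaural stage stays at the
   average NH gain alpha_B = -0.273.
2. **Version 2** — beta_L, beta_R by a profiled search: for each candidate
   beta the post gains are refitted to the narrowband functions starting
   from the version-1 state, and the profiled narrowband + broadband error
   is minimized (grid then local refinement). Restarting from version 1
   keeps the fit in the basin of the smallest adjustment to the
   lower-version solution; beta and the post gains are otherwise nearly
   collinear on narrowband data and a naive alternation can drift far
   along that ridge.
3. **Version 3** — alpha_B by bounded scalar minimization
   (alpha_B in [-0.5, 1]) on the diotic narrowband functions.
4. **Version 4** — (alpha_B, beta_B) by Nelder-Mead with the binaural
   aided broadband function added. "Version 3 modified" refits alpha_B
   alone on the same target set.

Versions freeze the parameters of lower versions except for the
version-2 post-gain profiling above. Structurally, a version-k+1 model
whose new parameters sit at their defaults (beta = 0,
alpha_B = -0.273) is bit-for-bit identical to the version-k model.

Performance metrics: ncc against the grand-mean level, adjusted
ncc' = 1 - (1 - ncc)(n - 1)/(n - p - 1) with n = 10 x stimuli (omitted
when p >= n - 1), pooled rmse, and bias with the convention that positive
bias means the predicted function sits at higher levels (loudness
underestimated). The printed bias formula in the source literature has
the opposite sign of its stated interpretation; this implementation
follows the interpretation, bias = mean(L_pred - L_meas).

## Synthetic listeners

The generator emulates the study conditions, not any particular cohort's
raw data:

- NH audiograms at or better than 15 dB HL; HI audiograms drawn per
  audiometric frequency around means (23, 33, 40, 48, 61, 59) dB HL with
  SDs (11, 12, 11, 18, 12, 17), truncated to 5-75 dB HL. Deviations are
  AR(1)-correlated across frequency (rho = 0.7; sensorineural audiograms
  are smooth) and correlated 0.8 between ears (asymmetric losses occur,
  exercising the equal-loudness ratio corrections).
- alpha_B: NH ~ Normal(-0.36, 0.08) truncated to [-0.5, -0.15];
  HI ~ Normal(-0.10, 0.30) truncated to [-0.5, 0.6] — the HI spread is
  wider and includes binaural excitation, the central empirical structure
  being emulated.
- beta_L, beta_R ~ Normal(0.25, 0.15) truncated to [0, 0.7]; post gains
  restore 50-100 % of the way to a normal uncomfortable level plus a 2-dB
  perturbation.
- Scaling sessions: level placement emulates the outcome of an adaptive
  procedure (range sweep, then stratified levels at the listener's own
  5-50 CU category levels plus near-threshold probes); responses are
  model CU plus Gaussian noise (default sigma = 3 CU, matching the coarse
  5-CU grid), rounded to the 11 categories; default 33 trials per
  function (three near-threshold probes plus three complete category
  sweeps, so every category carries equal weight).

What passing tests show — and what they do not: closed-loop recovery
demonstrates that the estimation machinery is consistent and that the
parameters are identifiable at realistic noise levels; because the same
model family generates and fits the data, it cannot demonstrate that the
model family describes real listeners, nor does the generator emulate
test-retest bias, response-time structure, or adaptive-procedure
artifacts.

## Numerical choices

- Problem sizes: N = 200 segments for tests and the recovery study
  (N = 1000 default elsewhere); level grid 0-115 dB in 1.5-dB steps;
  recovery study 20 listeners x 26 conditions x 33 trials.
- Bandwidth estimator conventions: all-zero input returns W = 0; a
  vanishing mean absolute deviation (uniform excitation) caps W at 1e3.
  Zero denominators in the binaural difference yield V = 0 (monaural
  pass-through).
- Optimizers: bounded Brent for all scalar fits (post gains to 0.01 dB,
  alpha_B to 1e-5, the data-driven alpha_B to 1e-8 with explicit
  bound-snapping); Nelder-Mead for (alpha_B, beta_B); trust-region
  least squares for function fits. All deterministic; every simulation
  consumes an explicit seed.
- Sone-to-CU inversion in the prediction path uses a dense cached grid
  (4001 points, interpolation error ~1e-5 CU); the exact cubic solve
  backs the public inverse.
- beta bounds [-0.5, 2], alpha_B bounds [-0.5, 1], post-gain bounds
  [-20, 40] dB, aided-gain cap 60 dB.

## Known limitations

- The front end is a stationary excitation-pattern stand-in: no cochlear
  wave mechanics, no temporal fine structure, interaural phase ignored;
  azimuth effects reduce to interaural level differences from a
  constructed table.
- The shipped speech-spectrum and ILD tables are representative
  constructed values (marked `synthetic` where applicable), adequate for
  exercising the pipeline, not for absolute predictions about specific
  sound fields.
- alpha_B is frequency-independent by design; a per-segment hook would be
  the natural extension for the observed decrease of summation ratios
  with center frequency, and is deliberately not implemented.
- Version-2 identifiability rests on the narrowband/broadband contrast of
  the bandwidth estimator; with very steep (strongly recruiting) loudness
  functions and few audible conditions, individual beta estimates can
  still scatter by a few tenths even though the median recovery is well
  inside 0.15.
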