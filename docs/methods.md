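# Methods

## Atmospheric model

Absorption follows the pure-tone formulation standard in bioacoustics
(classical viscous/thermal losses plus the humidity- and pressure-dependent
vibrational relaxation of O₂ and N₂, as standardised in ISO 9613-1). Inputs
are temperature (−20…50 °C), relative humidity (0…100 %) and static pressure
(10…110 kPa); output is dB per metre for 5–250 kHz. Saturation vapour
pressure uses the companion expression of that standard (a Magnus variant is
available; they differ by <1 % in range). The relaxation terms are
non-negative, so the classical coefficient is a lower bound — a property the
tests exploit.

Default pressure is 101.325 kPa everywhere. A montane study site at
1200–1800 m would sit nearer 84–88 kPa, which lowers α by a few percent;
pressure is a field of `AtmosphericState` precisely so site-specific values
can be supplied. The sea-level default keeps all headline numbers
reproducible from stated conditions alone.

Speed of sound comes from an ideal-gas binary mixture of dry air
(M = 28.965 g/mol, Cp = 3.5 R) and water vapour (M = 18.015 g/mol,
Cp = 4.0 R): c = √(γ_mix R T / M_mix). Against the Cramer (1993) empirical
formula this agrees to ~0.1 m/s over the study range; the humidity
contribution at 20 °C, 94 % RH is +1.2 m/s. Localization and the
overlap-zone calculation both consume this per-trial value.

## Sonar-equation detection distance

The echo level of prey at range d is
EL = aSL − 40 log₁₀(d/0.1) − 2α(d − 0.1) + TS, all referenced to 10 cm.
The reference leg carries no absorption, so EL(0.1) = aSL + TS exactly; the
alternative (absorbing over the full path) shifts DD by <0.05 m and is a
matter of convention. Prey classes are fixed at TS = −30/−20/−10 dB
(nominal 10/20/30 mm² of reflecting area).

The hearing threshold is 20 dB SPL at the reference duration and falls by
`db_per_doubling` (default 6) dB per doubling of duration, with the benefit
capped at an integration time of 2 ms — short calls gain detectability from
length, long calls do not. The reference duration is the individual's mean
duration at ambient temperature (the constant-call baseline); the rule then
leaves the baseline threshold untouched and only credits *changes* in
duration. Setting `db_per_doubling = 0` recovers a fixed threshold.
The 6 dB/doubling figure is exposed as a parameter rather than hard-coded:
published detectability gains in this literature are sometimes closer to
3 dB/doubling, and the choice materially affects the flexible-call model.

EL is strictly decreasing in d, so DD is the unique root of
EL(d) = threshold on [0.1, 50] m. Bisection runs to a 0.01 dB level
tolerance and a sub-0.1 mm bracket; a 0.5 mm grid-scan oracle agrees to
<1 mm in tests. Echoes below threshold at 10 cm or above threshold at 50 m
return flagged boundary results, never silent extrapolations.

## Scene simulator

The generator's defaults encode the study conditions: a 6 × 2.5 × 2.5 m
flight cage; a star array (three peripherals 0.6 m from a central
microphone, all facing into the cage); 500 kHz / 16-bit 4-channel
recordings; three treatments per individual in fixed order (T_a, T_a+2 °C,
T_a+4 °C with RH 94/94/89 %); and round(N(6, 3)) (floor 1) calls per
individual per treatment.

Calls are hyperbolic FM downsweeps spanning one octave into a terminal
plateau at the peak frequency (the plateau carries the spectral maximum, as
in vespertilionid search/approach calls); the −12 dB envelope width equals
the nominal duration and the rms over that window equals the nominal aSL by
construction. A second harmonic is added at −25 dB by default, muted where
it would alias. Call shape beyond these constraints (sweep octaves, ramp
fraction, harmonic level) is configurable and not a claim about any species.

Rendering applies, per channel and per spectral bin: the propagation delay
d/c with fractional-sample accuracy via frequency-domain phase shift (TOAD
accuracy well below one 2 µs sample is needed for cm-scale localization),
spherical spreading 20 log₁₀(d/0.1), absorption α(f)(d − 0.1), and the
microphone's frequency response and directivity at the incidence angle.
Channels sum with Gaussian sensor noise (default 40 dB SPL rms) and quantise
against a 5 Pa full scale; clipping is an error naming the offending event.
Species presets follow the reported magnitudes for *M. pilosatibialis*
(~68–78 kHz, ~110–121 dB, ~1.5–1.9 ms) and *E. brasiliensis* (~54–60 kHz,
~101–106 dB); the remaining presets are labelled assumptions. Temperature
slopes default to zero — a null model — and are switched on per study.

What the simulator does *not* emulate: reverberation and multipath (the real
cage was acoustically damped), Doppler, emission-beam directionality,
multiple simultaneous bats, and wind/temperature gradients. Passing
round-trip tests therefore demonstrate the internal consistency of the
forward and inverse models at the stated noise levels, not robustness to
every artefact of field recordings.

Flight paths are superposed incommensurate sinusoids constrained to speeds
of 1–6 m/s inside the cage, giving alternating approach and retreat legs;
calls are placed in approach legs ~95 ms apart (falling back to arbitrary
epochs in files too short to contain one). For statistical power and
parameter-recovery studies, `simulate_call_table` draws the filtered call
table directly from the preset distributions (per-individual random
intercepts and slopes plus within-individual scatter) — replicating the
audio chain a hundred times would add cost but no information about the
estimator.

## Localization

Generalized cross-correlation (plain correlation on 25–120 kHz bandpassed
channels, Butterworth order 4, forward–backward) with 3-point parabolic peak
interpolation gives the three outer-minus-central TOADs *and* the three
outer–outer pair delays. The pair delays are geometrically redundant but
carry independent measurement errors, making the Gauss–Newton solve
(damped, initialised 2 m in front of the array) overdetermined: its rms
residual is then a usable quality indicator (rank correlation ~0.9 with true
error under noise) rather than an identically-zero artefact. The front/back
mirror ambiguity of a planar array is resolved by constraining fixes to the
cage half-space; fixes with residual > 5 cm, low correlation quality, or at
the 20 m search boundary are flagged. Approach runs are maximal chains of
calls with strictly decreasing distance to the central microphone; ties
break the chain, and runs shorter than 4 calls are discarded.

## Call measurement and quality cascade

Duration is the width of the smoothed (50 µs moving average) Hilbert
envelope at −12 dB below its peak. Peak frequency is the maximum of the
Hann-tapered, ≥4096-point zero-padded spectrum of that −12 dB segment within
the session band, with parabolic bin interpolation; peaks within ~0.5 kHz of
the band edge or with <15 dB prominence over the median in-band level are
flagged. SNR compares the −12 dB call segment to an equal-length noise
window ending 5 ms before the call. aSL removes the microphone response and
directivity and restores spreading and absorption per spectral bin before
taking the rms — restricted to the session band, because the absorption
gain grows roughly as f² and would otherwise amplify out-of-band noise into
the estimate. A scalar broadband mode (correction at the peak frequency) is
provided; for the narrowband terminal sweeps here it differs by <0.3 dB.

The cascade runs in a fixed order: approach-run membership → SNR ≥ 30 dB →
second-harmonic rejection (a local maximum at 0.4–0.6 × the spectral peak
within 20 dB of it means the peak is a harmonic) → per-trial retention of
calls with aSL at or above the nearest-rank 90th percentile (the
⌈0.9 n⌉-th order statistic, read inclusively, so at least the loudest call
of every non-empty trial survives). Run membership and the percentile
threshold are defined against the trial's original sequence/population and
are memoized in the table, so re-applying the cascade is a no-op.

## Scenario analysis and mixed models

Per-individual means of the filtered calls at each treatment feed two
counterfactuals: the constant-call model combines the T_a parameters with
each trial's actual weather (a bat that does not adjust), the flexible-call
model uses each trial's own parameters. Both modes share the T_a duration as
the threshold reference, so the two are row-identical at T_a by
construction. Every scenario row stores its inputs; α and DD are
recomputable bit-identically from them.

Fixed-RH scenarios hold the constant-call parameters and sweep temperature
over the ambient span of the experiments (default 19–25 °C) at RH pinned to
50/75/100 %; the per-species change across the span summarises each surface.

Mixed models use REML with Wald z inference (exact degree-of-freedom
corrections are out of scope). The temperature-response models put a random
intercept and a random temperature slope on each individual; temperature
enters in °C and distance in metres, both uncentered, keeping coefficients
on the measurement scale. The constant-vs-flexible comparison uses random
intercepts by default ("individuals as random effects"), with random slopes
behind a flag, since the two readings of the original design are both
defensible. Singular or non-convergent fits are returned flagged with no
fabricated estimates; a constant distance column is detected as rank
deficiency before fitting.

## Problem sizes and numerical choices

Rendered-audio checks use 0.4–2.6 s files with tens of calls at 0.5–4 m and
≤45° off-axis — the envelope where the fidelity claims (≤5 cm RMSE position,
±1 dB aSL, ±10 % duration, ±1 kHz peak frequency at SNR ≥ 30 dB) are tested.
Mixed-model recovery uses 30 individuals × 3 treatments × ~6 calls over 100
seeded replicates (bias < 10 % of a 0.05 ms/°C duration slope). Bisection
tolerance is 0.01 dB; TOAD quality floor 0.15; localization residual flag at
5 cm. Degenerate inputs (flat windows, empty trials, missing treatments,
single fixes, constant regressors) raise or warn rather than guessing.

## Known limitations

- The absorption model is the pure-tone standard; broadband or octave-band
  weighting and CO₂-enriched atmospheres are out of scope.
- Target strength is frequency-independent within a prey class; glint,
  aspect and surface effects are not modelled.
- The simulator's omissions (above) mean field recordings will show
  reverberation and beam-direction effects the pipeline has not been
  stress-tested against.
- aSL is an apparent source level: emission directionality makes it a lower
  bound on the on-axis level, which is exactly why the loudest-decile filter
  exists.
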