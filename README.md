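# echotherm

Tools for studying how shifting ambient temperature alters the sensory reach
of echolocating bats. Insectivorous bats detect prey by listening for the
echoes of their own ultrasonic calls, and the atmosphere taxes those calls
heavily: absorption at 55–80 kHz runs at 2–3 dB per metre and depends
non-linearly on temperature, relative humidity and frequency. Warming can
therefore shrink (or occasionally extend) the distance at which a bat hears
a prey echo — unless the bat adjusts its calls. `echotherm` implements the
full analysis chain for flight-cage experiments on this question, from
simulated 4-microphone ultrasonic recordings to mixed-model inference, for
bioacousticians and sensory ecologists.

## What it computes

**Absorption and sound speed** (`echotherm.atmosphere`). The pure-tone
atmospheric absorption coefficient α(f, T, RH, p) in dB/m — classical losses
plus O₂ and N₂ vibrational relaxation (the ISO 9613-1 formulation) — and the
speed of sound in humid air from a moist-ideal-gas mixture model.

**Detection distance** (`echotherm.sonar`). The sonar equation for a prey
echo at distance *d*,

    EL = aSL − 40·log₁₀(d/0.1) − 2·α·(d − 0.1) + TS,

with aSL the apparent source level (dB rms re 20 µPa at 10 cm), TS the prey
target strength (−30/−20/−10 dB for small/medium/large prey at 10 cm), and a
hearing threshold of 20 dB SPL that drops 6 dB per doubling of call duration
for short calls (saturating at ~2 ms). The detection distance DD is the
range where EL meets the effective threshold, solved by bisection.

**Scene simulation** (`echotherm.scene_sim`). Synthetic bats flying in a
6 × 2.5 × 2.5 m cage under three treatments (ambient T_a, +2 °C, +4 °C at
94/94/89 % RH) emit hyperbolic-FM calls that are rendered into calibrated
4-channel 500 kHz PCM16 recordings — fractional-sample delays, spherical
spreading, per-bin absorption, microphone frequency response and
directivity, sensor noise — with full ground truth.

**Localization and call measurement** (`echotherm.localization`,
`echotherm.call_extraction`, `echotherm.pipeline`). Time-of-arrival
differences from generalized cross-correlation (sub-sample, ~2 µs) feed a
damped Gauss–Newton multilateration; calls emitted while approaching the
array are selected; duration (−12 dB Hilbert-envelope width), peak frequency
and aSL (back-propagated to 10 cm) are measured and passed through the
quality cascade (approach runs ≥ 4 calls, SNR ≥ 30 dB, second-harmonic
rejection, per-trial 90th-percentile aSL).

**Scenario analysis** (`echotherm.scenario_analysis`). Per-individual
summaries; the constant-call (parameters frozen at T_a) vs flexible-call
(parameters as measured) counterfactual for AA and DD; fixed-RH climate
scenarios (50/75/100 %); prey-size sensitivity; and random-slope linear
mixed models (per-individual intercepts and temperature slopes, REML).

## Worked example

```bash
python examples/02_detection_distance.py
```

```
calibrated aSL = 94.47 dB re 20 uPa at 10 cm
DD(small  prey, TS -30 dB) = 0.99 m   (alpha = 2.65 dB/m)
DD(medium prey, TS -20 dB) = 1.50 m   (alpha = 2.65 dB/m)
DD(large  prey, TS -10 dB) = 2.17 m   (alpha = 2.65 dB/m)

DD with 2.0 ms call (same aSL) = 1.65 m
overlap zone grows by 8.6 cm for the extra 0.5 ms
```

At 70 kHz in 20 °C / 94 % RH air the absorption is 2.65 dB/m; a source level
of 94.5 dB re 20 µPa at 10 cm puts medium prey at exactly 1.5 m of detection
range, and each prey-size class (10 dB of target strength) moves that range
by roughly half a metre. Lengthening the call from 1.5 to 2.0 ms buys 15 cm
of range through temporal integration but extends the zone where the
outgoing call masks the echo.

The other examples cover absorption/fixed-RH scenarios (`01`), simulation
plus localization (`03`), the extraction pipeline and filter cascade (`04`)
and the mixed-model layer (`05`). The physics calculators are also available
on the shell:

```bash
echotherm aa --freq 78 --temp 19 --rh 94          # -> 3.0081 (dB/m)
echotherm dd --freq 70 --asl 94.47 --duration 1.5 --temp 20 --rh 94
```

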