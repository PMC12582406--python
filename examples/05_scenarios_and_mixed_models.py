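"""Constant-call vs flexible-call scenarios and random-slope mixed models.

Simulates a species whose bats lengthen their calls as it warms, summarizes
per individual, and asks: (1) does a random-slope model recover the
temperature response? (2) do attenuation and detection distance differ
between a bat that keeps its ambient-temperature call (constant-call model)
and the bat as observed (flexible-call model)? (3) what happens in drier
climates (RH fixed at 50/75/100 %)?
"""

from echotherm import (
    build_scenario_table,
    fit_mode_interaction,
    fit_random_slope_m1,
    rh_scenarios,
    simulate_call_table,
    summarize_individuals,
)
from echotherm.scene_sim import DEFAULT_PRESETS

# bats that lengthen calls by 0.05 ms/C and raise source level by 0.3 dB/C
preset = DEFAULT_PRESETS["M_pilosatibialis"].with_slopes(dur=0.05, asl=0.3)
calls = simulate_call_table(preset, n_individuals=30, seed=7)
print(f"simulated {len(calls)} calls from 30 individuals x 3 treatments")

fit = fit_random_slope_m1(calls, "duration_ms")
est = fit.param("temperature_c")
p = float(fit.pvalues["temperature_c"])
print(f"duration ~ temperature random-slope model: "
      f"{est:.3f} ms/C (true 0.05), p = {p:.1e}")

summaries = summarize_individuals(calls)
scenarios = build_scenario_table(summaries, mode="both", prey="medium")
mode_fit = fit_mode_interaction(scenarios, response="dd")
inter = mode_fit.param("C(mode)[T.flexible]:temperature_c")
p_int = float(mode_fit.pvalues["C(mode)[T.flexible]:temperature_c"])
print(f"\nModel x Temperature on detection distance: {inter:+.4f} m/C, p = {p_int:.3f}")
# A positive interaction means the observed call adjustments buy range as it
# warms, relative to the keep-your-ambient-call counterfactual.

grid = rh_scenarios(summaries, temperatures_c=(19.0, 21.0, 23.0, 25.0))
print("\nfixed-humidity scenarios (constant-call parameters), 19 -> 25 C:")
for _, row in grid.deltas.iterrows():
    print(f"  RH {row['rh_fix_pct']:5.0f}%: attenuation {row['delta_alpha_db_per_m']:+.3f} dB/m, "
          f"detection distance {row['delta_dd_m'] * 100:+.1f} cm")
# Warming costs the most attenuation (and range) in the dry 50 % scenario;
# near saturation the attenuation barely moves.
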