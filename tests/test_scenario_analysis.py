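import dataclasses

import numpy as np
import pandas as pd
import pytest

from echotherm import (
    AtmosphericState,
    HearingModel,
    absorption_coefficient,
    build_scenario_table,
    detection_distance,
    fit_mode_interaction,
    fit_random_slope_m1,
    fit_random_slope_m2,
    prey_size_sensitivity,
    rh_scenarios,
    simulate_call_table,
    summarize_individuals,
)
from echotherm.scene_sim import DEFAULT_PRESETS
from echotherm.sonar import CallEmission, PreyTarget


def make_summaries(
    n_ind=6, asl_slope=0.0, pf_slope=0.0, dur_slope=0.0, pf0=70.0, asl0=112.0, dur0=1.5
):
    """Hand-built per-individual summary table over the three treatments."""
    rows = []
    temps = {"Ta": 19.0, "Ta+2": 21.0, "Ta+4": 23.0}
    rhs = {"Ta": 94.0, "Ta+2": 94.0, "Ta+4": 89.0}
    for i in range(n_ind):
        for trt, t in temps.items():
            dt = t - 19.0
            rows.append(
                dict(
                    individual_id=f"b{i}",
                    species="sp",
                    treatment=trt,
                    temperature_c=t,
                    rh_pct=rhs[trt],
                    pressure_kpa=101.325,
                    distance_m=2.0,
                    peak_frequency_khz=pf0 + i * 0.5 + pf_slope * dt,
                    asl_db=asl0 + i * 0.3 + asl_slope * dt,
                    duration_ms=dur0 + dur_slope * dt,
                )
            )
    return pd.DataFrame(rows)


class TestSummarizeIndividuals:
    def test_arithmetic_means(self):
        df = pd.DataFrame(
            dict(
                individual_id=["b1", "b1"],
                treatment=["Ta", "Ta"],
                peak_frequency_khz=[70.0, 72.0],
                asl_db=[110.0, 112.0],
                duration_ms=[1.4, 1.6],
                temperature_c=[19.0, 19.0],
                rh_pct=[94.0, 94.0],
            )
        )
        out = summarize_individuals(df)
        assert len(out) == 1
        assert out["peak_frequency_khz"].iloc[0] == 71.0
        assert out["n_calls"].iloc[0] == 2

    def test_missing_treatment_warns_and_omits(self):
        df = simulate_call_table(DEFAULT_PRESETS["M_pilosatibialis"], 3, seed=0)
        df = df[~((df["individual_id"] == df["individual_id"].iloc[0]) & (df["treatment"] == "Ta+4"))]
        with pytest.warns(UserWarning, match="missing"):
            out = summarize_individuals(df)
        assert len(out) == 8

    def test_preset_means_recovered_on_null_data(self):
        preset = DEFAULT_PRESETS["M_pilosatibialis"]
        df = simulate_call_table(preset, 60, seed=3)
        out = summarize_individuals(df)
        assert out["peak_frequency_khz"].mean() == pytest.approx(preset.peak_frequency_khz.mean, abs=1.0)
        assert out["duration_ms"].mean() == pytest.approx(preset.duration_ms.mean, abs=0.1)


class TestScenarioTable:
    def test_constant_equals_flexible_at_baseline(self):
        table = build_scenario_table(make_summaries(asl_slope=1.0, pf_slope=-0.5))
        ta = table[table["treatment"] == "Ta"]
        wide = ta.pivot_table(
            index="individual_id", columns="mode",
            values=["alpha_db_per_m", "dd_m", "peak_frequency_khz", "asl_db"],
        )
        for var in ("alpha_db_per_m", "dd_m", "peak_frequency_khz", "asl_db"):
            assert np.array_equal(wide[var]["constant"], wide[var]["flexible"])

    def test_constant_mode_freezes_baseline_parameters(self):
        s = make_summaries(pf_slope=-0.5)
        table = build_scenario_table(s, mode="constant")
        warm = table[table["treatment"] == "Ta+4"]
        base = s[(s["treatment"] == "Ta")].set_index("individual_id")
        for _, row in warm.iterrows():
            assert row["peak_frequency_khz"] == base.loc[row["individual_id"], "peak_frequency_khz"]
            assert row["temperature_c"] == 23.0  # actual trial weather retained
            assert row["rh_pct"] == 89.0

    def test_flexible_mode_uses_trial_parameters(self):
        s = make_summaries(pf_slope=-0.5)
        table = build_scenario_table(s, mode="flexible")
        warm = table[(table["treatment"] == "Ta+4") & (table["individual_id"] == "b0")]
        assert warm["peak_frequency_khz"].iloc[0] == pytest.approx(70.0 - 0.5 * 4.0)

    def test_alpha_recomputable_from_stored_inputs(self):
        table = build_scenario_table(make_summaries(n_ind=2, pf_slope=-0.5))
        for _, row in table.iterrows():
            state = AtmosphericState(row["temperature_c"], row["rh_pct"], row["pressure_kpa"])
            assert row["alpha_db_per_m"] == absorption_coefficient(row["peak_frequency_khz"], state)

    def test_missing_baseline_individual_skipped(self):
        s = make_summaries(n_ind=2)
        s = s[~((s["individual_id"] == "b0") & (s["treatment"] == "Ta"))]
        with pytest.warns(UserWarning, match="b0"):
            table = build_scenario_table(s)
        assert set(table["individual_id"]) == {"b1"}


class TestRhScenarios:
    def test_dry_scenario_attenuation_rise(self):
        grid = rh_scenarios(make_summaries(), temperatures_c=(19.0, 25.0))
        d = grid.deltas.set_index("rh_fix_pct")["delta_alpha_db_per_m"]
        assert d[50.0] >= 0.5
        assert d[75.0] <= 0.4
        assert d[75.0] == pytest.approx(0.25, abs=0.1)
        assert abs(d[100.0]) < 0.1

    def test_delta_ordering_across_humidity(self):
        # for the Myotis band, warming costs most attenuation in dry air
        for pf in (55.0, 70.0, 80.0):
            grid = rh_scenarios(make_summaries(n_ind=1, pf0=pf), temperatures_c=(19.0, 25.0))
            d = grid.deltas.set_index("rh_fix_pct")["delta_alpha_db_per_m"]
            assert d[50.0] > d[75.0] > d[100.0] >= -0.15

    def test_grid_matches_direct_absorption_calls(self):
        grid = rh_scenarios(make_summaries(n_ind=1), rh_levels=(75.0,), temperatures_c=(19.0, 25.0))
        for _, row in grid.grid.iterrows():
            direct = absorption_coefficient(
                row["peak_frequency_khz"],
                AtmosphericState(row["temperature_c"], row["rh_fix_pct"]),
            )
            assert row["alpha_db_per_m"] == direct


class TestPreySizeSensitivity:
    def test_wrapper_matches_scalar_detection_distances(self):
        s = make_summaries(n_ind=2)
        out = prey_size_sensitivity(s)
        h = HearingModel()
        for (_, srow), (_, orow) in zip(s.iterrows(), out.iterrows()):
            call = CallEmission(
                srow["peak_frequency_khz"], srow["asl_db"], srow["duration_ms"]
            )
            href = HearingModel(reference_duration_ms=call.duration_ms)
            state = AtmosphericState(srow["temperature_c"], srow["rh_pct"], srow["pressure_kpa"])
            dd_med = detection_distance(call, state, PreyTarget.from_label("medium"), href)
            assert orow["dd_medium_m"] == pytest.approx(dd_med.distance_m, abs=1e-9)
        assert (out["dd_large_m"] > out["dd_medium_m"]).all()
        assert (out["dd_medium_m"] > out["dd_small_m"]).all()


class TestRandomSlopeModels:
    def test_m1_recovers_duration_slope(self):
        preset = DEFAULT_PRESETS["M_pilosatibialis"].with_slopes(dur=0.05)
        df = simulate_call_table(preset, 30, seed=7)
        fit = fit_random_slope_m1(df, "duration_ms")
        assert fit.converged
        assert fit.param("temperature_c") == pytest.approx(0.05, abs=0.02)

    def test_m1_null_slope_ci_covers_zero(self):
        cover = 0
        reps = 40
        for rep in range(reps):
            df = simulate_call_table(DEFAULT_PRESETS["M_pilosatibialis"], 30, seed=2000 + rep)
            fit = fit_random_slope_m1(df, "duration_ms")
            est, se = fit.param("temperature_c"), float(fit.bse["temperature_c"])
            if abs(est) <= 1.96 * se:
                cover += 1
        assert cover / reps >= 0.85

    def test_too_few_individuals_rejected(self):
        df = simulate_call_table(DEFAULT_PRESETS["M_pilosatibialis"], 1, seed=0)
        with pytest.raises(ValueError):
            fit_random_slope_m1(df, "duration_ms")

    def test_m2_recovers_temperature_distance_interaction(self):
        preset = DEFAULT_PRESETS["M_pilosatibialis"]
        preset = dataclasses.replace(
            preset,
            peak_frequency_khz=dataclasses.replace(preset.peak_frequency_khz, txd_per_c_m=0.5),
        )
        df = simulate_call_table(preset, 30, seed=11)
        fit = fit_random_slope_m2(df, "peak_frequency_khz")
        est = fit.param("temperature_c:distance_m")
        assert est > 0
        assert abs(est - 0.5) < 0.25

    def test_m2_constant_distance_flagged_rank_deficient(self):
        df = simulate_call_table(DEFAULT_PRESETS["M_pilosatibialis"], 6, seed=1)
        df["distance_m"] = 2.0
        fit = fit_random_slope_m2(df, "peak_frequency_khz")
        assert fit.singular and not fit.converged
        assert len(fit.params) == 0


class TestModeInteraction:
    def test_identical_modes_give_null_interaction(self):
        table = build_scenario_table(make_summaries())  # no slopes: modes identical
        fit = fit_mode_interaction(table, "aa")
        assert abs(fit.param("C(mode)[T.flexible]:temperature_c")) < 1e-6

    def test_compensating_adjustment_detected(self):
        # flexible bats raise aSL by 1.5 dB/°C: DD slopes must diverge between
        # models, i.e. a positive Model x Temperature interaction on DD
        table = build_scenario_table(make_summaries(n_ind=10, asl_slope=1.5))
        fit = fit_mode_interaction(table, "dd")
        est = fit.param("C(mode)[T.flexible]:temperature_c")
        p = float(fit.pvalues["C(mode)[T.flexible]:temperature_c"])
        assert est > 0
        assert p < 0.05

    def test_missing_mode_dropped_with_warning(self):
        table = build_scenario_table(make_summaries(n_ind=3))
        table = table[~((table["individual_id"] == "b0") & (table["mode"] == "flexible"))]
        with pytest.warns(UserWarning, match="b0"):
            fit = fit_mode_interaction(table, "aa")
        assert fit.n_groups == 2

    def test_with_distance_three_way_form(self):
        s = make_summaries(n_ind=6, asl_slope=1.0)
        s["distance_m"] = np.random.default_rng(0).uniform(0.5, 4.0, len(s))
        table = build_scenario_table(s)
        fit = fit_mode_interaction(table, "dd", with_distance=True)
        assert "C(mode)[T.flexible]:temperature_c:distance_m" in fit.params.index
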