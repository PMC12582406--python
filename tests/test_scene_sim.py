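import numpy as np
import pytest

from echotherm import (
    ArrayGeometry,
    AtmosphericState,
    CallEmission,
    EmittedCallEvent,
    MicCalibration,
    Recording,
    generate_trajectory,
    generate_trial_set,
    render_array_recording,
    simulate_call_table,
    synthesize_call_waveform,
)
from echotherm.atmosphere import absorption_coefficient, speed_of_sound
from echotherm.call_extraction import (
    call_spectrum,
    measure_duration,
    measure_peak_frequency,
    smoothed_envelope,
)
from echotherm.scene_sim import DEFAULT_PRESETS, RenderClippingError

FS = 500_000
P_REF = 20e-6


class TestTrajectory:
    def test_speed_envelope_and_cage_bounds(self):
        for seed in range(5):
            traj = generate_trajectory(duration_s=5.0, seed=seed)
            speed = np.linalg.norm(traj.velocities, axis=1)
            assert speed.max() <= 6.0 and speed.min() >= 1.0
            x, y, z = traj.positions.T
            assert x.min() > 0 and x.max() < 6.0
            assert np.abs(y).max() < 1.25 and np.abs(z).max() < 1.25

    def test_deterministic_in_seed(self):
        t1 = generate_trajectory(seed=3)
        t2 = generate_trajectory(seed=3)
        assert np.array_equal(t1.positions, t2.positions)

    def test_contains_approach_leg_for_at_least_four_call_epochs(self):
        # approaching interval long enough for >= 4 calls ~95 ms apart
        traj = generate_trajectory(duration_s=5.0, seed=1)
        d = traj.radial_distance()
        dec = np.diff(d) < 0
        # longest run of decreasing-distance samples, in seconds
        runs, n = [], 0
        for v in dec:
            n = n + 1 if v else 0
            runs.append(n)
        longest_s = max(runs) / 200.0
        assert longest_s >= 4 * 0.095

    def test_degenerate_cage_rejected(self):
        with pytest.raises(ValueError):
            generate_trajectory(cage_dims=(6.0, 0.5, 2.5))


class TestCallWaveform:
    def test_rms_level_exact_by_construction(self):
        w = synthesize_call_waveform(CallEmission(70.0, 110.0, 1.5), FS)
        env = smoothed_envelope(w, FS)
        win = env >= env.max() * 10 ** (-12 / 20)
        rms = np.sqrt(np.mean(w[win] ** 2))
        assert 20 * np.log10(rms / P_REF) == pytest.approx(110.0, abs=0.1)

    @pytest.mark.parametrize("dur", [1.0, 1.5, 2.0])
    def test_minus12db_duration_matches_parameter(self, dur):
        w = synthesize_call_waveform(CallEmission(70.0, 110.0, dur), FS)
        assert measure_duration(w, FS) == pytest.approx(dur, rel=0.05)

    def test_sweep_ends_at_peak_frequency(self):
        w = synthesize_call_waveform(CallEmission(70.0, 110.0, 1.5), FS)
        pf = measure_peak_frequency(w, FS, band_khz=(25.0, 200.0))
        assert pf.frequency_khz == pytest.approx(70.0, abs=1.0)

    def test_dominant_harmonic_moves_spectral_peak_to_2f(self):
        w = synthesize_call_waveform(
            CallEmission(70.0, 110.0, 1.5), FS, harmonic_rel_db=6.0
        )
        pf = measure_peak_frequency(w, FS, band_khz=(25.0, 200.0))
        assert pf.frequency_khz == pytest.approx(140.0, abs=2.0)

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError):
            synthesize_call_waveform(CallEmission(120.0, 110.0, 1.5), sample_rate=250_000)


class TestRenderArrayRecording:
    GEOM = ArrayGeometry()
    CAL = MicCalibration.flat()
    STATE = AtmosphericState(20.0, 94.0)

    def _single_event_scene(self, pos, noise_db=None, seed=0, asl=112.0):
        ev = EmittedCallEvent(0.03, pos, CallEmission(70.0, asl, 1.5))
        rec = render_array_recording(
            [ev], self.GEOM, self.CAL, self.STATE, noise_db=noise_db, seed=seed,
            duration_s=0.08,
        )
        return ev, rec

    def test_equidistant_mics_have_zero_pair_delay(self):
        # default outer mic 1 sits at (0, 0, 0.6); the plane z = 0.3 is
        # equidistant from it and the central mic
        ev, rec = self._single_event_scene((2.0, 0.0, 0.3))
        x = rec.to_pa()
        c = np.correlate(x[:, 1], x[:, 0], "full")
        lag = np.argmax(c) - (len(x) - 1)
        assert abs(lag) <= 1  # sub-sample residual only

    def test_channel_level_matches_analytic_propagation(self):
        # narrowband tone burst: channel level = aSL - spreading - absorption
        state = self.STATE
        pos = (1.0, 0.0, 0.0)
        ev = EmittedCallEvent(
            0.03, pos, CallEmission(70.0, 112.0, 1.5)
        )
        rec = render_array_recording(
            [ev], self.GEOM, self.CAL, state, noise_db=None, duration_s=0.08,
            synth_kwargs=dict(sweep_octaves=0.0, harmonic_rel_db=None),
        )
        x = rec.to_pa()[:, 0]
        env = smoothed_envelope(x, FS)
        win = env >= env.max() * 10 ** (-12 / 20)
        level = 20 * np.log10(np.sqrt(np.mean(x[win] ** 2)) / P_REF)
        alpha = absorption_coefficient(70.0, state)
        expected = 112.0 - 20.0 - alpha * 0.9
        assert level == pytest.approx(expected, abs=0.3)

    def test_central_vs_outer_level_difference_is_analytic(self):
        # noiseless energy-conservation check between channels
        ev, rec = self._single_event_scene((1.5, 0.4, 0.3))
        x = rec.to_pa()
        pos = np.asarray(ev.position_m)
        mics = self.GEOM.mic_positions
        alpha = absorption_coefficient(70.0, self.STATE)
        for ch in (1, 2, 3):
            d0 = np.linalg.norm(pos - mics[0])
            di = np.linalg.norm(pos - mics[ch])
            lvl = []
            for sig in (x[:, 0], x[:, ch]):
                env = smoothed_envelope(sig, FS)
                win = env >= env.max() * 10 ** (-12 / 20)
                lvl.append(20 * np.log10(np.sqrt(np.mean(sig[win] ** 2)) / P_REF))
            expected = 20 * np.log10(di / d0) + alpha * (di - d0)
            assert lvl[0] - lvl[1] == pytest.approx(expected, abs=0.1)

    def test_propagation_delay_round_trips_speed_of_sound(self):
        # delay x speed of sound must reproduce the geometric distance to 0.1 %
        ev, rec = self._single_event_scene((2.5, 0.3, -0.4))
        x = rec.to_pa()[:, 0]
        template = synthesize_call_waveform(ev.call, FS)
        corr = np.correlate(x, template, "valid")
        lag = int(np.argmax(corr))
        t_travel = lag / FS - ev.time_s
        d = np.linalg.norm(ev.position_m)
        c = speed_of_sound(self.STATE)
        assert t_travel * c == pytest.approx(d, rel=1e-3)

    def test_noiseless_same_seed_bit_identical(self):
        _, r1 = self._single_event_scene((2.0, 0.5, 0.2), noise_db=-np.inf, seed=5)
        _, r2 = self._single_event_scene((2.0, 0.5, 0.2), noise_db=-np.inf, seed=5)
        assert np.array_equal(r1.data, r2.data)

    def test_clipping_names_offending_event(self):
        with pytest.raises(RenderClippingError, match="t=0.03"):
            self._single_event_scene((0.2, 0.0, 0.0), asl=130.0)

    def test_unsorted_events_rejected(self):
        evs = [
            EmittedCallEvent(0.05, (2.0, 0, 0), CallEmission(70, 110, 1.5)),
            EmittedCallEvent(0.02, (2.0, 0, 0), CallEmission(70, 110, 1.5)),
        ]
        with pytest.raises(ValueError):
            render_array_recording(evs, self.GEOM, self.CAL, self.STATE)

    def test_wav_round_trip(self, tmp_path):
        _, rec = self._single_event_scene((2.0, 0.0, 0.0), noise_db=40.0, seed=2)
        rec.write(tmp_path / "r.wav")
        back = Recording.read(tmp_path / "r.wav")
        assert back.sample_rate == FS
        assert back.full_scale_pa == rec.full_scale_pa
        assert np.array_equal(back.data, rec.data)


class TestGenerateTrialSet:
    def test_structure_and_ground_truth_conservation(self, tmp_path):
        man = generate_trial_set(
            DEFAULT_PRESETS["M_pilosatibialis"], 1, tmp_path, seed=9,
            files_per_trial=1, file_duration_s=1.0,
        )
        gt = man["ground_truth"]
        # three treatments in fixed order, each with >= 1 call
        assert set(gt["treatment"]) == {"Ta", "Ta+2", "Ta+4"}
        assert len(man["wav_files"]) == 3
        assert (tmp_path / "geometry.json").exists()
        assert (tmp_path / "calibration.json").exists()
        assert (tmp_path / "weather_log.csv").exists()
        # every emitted event has exactly one ground-truth row
        assert gt.groupby(["treatment", "file"]).size().sum() == len(gt)
        w = man["weather"]
        ta = w.set_index("treatment")["temperature_c"]
        assert ta["Ta+2"] - ta["Ta"] == pytest.approx(2.0)
        assert ta["Ta+4"] - ta["Ta"] == pytest.approx(4.0)
        assert w.set_index("treatment")["rh_pct"].to_dict() == {
            "Ta": 94.0, "Ta+2": 94.0, "Ta+4": 89.0,
        }

    def test_zero_individuals_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            generate_trial_set(DEFAULT_PRESETS["M_pilosatibialis"], 0, tmp_path)


class TestSimulateCallTable:
    def test_calls_per_treatment_distribution(self):
        df = simulate_call_table(DEFAULT_PRESETS["M_pilosatibialis"], 200, seed=0)
        counts = df.groupby(["individual_id", "treatment"]).size()
        assert counts.min() >= 1
        assert counts.mean() == pytest.approx(6.0, abs=0.5)
        assert counts.std() == pytest.approx(3.0, abs=0.5)

    def test_null_preset_means_recovered(self):
        preset = DEFAULT_PRESETS["M_pilosatibialis"]
        df = simulate_call_table(preset, 150, seed=1)
        assert df["peak_frequency_khz"].mean() == pytest.approx(preset.peak_frequency_khz.mean, abs=0.8)
        assert df["asl_db"].mean() == pytest.approx(preset.asl_db.mean, abs=0.8)
        assert df["duration_ms"].mean() == pytest.approx(preset.duration_ms.mean, abs=0.08)

    def test_injected_temperature_slope_visible(self):
        preset = DEFAULT_PRESETS["M_pilosatibialis"].with_slopes(dur=0.1)
        df = simulate_call_table(preset, 100, seed=2)
        by_t = df.groupby("treatment")["duration_ms"].mean()
        assert by_t["Ta+4"] - by_t["Ta"] == pytest.approx(0.4, abs=0.1)
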