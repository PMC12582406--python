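"""End-to-end processing of 4-channel recordings into a filtered call table.

Chains the stages: detect calls on the central channel, estimate TOADs and
localize each call, reconstruct the per-file trajectory and mark approach
runs, measure duration / peak frequency / aSL / SNR, flag second-harmonic
dominance, and apply the quality cascade. The result is the call table the
inferential layer consumes.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .arrays import ArrayGeometry, MicCalibration
from .atmosphere import AtmosphericState
from .call_extraction import (
    SessionFilterSpec,
    apply_quality_filters,
    back_propagate_level,
    call_spectrum,
    compute_snr,
    detect_calls,
    flag_second_harmonic,
    measure_duration,
    measure_peak_frequency,
    smoothed_envelope,
)
from .localization import build_trajectory, estimate_toads, localize, select_approaching_runs
from .scene_sim import Recording
from .atmosphere import speed_of_sound

__all__ = ["process_recording", "process_trial_set"]


def process_recording(
    recording: Recording,
    geometry: ArrayGeometry,
    calibration: MicCalibration,
    state: AtmosphericState,
    spec: SessionFilterSpec | None = None,
    metadata: dict | None = None,
    time_offset_s: float = 0.0,
) -> pd.DataFrame:
    """Measure every detected call in one recording (no trial-level filtering).

    Returns one row per call with the measurement columns plus localization
    diagnostics; ``approaching`` marks membership in approach runs of at
    least ``spec.min_consecutive`` calls. ``time_offset_s`` shifts the time
    axis so calls from consecutive files of one trial stay ordered.
    """
    spec = spec or SessionFilterSpec()
    meta = metadata or {}
    fs = recording.sample_rate
    x = recording.to_pa()
    band = (spec.band_low_khz, spec.band_high_khz)
    c = speed_of_sound(state)

    windows = detect_calls(x[:, 0], fs)
    fixes, rows = [], []
    for k, (a, b) in enumerate(windows):
        win = x[a:b, :]
        toads = estimate_toads(win, fs, band_khz=band, state=state)
        env = smoothed_envelope(win[:, 0], fs)
        peak_t = (a + int(np.argmax(env))) / fs
        fix = localize(toads, geometry, state, time_s=peak_t)
        # emission time: arrival at the central mic minus the travel time
        fix.time_s = peak_t - fix.distance_m / c + time_offset_s
        fixes.append((k, a, b, fix))

    if len(fixes) >= 2:
        traj = build_trajectory([f for *_, f in fixes])
        select_approaching_runs(traj, min_run=spec.min_consecutive)
    else:
        for *_, f in fixes:
            f.approaching = False

    for k, a, b, fix in fixes:
        cw = x[a:b, 0]
        try:
            dur = measure_duration(cw, fs)
        except ValueError:
            continue
        pf = measure_peak_frequency(cw, fs, band_khz=band)
        asl = back_propagate_level(
            cw, fix.distance_m, fix.incidence_angle_deg, state, calibration, fs,
            band_khz=band,
        )
        # SNR over the call's −12 dB segment against an equal-length noise
        # window ending 5 ms before the detection window
        env = smoothed_envelope(cw, fs)
        thr = env.max() * 10 ** (-12 / 20)
        onsets = np.flatnonzero(env >= thr)
        seg = cw[onsets[0] : onsets[-1] + 1]
        gap = int(0.005 * fs)
        n_start = a - gap - len(seg)
        if n_start >= 0:
            snr = compute_snr(seg, x[n_start : n_start + len(seg), 0])
        else:
            snr = np.nan
        freqs, db = call_spectrum(cw, fs)
        rows.append(
            dict(
                call_id=f"{meta.get('file', 'rec')}_{k:03d}",
                time_s=fix.time_s,
                duration_ms=dur,
                peak_frequency_khz=pf.frequency_khz,
                asl_db=asl.asl_db,
                snr_db=snr,
                second_harmonic_dominant=flag_second_harmonic(freqs, db),
                approaching=bool(fix.approaching),
                distance_m=fix.distance_m,
                incidence_angle_deg=fix.incidence_angle_deg,
                residual_m=fix.residual_m,
                quality=fix.quality,
                localization_flagged=fix.flagged,
                x_m=fix.position_m[0],
                y_m=fix.position_m[1],
                z_m=fix.position_m[2],
                treatment=meta.get("treatment", ""),
                individual_id=meta.get("individual_id", ""),
                species=meta.get("species", ""),
                temperature_c=state.temperature_c,
                rh_pct=state.relative_humidity_pct,
                pressure_kpa=state.pressure_kpa,
            )
        )
    return pd.DataFrame(rows)


def process_trial_set(
    run_dir: str | Path,
    spec: SessionFilterSpec | None = None,
    apply_filters: bool = True,
) -> tuple[pd.DataFrame, list[dict]]:
    """Process a ``generate_trial_set`` run directory into a call table.

    Reads geometry/calibration JSON, the weather log and every WAV; returns
    (call table, filter stage log). With ``apply_filters=False`` the raw
    measurements are returned and the log is empty.
    """
    run_dir = Path(run_dir)
    spec = spec or SessionFilterSpec()
    geometry = ArrayGeometry.from_json(run_dir / "geometry.json")
    calibration = MicCalibration.from_json(run_dir / "calibration.json")
    weather = pd.read_csv(run_dir / "weather_log.csv")

    tables = []
    for _, w in weather.iterrows():
        state = AtmosphericState(w["temperature_c"], w["rh_pct"], w["pressure_kpa"])
        wavs = sorted(run_dir.glob(f"{w['individual_id']}_{w['treatment']}_*.wav"))
        for fi, wav in enumerate(wavs):
            rec = Recording.read(wav)
            meta = dict(
                file=wav.name,
                individual_id=w["individual_id"],
                species=w["species"],
                treatment=w["treatment"],
            )
            tables.append(
                process_recording(
                    rec, geometry, calibration, state, spec, meta,
                    time_offset_s=fi * (rec.duration_s + 1.0),
                )
            )
    table = pd.concat([t for t in tables if len(t)], ignore_index=True) if tables else pd.DataFrame()
    if not apply_filters or table.empty:
        return table, []
    return apply_quality_filters(table, spec)
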