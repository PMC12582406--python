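import numpy as np
import pytest

from echotherm import (
    ArrayGeometry,
    AtmosphericState,
    CallEmission,
    EmittedCallEvent,
    MicCalibration,
    render_array_recording,
)


@pytest.fixture(scope="session")
def geometry():
    return ArrayGeometry()


@pytest.fixture(scope="session")
def flat_calibration():
    return MicCalibration.flat()


@pytest.fixture(scope="session")
def study_state():
    """Ambient-treatment weather: 20 °C, 94 % RH, sea-level pressure."""
    return AtmosphericState(20.0, 94.0)


def _scatter_positions(rng, n, r_min=0.5, r_max=4.0, max_off_axis_deg=45.0):
    """Random source positions in front of the array within the study ranges."""
    pos = []
    while len(pos) < n:
        r = rng.uniform(r_min, r_max)
        theta = np.deg2rad(rng.uniform(0.0, max_off_axis_deg))
        phi = rng.uniform(0, 2 * np.pi)
        p = np.array(
            [r * np.cos(theta), r * np.sin(theta) * np.cos(phi), r * np.sin(theta) * np.sin(phi)]
        )
        if abs(p[1]) < 1.2 and abs(p[2]) < 1.2:
            pos.append(p)
    return np.array(pos)


@pytest.fixture(scope="session")
def hundred_call_roundtrip(geometry, flat_calibration, study_state):
    """100 calls at 0.5-4 m rendered in four scenes, processed blind.

    Returns (truth row, measured row) pairs matched by emission time.
    """
    import pandas as pd

    from echotherm.pipeline import process_recording

    rng = np.random.default_rng(314)
    truth_rows, measured = [], []
    for scene in range(4):
        positions = _scatter_positions(rng, 25)
        events = []
        for i, p in enumerate(positions):
            call = CallEmission(
                float(rng.uniform(55, 80)),
                float(rng.uniform(110, 118)),
                float(rng.uniform(1.3, 2.0)),
            )
            events.append(EmittedCallEvent(0.05 + 0.1 * i, tuple(p), call))
        rec = render_array_recording(
            events, geometry, flat_calibration, study_state,
            noise_db=35.0, seed=1000 + scene,
        )
        table = process_recording(rec, geometry, flat_calibration, study_state)
        for ev in events:
            truth_rows.append(
                dict(
                    scene=scene,
                    time_s=ev.time_s,
                    x=ev.position_m[0], y=ev.position_m[1], z=ev.position_m[2],
                    pf=ev.call.peak_frequency_khz,
                    asl=ev.call.asl_db,
                    dur=ev.call.duration_ms,
                    dist=float(np.linalg.norm(ev.position_m)),
                )
            )
        table["scene"] = scene
        measured.append(table)
    truth = pd.DataFrame(truth_rows)
    meas = pd.concat(measured, ignore_index=True)
    matched = []
    for scene in range(4):
        t_sc = truth[truth["scene"] == scene]
        m_sc = meas[meas["scene"] == scene]
        for _, m in m_sc.iterrows():
            k = (t_sc["time_s"] - m["time_s"]).abs().idxmin()
            row = t_sc.loc[k]
            if abs(row["time_s"] - m["time_s"]) < 0.02:
                matched.append((row, m))
    return matched


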