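"""Render a synthetic flight-cage recording and localize the calls.

A simulated bat flies in the 6 x 2.5 x 2.5 m cage emitting FM calls; the
4-microphone star array records them at 500 kHz, and the TOAD stage
reconstructs where each call was emitted.
"""

import numpy as np

from echotherm import (
    ArrayGeometry,
    AtmosphericState,
    CallEmission,
    EmittedCallEvent,
    MicCalibration,
    generate_trajectory,
    render_array_recording,
)
from echotherm.localization import (
    build_trajectory,
    estimate_toads,
    localize,
    select_approaching_runs,
)
from echotherm.call_extraction import detect_calls

geometry = ArrayGeometry()
calibration = MicCalibration.flat()
state = AtmosphericState(21.0, 94.0)

traj = generate_trajectory(duration_s=3.0, seed=5)
times = np.arange(0.3, 2.8, 0.12)
events = [
    EmittedCallEvent(float(t), tuple(traj.position_at(t)), CallEmission(72.0, 113.0, 1.6))
    for t in times
]
rec = render_array_recording(events, geometry, calibration, state, noise_db=40.0, seed=1)
print(f"rendered {len(events)} calls into {rec.duration_s:.1f} s of 4-channel audio")

x = rec.to_pa()
fixes = []
for a, b in detect_calls(x[:, 0], rec.sample_rate):
    toads = estimate_toads(x[a:b, :], rec.sample_rate, state=state)
    fixes.append(localize(toads, geometry, state, time_s=a / rec.sample_rate))

traj_fixes = build_trajectory(fixes)
approaching = select_approaching_runs(traj_fixes, min_run=4)
errors = []
for ev in events:
    best = min(fixes, key=lambda f: abs(f.time_s - ev.time_s))
    errors.append(np.linalg.norm(best.position_m - np.asarray(ev.position_m)))
print(f"localized {len(fixes)} calls; median position error = "
      f"{np.median(errors) * 100:.2f} cm")
print(f"{len(approaching)} calls lie in approach runs (>= 4 consecutive calls "
      f"closing on the array) and would enter the analysis")
# Centimetre-scale errors from 2 us time-of-arrival differences are what make
# per-call source-level reconstruction possible.
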