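"""Call localization from time-of-arrival differences (TOADs).

The three peripheral-minus-central arrival-time differences of a call on the
star array, together with the speed of sound for the trial's weather, fix
the emitting bat's 3D position: each TOAD defines one sheet of a hyperboloid
of revolution, and the three sheets intersect in (generically) one point in
the cage half-space. TOADs come from generalized cross-correlation of
bandpassed channels with parabolic sub-sample peak interpolation (one sample
at 500 kHz is 2 µs ≈ 0.7 mm of path difference).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .arrays import ArrayGeometry, STAR_RADIUS_M
from .atmosphere import AtmosphericState, speed_of_sound

__all__ = [
    "ToadSet",
    "LocalizedCall",
    "estimate_toads",
    "localize",
    "build_trajectory",
    "select_approaching_runs",
]

_RESIDUAL_FLAG_M = 0.05
_DEFAULT_QUALITY_FLOOR = 0.15


@dataclass(frozen=True)
class ToadSet:
    """Arrival-time differences tau_i = t(outer_i) − t(central), seconds,
    with the normalized correlation peak height as a per-pair quality.

    ``cross_taus_s`` are the independently measured outer–outer differences
    t(outer_j) − t(outer_i) for pairs (1,2), (1,3), (2,3). They carry no new
    geometry in the noiseless limit, but their measurement errors are
    independent, which makes the localization overdetermined and its
    residual an honest misfit indicator.
    """

    taus_s: tuple[float, float, float]
    qualities: tuple[float, float, float]
    flagged: bool = False
    note: str = ""
    cross_taus_s: tuple[float, float, float] | None = None
    cross_qualities: tuple[float, float, float] | None = None


@dataclass
class LocalizedCall:
    """One localized call: position, range, geometry and solver diagnostics."""

    time_s: float
    position_m: np.ndarray
    distance_m: float
    incidence_angle_deg: float
    residual_m: float
    quality: float
    flagged: bool = False
    approaching: bool | None = None
    radial_velocity_mps: float | None = None


def _parabolic_refine(corr: np.ndarray, peak: int) -> float:
    """Sub-sample peak offset from a 3-point parabola; 0 at edges."""
    if peak <= 0 or peak >= len(corr) - 1:
        return 0.0
    y0, y1, y2 = corr[peak - 1], corr[peak], corr[peak + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return 0.0
    return float(np.clip(0.5 * (y0 - y2) / denom, -1.0, 1.0))


def estimate_toads(
    call_window: np.ndarray,
    sample_rate: int,
    band_khz: tuple[float, float] = (25.0, 120.0),
    state: AtmosphericState | None = None,
    quality_floor: float = _DEFAULT_QUALITY_FLOOR,
) -> ToadSet:
    """TOADs of one call from a (n, 4) window (column 0 = central mic).

    Channels are bandpass-filtered, each peripheral is cross-correlated
    against the central channel, and the correlation peak is refined by
    parabolic interpolation. Quality is the peak height normalized by the
    channel energies (1 for identical channels). TOADs beyond the geometric
    bound |tau| <= 0.6 m / c (+10 % slack), or qualities below the floor, flag
    the set rather than failing silently.
    """
    x = np.asarray(call_window, float)
    if x.ndim != 2 or x.shape[1] != 4:
        raise ValueError("call_window must be (n_samples, 4)")
    if band_khz[0] >= band_khz[1]:
        raise ValueError("band_khz must be (low, high) with low < high")
    nyq = sample_rate / 2.0
    hi = min(band_khz[1] * 1e3, 0.95 * nyq)
    sos = signal.butter(4, [band_khz[0] * 1e3, hi], btype="bandpass", fs=sample_rate, output="sos")
    xf = signal.sosfiltfilt(sos, x, axis=0)

    c = speed_of_sound(state or AtmosphericState())
    n = xf.shape[0]
    energies = [float(np.dot(xf[:, ch], xf[:, ch])) for ch in range(4)]
    flagged, notes = False, []

    def _pair_tau(ref: int, other: int, bound: float):
        nonlocal flagged
        corr = signal.correlate(xf[:, other], xf[:, ref], mode="full")
        peak = int(np.argmax(corr))
        lag = peak - (n - 1) + _parabolic_refine(corr, peak)
        tau = lag / sample_rate
        e0, ei = energies[ref], energies[other]
        q = float(corr[peak] / np.sqrt(e0 * ei)) if e0 > 0 and ei > 0 else 0.0
        if q < quality_floor:
            flagged = True
            notes.append(f"pair ({ref},{other}): correlation quality {q:.2f} below floor")
        if abs(tau) > bound:
            flagged = True
            notes.append(f"pair ({ref},{other}): tau {tau * 1e3:.2f} ms beyond geometric bound")
        return float(tau), q

    bound_c = STAR_RADIUS_M / c * 1.1
    central = [_pair_tau(0, ch, bound_c) for ch in (1, 2, 3)]
    # outer mics are up to sqrt(3)*0.6 m apart in the default star
    bound_x = np.sqrt(3.0) * STAR_RADIUS_M / c * 1.1
    cross = [_pair_tau(i, j, bound_x) for i, j in ((1, 2), (1, 3), (2, 3))]
    return ToadSet(
        tuple(t for t, _ in central),
        tuple(q for _, q in central),
        flagged,
        "; ".join(notes),
        tuple(t for t, _ in cross),
        tuple(q for _, q in cross),
    )


def localize(
    toads: ToadSet,
    geometry: ArrayGeometry,
    state: AtmosphericState,
    time_s: float = 0.0,
    max_iter: int = 100,
) -> LocalizedCall:
    """Solve ||p − m_i|| − ||p − m_0|| = c tau_i (i = 1..3) for the position.

    Damped Gauss–Newton from an initial guess 2 m in front of the array,
    constrained to the cage half-space (front/back mirror solutions are
    geometrically indistinguishable from TOADs alone). The rms range-difference
    residual is reported with every fix; divergence or residual > 5 cm flags
    the fix.
    """
    c = speed_of_sound(state)
    mics = geometry.mic_positions
    pairs: list[tuple[int, int, float]] = [
        (0, k + 1, c * toads.taus_s[k]) for k in range(3)
    ]
    if toads.cross_taus_s is not None:
        for (i, j), tau in zip(((1, 2), (1, 3), (2, 3)), toads.cross_taus_s):
            pairs.append((i, j, c * tau))
    axis = geometry.look_axis
    p = mics[0] + 2.0 * axis

    def residuals(p):
        d = [np.linalg.norm(p - m) for m in mics]
        return np.array([d[j] - d[i] - rng for i, j, rng in pairs])

    lam = 1e-3
    r = residuals(p)
    for _ in range(max_iter):
        d = [max(np.linalg.norm(p - m), 1e-9) for m in mics]
        units = [(p - m) / dk for m, dk in zip(mics, d)]
        J = np.array([units[j] - units[i] for i, j, _ in pairs])
        try:
            step = np.linalg.solve(J.T @ J + lam * np.eye(3), -J.T @ r)
        except np.linalg.LinAlgError:
            break
        p_new = p + step
        # keep the fix in front of the array plane and inside a sane volume
        depth = float(np.dot(p_new - mics[0], axis))
        if depth < 0.01:
            p_new = p_new + (0.01 - depth) * axis
        off = p_new - mics[0]
        rad = float(np.linalg.norm(off))
        if rad > 20.0:
            p_new = mics[0] + off * (20.0 / rad)
        r_new = residuals(p_new)
        if np.linalg.norm(r_new) < np.linalg.norm(r):
            p, r = p_new, r_new
            lam = max(lam / 3.0, 1e-9)
            if np.linalg.norm(step) < 1e-7:
                break
        else:
            lam *= 10.0
            if lam > 1e6:
                break

    residual = float(np.linalg.norm(r) / np.sqrt(len(pairs)))
    dist = float(np.linalg.norm(p - mics[0]))
    flagged = toads.flagged or residual > _RESIDUAL_FLAG_M or dist >= 19.99
    return LocalizedCall(
        time_s=time_s,
        position_m=p,
        distance_m=dist,
        incidence_angle_deg=geometry.incidence_angle_deg(p),
        residual_m=residual,
        quality=float(min(toads.qualities)),
        flagged=flagged,
    )


def build_trajectory(fixes: list[LocalizedCall]) -> list[LocalizedCall]:
    """Time-order the fixes and attach per-call radial velocity (m/s).

    Radial velocity is the finite-difference rate of change of the distance
    to the central microphone (central differences inside, one-sided at the
    ends); negative means the bat is closing on the array.
    """
    if len(fixes) < 2:
        raise ValueError("need at least two fixes to build a trajectory")
    fixes = sorted(fixes, key=lambda f: f.time_s)
    t = np.array([f.time_s for f in fixes])
    if np.any(np.diff(t) <= 0):
        raise ValueError("duplicate timestamps in fixes")
    d = np.array([f.distance_m for f in fixes])
    v = np.gradient(d, t)
    for f, vi in zip(fixes, v):
        f.radial_velocity_mps = float(vi)
    return fixes


def select_approaching_runs(
    trajectory: list[LocalizedCall], min_run: int = 4
) -> list[LocalizedCall]:
    """Keep maximal runs of >= ``min_run`` consecutive calls closing on the array.

    A run is a maximal chain of calls whose distance to the central
    microphone strictly decreases between consecutive calls (ties and exactly
    zero change break the run — not approaching). Every call in the input has
    its ``approaching`` flag set; the retained calls are returned in time
    order. Empty selections are legitimate (e.g. a strictly receding pass).
    """
    for f in trajectory:
        f.approaching = False
    if not trajectory:
        return []
    selected: list[LocalizedCall] = []
    run = [trajectory[0]]
    for prev, cur in zip(trajectory, trajectory[1:]):
        if cur.distance_m < prev.distance_m:
            run.append(cur)
        else:
            if len(run) >= min_run:
                selected.extend(run)
            run = [cur]
    if len(run) >= min_run:
        selected.extend(run)
    for f in selected:
        f.approaching = True
    return selected
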