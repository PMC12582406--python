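"""Sonar-equation model of prey echo level and detection distance.

A bat detects prey when the echo returning from it reaches the bat's
effective hearing threshold. The one-way level drops by spherical spreading
(40 log10 d/d0 two-way) and atmospheric absorption (2 alpha d two-way); the
prey reflects a fraction set by its target strength. Longer calls integrate
more energy, which is modelled as a threshold reduction of a fixed number of
dB per doubling of duration, saturating for calls longer than the ear's
integration time (~2 ms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .atmosphere import AtmosphericState, absorption_coefficient, speed_of_sound

__all__ = [
    "CallEmission",
    "PreyTarget",
    "HearingModel",
    "DetectionResult",
    "effective_threshold",
    "echo_level",
    "detection_distance",
    "overlap_zone_extension",
    "dd_sensitivity_to_target_strength",
    "REFERENCE_DISTANCE_M",
]

REFERENCE_DISTANCE_M = 0.1  # 10 cm reference for aSL and TS
_MAX_RANGE_M = 50.0
_LEVEL_TOL_DB = 0.01

# Fixed prey-size classes: sound-reflecting area (mm^2) -> target strength at 10 cm.
TARGET_STRENGTH_CLASSES = {
    "small": (-30.0, 10.0),
    "medium": (-20.0, 20.0),
    "large": (-10.0, 30.0),
}


@dataclass(frozen=True)
class CallEmission:
    """An emitted echolocation call: peak frequency (kHz), apparent source
    level (dB rms re 20 µPa at 10 cm) and duration (ms, −12 dB envelope)."""

    peak_frequency_khz: float
    asl_db: float
    duration_ms: float

    def __post_init__(self) -> None:
        if not 5.0 <= self.peak_frequency_khz <= 250.0:
            raise ValueError(f"peak_frequency_khz={self.peak_frequency_khz} outside [5, 250]")
        if not 60.0 <= self.asl_db <= 140.0:
            raise ValueError(f"asl_db={self.asl_db} outside [60, 140]")
        if not 0.2 <= self.duration_ms <= 20.0:
            raise ValueError(f"duration_ms={self.duration_ms} outside [0.2, 20]")


@dataclass(frozen=True)
class PreyTarget:
    """Prey size class with its target strength at the 10 cm reference."""

    label: str
    ts_db: float
    nominal_area_mm2: float

    @classmethod
    def from_label(cls, label: str) -> "PreyTarget":
        try:
            ts, area = TARGET_STRENGTH_CLASSES[label]
        except KeyError:
            raise ValueError(
                f"unknown prey class {label!r}; expected one of {sorted(TARGET_STRENGTH_CLASSES)}"
            ) from None
        return cls(label, ts, area)


@dataclass(frozen=True)
class HearingModel:
    """Hearing threshold and its duration dependence.

    ``threshold_db_spl`` is the detection threshold for a call at the
    reference duration; every doubling of duration below the integration cap
    lowers it by ``db_per_doubling`` dB. ``db_per_doubling = 0`` is the
    constant-threshold limit.
    """

    threshold_db_spl: float = 20.0
    reference_duration_ms: float | None = None
    db_per_doubling: float = 6.0
    integration_cap_ms: float = 2.0

    def __post_init__(self) -> None:
        if self.threshold_db_spl < 0:
            raise ValueError("threshold_db_spl must be >= 0")
        if self.db_per_doubling < 0:
            raise ValueError("db_per_doubling must be >= 0")
        if self.integration_cap_ms <= 0:
            raise ValueError("integration_cap_ms must be > 0")


def effective_threshold(hearing: HearingModel, duration_ms: float) -> float:
    """Duration-adjusted hearing threshold, dB SPL.

    threshold − db_per_doubling · log2(min(d, cap) / min(ref, cap)): the
    threshold drops 6 dB (by default) per doubling of call duration, but the
    benefit saturates beyond the integration cap (~2 ms). Equal to the base
    threshold at the reference duration.
    """
    if duration_ms <= 0:
        raise ValueError("duration_ms must be positive")
    if hearing.reference_duration_ms is None:
        raise ValueError("HearingModel.reference_duration_ms is not set")
    if hearing.reference_duration_ms <= 0:
        raise ValueError("reference_duration_ms must be positive")
    cap = hearing.integration_cap_ms
    gain = hearing.db_per_doubling * math.log2(
        min(duration_ms, cap) / min(hearing.reference_duration_ms, cap)
    )
    return hearing.threshold_db_spl - gain


def echo_level(
    distance_m: float,
    call: CallEmission,
    alpha_db_per_m: float,
    target: PreyTarget,
) -> float:
    """Echo level at the bat's ear from prey at ``distance_m``, dB SPL.

    EL = aSL − 40 log10(d / 0.1) − 2 α (d − 0.1) + TS. Spreading and
    absorption are two-way; the 10 cm reference leg carries no absorption so
    that EL(0.1) = aSL + TS exactly. Strictly decreasing in distance.
    """
    if distance_m < REFERENCE_DISTANCE_M:
        raise ValueError(f"distance_m={distance_m} below the 10 cm reference")
    if alpha_db_per_m < 0:
        raise ValueError("alpha_db_per_m must be >= 0")
    return (
        call.asl_db
        - 40.0 * math.log10(distance_m / REFERENCE_DISTANCE_M)
        - 2.0 * alpha_db_per_m * (distance_m - REFERENCE_DISTANCE_M)
        + target.ts_db
    )


@dataclass(frozen=True)
class DetectionResult:
    """Detection distance plus solver provenance.

    ``at_lower_bound``: echo below threshold even at 10 cm (DD pinned there);
    ``at_upper_bound``: echo still above threshold at 50 m (DD truncated).
    """

    distance_m: float
    alpha_db_per_m: float
    threshold_db_spl: float
    at_lower_bound: bool = False
    at_upper_bound: bool = False

    def __float__(self) -> float:
        return self.distance_m


def detection_distance(
    call: CallEmission,
    state: AtmosphericState,
    target: PreyTarget,
    hearing: HearingModel,
) -> DetectionResult:
    """Maximum distance at which the prey echo reaches the effective threshold.

    Absorption is evaluated at the call's peak frequency. The echo level is
    strictly decreasing in distance, so the unique root of
    EL(d) = threshold on [0.1, 50] m is found by bisection to within
    0.01 dB. Out-of-bracket cases are flagged, never silent.
    """
    alpha = absorption_coefficient(call.peak_frequency_khz, state)
    if hearing.reference_duration_ms is None:
        hearing = HearingModel(
            hearing.threshold_db_spl,
            call.duration_ms,
            hearing.db_per_doubling,
            hearing.integration_cap_ms,
        )
    thr = effective_threshold(hearing, call.duration_ms)

    lo, hi = REFERENCE_DISTANCE_M, _MAX_RANGE_M
    f_lo = echo_level(lo, call, alpha, target) - thr
    if f_lo < 0:
        return DetectionResult(lo, alpha, thr, at_lower_bound=True)
    f_hi = echo_level(hi, call, alpha, target) - thr
    if f_hi > 0:
        return DetectionResult(hi, alpha, thr, at_upper_bound=True)

    # Monotone decreasing => plain bisection is robust; iterate until the
    # level mismatch is inside tolerance and the bracket is sub-0.1 mm.
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f_mid = echo_level(mid, call, alpha, target) - thr
        if f_mid > 0:
            lo = mid
        else:
            hi = mid
        if abs(f_mid) < _LEVEL_TOL_DB and (hi - lo) < 1e-4:
            break
    return DetectionResult(0.5 * (lo + hi), alpha, thr)


def overlap_zone_extension(
    extra_duration_ms: float, state: AtmosphericState | None = None
) -> float:
    """Growth of the call–echo overlap zone for extra call duration, in cm.

    While the bat is still calling it cannot hear returning echoes; the
    blind zone extends one-way by c · Δt / 2. One extra millisecond at
    ~20 °C costs ≈17 cm of close range.
    """
    if extra_duration_ms < 0:
        raise ValueError("extra_duration_ms must be >= 0")
    if state is None:
        state = AtmosphericState(20.0, 94.0)
    c = speed_of_sound(state)
    return c * (extra_duration_ms * 1e-3) / 2.0 * 100.0


def dd_sensitivity_to_target_strength(
    base_call: CallEmission,
    state: AtmosphericState,
    hearing: HearingModel,
    ts_step_db: float = 10.0,
) -> tuple[float, float]:
    """DD change for a ±``ts_step_db`` shift of target strength around medium prey.

    Returns (DD(TS+step) − DD(TS), DD(TS) − DD(TS−step)) in metres, each from
    an independent detection_distance solve. A 10 dB step stands for a
    ±10 mm² change of prey area around the 20 mm² medium class.
    """
    medium = PreyTarget.from_label("medium")
    base = detection_distance(base_call, state, medium, hearing)
    up = detection_distance(
        base_call,
        state,
        PreyTarget("medium+", medium.ts_db + ts_step_db, medium.nominal_area_mm2),
        hearing,
    )
    down = detection_distance(
        base_call,
        state,
        PreyTarget("medium-", medium.ts_db - ts_step_db, medium.nominal_area_mm2),
        hearing,
    )
    if base.at_lower_bound or base.at_upper_bound:
        raise ValueError("baseline medium-prey DD is not finite inside the bracket")
    return up.distance_m - base.distance_m, base.distance_m - down.distance_m


def calibrate_asl_for_dd(
    target_dd_m: float,
    frequency_khz: float,
    state: AtmosphericState,
    target: PreyTarget,
    hearing: HearingModel,
    duration_ms: float = 1.5,
) -> CallEmission:
    """Closed-form aSL such that detection distance equals ``target_dd_m``.

    Inverts the sonar equation at the requested range; used to anchor
    scenario studies at a stated baseline (e.g. medium-prey DD of 1.5 m).
    """
    alpha = absorption_coefficient(frequency_khz, state)
    ref = hearing.reference_duration_ms or duration_ms
    thr = effective_threshold(
        HearingModel(
            hearing.threshold_db_spl, ref, hearing.db_per_doubling, hearing.integration_cap_ms
        ),
        duration_ms,
    )
    asl = (
        thr
        + 40.0 * math.log10(target_dd_m / REFERENCE_DISTANCE_M)
        + 2.0 * alpha * (target_dd_m - REFERENCE_DISTANCE_M)
        - target.ts_db
    )
    return CallEmission(frequency_khz, asl, duration_ms)
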