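"""Physics of ultrasound in humid air.

Pure-tone atmospheric absorption (ISO 9613-1: classical losses plus O2 and
N2 vibrational relaxation), saturation vapour pressure, and the speed of
sound in moist air. These drive everything downstream: time-of-arrival
localization needs the sound speed, and the sonar-equation detection range
needs the absorption coefficient at the call's peak frequency.

Conventions: temperature in degrees Celsius, relative humidity in percent,
static pressure in kilopascal, frequency in kilohertz, absorption in dB per
metre, speed in metres per second.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "AtmosphericState",
    "saturation_vapour_pressure",
    "water_molar_fraction",
    "absorption_coefficient",
    "speed_of_sound",
    "attenuation_grid",
    "REFERENCE_PRESSURE_KPA",
]

#: Reference atmospheric pressure (kPa) used to normalise relaxation frequencies.
REFERENCE_PRESSURE_KPA = 101.325

_T0_K = 293.15  # reference air temperature, K
_T01_K = 273.16  # triple point of water, K
_CELSIUS_OFFSET = 273.15

_TEMP_RANGE_C = (-20.0, 50.0)
_RH_RANGE_PCT = (0.0, 100.0)
_PRESSURE_RANGE_KPA = (10.0, 110.0)
_FREQ_RANGE_KHZ = (5.0, 250.0)


@dataclass(frozen=True)
class AtmosphericState:
    """Ambient air state: temperature (°C), relative humidity (%), pressure (kPa).

    Defaults give the study-site flavour of a humid tropical night at sea-level
    pressure: 19 °C, 94 % RH, 101.325 kPa.
    """

    temperature_c: float = 19.0
    relative_humidity_pct: float = 94.0
    pressure_kpa: float = REFERENCE_PRESSURE_KPA

    def __post_init__(self) -> None:
        t, rh, p = self.temperature_c, self.relative_humidity_pct, self.pressure_kpa
        if not _TEMP_RANGE_C[0] <= t <= _TEMP_RANGE_C[1]:
            raise ValueError(f"temperature_c={t} outside {_TEMP_RANGE_C}")
        if not _RH_RANGE_PCT[0] <= rh <= _RH_RANGE_PCT[1]:
            raise ValueError(f"relative_humidity_pct={rh} outside {_RH_RANGE_PCT}")
        if not _PRESSURE_RANGE_KPA[0] <= p <= _PRESSURE_RANGE_KPA[1]:
            raise ValueError(f"pressure_kpa={p} outside {_PRESSURE_RANGE_KPA}")

    def warmed(self, delta_c: float) -> "AtmosphericState":
        """Same air with the temperature raised by ``delta_c`` degrees."""
        return AtmosphericState(
            self.temperature_c + delta_c, self.relative_humidity_pct, self.pressure_kpa
        )

    def with_humidity(self, rh_pct: float) -> "AtmosphericState":
        return AtmosphericState(self.temperature_c, rh_pct, self.pressure_kpa)


def saturation_vapour_pressure(
    temperature_c: float, method: Literal["iso", "magnus"] = "iso"
) -> float:
    """Saturation vapour pressure of water over a plane surface, in kPa.

    ``iso`` uses the companion expression of the ISO 9613-1 absorption model;
    ``magnus`` the August–Roche–Magnus fit. They agree to <1 % over the
    supported range.
    """
    t = float(temperature_c)
    if not _TEMP_RANGE_C[0] <= t <= _TEMP_RANGE_C[1]:
        raise ValueError(f"temperature_c={t} outside {_TEMP_RANGE_C}")
    if method == "iso":
        T = t + _CELSIUS_OFFSET
        return REFERENCE_PRESSURE_KPA * 10.0 ** (
            -6.8346 * (_T01_K / T) ** 1.261 + 4.6151
        )
    if method == "magnus":
        return 0.61094 * float(np.exp(17.625 * t / (t + 243.04)))
    raise ValueError(f"unknown method {method!r}")


def water_molar_fraction(state: AtmosphericState) -> float:
    """Molar concentration of water vapour, in percent.

    h = RH% * p_sat(T) / p ; linear in RH, zero for dry air.
    """
    return (
        state.relative_humidity_pct
        * saturation_vapour_pressure(state.temperature_c)
        / state.pressure_kpa
    )


def absorption_coefficient(frequency_khz, state: AtmosphericState):
    """Pure-tone atmospheric absorption coefficient, dB per metre.

    ISO 9613-1 model: classical (viscous/thermal) absorption plus the
    vibrational relaxation of O2 and N2, whose relaxation frequencies depend
    on humidity and pressure. Accepts scalar or array frequency.

    At the study conditions this gives e.g. ~3.0 dB/m at 78 kHz, 19 °C,
    94 % RH and ~2.1 dB/m at 60 kHz, 20 °C, 94 % RH.
    """
    f_khz = np.asarray(frequency_khz, dtype=float)
    if np.any(f_khz < _FREQ_RANGE_KHZ[0]) or np.any(f_khz > _FREQ_RANGE_KHZ[1]):
        raise ValueError(
            f"frequency_khz outside supported band {_FREQ_RANGE_KHZ}: {frequency_khz}"
        )
    f = f_khz * 1e3  # Hz
    T = state.temperature_c + _CELSIUS_OFFSET
    p = state.pressure_kpa
    pr = REFERENCE_PRESSURE_KPA
    h = water_molar_fraction(state)  # percent

    tr = T / _T0_K
    fr_o = (p / pr) * (24.0 + 4.04e4 * h * (0.02 + h) / (0.391 + h))
    fr_n = (p / pr) / np.sqrt(tr) * (
        9.0 + 280.0 * h * np.exp(-4.170 * (tr ** (-1.0 / 3.0) - 1.0))
    )

    classical = 1.84e-11 * (pr / p) * np.sqrt(tr)
    oxygen = 0.01275 * np.exp(-2239.1 / T) / (fr_o + f**2 / fr_o)
    nitrogen = 0.1068 * np.exp(-3352.0 / T) / (fr_n + f**2 / fr_n)
    alpha = 8.686 * f**2 * (classical + tr ** (-2.5) * (oxygen + nitrogen))
    return alpha if alpha.ndim else float(alpha)


def classical_absorption(frequency_khz, state: AtmosphericState):
    """Classical (viscous + thermal conduction) part of the absorption, dB/m.

    Lower bound on the full coefficient; the relaxation terms only add loss.
    """
    f = np.asarray(frequency_khz, dtype=float) * 1e3
    T = state.temperature_c + _CELSIUS_OFFSET
    alpha = (
        8.686
        * f**2
        * 1.84e-11
        * (REFERENCE_PRESSURE_KPA / state.pressure_kpa)
        * np.sqrt(T / _T0_K)
    )
    return alpha if alpha.ndim else float(alpha)


# Ideal-gas constants for the moist-air sound-speed mixture model.
_R_GAS = 8.314462618  # J mol-1 K-1
_M_DRY = 0.0289645  # kg mol-1
_M_WATER = 0.0180153  # kg mol-1
_CP_DRY_R = 3.5  # Cp/R, diatomic air
_CP_WATER_R = 4.0  # Cp/R, water vapour (~33.3 J mol-1 K-1)


def speed_of_sound(state: AtmosphericState) -> float:
    """Speed of sound in moist air, m/s.

    Ideal-gas binary mixture of dry air and water vapour:
    c = sqrt(gamma_mix * R * T / M_mix) with mole-fraction-weighted molar
    mass and heat capacity. Dry air at 20 °C gives 343.2 m/s; saturation
    humidity adds ~1 m/s (lighter molecules, slightly lower gamma), matching
    the Cramer (1993) empirical formula to ~0.1 m/s in-range.
    """
    T = state.temperature_c + _CELSIUS_OFFSET
    xw = water_molar_fraction(state) / 100.0  # mole fraction
    m_mix = (1.0 - xw) * _M_DRY + xw * _M_WATER
    cp_r = (1.0 - xw) * _CP_DRY_R + xw * _CP_WATER_R
    gamma = cp_r / (cp_r - 1.0)
    return float(np.sqrt(gamma * _R_GAS * T / m_mix))


def attenuation_grid(
    frequencies_khz: Iterable[float],
    temperatures_c: Iterable[float],
    humidities_pct: Iterable[float],
    pressure_kpa: float = REFERENCE_PRESSURE_KPA,
) -> pd.DataFrame:
    """Absorption coefficient over the Cartesian product of the three axes.

    Returns a DataFrame with columns frequency_khz, temperature_c, rh_pct,
    pressure_kpa, alpha_db_per_m — one row per combination, each cell equal
    to the scalar ``absorption_coefficient`` call. Used for the fixed-RH
    climate scenarios (RH pinned at 50/75/100 %).
    """
    freqs = list(frequencies_khz)
    temps = list(temperatures_c)
    hums = list(humidities_pct)
    if not freqs or not temps or not hums:
        raise ValueError("attenuation_grid: every axis must be non-empty")
    rows = []
    for t in temps:
        for rh in hums:
            try:
                state = AtmosphericState(t, rh, pressure_kpa)
                alphas = absorption_coefficient(np.array(freqs), state)
            except ValueError as exc:
                raise ValueError(
                    f"attenuation_grid failed at T={t}°C, RH={rh}%: {exc}"
                ) from exc
            for f, a in zip(freqs, np.atleast_1d(alphas)):
                rows.append((f, t, rh, pressure_kpa, float(a)))
    return pd.DataFrame(
        rows,
        columns=[
            "frequency_khz",
            "temperature_c",
            "rh_pct",
            "pressure_kpa",
            "alpha_db_per_m",
        ],
    )
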