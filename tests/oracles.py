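"""Independent reference implementations used only to check the package.

These are deliberately written as standalone transcriptions (different
variable arrangement, different sources where possible) so they can serve as
oracles for the production code paths.
"""

from __future__ import annotations

import numpy as np


def antoine_psat_kpa(t_c: float) -> float:
    """Saturation vapour pressure from the Antoine equation (water, 1-100 °C
    fit, acceptable down to ~0 °C). Independent of the production formula."""
    p_mmhg = 10.0 ** (8.07131 - 1730.63 / (233.426 + t_c))
    return p_mmhg * 0.133322


def iso9613_alpha_reference(f_hz: float, t_c: float, rh_pct: float, p_kpa: float) -> float:
    """Second, independent transcription of the pure-tone absorption model
    (classical + O2 + N2 relaxation), written from the published equations
    in a different arrangement than the package implementation."""
    T = 273.15 + t_c
    To = 293.15
    To1 = 273.16
    ps0 = 101.325
    # molar concentration of water vapour (%)
    C = -6.8346 * (To1 / T) ** 1.261 + 4.6151
    h = rh_pct * (10.0**C) * (ps0 / p_kpa)
    f2 = f_hz * f_hz
    pr = p_kpa / ps0
    frO = pr * (24.0 + 40400.0 * h * ((0.02 + h) / (0.391 + h)))
    frN = pr * (T / To) ** (-0.5) * (9.0 + 280.0 * h * np.exp(-4.17 * ((T / To) ** (-1.0 / 3.0) - 1.0)))
    term_cl = 1.84e-11 / pr * np.sqrt(T / To)
    term_O = 0.01275 * np.exp(-2239.1 / T) * (frO / (frO**2 + f2))
    term_N = 0.1068 * np.exp(-3352.0 / T) * (frN / (frN**2 + f2))
    npnp = f2 * (term_cl + (T / To) ** (-2.5) * (term_O + term_N))
    return float(8.686 * npnp)


def cramer_speed_of_sound(t_c: float, rh_pct: float, p_kpa: float = 101.325) -> float:
    """Cramer (1993) empirical sound-speed formula (zero-CO2 form), using the
    Antoine vapour pressure for the water mole fraction."""
    xw = rh_pct / 100.0 * antoine_psat_kpa(t_c) / p_kpa
    t = t_c
    return (
        331.5024
        + 0.603055 * t
        - 0.000528 * t**2
        + (51.471935 + 0.1495874 * t - 0.000782 * t**2) * xw
    )


def grid_scan_detection_distance(
    asl_db: float,
    alpha_db_per_m: float,
    ts_db: float,
    threshold_db: float,
    step_m: float = 0.0005,
    max_m: float = 50.0,
) -> float:
    """Brute-force detection distance: finest grid point where the two-way
    sonar-equation echo level still reaches the threshold."""
    d = np.arange(0.1, max_m, step_m)
    el = asl_db - 40.0 * np.log10(d / 0.1) - 2.0 * alpha_db_per_m * (d - 0.1) + ts_db
    above = el >= threshold_db
    if not above[0]:
        return 0.1
    idx = np.flatnonzero(~above)
    return float(d[idx[0] - 1]) if len(idx) else float(d[-1])
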