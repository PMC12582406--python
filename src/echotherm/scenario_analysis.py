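"""Inferential layer: per-individual summaries, counterfactual call models,
fixed-humidity scenarios, prey-size sensitivity, and random-slope mixed models.

The central contrast is constant-call vs flexible-call: the constant-call
model propagates each individual's ambient-temperature (Ta) call parameters
unchanged into the warmer trials (a bat that does not adjust), while the
flexible-call model uses the parameters actually measured per trial. Both
are pushed through the absorption and sonar-equation stages to per-row
atmospheric attenuation (AA, dB/m) and prey detection distance (DD, m),
which mixed models then relate to temperature, call model and distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .atmosphere import AtmosphericState, absorption_coefficient
from .sonar import CallEmission, HearingModel, PreyTarget, detection_distance

__all__ = [
    "LmmFit",
    "RhScenarioGrid",
    "summarize_individuals",
    "build_scenario_table",
    "rh_scenarios",
    "prey_size_sensitivity",
    "fit_random_slope_m1",
    "fit_random_slope_m2",
    "fit_mode_interaction",
]

_PARAM_COLS = ["peak_frequency_khz", "asl_db", "duration_ms"]


def summarize_individuals(call_table: pd.DataFrame) -> pd.DataFrame:
    """Per-individual mean call parameters at each experimental temperature.

    One row per (individual, treatment) with arithmetic means of the filtered
    calls' peak frequency, aSL and duration, plus the trial weather and mean
    distance to the microphone. Individuals missing a treatment have that row
    omitted with a warning.
    """
    required = {"individual_id", "treatment", *_PARAM_COLS}
    missing = required - set(call_table.columns)
    if missing:
        raise ValueError(f"call table lacks columns {sorted(missing)}")
    agg: dict = {c: (c, "mean") for c in _PARAM_COLS}
    for extra in ("temperature_c", "rh_pct", "pressure_kpa", "distance_m"):
        if extra in call_table.columns:
            agg[extra] = (extra, "mean")
    if "species" in call_table.columns:
        agg["species"] = ("species", "first")
    out = (
        call_table.groupby(["individual_id", "treatment"], sort=False)
        .agg(**agg)
        .reset_index()
    )
    out.insert(len(out.columns), "n_calls",
               call_table.groupby(["individual_id", "treatment"], sort=False)
               .size().to_numpy())
    n_treat = call_table["treatment"].nunique()
    short = out.groupby("individual_id")["treatment"].nunique()
    for ind in short[short < n_treat].index:
        warnings.warn(f"individual {ind} is missing one or more treatments; rows omitted")
    return out


def _state_from_row(row: pd.Series) -> AtmosphericState:
    return AtmosphericState(
        float(row["temperature_c"]),
        float(row.get("rh_pct", 94.0)),
        float(row.get("pressure_kpa", 101.325)) if not pd.isna(row.get("pressure_kpa", np.nan)) else 101.325,
    )


def build_scenario_table(
    summaries: pd.DataFrame,
    mode: str = "both",
    prey: PreyTarget | str = "medium",
    hearing: HearingModel | None = None,
    baseline_treatment: str = "Ta",
) -> pd.DataFrame:
    """Per-row AA and DD under the constant-call and/or flexible-call models.

    Constant mode: call parameters frozen at the individual's
    ``baseline_treatment`` means, combined with each trial's actual weather.
    Flexible mode: each trial's own means. The duration-dependent hearing
    threshold uses the individual's baseline duration as reference in both
    modes, so at Ta the two modes are row-identical by construction.
    Individuals without a baseline row are dropped with a warning. Stored
    inputs (parameters + weather) make every alpha and DD recomputable.
    """
    if isinstance(prey, str):
        prey = PreyTarget.from_label(prey)
    hearing = hearing or HearingModel()
    modes = ("constant", "flexible") if mode == "both" else (mode,)
    if any(m not in ("constant", "flexible") for m in modes):
        raise ValueError("mode must be 'constant', 'flexible' or 'both'")

    rows = []
    for ind, g in summaries.groupby("individual_id", sort=False):
        base = g[g["treatment"] == baseline_treatment]
        if base.empty:
            warnings.warn(f"individual {ind} has no {baseline_treatment} trial; skipped")
            continue
        base = base.iloc[0]
        ref_dur = float(base["duration_ms"])
        href = HearingModel(
            hearing.threshold_db_spl, ref_dur, hearing.db_per_doubling, hearing.integration_cap_ms
        )
        for _, trial in g.iterrows():
            state = _state_from_row(trial)
            for m in modes:
                src = base if m == "constant" else trial
                call = CallEmission(
                    float(src["peak_frequency_khz"]),
                    float(src["asl_db"]),
                    float(src["duration_ms"]),
                )
                alpha = absorption_coefficient(call.peak_frequency_khz, state)
                dd = detection_distance(call, state, prey, href)
                rows.append(
                    dict(
                        individual_id=ind,
                        species=trial.get("species", ""),
                        treatment=trial["treatment"],
                        mode=m,
                        temperature_c=state.temperature_c,
                        rh_pct=state.relative_humidity_pct,
                        pressure_kpa=state.pressure_kpa,
                        peak_frequency_khz=call.peak_frequency_khz,
                        asl_db=call.asl_db,
                        duration_ms=call.duration_ms,
                        reference_duration_ms=ref_dur,
                        distance_m=float(trial["distance_m"]) if "distance_m" in trial else np.nan,
                        prey=prey.label,
                        alpha_db_per_m=float(alpha),
                        dd_m=dd.distance_m,
                        dd_flagged=dd.at_lower_bound or dd.at_upper_bound,
                    )
                )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RhScenarioGrid:
    """Fixed-RH counterfactual surfaces and their temperature spans.

    ``grid``: per (individual, RHfix, temperature) alpha and DD using the
    constant-call (Ta) parameters. ``deltas``: per (species, RHfix) the mean
    change of alpha and DD across the temperature span.
    """

    grid: pd.DataFrame
    deltas: pd.DataFrame
    rh_levels: tuple[float, ...]
    temperatures_c: tuple[float, ...]


def rh_scenarios(
    summaries: pd.DataFrame,
    rh_levels: tuple[float, ...] = (50.0, 75.0, 100.0),
    temperatures_c: tuple[float, ...] = (19.0, 21.0, 23.0, 25.0),
    prey: PreyTarget | str = "medium",
    hearing: HearingModel | None = None,
    baseline_treatment: str = "Ta",
) -> RhScenarioGrid:
    """AA and DD over a (RHfix x temperature) grid at constant-call parameters.

    Humidity cannot be manipulated in an open-air cage, so drier climates are
    explored counterfactually: RH pinned at 50/75/100 % while temperature
    sweeps the ambient span of the experiments (19–25 °C by default). Per
    species, ``deltas`` reports the mean AA and DD change from the coolest to
    the warmest temperature at each RH level.
    """
    if isinstance(prey, str):
        prey = PreyTarget.from_label(prey)
    hearing = hearing or HearingModel()
    base = summaries[summaries["treatment"] == baseline_treatment]
    if base.empty:
        raise ValueError(f"summaries contain no {baseline_treatment} rows")
    rows = []
    for _, b in base.iterrows():
        call = CallEmission(
            float(b["peak_frequency_khz"]), float(b["asl_db"]), float(b["duration_ms"])
        )
        href = HearingModel(
            hearing.threshold_db_spl, call.duration_ms,
            hearing.db_per_doubling, hearing.integration_cap_ms,
        )
        for rh in rh_levels:
            for t in temperatures_c:
                state = AtmosphericState(t, rh, float(b.get("pressure_kpa", 101.325)) if not pd.isna(b.get("pressure_kpa", np.nan)) else 101.325)
                alpha = absorption_coefficient(call.peak_frequency_khz, state)
                dd = detection_distance(call, state, prey, href)
                rows.append(
                    dict(
                        individual_id=b["individual_id"],
                        species=b.get("species", ""),
                        rh_fix_pct=rh,
                        temperature_c=t,
                        peak_frequency_khz=call.peak_frequency_khz,
                        alpha_db_per_m=float(alpha),
                        dd_m=dd.distance_m,
                        dd_flagged=dd.at_lower_bound or dd.at_upper_bound,
                    )
                )
    grid = pd.DataFrame(rows)
    t_lo, t_hi = min(temperatures_c), max(temperatures_c)
    lo = grid[grid["temperature_c"] == t_lo].set_index(["individual_id", "rh_fix_pct"])
    hi = grid[grid["temperature_c"] == t_hi].set_index(["individual_id", "rh_fix_pct"])
    d = pd.DataFrame(
        {
            "species": lo["species"],
            "delta_alpha_db_per_m": hi["alpha_db_per_m"] - lo["alpha_db_per_m"],
            "delta_dd_m": hi["dd_m"] - lo["dd_m"],
        }
    ).reset_index()
    deltas = (
        d.groupby(["species", "rh_fix_pct"], sort=True)[["delta_alpha_db_per_m", "delta_dd_m"]]
        .mean()
        .reset_index()
    )
    return RhScenarioGrid(grid, deltas, tuple(rh_levels), tuple(temperatures_c))


def prey_size_sensitivity(
    summaries: pd.DataFrame,
    hearing: HearingModel | None = None,
) -> pd.DataFrame:
    """DD per prey-size class for every summary row, plus pairwise shifts.

    Each 10 dB target-strength step (one size class, ±10 mm² of nominal prey
    area) is solved independently; ``dd_medium_minus_small`` and
    ``dd_large_minus_medium`` are the table-level counterparts of the scalar
    sensitivity operation.
    """
    hearing = hearing or HearingModel()
    rows = []
    for _, r in summaries.iterrows():
        call = CallEmission(
            float(r["peak_frequency_khz"]), float(r["asl_db"]), float(r["duration_ms"])
        )
        href = HearingModel(
            hearing.threshold_db_spl,
            hearing.reference_duration_ms or call.duration_ms,
            hearing.db_per_doubling,
            hearing.integration_cap_ms,
        )
        state = _state_from_row(r)
        dds = {
            label: detection_distance(call, state, PreyTarget.from_label(label), href)
            for label in ("small", "medium", "large")
        }
        rows.append(
            dict(
                individual_id=r["individual_id"],
                species=r.get("species", ""),
                treatment=r.get("treatment", ""),
                dd_small_m=dds["small"].distance_m,
                dd_medium_m=dds["medium"].distance_m,
                dd_large_m=dds["large"].distance_m,
                dd_medium_minus_small_m=dds["medium"].distance_m - dds["small"].distance_m,
                dd_large_minus_medium_m=dds["large"].distance_m - dds["medium"].distance_m,
                any_flagged=any(d.at_lower_bound or d.at_upper_bound for d in dds.values()),
            )
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class LmmFit:
    """A fitted mixed model: fixed effects with Wald inference, random-effect
    variances, and convergence/singularity diagnostics."""

    formula: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    random_effect_var: pd.Series
    converged: bool
    singular: bool
    n_obs: int
    n_groups: int
    note: str = ""

    def param(self, name: str) -> float:
        return float(self.params[name])

    def summary_dict(self) -> dict:
        return {
            "formula": self.formula,
            "converged": self.converged,
            "singular": self.singular,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "fixed_effects": {
                k: {"estimate": float(self.params[k]), "se": float(self.bse[k]),
                    "p": float(self.pvalues[k])}
                for k in self.params.index
            },
            "random_effect_var": {k: float(v) for k, v in self.random_effect_var.items()},
        }


def _fit_mixedlm(
    data: pd.DataFrame, formula: str, groups: str, re_formula: str | None
) -> LmmFit:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = smf.mixedlm(formula, data, groups=data[groups], re_formula=re_formula)
        try:
            result = model.fit(reml=True, method=["lbfgs", "powell"])
        except np.linalg.LinAlgError:
            empty = pd.Series(dtype=float)
            return LmmFit(formula, empty, empty, empty, empty, False, True,
                          len(data), data[groups].nunique(),
                          note="singular system during estimation")
    fe = result.fe_params
    cov_re = np.asarray(result.cov_re)
    singular = bool(np.any(np.diag(cov_re) < 1e-8 * max(np.diag(cov_re).max(), 1e-12)))
    re_var = pd.Series(np.diag(cov_re), index=result.cov_re.index if hasattr(result.cov_re, "index") else None)
    return LmmFit(
        formula=formula,
        params=fe,
        bse=result.bse_fe.loc[fe.index],
        pvalues=result.pvalues.loc[fe.index],
        random_effect_var=re_var,
        converged=bool(result.converged),
        singular=singular,
        n_obs=int(result.nobs),
        n_groups=data[groups].nunique(),
    )


def _check_design(data: pd.DataFrame, min_individuals: int = 5) -> None:
    n_ind = data["individual_id"].nunique()
    if n_ind < min_individuals:
        raise ValueError(f"need >= {min_individuals} individuals, got {n_ind}")
    per = data.groupby("individual_id")["temperature_c"].nunique()
    if (per < 2).any():
        raise ValueError("every individual needs >= 2 distinct temperatures")


def fit_random_slope_m1(data: pd.DataFrame, response: str) -> LmmFit:
    """Random-slope model with temperature as the sole fixed effect.

    response ~ temperature, with a per-individual random intercept and random
    temperature slope; REML estimation, Wald z p-values. Temperature enters
    in °C, uncentered.
    """
    _check_design(data)
    return _fit_mixedlm(
        data, f"{response} ~ temperature_c", "individual_id", "~temperature_c"
    )


def fit_random_slope_m2(data: pd.DataFrame, response: str) -> LmmFit:
    """Random-slope model adding distance and its interaction with temperature.

    response ~ temperature * distance-to-microphone, random structure as in
    the temperature-only model. A constant distance column makes the design
    rank-deficient: the fit is returned flagged (singular, not converged)
    rather than fabricating estimates.
    """
    _check_design(data)
    if "distance_m" not in data.columns:
        raise ValueError("distance_m column required")
    formula = f"{response} ~ temperature_c * distance_m"
    X = np.column_stack(
        [
            np.ones(len(data)),
            data["temperature_c"],
            data["distance_m"],
            data["temperature_c"] * data["distance_m"],
        ]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        empty = pd.Series(dtype=float)
        return LmmFit(formula, empty, empty, empty, empty, False, True,
                      len(data), data["individual_id"].nunique(),
                      note="rank-deficient fixed-effects design (constant distance?)")
    return _fit_mixedlm(data, formula, "individual_id", "~temperature_c")


def fit_mode_interaction(
    scenario_table: pd.DataFrame,
    response: str = "aa",
    with_distance: bool = False,
    random_slopes: bool = False,
) -> LmmFit:
    """Constant-call vs flexible-call comparison of AA or DD.

    Fixed effects: call model (constant/flexible), temperature and their
    interaction — plus the distance terms when ``with_distance`` — with
    individuals as random effects (random intercepts by default; random
    temperature slopes optionally). A significant Model x Temperature term
    means the two call models diverge as it warms, i.e. the bats' measured
    adjustments altered AA/DD relative to the no-adjustment counterfactual.
    """
    col = {"aa": "alpha_db_per_m", "dd": "dd_m"}.get(response, response)
    if col not in scenario_table.columns:
        raise ValueError(f"response column {col!r} not in scenario table")
    df = scenario_table.copy()
    both = df.groupby("individual_id")["mode"].nunique()
    incomplete = both[both < 2].index
    if len(incomplete):
        warnings.warn(
            f"dropping individuals missing a call model: {list(incomplete)}"
        )
        df = df[~df["individual_id"].isin(incomplete)]
    if df.empty:
        raise ValueError("no individuals with both call models present")
    formula = f"{col} ~ C(mode) * temperature_c"
    if with_distance:
        formula += " * distance_m"
    return _fit_mixedlm(
        df, formula, "individual_id", "~temperature_c" if random_slopes else None
    )
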