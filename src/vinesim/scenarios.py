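"""Advanced-veraison virtual experiments.

Shifts the simulation window earlier by a fixed number of days while
keeping its duration and every other initial setting unchanged, then
compares growing degree days, final berry fresh/dry weight and sugar
concentration, and the maturity date (the day the scenario reaches the
default run's maximum sugar concentration) against the default scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .environment import gdd
from .plant import PlantParams, SeasonInputs, SeasonTrajectory, simulate_season

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "shift_inputs",
    "maturity_doy",
    "relative_change",
    "run_scenarios",
]

DEFAULT_SHIFTS = (14, 28)


@dataclass(frozen=True)
class ScenarioSpec:
    """A veraison advancement of ``shift_days`` (0 = default scenario)."""

    shift_days: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.shift_days < 0:
            raise ValueError("shift_days must be >= 0")
        if not self.label:
            object.__setattr__(
                self,
                "label",
                "default" if self.shift_days == 0 else f"eVer_{self.shift_days}",
            )


@dataclass
class ScenarioResult:
    """One vintage x scenario outcome."""

    vintage: str
    label: str
    trajectory: SeasonTrajectory
    gdd_window: float
    final_fw: float
    final_dw: float
    final_sugar_conc: float
    maturity_doy: int | None


def shift_inputs(inputs: SeasonInputs, spec: ScenarioSpec) -> SeasonInputs:
    """Advance the simulation window by ``shift_days``, duration unchanged.

    Weather and predawn series are the same physical series, re-anchored by
    moving veraison and harvest earlier; berry initial state and all
    parameters stay as in the default scenario. A zero shift returns the
    inputs unchanged.
    """
    if spec.shift_days == 0:
        return inputs
    shift = pd.Timedelta(days=spec.shift_days)
    veraison = inputs.veraison - shift
    if veraison.dayofyear < 1 and veraison.year == inputs.veraison.year:
        raise ValueError("shift moves veraison before the start of the year")
    out = replace(inputs, veraison=veraison, harvest=inputs.harvest - shift)
    out.validate_coverage()
    return out


def maturity_doy(traj: SeasonTrajectory, target_sugar: float) -> int | None:
    """First day whose end-of-day sugar concentration reaches the target.

    The target is the default run's maximum [Sugar]; returns None when the
    scenario never reaches it.
    """
    df = traj.hourly
    eod = df[df.index.hour == 23]["berry_sugar_conc"]
    for ts, val in eod.items():
        if val >= target_sugar:
            return int(ts.dayofyear)
    return None


def relative_change(x_scen: float, x_default: float) -> float:
    """Relative change (%) of a scenario value against the default baseline."""
    if x_default == 0:
        raise ValueError("zero baseline")
    return (x_scen - x_default) / x_default * 100.0


def _duration_class(m_default: int | None, m_scen: int | None, shift: int) -> str:
    if m_default is None or m_scen is None:
        return "target_not_reached"
    advancement = m_default - m_scen
    if advancement > shift:
        return "shortened"
    if advancement < shift:
        return "lengthened"
    return "unchanged"


def run_scenarios(
    inputs_by_vintage: dict[str, SeasonInputs],
    params: PlantParams,
    specs: tuple[ScenarioSpec, ...] = tuple(ScenarioSpec(s) for s in DEFAULT_SHIFTS),
) -> tuple[pd.DataFrame, dict[str, dict[str, float]], dict[str, dict[str, ScenarioResult]]]:
    """Run the default and shifted scenarios for every vintage.

    Returns (comparison table, ANOVA p-values per scenario and variable,
    raw results). The table carries per vintage x scenario the GDD delta
    over the simulation window, relative changes of final FW/DW/[Sugar],
    the maturity day-of-year, and the ripening-duration class. The
    across-vintage location test is a one-way F-test of scenario final
    values against default final values.
    """
    rows = []
    results: dict[str, dict[str, ScenarioResult]] = {}
    for vintage, inputs in inputs_by_vintage.items():
        try:
            default_traj = simulate_season(inputs, params)
        except Exception as exc:  # propagate per-vintage failure, continue others
            rows.append({"vintage": vintage, "label": "default", "error": str(exc)})
            continue
        d_df = default_traj.hourly
        d_gdd = gdd(inputs.weather, (inputs.veraison, inputs.harvest))
        d_fw = float(d_df["berry_fw"].iloc[-1])
        d_dw = float(d_df["berry_dw"].iloc[-1])
        d_sc = float(d_df["berry_sugar_conc"].iloc[-1])
        target = float(d_df[d_df.index.hour == 23]["berry_sugar_conc"].max())
        d_mat = maturity_doy(default_traj, target)
        results[vintage] = {
            "default": ScenarioResult(vintage, "default", default_traj, d_gdd, d_fw, d_dw, d_sc, d_mat)
        }
        rows.append(
            {
                "vintage": vintage,
                "label": "default",
                "gdd": d_gdd,
                "gdd_delta": 0.0,
                "final_fw": d_fw,
                "final_dw": d_dw,
                "final_sugar_conc": d_sc,
                "d_fw_pct": 0.0,
                "d_dw_pct": 0.0,
                "d_sugar_pct": 0.0,
                "maturity_doy": d_mat,
                "duration_class": "unchanged",
            }
        )
        for spec in specs:
            if spec.shift_days == 0:
                continue
            try:
                shifted = shift_inputs(inputs, spec)
                traj = simulate_season(shifted, params)
            except Exception as exc:
                rows.append({"vintage": vintage, "label": spec.label, "error": str(exc)})
                continue
            s_df = traj.hourly
            s_gdd = gdd(shifted.weather, (shifted.veraison, shifted.harvest))
            s_fw = float(s_df["berry_fw"].iloc[-1])
            s_dw = float(s_df["berry_dw"].iloc[-1])
            s_sc = float(s_df["berry_sugar_conc"].iloc[-1])
            s_mat = maturity_doy(traj, target)
            results[vintage][spec.label] = ScenarioResult(
                vintage, spec.label, traj, s_gdd, s_fw, s_dw, s_sc, s_mat
            )
            rows.append(
                {
                    "vintage": vintage,
                    "label": spec.label,
                    "gdd": s_gdd,
                    "gdd_delta": s_gdd - d_gdd,
                    "final_fw": s_fw,
                    "final_dw": s_dw,
                    "final_sugar_conc": s_sc,
                    "d_fw_pct": relative_change(s_fw, d_fw),
                    "d_dw_pct": relative_change(s_dw, d_dw),
                    "d_sugar_pct": relative_change(s_sc, d_sc),
                    "maturity_doy": s_mat,
                    "duration_class": _duration_class(d_mat, s_mat, spec.shift_days),
                }
            )
    table = pd.DataFrame(rows)
    anova: dict[str, dict[str, float]] = {}
    ok = table[table["error"].isna()] if "error" in table.columns else table
    default_rows = ok[ok["label"] == "default"]
    for spec in specs:
        if spec.shift_days == 0:
            continue
        scen_rows = ok[ok["label"] == spec.label]
        if len(scen_rows) < 2 or len(default_rows) < 2:
            continue
        anova[spec.label] = {
            var: float(
                stats.f_oneway(default_rows[col].to_numpy(), scen_rows[col].to_numpy()).pvalue
            )
            for var, col in (
                ("final_fw", "final_fw"),
                ("final_dw", "final_dw"),
                ("final_sugar_conc", "final_sugar_conc"),
            )
        }
    return table, anova, results
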