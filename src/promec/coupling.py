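"""Hydraulic and energetic coupling of the PRO stage to the MEC.

The PRO feed effluent (concentrated wastewater) becomes the MEC anolyte and
the diluted draw effluent becomes the catholyte; the osmotic energy harvested
by the PRO stage caps the MEC's electrical consumption ("no energy loss"
idealization of the power-conversion train).  The MEC therefore stops either
at its organic-removal target or when its cumulative energy E_ext*charge
reaches the PRO budget, whichever comes first.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import pandas as pd

from .chemistry import conductivity_to_molarity, molarity_to_conductivity
from .mec import (
    MECParams,
    MECState,
    MECStop,
    MECTrajectory,
    make_mec_initial_state,
    performance_metrics,
    simulate_mec,
)
from .pro import (
    PROMembraneParams,
    PROStop,
    PROTrajectory,
    PressurePolicy,
    effluent_summary,
    make_pro_initial_state,
    simulate_pro,
)
from . import refdata
from .defaults import DEFAULT_MEMBRANE, default_mec_params

__all__ = ["SystemScenario", "SystemResult", "couple", "run_system", "sweep"]


@dataclass(frozen=True)
class SystemScenario:
    """One coupled PRO->MEC run description.

    ``efficiency_voltage`` pins the Coulombic/cathodic efficiency constants
    to a reference operating voltage (used by sweeps so that a voltage grid
    varies only the electrical driving force); ``None`` resolves them from
    the scenario's own voltage.
    """

    feed_volume_mL: float = refdata.FEED_VOLUME_ML
    draw_volume_mL: float = refdata.FEED_VOLUME_ML
    draw_molarity_M: float = refdata.FEASIBILITY_DRAW_M
    feed_pi_bar: float = refdata.FEED_PI_BAR
    feed_substrate_mg_L: float = refdata.FEED_SUBSTRATE_MG_L
    feed_conductivity_mS_cm: float = refdata.FEED_CONDUCTIVITY_MS_CM
    membrane: PROMembraneParams = DEFAULT_MEMBRANE
    pressure_policy: PressurePolicy = PressurePolicy()
    pro_stop: PROStop = PROStop()
    pro_dt: float = 60.0
    voltage_V: float = refdata.FEASIBILITY_VOLTAGE_V
    efficiency_voltage: float | None = None
    mec_overrides: dict[str, Any] = field(default_factory=dict)
    mec_stop: MECStop = MECStop()
    use_pro_energy_budget: bool = True
    anolyte_from_feed_effluent: bool = True
    catholyte_from_draw_effluent: bool = True
    min_anolyte_mL: float = 10.0


@dataclass
class SystemResult:
    """Outcome of a coupled run: both trajectories plus a flat summary."""

    scenario: SystemScenario
    pro: PROTrajectory
    mec: MECTrajectory
    summary: dict[str, float | str | None]


def couple(
    pro_traj: PROTrajectory, scenario: SystemScenario
) -> tuple[MECParams, MECState, MECStop]:
    """Derive the MEC configuration from a completed PRO run.

    Anolyte = feed effluent (volume, substrate, concentration factor);
    catholyte = draw effluent; energy budget = harvested PRO energy.
    """
    eff = effluent_summary(pro_traj)
    feed, draw = eff["feed"], eff["draw"]
    if scenario.anolyte_from_feed_effluent:
        V_a = feed.volume_L
        substrate = feed.substrate_mg_L
        conc_factor = pro_traj.init.V_F / feed.volume_L
    else:
        V_a = pro_traj.init.V_F
        substrate = pro_traj.init.m_sub / pro_traj.init.V_F
        conc_factor = 1.0
    if V_a * 1000.0 < scenario.min_anolyte_mL:
        raise ValueError(
            f"anolyte volume {V_a * 1e3:.1f} mL below the feasible minimum"
        )
    V_c = (
        draw.volume_L
        if scenario.catholyte_from_draw_effluent
        else pro_traj.init.V_D
    )
    params = default_mec_params(
        voltage_V=scenario.voltage_V,
        V_a=V_a,
        V_c=V_c,
        conc_factor=conc_factor,
        efficiency_voltage=scenario.efficiency_voltage,
        **scenario.mec_overrides,
    )
    init = make_mec_initial_state(substrate, params)
    budget = pro_traj.Q_total if scenario.use_pro_energy_budget else None
    stop = replace(scenario.mec_stop, energy_budget_J=budget)
    return params, init, stop


def run_system(scenario: SystemScenario) -> SystemResult:
    """Run PRO, couple the effluents and energy, run the MEC, summarize."""
    pro_init = make_pro_initial_state(
        feed_volume_mL=scenario.feed_volume_mL,
        draw_volume_mL=scenario.draw_volume_mL,
        draw_molarity_M=scenario.draw_molarity_M,
        feed_pi_bar=scenario.feed_pi_bar,
        feed_substrate_mg_L=scenario.feed_substrate_mg_L,
    )
    pro_traj = simulate_pro(
        pro_init,
        scenario.membrane,
        policy=scenario.pressure_policy,
        stop=scenario.pro_stop,
        dt=scenario.pro_dt,
        feed_conductivity_mS_cm=scenario.feed_conductivity_mS_cm,
    )
    params, mec_init, mec_stop = couple(pro_traj, scenario)
    mec_traj = simulate_mec(mec_init, params, stop=mec_stop)
    metrics = performance_metrics(mec_traj, params)
    eff = effluent_summary(pro_traj)
    summary: dict[str, float | str | None] = {
        "water_recovered_mL": pro_traj.water_recovered_L * 1000.0,
        "Q_PRO_J": pro_traj.Q_total,
        "PRO_HRT_h": pro_traj.hrt_h,
        "PRO_stop": pro_traj.stop_reason,
        "anolyte_mL": eff["feed"].volume_L * 1000.0,
        "anolyte_substrate_mg_L": eff["feed"].substrate_mg_L,
        "anolyte_conductivity_mS_cm": eff["feed"].conductivity_mS_cm,
        "catholyte_mL": eff["draw"].volume_L * 1000.0,
        "catholyte_M": eff["draw"].molarity_M,
        "catholyte_conductivity_mS_cm": eff["draw"].conductivity_mS_cm,
        "voltage_V": scenario.voltage_V,
        "Q_MEC_J": metrics["Q_MEC_J"],
        "energy_surplus_J": pro_traj.Q_total - float(metrics["Q_MEC_J"]),
        "V_H2_mL": metrics["V_H2_mL"],
        "removal_pct": metrics["removal_pct"],
        "CE_pct": metrics["CE_pct"],
        "cathodic_eff_pct": metrics["cathodic_eff_pct"],
        "H2_rate_m3_m3_d": metrics["H2_rate_m3_m3_d"],
        "MEC_HRT_h": metrics["HRT_h"],
        "MEC_stop": mec_traj.stop_reason,
        "max_current_mA": metrics["max_current_mA"],
    }
    return SystemResult(
        scenario=scenario, pro=pro_traj, mec=mec_traj, summary=summary
    )


_SWEEP_VARIABLES = ("pro_influent_volume", "draw_molarity", "voltage")


def sweep(
    scenario: SystemScenario,
    variable: str,
    grid: list[float],
) -> pd.DataFrame:
    """Scenario sweep over influent volume (feed and draw together, mL),
    draw molarity (M) or external voltage (V); one summary row per point.

    Voltage sweeps pin the efficiency constants to the base scenario's
    voltage so the grid varies only the electrical driving force.
    """
    if variable not in _SWEEP_VARIABLES:
        raise ValueError(
            f"variable must be one of {_SWEEP_VARIABLES}, got {variable!r}"
        )
    rows = []
    for value in grid:
        if variable == "pro_influent_volume":
            s = replace(
                scenario, feed_volume_mL=value, draw_volume_mL=value
            )
        elif variable == "draw_molarity":
            s = replace(scenario, draw_molarity_M=value)
        else:
            s = replace(
                scenario,
                voltage_V=value,
                efficiency_voltage=scenario.efficiency_voltage
                if scenario.efficiency_voltage is not None
                else scenario.voltage_V,
            )
        result = run_system(s)
        row = {variable: value}
        row.update(result.summary)
        rows.append(row)
    return pd.DataFrame(rows)
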