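"""Batch-mode two-population microbial electrolysis cell (MEC) model.

The anode biofilm hosts two populations competing for acetate: exoelectrogens
(``x_e``), which oxidize substrate through an intracellular redox-mediator
pool and deliver electrons to the circuit, and acetoclastic methanogens
(``x_m``), which consume substrate without producing current.  Substrate,
biomass and the oxidized mediator fraction follow Monod kinetics:

    dS/dt    = -q_e_max * S/(K_e+S) * M_OX/(K_M+M_OX) * x_e
               - q_m_max * S/(K_m+S) * x_m
    dx/dt    = +mu_max * (saturation terms) * x - d * x
    dM_OX/dt = -Y_M * q_e_max * (saturation terms)
               + gamma/(V_a x_e) * I/(n_e F)

Substrate oxidation reduces the mediator pool; current through the circuit
reoxidizes it.  The current closes algebraically each instant through the
cell voltage balance

    I = [(E_C - E_A) + E_ext - eta_con] / (R_ext + R_in)
        * (M_Total - M_OX)/(eps + M_Total - M_OX)

with Nernst electrode potentials, a concentration overpotential from
mediator and substrate depletion, and a biomass-dependent internal
resistance.  Cumulative energy and hydrogen follow identically from the
charge: Q_MEC = E_ext * integral(I dt) and V_H2 = Y_H2 * charge/(2F) * RT/P.

Note on signs: the growth terms of the biomass balances are positive
(growth minus first-order decay).  A literal transcription with negative
growth would only ever lose biomass, contradicting the multi-population
models this formulation descends from.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .chemistry import CONSTANTS, PhysicalConstants

__all__ = [
    "MECParams",
    "MECState",
    "MECStop",
    "MECTrajectory",
    "anode_potential",
    "cathode_potential",
    "concentration_overpotential",
    "internal_resistance",
    "current",
    "mec_rhs",
    "simulate_mec",
    "make_mec_initial_state",
    "performance_metrics",
]

_DAY = 86400.0
_HPLUS_FLOOR = 1.0e-14


@dataclass(frozen=True)
class MECParams:
    """Kinetic and electrochemical constants of the batch MEC.

    Rates are per day; concentrations in mg/L; the mediator pool is tracked
    as mg of mediator per mg of exoelectrogen biomass.  ``CE_param`` and
    ``Y_H2`` (fractions of 1) are the Coulombic and cathodic efficiencies
    treated as per-scenario constants: ``CE_param`` enters the proton
    balance, ``Y_H2`` converts charge to hydrogen volume.  ``conc_factor``
    is the upstream concentration factor V_F,0/V_F of the osmosis stage
    (it scales the inherited bicarbonate).
    """

    # substrate / growth kinetics
    q_e_max: float = 8.48      # mg-S mg-x^-1 day^-1
    q_m_max: float = 8.20      # mg-S mg-x^-1 day^-1
    mu_e_max: float = 0.196    # day^-1
    mu_m_max: float = 0.100    # day^-1
    d_e: float = 0.040         # day^-1
    d_m: float = 0.010         # day^-1
    K_e: float = 20.0          # mg-S L^-1
    K_m: float = 80.0          # mg-S L^-1
    # mediator pool
    K_M: float = 0.0100        # mg-M mg-x^-1
    Y_M: float = 36.0          # mg-M mg-S^-1
    gamma: float = 663400.0    # mg-M mole-M^-1
    M_Total: float = 0.05      # mg-M mg-x^-1
    n_e: float = 2.0           # electrons per mediator
    eps: float = 1.0e-4        # mg-M mg-x^-1, saturation regularizer
    # electrochemistry
    E_A0: float = 0.187        # V, bicarbonate/acetate couple
    E_C0: float = 0.0          # V, H+/H2 couple
    E_ext: float = 0.8         # V
    R_ext: float = 1.0         # ohm (measurement resistor)
    R_min: float = 25.0        # ohm
    R_max: float = 2000.0      # ohm
    K_R: float = 0.024         # L mg-x^-1
    cathode_pH: float = 11.0
    # anolyte composition
    HCO3_0: float = 1.2e-4     # M, bicarbonate in the upstream feed
    m_S: float = 82.0          # g mol^-1, sodium acetate
    beta: float = 0.0          # buffer efficiency (fraction), signed
    CE_param: float = 0.575    # fraction
    Y_H2: float = 0.481        # fraction
    conc_factor: float = 1.0
    # volumes
    V_a: float = 0.115         # L, anolyte
    V_c: float = 1.085         # L, catholyte
    # model-form switch: literal mediator balance omits the q_e_max factor
    literal_mediator_term: bool = False

    def __post_init__(self) -> None:
        positives = (
            "q_e_max", "q_m_max", "mu_e_max", "mu_m_max", "K_e", "K_m",
            "K_M", "Y_M", "gamma", "M_Total", "n_e", "eps", "R_ext",
            "R_min", "R_max", "m_S", "V_a", "V_c", "conc_factor",
        )
        for name in positives:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.K_R < 0:
            raise ValueError("K_R must be non-negative")
        if self.R_min > self.R_max:
            raise ValueError("require R_min <= R_max")
        for name in ("CE_param", "Y_H2"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class MECState:
    """Instantaneous MEC state (concentrations plus cumulative tallies)."""

    t: float            # s
    S: float            # substrate, mg/L
    x_e: float          # exoelectrogens, mg/L
    x_m: float          # methanogens, mg/L
    M_OX: float         # oxidized mediator fraction, mg-M/mg-x
    Hplus: float        # anolyte protons, M
    charge: float = 0.0  # C
    S_0: float = None   # type: ignore[assignment]  # initial substrate, mg/L

    def __post_init__(self) -> None:
        if self.S_0 is None:
            self.S_0 = self.S


@dataclass(frozen=True)
class MECStop:
    """Stop at a removal target, an energy budget (J), or t_max (s)."""

    removal_fraction: float = 0.999
    energy_budget_J: float | None = None
    t_max: float = 200.0 * 3600.0

    def __post_init__(self) -> None:
        if not 0.0 < self.removal_fraction <= 1.0:
            raise ValueError("removal_fraction must lie in (0, 1]")
        if self.energy_budget_J is not None and self.energy_budget_J < 0:
            raise ValueError("energy budget must be non-negative")
        if self.t_max <= 0:
            raise ValueError("t_max must be strictly positive")


def bicarbonate(S: float, S_0: float, p: MECParams) -> float:
    """Anolyte bicarbonate (M): inherited pool plus oxidation product.

    [HCO3-] = [HCO3-]_0 * conc_factor + 2 (S_0 - S)/m_S, with m_S in mg/mol.
    """
    return p.HCO3_0 * p.conc_factor + 2.0 * (S_0 - S) / (p.m_S * 1000.0)


def anode_potential(
    S: float,
    HCO3: float,
    Hplus: float,
    p: MECParams,
    consts: PhysicalConstants = CONSTANTS,
) -> float:
    """Nernst anode potential of the bicarbonate/acetate couple (V).

    E_A = E_A0 - (RT/8F) ln( S_molar / ([HCO3-]^2 [H+]^9) ).
    """
    if S <= 0 or HCO3 <= 0 or Hplus <= 0:
        raise ValueError("Nernst arguments must be strictly positive")
    S_molar = S / (p.m_S * 1000.0)
    q = S_molar / (HCO3**2 * Hplus**9)
    return p.E_A0 - consts.RT_over_F / 8.0 * math.log(q)


def cathode_potential(
    p: MECParams, consts: PhysicalConstants = CONSTANTS
) -> float:
    """Nernst cathode potential of H+/H2 at the fixed catholyte pH (V)."""
    return p.E_C0 - consts.RT_over_F / 2.0 * math.log(
        10.0 ** (2.0 * p.cathode_pH)
    )


def concentration_overpotential(
    M_OX: float, S: float, S_0: float, p: MECParams,
    consts: PhysicalConstants = CONSTANTS,
) -> float:
    """Anode concentration overpotential (V), infinite at full depletion.

    eta_con = (RT/F) ln[ M_Total/(M_Total - M_OX) * S_0/S ].
    """
    if M_OX < 0 or S < 0 or S > S_0:
        raise ValueError("require 0 <= M_OX and 0 <= S <= S_0")
    if S == 0.0 or M_OX >= p.M_Total:
        return math.inf
    return consts.RT_over_F * math.log(
        p.M_Total / (p.M_Total - M_OX) * S_0 / S
    )


def internal_resistance(x_e: float, p: MECParams) -> float:
    """Biofilm-dependent internal resistance (ohm), R_max down to R_min."""
    if x_e < 0:
        raise ValueError("x_e must be non-negative")
    return p.R_min + (p.R_max - p.R_min) * math.exp(-p.K_R * x_e)


def current(
    state: MECState, p: MECParams, consts: PhysicalConstants = CONSTANTS
) -> float:
    """Circuit current (A), floored at zero (no reverse current)."""
    M_OX = min(max(state.M_OX, 0.0), p.M_Total)
    S = max(state.S, 0.0)
    if S == 0.0:
        return 0.0
    eta = concentration_overpotential(M_OX, S, state.S_0, p, consts)
    if not math.isfinite(eta):
        return 0.0
    HCO3 = bicarbonate(S, state.S_0, p)
    E_A = anode_potential(S, HCO3, max(state.Hplus, _HPLUS_FLOOR), p, consts)
    E_C = cathode_potential(p, consts)
    driving = (E_C - E_A) + p.E_ext - eta
    if driving <= 0.0:
        return 0.0
    R_in = internal_resistance(state.x_e, p)
    sat = (p.M_Total - M_OX) / (p.eps + p.M_Total - M_OX)
    return driving / (p.R_ext + R_in) * sat


def mec_rhs(
    state: MECState, p: MECParams, consts: PhysicalConstants = CONSTANTS
) -> tuple[float, float, float, float, float, float]:
    """Time derivatives (per second) of (S, x_e, x_m, M_OX, H+, charge)."""
    S = max(state.S, 0.0)
    M_OX = min(max(state.M_OX, 0.0), p.M_Total)
    x_e = max(state.x_e, 0.0)
    x_m = max(state.x_m, 0.0)

    monod_e = S / (p.K_e + S)
    monod_m = S / (p.K_m + S)
    monod_M = M_OX / (p.K_M + M_OX)

    I = current(replace(state, S=S, M_OX=M_OX), p, consts) if S > 0 else 0.0

    r_e = p.q_e_max * monod_e * monod_M * x_e / _DAY  # mg-S L^-1 s^-1
    r_m = p.q_m_max * monod_m * x_m / _DAY
    dS = -(r_e + r_m)

    dx_e = (p.mu_e_max * monod_e * monod_M - p.d_e) * x_e / _DAY
    dx_m = (p.mu_m_max * monod_m - p.d_m) * x_m / _DAY

    if p.literal_mediator_term:
        reduction = p.Y_M * monod_e * monod_M / _DAY
    else:
        reduction = p.Y_M * p.q_e_max * monod_e * monod_M / _DAY
    if x_e > 0.0:
        reoxidation = p.gamma / (p.V_a * x_e) * I / (p.n_e * consts.F)
    else:
        reoxidation = 0.0
    dM_OX = -reduction + reoxidation

    if state.Hplus <= _HPLUS_FLOOR and p.beta * dS * (
        9.0 - 8.0 * p.CE_param * p.Y_H2
    ) < 0:
        dH = 0.0
    else:
        dH = p.beta / (p.m_S * 1000.0) * dS * (
            9.0 - 8.0 * p.CE_param * p.Y_H2
        )

    return dS, dx_e, dx_m, dM_OX, dH, I


@dataclass
class MECTrajectory:
    """A completed batch MEC run on the reporting grid."""

    t: np.ndarray
    S: np.ndarray
    x_e: np.ndarray
    x_m: np.ndarray
    M_OX: np.ndarray
    Hplus: np.ndarray
    I: np.ndarray          # A
    charge: np.ndarray     # C
    stop_reason: str
    params: MECParams = field(repr=False)
    init: MECState = field(repr=False)
    consts: PhysicalConstants = field(default=CONSTANTS, repr=False)

    @property
    def Q_MEC(self) -> np.ndarray:
        """Cumulative electrical energy E_ext * charge, J (exact identity)."""
        return self.params.E_ext * self.charge

    @property
    def V_H2(self) -> np.ndarray:
        """Cumulative hydrogen, mL: Y_H2 * charge/(2F) * RT/P (identity)."""
        c = self.consts
        return (
            self.params.Y_H2 * self.charge / (2.0 * c.F) * c.molar_volume_mL
        )

    @property
    def removal_fraction(self) -> float:
        return 1.0 - float(self.S[-1]) / self.init.S_0

    @property
    def hrt_h(self) -> float:
        return float(self.t[-1]) / 3600.0

    @property
    def final(self) -> MECState:
        return MECState(
            t=float(self.t[-1]),
            S=float(self.S[-1]),
            x_e=float(self.x_e[-1]),
            x_m=float(self.x_m[-1]),
            M_OX=float(self.M_OX[-1]),
            Hplus=float(self.Hplus[-1]),
            charge=float(self.charge[-1]),
            S_0=self.init.S_0,
        )

    def to_frame(self) -> pd.DataFrame:
        p, c = self.params, self.consts
        E_C = cathode_potential(p, c)
        E_A = np.empty_like(self.t)
        eta = np.empty_like(self.t)
        for idx in range(len(self.t)):
            S = max(float(self.S[idx]), 1e-12)
            HCO3 = bicarbonate(S, self.init.S_0, p)
            E_A[idx] = anode_potential(
                S, HCO3, max(float(self.Hplus[idx]), _HPLUS_FLOOR), p, c
            )
            eta[idx] = concentration_overpotential(
                min(float(self.M_OX[idx]), p.M_Total * (1 - 1e-12)),
                S, self.init.S_0, p, c,
            )
        return pd.DataFrame(
            {
                "t_s": self.t,
                "S_mg_L": self.S,
                "x_e_mg_L": self.x_e,
                "x_m_mg_L": self.x_m,
                "M_OX": self.M_OX,
                "I_mA": self.I * 1000.0,
                "E_A_V": E_A,
                "E_C_V": np.full_like(self.t, E_C),
                "eta_con_V": eta,
                "R_in_ohm": np.array(
                    [internal_resistance(x, p) for x in self.x_e]
                ),
                "charge_C": self.charge,
                "Q_J": self.Q_MEC,
                "V_H2_mL": self.V_H2,
            }
        )


def make_mec_initial_state(
    substrate_mg_L: float,
    p: MECParams,
    x_e0: float = 400.0,
    x_m0: float = 8.14911,
    M_OX0_fraction: float = 0.9,
    pH0: float = 7.0,
) -> MECState:
    """Initial MEC state: inoculated biofilm, mostly-oxidized mediator pool,
    neutral anolyte.

    The default standing biomasses are the calibrated values for the
    reference cell: enough exoelectrogens that the internal resistance sits
    on its R_min plateau, and a small methanogen inoculum that grows in
    over a multi-day batch.
    """
    if substrate_mg_L <= 0:
        raise ValueError("substrate must be strictly positive")
    if not 0.0 <= M_OX0_fraction < 1.0:
        raise ValueError("M_OX0_fraction must lie in [0, 1)")
    return MECState(
        t=0.0,
        S=substrate_mg_L,
        x_e=x_e0,
        x_m=x_m0,
        M_OX=M_OX0_fraction * p.M_Total,
        Hplus=10.0 ** (-pH0),
    )


def simulate_mec(
    init: MECState,
    p: MECParams,
    stop: MECStop = MECStop(),
    consts: PhysicalConstants = CONSTANTS,
    dt_report: float = 300.0,
    rtol: float = 1e-8,
    max_step: float = 600.0,
) -> MECTrajectory:
    """Integrate the batch MEC to its removal target, energy budget or t_max.

    The ODE system is semi-explicit: the current closes algebraically from
    the state at every right-hand-side evaluation (LSODA, adaptive).  Events
    terminate the run at the removal target and, if set, at the charge
    equivalent of the energy budget.
    """
    if init.S <= 0:
        raise ValueError("initial substrate must be strictly positive")

    if stop.energy_budget_J is not None and stop.energy_budget_J == 0.0:
        arr = np.array
        return MECTrajectory(
            t=arr([0.0]), S=arr([init.S]), x_e=arr([init.x_e]),
            x_m=arr([init.x_m]), M_OX=arr([init.M_OX]),
            Hplus=arr([init.Hplus]), I=arr([0.0]), charge=arr([0.0]),
            stop_reason="energy_budget", params=p, init=replace(init),
            consts=consts,
        )

    S_target = (1.0 - stop.removal_fraction) * init.S_0
    charge_budget = (
        None
        if stop.energy_budget_J is None
        else stop.energy_budget_J / p.E_ext
    )

    def rhs(t: float, y: np.ndarray) -> list[float]:
        state = MECState(
            t=t, S=y[0], x_e=y[1], x_m=y[2], M_OX=y[3], Hplus=y[4],
            charge=y[5], S_0=init.S_0,
        )
        dS, dx_e, dx_m, dM, dH, I = mec_rhs(state, p, consts)
        return [dS, dx_e, dx_m, dM, dH, I]

    def removal_event(t: float, y: np.ndarray) -> float:
        return y[0] - S_target

    removal_event.terminal = True
    removal_event.direction = -1
    events = [removal_event]

    if charge_budget is not None:
        def budget_event(t: float, y: np.ndarray) -> float:
            return y[5] - charge_budget

        budget_event.terminal = True
        budget_event.direction = 1
        events.append(budget_event)

    y0 = [init.S, init.x_e, init.x_m, init.M_OX, init.Hplus, init.charge]
    sol = solve_ivp(
        rhs,
        (init.t, init.t + stop.t_max),
        y0,
        method="LSODA",
        events=events,
        dense_output=True,
        rtol=rtol,
        atol=[1e-8, 1e-8, 1e-8, 1e-12, 1e-16, 1e-6],
        max_step=max_step,
    )
    if not sol.success:
        raise RuntimeError(f"MEC integration failed: {sol.message}")

    if sol.status == 1:
        if len(sol.t_events[0]) > 0:
            stop_reason, t_end = "substrate_depleted", sol.t_events[0][0]
        else:
            stop_reason, t_end = "energy_budget", sol.t_events[1][0]
    else:
        stop_reason, t_end = "t_max", sol.t[-1]

    n_pts = max(int(math.ceil((t_end - init.t) / dt_report)), 1) + 1
    t_grid = np.linspace(init.t, t_end, n_pts)
    y = sol.sol(t_grid)
    y[0] = np.clip(y[0], 0.0, init.S)
    y[3] = np.clip(y[3], 0.0, p.M_Total)

    I_grid = np.array(
        [
            current(
                MECState(
                    t=t_grid[idx], S=float(y[0, idx]), x_e=float(y[1, idx]),
                    x_m=float(y[2, idx]), M_OX=float(y[3, idx]),
                    Hplus=float(y[4, idx]), charge=float(y[5, idx]),
                    S_0=init.S_0,
                ),
                p,
                consts,
            )
            for idx in range(n_pts)
        ]
    )
    charge = np.maximum.accumulate(y[5])
    return MECTrajectory(
        t=t_grid, S=y[0], x_e=y[1], x_m=y[2], M_OX=y[3], Hplus=y[4],
        I=I_grid, charge=charge, stop_reason=stop_reason, params=p,
        init=replace(init), consts=consts,
    )


def performance_metrics(
    traj: MECTrajectory, p: MECParams | None = None,
    consts: PhysicalConstants = CONSTANTS,
) -> dict[str, float | None]:
    """Derived performance metrics of a completed MEC run.

    removal_pct    (S_0 - S_end)/S_0
    CE_pct         charge recovered over the 8-electron equivalent of the
                   removed substrate
    cathodic_eff_pct  2F * mol H2 / charge (equals Y_H2 by model identity)
    H2_rate_m3_m3_d   hydrogen volume per catholyte volume per day
    HRT_h          batch operating time
    """
    p = p or traj.params
    final = traj.final
    removal = 1.0 - final.S / traj.init.S_0
    delta_S_mg = (traj.init.S_0 - final.S) * p.V_a
    charge = final.charge
    V_H2 = float(traj.V_H2[-1])
    hrt_h = traj.hrt_h

    if delta_S_mg > 0 and charge > 0:
        CE = charge / (8.0 * consts.F * delta_S_mg / (p.m_S * 1000.0)) * 100.0
    else:
        CE = None
    if charge > 0:
        n_H2 = V_H2 / consts.molar_volume_mL
        cathodic = 2.0 * consts.F * n_H2 / charge * 100.0
    else:
        cathodic = 0.0 if V_H2 == 0.0 else None
    rate = (
        (V_H2 / 1000.0) / (p.V_c * hrt_h / 24.0) if hrt_h > 0 else 0.0
    )
    return {
        "removal_pct": removal * 100.0,
        "CE_pct": CE,
        "cathodic_eff_pct": cathodic,
        "H2_rate_m3_m3_d": rate,
        "HRT_h": hrt_h,
        "V_H2_mL": V_H2,
        "Q_MEC_J": p.E_ext * charge,
        "charge_C": charge,
        "mean_current_mA": (
            charge / (hrt_h * 3600.0) * 1000.0 if hrt_h > 0 else 0.0
        ),
        "max_current_mA": float(np.max(traj.I)) * 1000.0,
    }
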