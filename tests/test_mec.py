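"""MEC stage: Nernst potentials, current closure, batch dynamics,
energy/hydrogen identities."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from promec.chemistry import CONSTANTS
from promec.defaults import default_mec_params
from promec.mec import (
    MECParams,
    MECState,
    MECStop,
    anode_potential,
    bicarbonate,
    cathode_potential,
    concentration_overpotential,
    current,
    internal_resistance,
    make_mec_initial_state,
    mec_rhs,
    performance_metrics,
    simulate_mec,
)

RT_F = CONSTANTS.RT_over_F


@pytest.fixture(scope="module")
def cycle(mec_params):
    """Full 0.8 V batch cycle with the standard coupled anolyte."""
    init = make_mec_initial_state(1007.0, mec_params)
    return simulate_mec(init, mec_params, stop=MECStop())


class TestAnodePotential:
    def test_unit_reaction_quotient_gives_standard_potential(self):
        p = MECParams()
        # choose S (mg/L) such that S_molar = HCO3^2 * H+^9 exactly
        HCO3, Hplus = 2.0, 0.9
        S = HCO3**2 * Hplus**9 * p.m_S * 1000.0
        assert anode_potential(S, HCO3, Hplus, p) == pytest.approx(0.187)

    def test_standard_coupled_anolyte_state(self):
        # S = 1007 mg/L (0.01228 M), HCO3 = 6.26e-4 M, pH 7
        p = MECParams(conc_factor=600.0 / 115.0)
        HCO3 = bicarbonate(1007.0, 1007.0, p)
        assert HCO3 == pytest.approx(6.26e-4, rel=0.01)
        E_A = anode_potential(1007.0, HCO3, 1e-7, p)
        # independent arithmetic: 0.187 - (RT/8F) ln(0.01228/(HCO3^2 1e-63))
        expected = 0.187 - RT_F / 8 * math.log(
            (1007.0 / 82000.0) / (HCO3**2 * 1e-63)
        )
        assert E_A == pytest.approx(expected, rel=1e-12)
        assert E_A == pytest.approx(-0.312, abs=0.002)

    def test_monotone_increasing_in_protons(self):
        p = MECParams()
        E = [anode_potential(500.0, 1e-3, h, p) for h in (1e-8, 1e-7, 1e-6)]
        assert E[0] < E[1] < E[2]

    def test_non_positive_arguments_rejected(self):
        p = MECParams()
        for args in ((0.0, 1e-3, 1e-7), (500.0, 0.0, 1e-7),
                     (500.0, 1e-3, 0.0)):
            with pytest.raises(ValueError):
                anode_potential(*args, p)


class TestCathodePotential:
    @pytest.mark.parametrize(
        "pH,expected", [(11.0, -0.651), (0.0, 0.0), (7.0, -0.414)]
    )
    def test_nernstian_pH_dependence(self, pH, expected):
        p = MECParams(cathode_pH=pH)
        assert cathode_potential(p) == pytest.approx(expected, abs=5e-4)


class TestConcentrationOverpotential:
    def test_fresh_state_has_no_overpotential(self):
        p = MECParams()
        assert concentration_overpotential(0.0, 500.0, 500.0, p) == 0.0

    def test_half_oxidized_mediator(self):
        p = MECParams()
        eta = concentration_overpotential(p.M_Total / 2, 500.0, 500.0, p)
        assert eta == pytest.approx(RT_F * math.log(2), rel=1e-9)

    def test_tenfold_substrate_depletion(self):
        p = MECParams()
        eta = concentration_overpotential(0.0, 50.0, 500.0, p)
        assert eta == pytest.approx(RT_F * math.log(10), rel=1e-9)

    def test_full_depletion_is_infinite(self):
        p = MECParams()
        assert concentration_overpotential(p.M_Total, 500.0, 500.0, p) \
            == math.inf
        assert concentration_overpotential(0.0, 0.0, 500.0, p) == math.inf


class TestInternalResistance:
    def test_limits(self):
        p = MECParams()
        assert internal_resistance(0.0, p) == p.R_max
        assert internal_resistance(1e6, p) == pytest.approx(p.R_min)

    def test_flat_when_insensitive_to_biomass(self):
        p = MECParams(K_R=0.0)
        assert internal_resistance(0.0, p) == p.R_max
        assert internal_resistance(500.0, p) == p.R_max

    def test_monotone_decreasing(self):
        p = MECParams()
        r = [internal_resistance(x, p) for x in (0, 50, 100, 500)]
        assert all(a > b for a, b in zip(r, r[1:]))


class TestCurrent:
    def test_saturated_mediator_blocks_current(self, mec_params):
        state = MECState(t=0, S=1000.0, x_e=400.0, x_m=10.0,
                         M_OX=mec_params.M_Total, Hplus=1e-7)
        assert current(state, mec_params) == 0.0

    def test_non_spontaneous_cell_floored_at_zero(self):
        p = default_mec_params(0.8, E_ext=0.05)  # far below the deficit
        state = MECState(t=0, S=1007.0, x_e=400.0, x_m=10.0,
                         M_OX=0.0, Hplus=1e-7)
        assert current(state, p) == 0.0

    def test_nominal_feasibility_current_is_milliamp_scale(self, mec_params):
        state = MECState(t=0, S=1007.0, x_e=400.0, x_m=10.0,
                         M_OX=0.0, Hplus=1e-7)
        I = current(state, mec_params)
        assert 3e-3 < I < 6e-3


class TestRHS:
    def test_exhausted_substrate_is_stationary(self, mec_params):
        state = MECState(t=0, S=0.0, x_e=400.0, x_m=10.0, M_OX=0.01,
                         Hplus=1e-7, S_0=1007.0)
        dS, _, _, _, dH, I = mec_rhs(state, mec_params)
        assert dS == 0.0 and dH == 0.0 and I == 0.0

    def test_no_biomass_no_consumption(self, mec_params):
        state = MECState(t=0, S=500.0, x_e=0.0, x_m=0.0, M_OX=0.01,
                         Hplus=1e-7)
        dS, *_ = mec_rhs(state, mec_params)
        assert dS == 0.0

    def test_single_population_monod_limit(self):
        """With the mediator saturated away (K_M -> 0, Y_M -> 0, I = 0) and
        no methanogens, S(t) must follow plain single-population Monod
        depletion; checked against an independent high-accuracy
        integration."""
        p = default_mec_params(
            0.8, E_ext=1e-6, K_M=1e-12, Y_M=1e-12, R_min=1e6, R_max=1e6,
            beta=0.0,
        )
        init = make_mec_initial_state(
            1007.0, p, x_e0=100.0, x_m0=1e-12, M_OX0_fraction=0.5
        )
        traj = simulate_mec(
            init, p, stop=MECStop(removal_fraction=1.0, t_max=30 * 3600.0),
            rtol=1e-10,
        )

        def reference(t, y):
            S, x = y
            monod = S / (p.K_e + S)
            return [
                -p.q_e_max * monod * x / 86400.0,
                (p.mu_e_max * monod - p.d_e) * x / 86400.0,
            ]

        ref = solve_ivp(
            reference, (0.0, traj.t[-1]), [1007.0, 100.0],
            t_eval=traj.t, rtol=1e-12, atol=1e-12, method="LSODA",
        )
        assert np.allclose(traj.S, ref.y[0], rtol=2e-6, atol=1e-6)
        assert np.allclose(traj.x_e, ref.y[1], rtol=2e-6)


class TestSimulateMec:
    def test_energy_identity(self, cycle, mec_params):
        assert np.allclose(
            cycle.Q_MEC, mec_params.E_ext * cycle.charge, rtol=1e-12
        )

    def test_hydrogen_identity(self, cycle, mec_params):
        expected = (
            mec_params.Y_H2 * cycle.charge / (2 * CONSTANTS.F)
            * CONSTANTS.molar_volume_mL
        )
        assert np.allclose(cycle.V_H2, expected, rtol=1e-12)

    def test_hydrogen_never_exceeds_coulombic_maximum(self, cycle):
        max_H2 = cycle.charge / (2 * CONSTANTS.F) * CONSTANTS.molar_volume_mL
        assert np.all(cycle.V_H2 <= max_H2 + 1e-9)

    def test_substrate_monotone_non_increasing(self, cycle):
        assert np.all(np.diff(cycle.S) <= 1e-9)

    def test_mediator_and_resistance_bounds(self, cycle, mec_params):
        assert np.all(cycle.M_OX >= -1e-12)
        assert np.all(cycle.M_OX <= mec_params.M_Total + 1e-12)
        r = [internal_resistance(x, mec_params) for x in cycle.x_e]
        assert all(mec_params.R_min <= v <= mec_params.R_max for v in r)

    def test_charge_non_decreasing(self, cycle):
        assert np.all(np.diff(cycle.charge) >= -1e-9)

    def test_zero_energy_budget_stops_immediately(self, mec_params):
        init = make_mec_initial_state(1007.0, mec_params)
        tr = simulate_mec(
            init, mec_params, stop=MECStop(energy_budget_J=0.0)
        )
        assert tr.stop_reason == "energy_budget"
        assert tr.V_H2[-1] == 0.0
        assert tr.removal_fraction == 0.0

    def test_energy_budget_respected(self, mec_params):
        init = make_mec_initial_state(1007.0, mec_params)
        tr = simulate_mec(
            init, mec_params, stop=MECStop(energy_budget_J=200.0)
        )
        assert tr.stop_reason == "energy_budget"
        assert tr.Q_MEC[-1] == pytest.approx(200.0, rel=1e-6)

    def test_subthreshold_voltage_stalls_removal(self):
        # below the ~0.34 V thermodynamic deficit: no current, methanogens
        # alone chip away at the substrate
        p = default_mec_params(0.8, E_ext=0.2)
        init = make_mec_initial_state(1007.0, p)
        tr = simulate_mec(init, p, stop=MECStop(t_max=24 * 3600.0))
        assert tr.charge[-1] == pytest.approx(0.0, abs=1e-3)
        assert tr.removal_fraction < 0.5

    def test_grid_convergence_of_terminal_charge(self, mec_params):
        init = make_mec_initial_state(1007.0, mec_params)
        stop = MECStop(t_max=20 * 3600.0, removal_fraction=1.0)
        coarse = simulate_mec(init, mec_params, stop=stop, max_step=600.0)
        fine = simulate_mec(init, mec_params, stop=stop, max_step=300.0)
        assert fine.charge[-1] == pytest.approx(
            coarse.charge[-1], rel=1e-3
        )

    def test_trajectory_table_schema(self, cycle):
        df = cycle.to_frame()
        for col in ("t_s", "S_mg_L", "I_mA", "E_A_V", "eta_con_V",
                    "R_in_ohm", "charge_C", "Q_J", "V_H2_mL"):
            assert col in df.columns


class TestPerformanceMetrics:
    def test_coulombic_efficiency_arithmetic(self, cycle, mec_params):
        m = performance_metrics(cycle, mec_params)
        delta_mg = (1007.0 - cycle.final.S) * mec_params.V_a
        expected = cycle.final.charge / (
            8 * CONSTANTS.F * delta_mg / 82000.0
        ) * 100.0
        assert m["CE_pct"] == pytest.approx(expected, rel=1e-9)

    def test_printed_efficiency_example(self):
        # 587.5 C against 115 mL x 1009 mg/L x 93.7 % removed: CE ~ 57.4 %
        delta_mg = 115e-3 * 1009.0 * 0.937
        CE = 587.5 / (8 * CONSTANTS.F * delta_mg / 82000.0) * 100.0
        assert CE == pytest.approx(57.4, abs=0.2)

    def test_cathodic_efficiency_equals_Y_H2_by_identity(
        self, cycle, mec_params
    ):
        m = performance_metrics(cycle, mec_params)
        assert m["cathodic_eff_pct"] == pytest.approx(
            mec_params.Y_H2 * 100.0, rel=1e-9
        )

    def test_hydrogen_rate_example(self):
        # 32.8 mL into 1.085 L of catholyte over 46.9 h -> 0.016 m3 m-3 d-1
        rate = (32.8 / 1000.0) / (1.085 * 46.9 / 24.0)
        assert rate == pytest.approx(0.0155, abs=2e-4)

    def test_zero_charge_reports_missing_CE(self, mec_params):
        init = make_mec_initial_state(1007.0, mec_params)
        tr = simulate_mec(init, mec_params, stop=MECStop(energy_budget_J=0.0))
        m = performance_metrics(tr, mec_params)
        assert m["CE_pct"] is None
        assert m["cathodic_eff_pct"] == 0.0
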