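# Methods

## Scope and structure

`promec` simulates a batch PRO stage and a batch two-population MEC,
hydraulically coupled (PRO effluents become MEC electrolytes) and
energetically coupled (the MEC's electrical consumption is capped by the
PRO's harvested osmotic energy, an idealization that assumes a lossless
power-conversion train). The library is organized as: `chemistry`
(constants and concentration/pressure/conductivity conversions), `pro`,
`mec`, `coupling`, `calibration`, and the I/O layer (`config`, `presets`,
`cli`).

## Osmotic-pressure convention

All streams carry an *equivalent NaCl molarity* and osmotic pressures are
computed with the ideal van't Hoff relation π = i·R·T·C (φ = 1 in the
exposed `OsmoticModel`). A real 0.8 M NaCl solution measures about 36.2 bar
rather than the ideal 39.66 bar (osmotic coefficient ≈ 0.91, exposed as
`chemistry.NACL_OSMOTIC_COEFF`), but the simulator and its calibrated
transport constants are built consistently on the ideal convention: the
equivalent molarities are model bookkeeping, not assays. The choice is not
cosmetic — under the maximum-power schedule P = Δπ/2 the harvested energy is
bounded by the exact mass-balance integral a∫(Δπ/2) dV, and only the ideal
convention makes that bound consistent with the energy the reference system
harvests for the water it recovers. φ remains a config knob
(`phi`), and `phi=NACL_OSMOTIC_COEFF` converts measured pressures.

The multi-solute feed (acetate, phosphate buffer, bicarbonate) cannot have
its pressure computed from a single molarity, so its osmotic pressure is an
*input* (default 2.4 bar) carried as the equivalent molarity
π_F,0/(φ·i·R·T); reverse-salt-flux additions increment that equivalent
amount. Conductivity ↔ molarity uses the standard empirical factor
0.64 g/L TDS per mS/cm over the NaCl molar mass (so 1 mS/cm ≈ 640 ppm);
with it, a 54.7 mS/cm seawater-strength draw maps to 0.598 M.

## PRO stage

The implicit flux equation (internal concentration polarization on the
feed/support side, dilutive external polarization on the draw side, B/J
leakage correction) is solved per step by bracketed root finding (Brent) on
(0, A·π_D]; the residual is strictly decreasing in J, so the root is unique
and a sign check at the origin decides "flux exhausted" (J = 0). `expm1`
keeps the B/J term accurate as J → 0. The solver was verified against a
dense grid-scan oracle and the ideal-membrane closed form J = A(Δπ − P).

Batch dynamics use a fixed-step quasi-static update (default Δt = 60 s):
recompute π from current amounts and volumes, P from the policy, J from the
solver; then transfer volume J·a·Δt and salt J_s·a·Δt and accumulate
Q += a·P·J·Δt. The volume dynamics are slow and non-stiff; halving Δt moves
terminal volumes by far less than 0.1 % (tested). Runs stop at the flux
threshold (default 0.5 LMH), at t_max, on feed exhaustion, or on osmotic
reversal. Negative computed flux is treated as termination, never as
reverse osmosis. Units are SI internally (m³, s; bar for pressures, as in
the flux law); mL, hours and LMH appear only at I/O boundaries.

## Membrane calibration

Transport constants are calibrated to the bundled constant-pressure
validation observations (`refdata.PRO_CALIBRATION_POINTS`): the 0.8 M/1 bar
run's trajectory pair (600 → 177 mL at 5 h → 138 mL at 6 h) and the
2.0 M/1 bar point (285 mL at 2 h). Three findings shaped the design:

1. **B is structurally unidentifiable from feed-volume data.** Free
   three-parameter fits run along a flat valley in B with essentially equal
   cost but very different extrapolations. This is the known limitation of
   characterizing a membrane from water flux alone; B is therefore held at
   the published salt permeability of the CTA-ES membrane family
   (2.0×10⁻⁷ m/s ≈ 0.7 LMH) and only A and S_struct are fitted
   (2 parameters, 3 constraints, relative fit RMSE < 1 %).
2. **D and k are fixed** at literature-typical values (1.5×10⁻⁹ m²/s;
   1×10⁻⁴ m/s for the high-cross-flow draw channel). S enters the flux law
   only as S/D, so fixing D merely sets S's scale; external polarization is
   mild at these cross-flows.
3. **The 0.5 M validation endpoint (600 → 452 mL at 5 h) is an outlier**
   that no parameterization of this flux law can reconcile with the other
   observations: late states of the 0.8 M run present a *smaller* osmotic
   driving force than the initial 0.5 M state yet moved much faster, which
   no memoryless flux law f(π_D, π_F, P) can produce. (Parameter sets that
   do force it — large-B leakage thresholds — stall the maximum-power
   feasibility run at start-up, contradicting the observed behaviour.) The
   point is kept as a reported holdout (`calibration.holdout_rmse`), never
   a fit constraint. Consequently the model's low-draw-concentration
   behaviour is its least certain regime: it recovers somewhat more water,
   faster, at 0.3–0.6 M draws than the reference system reports (e.g. the
   longest batch over a 0.1–2.0 M draw sweep comes out ≈18 h at 0.3 M
   rather than ≈21 h at 0.4 M).

Defaults (`defaults.DEFAULT_MEMBRANE`): A = 5.49×10⁻⁷ m³ m⁻² s⁻¹ bar⁻¹,
B = 2.0×10⁻⁷ m³ m⁻² s⁻¹, S = 1.38 mm, area 0.014 m².

## MEC stage

State: substrate S (mg/L), biomasses x_e, x_m (mg/L), oxidized mediator
fraction M_OX (mg-M/mg-x), anolyte protons (M), cumulative charge (C).
Bicarbonate is algebraic: the inherited pool scaled by the upstream
concentration factor plus 2(S₀−S)/m_S from oxidation. The current closes
algebraically from the state at every right-hand-side evaluation
(semi-explicit DAE treatment) and is floored at zero; LSODA integrates the
ODEs (rtol 10⁻⁸) with terminal events at the removal target and at the
charge equivalent of the energy budget. Q_MEC = E_ext·charge and
V_H₂ = Y_H₂·charge/(2F)·RT/P hold as exact identities of the trajectory
object, hence hydrogen can never exceed its coulombic maximum.

Two deliberate deviations from a literal transcription of the printed
model family, both flagged here:

- **Biomass growth signs.** The growth terms are implemented positive
  (dx/dt = +μ·(saturation)·x − d·x). With negative signs the populations
  could only decay, which contradicts the multi-population models this
  formulation descends from.
- **Mediator reduction rate.** The mediator balance's reduction term is
  Y_M·q_e,max·(S/(K_e+S))·(M_OX/(K_M+M_OX)) — mediator consumption
  proportional to the exoelectrogenic substrate-oxidation *rate*. The
  dimensionally irregular literal form (without the rate factor) is
  available via `MECParams(literal_mediator_term=True)` for comparison.

The proton balance d[H⁺]/dt = (β/m_S)(dS/dt)(9 − 8·CE·Y_H₂) is implemented
literally with β a *signed* calibration parameter. The calibrated default
is negative (−1.7×10⁻⁵), i.e. the anolyte acidifies slightly (pH 7 → ≈5.8
over a full cycle) as acetate is oxidized — the physically expected
direction at an anode, and the magnitude expected of a strongly
phosphate-buffered medium. [H⁺] is floored at 10⁻¹⁴ M as a numerical guard.
The cathode potential is fixed at pH 11 (the catholyte is unbuffered and
observed to settle there); cathode pH dynamics, carbonate speciation and
endogenous respiration are out of scope.

CE and Y_H₂ (Coulombic and cathodic efficiency) are per-scenario constants:
CE enters only the proton balance, Y_H₂ only the charge→hydrogen
conversion. Single runs at 0.6/0.8/1.0 V use the measured per-voltage
values; sweeps pin both to the base scenario's values (default: the 0.8 V
feasibility values, CE = 57.5 %, Y_H₂ = 48.1 %) so a voltage grid varies
only the electrical driving force — this is also the only reading
consistent with the reference sweep's hydrogen numbers.

## MEC calibration

Five parameters — R_min, Y_M, x_m0, μ_m,max and β — are fitted to seven
anchors of the reference cell: peak currents 2.7/4.5/6.6 mA at
0.6/0.8/1.0 V, and full-cycle (99.9 % removal) charge and duration at 0.5 V
(178 C, 68.8 h) and 0.8 V (610 C, 46.9 h). The Nernst potentials already
fix the thermodynamic deficit near 0.34 V, so the peak currents pin the
ohmic scale (R_in ≈ 97 Ω; x_e0 = 400 mg/L puts R_in on its R_min plateau,
as the near-linear observed current–voltage response requires); Y_M sets
the charge harvested per unit of exoelectrogenic substrate; x_m0 and
μ_m,max set the current-free substrate sink; β shapes the late-cycle
decline. Each anchor is its own relative residual (heterogeneous
quantities must not share a normalization). The fit lands within ~3 % on
every anchor. Remaining kinetic constants (q_max, μ_e, K's, γ, M_Total, ε,
n = 2, E_A⁰ = 0.187 V, E_C⁰ = 0) are literature-typical values for
acetate-fed anode biofilms.

## Fitting machinery

`calibration.fit` is bounded least squares (scipy `trf`) in log-parameter
space with a deterministic midpoint start plus seeded random multistarts;
the reported per-series error is the relative RMSE
100·√(Σ(y−ŷ)²/N)/max(ŷ) normalized by the *observed* series maximum.
`make_fixture` produces seeded multiplicative-Gaussian perturbations of
forward simulations for parameter-recovery studies; at the bench logging
rate (2-min volume sampling) and 2 % noise, (A, S_struct) recover to within
10 % across seeds, and recovery error shrinks with the noise level.

## What the synthetic fixtures do and do not show

Recovery fixtures perturb the model's own forward simulations with i.i.d.
multiplicative noise; they validate the estimator (identifiability,
determinism, noise response), not the model's adequacy for real membranes —
real residuals are autocorrelated (fouling drift, temperature) and the
0.5 M holdout shows a structural, not stochastic, misfit. Passing recovery
tests therefore says "the fit recovers parameters when the model is true",
no more.

## Numerical choices and degenerate inputs

Flux bracket [0, A·π_D] with warm-started tight re-bracketing from the
previous step; zero driving force returns a length-1 trajectory with
Q = 0; an energy budget of exactly 0 J returns an immediate-stop MEC
trajectory; S = 0 or M_OX = M_Total force zero current (infinite
overpotential); exoelectrogen extinction guards the mediator reoxidation
term. PRO problem sizes in the shipped scenarios: ≈900 steps for the
feasibility run, ≤5,800 for the longest sweep batches; MEC cycles
integrate 2–11 simulated days in a few thousand adaptive steps.

## Known limitations

No membrane fouling, no spatial discretization along the module, no pump or
turbine losses (the energy coupling is ideal), fixed temperature, fixed
cathode pH, no methane accounting, and the calibrated defaults inherit the
reference study's single feed chemistry. The low-draw-concentration PRO
regime is calibration-limited as described above.
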