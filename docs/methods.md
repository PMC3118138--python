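# Methods

## Model overview

`dynafba` implements dynamic flux balance analysis (DFBA) for anaerobic batch
yeast fermentations, in the static-optimization form: a constraint-based LP is
solved repeatedly over short intervals, and the resulting exchange rates drive
the bioreactor mass balances between solves.

Each interval of length Δt (default 0.5 h):

1. **Fixed constraints** (applied once, before the loop): the anaerobic set —
   oxygen uptake pinned to zero; the TCA cycle split into an oxidative and a
   reductive branch by zeroing the succinate-dehydrogenase and succinyl-CoA
   ligase steps; quinone-mediated NADH/FADH2 reoxidation turned off; sterol
   uptake made non-limiting (yeast cannot synthesize sterols anaerobically);
   phosphate/sulphate supply non-limiting — plus any genetic modifications
   (deletions, insertions, expression changes), which hold for the whole run.
2. **Dynamic constraints**: sugar and nitrogen transport kinetics, the
   stress-dependent maintenance-ATP floor, and the time-medium-specific
   biomass equation, all recomputed from the current state.
3. **LP**: maximize growth while assimilable nitrogen (YAN) remains above an
   exhaustion threshold; afterwards minimize maintenance ATP with the growth
   flux pinned to zero. Every solve is lexicographic: the primary optimum is
   fixed (relative tolerance 1e-6) and total flux magnitude Σ|v| is minimized,
   so trajectories do not depend on which optimal vertex the solver happens to
   return.
4. **Integration**: with the growth rate μ and specific exchange rates q_i
   held constant, dX/dt = μX and dM_i/dt = q_i X have the exact solution
   X(t+Δt) = X e^{μΔt}, M_i(t+Δt) = M_i + q_i X (e^{μΔt} − 1)/μ (limit q_i X Δt
   as μ → 0). If a consumed species would cross zero inside the interval, the
   interval is cut at the analytically computed crossing time and the
   remainder re-solved, so concentrations are never negative.

The loop terminates when total sugars fall below a residual threshold
(default 3 g/L, a "dry" fermentation), when the LP is infeasible after a
single retry with the maintenance floor relaxed by 50% (to separate numerical
edge cases from true metabolic infeasibility), or at a safety time cap
(1000 h).

## Transport-limited sugar uptake

Hexose transport is treated as the rate-limiting step of nitrogen-limited
fermentations: the sugar exchange fluxes are *pinned at* the kinetic
transporter capacity (not merely bounded by it), and the LP distributes the
incoming carbon. This is what lets fermentation continue after nitrogen
exhaustion — the biological behaviour of wine yeast, where most sugar is
consumed by a non-growing population — independent of the maintenance
formulation. With a pure bound, the stationary-phase objective (minimize
maintenance ATP) would consume no sugar at all once the maintenance floor is
removed, and a zero-maintenance ablation could never finish.

The capacity for each sugar is Michaelis–Menten with competitive inhibition
by the other hexose, non-competitive inhibition by ethanol, and Arrhenius
temperature scaling:

    u_glc = vmax_glc(T) · G / (K_g (1 + F/K_ig) + G) · K_i/(K_i + E)
    vmax(T) = vmax_ref · exp(−E_a/R (1/T_K − 1/T_ref,K))

and symmetrically for fructose. Glucose has the higher affinity (glucophilic
uptake), so glucose is exhausted first, as observed.

Nitrogen compounds (ammonia and a pooled amino acid, both tracked in
mg N/L) share a single saturable uptake capacity v_N = vmax_N·YAN/(K_N+YAN)
in proportion to their share of current YAN — competition for a limited
transporter pool. The allocation conserves total nitrogen flux exactly.

## Maintenance

The maintenance-ATP floor is a hinge function of the stressors known to raise
non-growth energy expenditure:

    m_ATP = m0 + a_eth·max(0, E − E_thr) + a_T·max(0, T − T_thr)
          + a_slug·[YAN₀ < N_slug]

The sluggish surcharge keys on the culture's *initial* YAN (a culture-level
property), so maintenance does not jump when nitrogen is consumed normally. A
legacy mode replaces the whole expression with the constant 1 mmol/gDW/h used
by earlier genome-scale models, for ablation comparisons.

The empirical dependencies here were originally lookup-table fits; this
package uses closed forms with the same monotone structure because they are
testable and parameterizable, and every constant is overridable from the
config.

## Time-medium-specific biomass equation

The biomass pseudo-reaction is rebuilt every interval: the storage
carbohydrate fraction follows c(f) = c_min + (c_max − c_min)·f^k, where f is
the fraction of initial sugar consumed, and the remaining macromolecular
fractions (protein, lipid, RNA, DNA) are rescaled proportionally so the
composition always sums to 1 g/gDW. Precursor coefficients are
fraction/MW (mmol/gDW), making the biomass flux the specific growth rate in
1/h; a growth-associated ATP cost (60 mmol ATP/gDW) is included. A legacy
mode freezes the composition.

## The toy network

All tests and the acceptance script run on a ~43-reaction, one-compartment,
elementally balanced (C, H, O, N audited exactly) caricature of wine-yeast
metabolism with integer-friendly molar masses, so carbon closure can be
checked by hand. Key design features:

* **Redox coupling.** Glycolysis→ethanol is NADH-neutral; amino-acid and
  nucleotide synthesis from sugar and ammonia release NADH. Anaerobic growth
  therefore *requires* the glycerol branch (glc + 2 ATP + 2 NADH → 2
  glycerol) as a redox valve.
* **Maintenance as oxidative turnover.** The maintenance reaction hydrolyses
  1 ATP and additionally oxidizes a small amount of sugar
  (0.01 glc + 0.12 NAD⁺ → 0.06 CO2 + 0.12 NADH per ATP), representing
  protein/membrane turnover. This is what couples maintenance load to
  glycerol production: stress → higher maintenance → more reducing
  equivalents → more glycerol and less ethanol, the direction observed
  experimentally. A separate uncoupled ATP hydrolysis (ATPSLIP) absorbs
  surplus ATP without byproducts, so the coupling is exactly the declared
  0.12 NADH per maintenance ATP.
* **Split vs complete TCA.** The reductive branch (OAA→malate→fumarate→
  succinate) and the oxidative branch (pyruvate+OAA→2-oxoglutarate→succinate)
  are present; the ligase and dehydrogenase steps are tagged and pinned under
  anaerobiosis. Because those steps are written reversible, un-splitting the
  cycle opens a *reducing cycle* (succinate → 2-oxoglutarate → pyruvate,
  reversing the oxidative steps) that consumes NADH and fixes CO2 — so a
  complete cycle strictly lowers glycerol and raises ethanol, as reported for
  unconstrained-TCA simulations. Succinate secretion is capped at a trace
  (0.002 mmol/gDW/h): with a generous outlet, the flux-parsimony tie-break
  discovers an unintended ATP-dumping loop through the oxidative branch that
  reverses the effect.
* **Quinone sinks.** Quinone-mediated reoxidation is modelled as terminal
  electron disposal (NADH → NAD⁺ + H; FADH2 → FAD + 2H): elementally balanced
  but deliberately not redox-balanced, mirroring the modelling artifact being
  studied — these reactions accept electrons without requiring oxygen, and
  when enabled anaerobically they usurp glycerol's redox role.
* **Sterols.** Biomass carries a fixed 0.005 g/gDW sterol requirement carved
  out of the lipid fraction; sterol synthesis needs O2, so anaerobic growth
  requires the sterol-uptake relaxation (limiting it stalls growth).
* **Trace by-products.** Acetate secretion and the acetoin/butanediol route
  are capped at 0.05 mmol/gDW/h, keeping them at the observed trace levels
  and preventing them from acting as unbounded redox/ATP valves.

## Default parameters (the benchmark study condition)

The benchmark condition is 28 °C, 300 mg N/L YAN (40% ammonia / 60% amino
acid), 233 g/L sugars (equal glucose/fructose), 0.1 gDW/L inoculum. Defaults
were chosen once so this condition completes in 100–150 h with qualitatively
correct profiles, and are all overridable:

| parameter | value | units |
|---|---|---|
| vmax_ref glc / fru | 4.2 / 4.0 | mmol/gDW/h at 28 °C |
| K_g / K_f | 1.0 / 2.0 | g/L |
| K_ig / K_if (cross-inhibition) | 20 / 10 | g/L |
| K_i ethanol | 150 | g/L |
| E_a | 60 | kJ/mol |
| vmax_N / K_N | 35 / 30 | mg N/gDW/h, mg N/L |
| m0 | 1.2 | mmol ATP/gDW/h |
| a_eth / E_thr | 0.01 / 31.6 | per g/L above ~4% v/v |
| a_T / T_thr | 0.12 / 30 | per °C |
| a_sluggish / N_sluggish | 1.0 / 140 | mmol ATP/gDW/h, mg N/L |
| c_min / c_max / k_c | 0.25 / 0.45 / 2 | g/gDW |
| GAM (biomass ATP) | 60 | mmol ATP/gDW |

With these defaults the benchmark finishes at 149 h with 109.5 g/L ethanol,
10.5 g/L glycerol, 2.0 gDW/L biomass, and machine-precision carbon closure.

## Numerical choices

* LP backend: scipy's HiGHS interface (feasibility and optimality tolerances
  1e-9), behind a single `solve(c, A_eq, b_eq, bounds, ...)` contract so other
  backends can be plugged. Status codes map to optimal/infeasible/unbounded;
  anything else raises.
* "Infinity" bounds are ±1000 mmol/gDW/h — a solver-safe big-M exceeding any
  physiological flux.
* Composed bounds with lb > ub report infeasibility rather than raising, so
  contradictory patches surface as a trajectory termination reason.
* Flux parsimony (stage 2) uses variable splitting (min Σt, −t ≤ v ≤ t);
  ties are then resolved identically on every run of the same platform.
* The nitrogen-exhaustion switch is boundary-inclusive on the stationary side
  (YAN ≤ threshold → minimize maintenance).
* Genetic bound overrides are re-asserted after dynamic patches, so a
  knockout can never be relaxed by a kinetic bound.

## What the synthetic data do and do not show

The synthetic "experiments" resample a simulated trajectory with
multiplicative Gaussian noise (default CV 5%, the reported precision of
triplicate measurements) and clamp at zero. They validate the scoring
pipeline (interpolation, correlation, relative-change scores) and the
determinism of the stack — they cannot validate the kinetic parameter values
against real fermentations, since they inherit the simulator's own dynamics.
Likewise the toy network demonstrates the *mechanistic couplings* (redox →
glycerol, maintenance → glycerol, constraint ablations) rather than
genome-scale flux predictions; absolute concentrations from the toy are
order-of-magnitude realistic but not fitted to any strain.

## Known limitations

* Viable biomass is treated as total biomass; there is no death phase, so
  late-fermentation biomass declines seen experimentally are not reproduced.
* Volume is constant (no fed-batch), CO2 is tracked as cumulative evolved
  mass without stripping dynamics, and pH is not modelled.
* The stationary-phase LP is only meaningfully constrained because sugar
  uptake is transport-pinned; under a pure uptake bound the min-ATP phase is
  degenerate.
* Genome-scale SBML models load through the optional cobra reader, but the
  kinetic layer expects the canonical species ids (glc, fru, nh4, aa, etoh,
  ...) on the exchanged metabolites; mapping arbitrary reconstruction
  namespaces is the user's responsibility.
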