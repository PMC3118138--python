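"""The outer dynamic loop: kinetic bounds -> LP -> mass-balance integration.

Each interval (default 30 min) the simulator (1) evaluates the temperature
profile, (2) rebuilds the dynamic bounds and the time-medium-specific biomass
equation from the current state, (3) picks the phase objective (maximize growth
while assimilable nitrogen remains; minimize maintenance ATP with growth pinned
to zero after exhaustion), (4) solves the LP with flux-parsimony tie-breaking,
and (5) integrates the bioreactor mass balances with the exchange rates held
constant:

    dX_V/dt = mu * X_V           dM_i/dt = q_i * X_V

whose exact solution over an interval is X_V(t+dt) = X_V e^{mu dt} and
M_i(t+dt) = M_i + q_i X_V (e^{mu dt} - 1)/mu.  If any species would cross zero
inside the interval, the interval is cut at the earliest crossing and the
remainder re-solved (so concentrations never go negative).  The loop stops on
sugar exhaustion, LP infeasibility (after a single maintenance-relaxation
retry), or a safety time cap.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .fba import FluxDistribution, select_objective, solve_parsimonious
from .kinetics import (
    BiomassComposition,
    KineticParameters,
    NitrogenCompound,
    PrecursorSet,
    biomass_equation,
    maintenance_lower_bound,
    nitrogen_uptake_bounds,
    sugar_uptake_bounds,
)
from .model import (
    INF,
    ConstraintPatch,
    GeneticModification,
    MetabolicModel,
    apply_anaerobic_constraints,
    apply_genetic_modifications,
)
from .state import FRUCTOSE, GLUCOSE, FermentationState, temperature_at

_MIN_SUBSTEP = 1e-9


@dataclass
class SimulationConfig:
    """Everything the dynamic loop needs besides the model and initial state."""

    step: float = 0.5  # h
    temperature: object = 28.0  # degC, or [(t_h, degC), ...]
    sugar_threshold: float = 3.0  # g/L, termination threshold on total sugars
    N_exhaust: float = 1.0  # mg N/L, objective-switch threshold
    max_time: float = 1000.0  # h, safety stop
    params: KineticParameters = field(default_factory=KineticParameters)
    composition: BiomassComposition | None = None
    precursors: PrecursorSet | None = None
    nitrogen_compounds: list[NitrogenCompound] = field(
        default_factory=lambda: [NitrogenCompound("nh4", 14.0), NitrogenCompound("aa", 14.0)]
    )
    biomass_reaction: str = "BIOMASS"
    maintenance_reaction: str = "ATPM"
    modifications: list[GeneticModification] = field(default_factory=list)
    # fixed-constraint toggles (ablation studies)
    apply_anaerobic: bool = True
    enable_quinones: bool = False
    complete_tca: bool = False
    allow_oxygen: bool = False
    limit_sterols: bool = False
    # legacy modes
    legacy_maintenance: bool = False  # constant 1 mmol/gDW/h
    legacy_biomass: bool = False  # time-invariant composition
    zero_maintenance: bool = False  # maintenance lb = 0 (ablation)
    unbounded_maintenance: bool = False  # maintenance free, no lb (ablation)
    bilevel_tol: float = 1e-6
    #: optional callable (f_consumed, legacy) -> g C per gDW, for carbon
    #: accounting; defaults to the toy network's composition-derived value
    carbon_fraction_fn: object = None

    @property
    def nitrogen_species(self) -> list[str]:
        return [c.species for c in self.nitrogen_compounds]

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "step", "temperature", "sugar_threshold", "N_exhaust", "max_time",
                "apply_anaerobic", "enable_quinones", "complete_tca", "allow_oxygen",
                "limit_sterols", "legacy_maintenance", "legacy_biomass",
                "zero_maintenance", "unbounded_maintenance", "bilevel_tol",
            )
        }
        d["params"] = self.params.to_dict()
        d["nitrogen_compounds"] = [
            {"species": c.species, "mg_n_per_mmol": c.mg_n_per_mmol}
            for c in self.nitrogen_compounds
        ]
        return d


@dataclass
class Trajectory:
    """Time-ordered (state, flux) pairs plus termination reason and metadata.

    ``entries[i]`` holds the state at time t_i and the flux distribution
    applied over [t_i, t_{i+1}); the final entry carries no fluxes.
    ``biomass_carbon`` is the cumulative carbon bound in biomass (g C/L),
    aligned with entries.
    """

    entries: list[tuple[FermentationState, FluxDistribution | None]]
    termination: str  # sugar_exhausted | infeasible | max_time
    metadata: dict = field(default_factory=dict)
    biomass_carbon: list[float] = field(default_factory=list)

    @property
    def states(self) -> list[FermentationState]:
        return [s for s, _ in self.entries]

    @property
    def final_state(self) -> FermentationState:
        return self.entries[-1][0]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s, _ in self.entries:
            row = {"time_h": s.t, "temperature_C": s.T, "biomass_gDW_L": s.X_V}
            row.update(s.M_EX)
            rows.append(row)
        return pd.DataFrame(rows)

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.10g")

    def manifest(self) -> dict:
        return dict(self.metadata, termination=self.termination)


# ---------------------------------------------------------------------------
# Dynamic bounds (block 1)
# ---------------------------------------------------------------------------


def build_dynamic_bounds(
    state: FermentationState, model: MetabolicModel, config: SimulationConfig
) -> tuple[ConstraintPatch, MetabolicModel]:
    """Kinetic bounds for the current state, plus the current biomass equation.

    Returns the ``dynamic`` patch and the model with the biomass reaction
    rebuilt for the current sugar-consumption fraction (the stoichiometry of
    the time-medium-specific biomass equation cannot be expressed as a bound
    override).  Uptake bounds follow the sign convention: a maximum uptake u
    becomes lower bound -u on the exchange flux.  Exchanges of tracked species
    at zero concentration are closed to uptake.
    """
    patch = ConstraintPatch(label="dynamic")
    p = config.params

    # Sugar transport is the rate-limiting step: the exchange flux is pinned
    # at the kinetic transporter capacity (uptake negative), and the LP
    # distributes the incoming sugar.  An absent sugar pins the flux to zero.
    ub_glc, ub_fru = sugar_uptake_bounds(state, p)
    for sp, ub in ((GLUCOSE, ub_glc), (FRUCTOSE, ub_fru)):
        rid = model.exchange_map.get(sp)
        if rid is not None:
            patch.set(rid, -ub, -ub)

    n_bounds = nitrogen_uptake_bounds(state, p, config.nitrogen_compounds)
    for c in config.nitrogen_compounds:
        rid = model.exchange_map.get(c.species)
        if rid is not None:
            patch.set(rid, -n_bounds[c.species], 0.0)

    if model.has_reaction(config.maintenance_reaction):
        rxn = model.reaction(config.maintenance_reaction)
        if config.zero_maintenance:
            patch.set(rxn.id, 0.0, rxn.ub)
        elif not config.unbounded_maintenance:
            m = maintenance_lower_bound(state, p, legacy=config.legacy_maintenance)
            patch.set(rxn.id, m, max(rxn.ub, m))

    # close uptake for any tracked species that has run out
    for sp, conc in state.M_EX.items():
        rid = model.exchange_map.get(sp)
        if rid is None or rid in patch:
            continue
        if conc <= 1e-12 and model.reaction(rid).lb < 0:
            patch.set(rid, 0.0, model.reaction(rid).ub)

    if config.composition is not None and model.has_reaction(config.biomass_reaction):
        bm = biomass_equation(
            state.f_consumed,
            config.composition,
            p,
            config.precursors,
            legacy=config.legacy_biomass,
            reaction_id=config.biomass_reaction,
        )
        model = model.replace_reaction(bm)
    return patch, model


def build_fixed_patches(model: MetabolicModel, config: SimulationConfig) -> list[ConstraintPatch]:
    """Anaerobic constraint set plus the configured ablation overrides."""
    patches: list[ConstraintPatch] = []
    if config.apply_anaerobic:
        patches.append(apply_anaerobic_constraints(model))
        ablate = ConstraintPatch(label="fixed")
        restore: list[str] = []
        if config.enable_quinones:
            restore += [r.id for r in model.tagged("quinone")]
        if config.complete_tca:
            restore += [r.id for r in model.tagged("tca_oxidative_break")]
        if config.allow_oxygen:
            restore += [r.id for r in model.tagged("oxygen_uptake")]
        for rid in restore:
            r = model.reaction(rid)
            ablate.set(rid, r.lb, r.ub)
        if config.limit_sterols:
            for r in model.tagged("sterol_uptake"):
                ablate.set(r.id, r.lb, r.ub)  # keep the model's own (limiting) bound
        if ablate.bounds:
            patches.append(ablate)
    return patches


# ---------------------------------------------------------------------------
# Integration (block 3)
# ---------------------------------------------------------------------------


def _specific_rates(
    fluxes: FluxDistribution, model: MetabolicModel, config: SimulationConfig
) -> dict[str, float]:
    """Exchange fluxes converted to medium units: g/gDW/h (mg N/gDW/h for
    nitrogen compounds, which are tracked as mg N/L)."""
    n_content = {c.species: c.mg_n_per_mmol for c in config.nitrogen_compounds}
    rates: dict[str, float] = {}
    for sp, rid in model.exchange_map.items():
        v = fluxes.get(rid, 0.0)
        if sp in n_content:
            rates[sp] = v * n_content[sp]  # mmol/gDW/h * mgN/mmol
        else:
            mw = model.metabolite(sp).mw
            if mw is None:
                continue  # untracked boundary species (water, protons, O2)
            rates[sp] = v * mw / 1000.0  # g/gDW/h
    return rates


def _growth_factor(mu: float, dt: float) -> float:
    """(e^{mu dt} - 1)/mu, with the dt limit as mu -> 0."""
    if abs(mu * dt) < 1e-12:
        return dt
    return math.expm1(mu * dt) / mu


def integrate_interval(
    state: FermentationState,
    fluxes: FluxDistribution,
    model: MetabolicModel,
    dt: float,
    config: SimulationConfig,
    sugar0: float | None = None,
) -> FermentationState:
    """Advance the state by up to ``dt`` hours with rates held constant.

    Exact solution of the batch mass balances; if a consumed species would
    cross zero the interval is cut at the earliest crossing (the species is
    then exactly zero).  Untracked species are ignored.  ``sugar0`` (initial
    total sugar, g/L) updates ``f_consumed``; defaults to the value implied by
    the state's current f_consumed.
    """
    if dt <= 0:
        raise ConfigError(f"dt must be > 0, got {dt}")
    mu = fluxes.get(config.biomass_reaction, 0.0) if fluxes is not None else 0.0
    if abs(mu) < 1e-12:
        mu = 0.0
    rates = _specific_rates(fluxes, model, config) if fluxes is not None else {}

    # earliest zero crossing among consumed species
    dt_eff = dt
    crossing: str | None = None
    for sp, q in rates.items():
        M = state.conc(sp)
        if q >= 0 or M <= 0:
            continue
        qX = q * state.X_V
        if mu == 0.0:
            t_star = -M / qX
        else:
            arg = 1.0 - M * mu / qX
            t_star = math.log(arg) / mu if arg > 0 else float("inf")
        if t_star < dt_eff - 1e-15:
            dt_eff, crossing = t_star, sp
    dt_eff = max(dt_eff, _MIN_SUBSTEP)

    growth = math.exp(mu * dt_eff)
    factor = _growth_factor(mu, dt_eff) * state.X_V
    new_M = dict(state.M_EX)
    for sp, q in rates.items():
        if sp in new_M:
            new_M[sp] = max(0.0, state.conc(sp) + q * factor)
    if crossing is not None:
        new_M[crossing] = 0.0

    new = FermentationState(
        t=state.t + dt_eff,
        T=state.T,
        X_V=state.X_V * growth,
        M_EX=new_M,
        f_consumed=state.f_consumed,
        yan0=state.yan0,
    )
    if sugar0 and sugar0 > 0:
        new.f_consumed = min(1.0, max(0.0, (sugar0 - new.total_sugar) / sugar0))
    return new


# ---------------------------------------------------------------------------
# The loop (blocks 1-3)
# ---------------------------------------------------------------------------


def _solve_step(model, patches, objective, config):
    """One production solve, with the single maintenance-relaxation retry on
    infeasibility during the stationary phase."""
    dist = solve_parsimonious(model, patches, objective, tol=config.bilevel_tol)
    if dist.optimal or objective.sense != "min":
        return dist
    # retry once with maintenance lb relaxed by 50%
    relaxed = []
    for p in patches:
        if config.maintenance_reaction in p and p.label == "dynamic":
            q = ConstraintPatch(label="dynamic", bounds=dict(p.bounds))
            lo, hi = q.bounds[config.maintenance_reaction]
            q.bounds[config.maintenance_reaction] = (lo * 0.5, hi)
            relaxed.append(q)
        else:
            relaxed.append(p)
    return solve_parsimonious(model, relaxed, objective, tol=config.bilevel_tol)


def simulate(
    initial: FermentationState,
    model: MetabolicModel,
    config: SimulationConfig,
) -> Trajectory:
    """Run a batch fermentation to sugar exhaustion, infeasibility or timeout."""
    if config.carbon_fraction_fn is not None:
        biomass_carbon_fraction = config.carbon_fraction_fn
    else:
        from .toy import biomass_carbon_fraction  # default carbon accounting

    genetic_patch, model = apply_genetic_modifications(model, config.modifications)
    fixed = build_fixed_patches(model, config)
    base_patches = fixed + ([genetic_patch] if genetic_patch.bounds else [])

    state = initial.copy()
    if state.yan0 is None:
        state.yan0 = state.yan(config.nitrogen_species)
    sugar0 = state.total_sugar
    if sugar0 > 0:
        state.f_consumed = min(1.0, max(0.0, (sugar0 - state.total_sugar) / sugar0))

    entries: list[tuple[FermentationState, FluxDistribution | None]] = []
    biomass_carbon = [0.0]
    cum_bc = 0.0
    termination = "max_time"

    while True:
        if state.total_sugar <= config.sugar_threshold:
            termination = "sugar_exhausted"
            break
        if state.t >= config.max_time:
            termination = "max_time"
            break
        state.T = temperature_at(config.temperature, state.t)

        remaining = config.step
        infeasible = False
        while remaining > _MIN_SUBSTEP:
            dyn, model_step = build_dynamic_bounds(state, model, config)
            objective = select_objective(state, config)
            if objective.clamp_growth and model_step.has_reaction(config.biomass_reaction):
                dyn.set(config.biomass_reaction, 0.0, 0.0)
            dist = _solve_step(model_step, base_patches + [dyn], objective, config)
            if not dist.optimal:
                infeasible = True
                break
            new_state = integrate_interval(
                state, dist, model_step, remaining, config, sugar0=sugar0
            )
            used = new_state.t - state.t
            cum_bc += (new_state.X_V - state.X_V) * biomass_carbon_fraction(
                state.f_consumed, legacy=config.legacy_biomass
            )
            entries.append((state, dist))
            biomass_carbon.append(cum_bc)
            state = new_state
            remaining -= used
            if state.total_sugar <= config.sugar_threshold:
                break
        if infeasible:
            termination = "infeasible"
            break

    entries.append((state, None))
    cfg = config.to_dict()
    metadata = {
        "solver": "scipy-highs",
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "n_steps": len(entries) - 1,
    }
    return Trajectory(
        entries=entries,
        termination=termination,
        metadata=metadata,
        biomass_carbon=biomass_carbon,
    )


# ---------------------------------------------------------------------------
# Carbon accounting
# ---------------------------------------------------------------------------


def carbon_totals(traj: Trajectory, model: MetabolicModel, config: SimulationConfig) -> np.ndarray:
    """Total elemental carbon (g C/L) in medium + biomass at every recorded
    state.  Constant over a trajectory when the network is carbon-balanced and
    the integration exact."""
    n_species = set(config.nitrogen_species)
    n_content = {c.species: c.mg_n_per_mmol for c in config.nitrogen_compounds}
    totals = []
    for (s, _), bc in zip(traj.entries, traj.biomass_carbon):
        total = bc
        for sp, conc in s.M_EX.items():
            met = model.metabolite(sp) if sp in model.exchange_map else None
            if met is None or met.formula is None:
                continue
            n_c = met.elements.get("C", 0.0)
            if n_c == 0:
                continue
            if sp in n_species:
                mmol_per_l = conc / n_content[sp]  # mg N/L / (mg N/mmol)
            else:
                mmol_per_l = conc / met.mw * 1000.0  # g/L / (g/mol) * 1000
            total += mmol_per_l * n_c * 12.0 / 1000.0  # g C/L
        totals.append(total)
    return np.asarray(totals)


def carbon_closure_error(traj: Trajectory, model: MetabolicModel, config: SimulationConfig) -> float:
    """Max relative deviation of total carbon from its initial value."""
    totals = carbon_totals(traj, model, config)
    return float(np.max(np.abs(totals - totals[0])) / totals[0])
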