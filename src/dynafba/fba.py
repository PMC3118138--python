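"""Flux balance analysis: LP solves, objective switching, bi-level optimization.

The LP is  optimize c·v  subject to  S·v = 0,  lb <= v <= ub,  where S is the
stoichiometric matrix and the bounds come from composing the model's intrinsic
bounds with fixed/dynamic/genetic constraint patches.

Because FBA optima are routinely degenerate, every production solve inside the
dynamic loop goes through :func:`solve_parsimonious`: the primary optimum is
fixed (within a small tolerance) and total flux magnitude sum|v| is minimized,
which makes exchange rates — and hence whole trajectories — reproducible
independent of solver internals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .errors import DimensionMismatchError, SolverError
from .model import ConstraintPatch, MetabolicModel

FEASIBILITY_TOL = 1e-9
OPTIMALITY_TOL = 1e-9
BILEVEL_TOL = 1e-6


@dataclass(frozen=True)
class Objective:
    """An LP objective: optimize the flux of one reaction.

    ``clamp_growth`` marks the stationary-phase objective, where the dynamic
    layer pins the growth flux to zero while maintenance ATP is minimized.
    """

    sense: str  # "max" | "min"
    reaction_id: str
    clamp_growth: bool = False

    def __post_init__(self):
        if self.sense not in ("max", "min"):
            raise ValueError(f"objective sense must be max or min, got {self.sense!r}")


@dataclass
class FluxDistribution:
    """An LP solution: flux vector, objective value and solver status."""

    reaction_ids: list[str]
    v: np.ndarray
    objective_value: float
    status: str  # "optimal" | "infeasible" | "unbounded"

    def __getitem__(self, rxn_id: str) -> float:
        return float(self.v[self.reaction_ids.index(rxn_id)])

    def get(self, rxn_id: str, default: float = 0.0) -> float:
        try:
            return self[rxn_id]
        except ValueError:
            return default

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


class ScipyHighsBackend:
    """LP backend over scipy's HiGHS interface.

    Implements the single-solve contract ``solve(c, A_eq, b_eq, bounds,
    A_ub=None, b_ub=None)`` minimizing ``c @ x``; any backend honouring the
    same contract and status vocabulary can be substituted.
    """

    name = "scipy-highs"
    _status_map = {0: "optimal", 2: "infeasible", 3: "unbounded"}

    def solve(self, c, A_eq, b_eq, bounds, A_ub=None, b_ub=None):
        res = scipy.optimize.linprog(
            c,
            A_eq=A_eq,
            b_eq=b_eq,
            A_ub=A_ub,
            b_ub=b_ub,
            bounds=bounds,
            method="highs",
            options={
                "primal_feasibility_tolerance": FEASIBILITY_TOL,
                "dual_feasibility_tolerance": OPTIMALITY_TOL,
            },
        )
        status = self._status_map.get(res.status)
        if status is None:
            raise SolverError(f"LP backend failure: {res.message}")
        return status, res.x, res.fun


DEFAULT_BACKEND = ScipyHighsBackend()


def _prepare(model: MetabolicModel, patches, objective: Objective):
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays(patches)
    n = len(model.reactions)
    if S.shape[1] != n or lb.shape[0] != n:
        raise DimensionMismatchError(
            f"matrix has {S.shape[1]} columns for {n} reactions"
        )
    if not model.has_reaction(objective.reaction_id):
        raise DimensionMismatchError(
            f"objective reaction {objective.reaction_id!r} not in model"
        )
    c = np.zeros(n)
    c[model.reaction_index(objective.reaction_id)] = (
        -1.0 if objective.sense == "max" else 1.0
    )
    return S, lb, ub, c


def solve_fba(
    model: MetabolicModel,
    patches: list[ConstraintPatch] | None,
    objective: Objective,
    backend=DEFAULT_BACKEND,
) -> FluxDistribution:
    """Solve a single FBA LP; returns the status faithfully (no exception for
    infeasible or unbounded problems, including composed bounds with lb > ub).
    """
    S, lb, ub, c = _prepare(model, patches, objective)
    rids = [r.id for r in model.reactions]
    if np.any(lb > ub):
        return FluxDistribution(rids, np.zeros(len(rids)), float("nan"), "infeasible")
    status, x, fun = backend.solve(c, S, np.zeros(S.shape[0]), list(zip(lb, ub)))
    if status != "optimal":
        return FluxDistribution(rids, np.zeros(len(rids)), float("nan"), status)
    obj = -fun if objective.sense == "max" else fun
    return FluxDistribution(rids, np.asarray(x), float(obj), "optimal")


def select_objective(state, config) -> Objective:
    """Growth-phase vs stationary-phase objective.

    While assimilable nitrogen exceeds the exhaustion threshold the cell
    maximizes growth; at or below it (boundary inclusive on the stationary
    side) ATP consumption by maintenance is minimized with growth pinned to
    zero.  ``config`` must expose ``nitrogen_species``, ``N_exhaust``,
    ``biomass_reaction`` and ``maintenance_reaction``.
    """
    yan = state.yan(config.nitrogen_species)
    if yan > config.N_exhaust:
        return Objective("max", config.biomass_reaction)
    return Objective("min", config.maintenance_reaction, clamp_growth=True)


def _fix_primary_patch(objective: Objective, optimum: float, tol: float) -> ConstraintPatch:
    """A patch pinning the primary objective near its optimum for stage 2."""
    patch = ConstraintPatch(label="dynamic")
    slack = tol * max(1.0, abs(optimum))
    if objective.sense == "max":
        patch.set(objective.reaction_id, optimum - slack, np.inf)
    else:
        patch.set(objective.reaction_id, -np.inf, optimum + slack)
    return patch


def solve_bilevel(
    model: MetabolicModel,
    patches: list[ConstraintPatch] | None,
    primary: Objective,
    secondary: Objective,
    tol: float = BILEVEL_TOL,
    backend=DEFAULT_BACKEND,
) -> FluxDistribution:
    """Lexicographic two-stage solve.

    Stage 1 optimizes ``primary``; stage 2 fixes the primary flux at its
    optimum (within ``tol``, relative) and optimizes ``secondary`` over the
    optimal face.  A non-optimal stage 1 propagates unchanged.
    """
    stage1 = solve_fba(model, patches, primary, backend=backend)
    if not stage1.optimal:
        return stage1
    fix = _fix_primary_patch(primary, stage1.objective_value, tol)
    stage2 = solve_fba(model, (patches or []) + [fix], secondary, backend=backend)
    if not stage2.optimal:  # numerically tight face; fall back to stage 1
        return stage1
    stage2.objective_value = stage1.objective_value
    return stage2


def solve_parsimonious(
    model: MetabolicModel,
    patches: list[ConstraintPatch] | None,
    objective: Objective,
    tol: float = BILEVEL_TOL,
    backend=DEFAULT_BACKEND,
) -> FluxDistribution:
    """Bi-level solve with secondary = minimize sum|v| (flux parsimony).

    Used as the default tie-breaker for every solve inside the dynamic loop:
    among all flux distributions achieving the primary optimum, the one with
    minimal total flux is unique in practice and solver-independent.
    """
    S, lb, ub, c = _prepare(model, patches, objective)
    rids = [r.id for r in model.reactions]
    n = len(rids)
    if np.any(lb > ub):
        return FluxDistribution(rids, np.zeros(n), float("nan"), "infeasible")
    status, x, fun = backend.solve(c, S, np.zeros(S.shape[0]), list(zip(lb, ub)))
    if status != "optimal":
        return FluxDistribution(rids, np.zeros(n), float("nan"), status)
    opt = -fun if objective.sense == "max" else fun

    # stage 2: min sum t, with -t <= v <= t, S v = 0, primary pinned
    j = model.reaction_index(objective.reaction_id)
    slack = tol * max(1.0, abs(opt))
    lb2, ub2 = lb.copy(), ub.copy()
    if objective.sense == "max":
        lb2[j] = max(lb2[j], opt - slack)
    else:
        ub2[j] = min(ub2[j], opt + slack)
    A_eq = np.hstack([S, np.zeros((S.shape[0], n))])
    I = np.eye(n)
    A_ub = np.vstack([np.hstack([I, -I]), np.hstack([-I, -I])])
    b_ub = np.zeros(2 * n)
    c2 = np.concatenate([np.zeros(n), np.ones(n)])
    bounds2 = list(zip(lb2, ub2)) + [(0.0, None)] * n
    status2, x2, _ = backend.solve(c2, A_eq, np.zeros(S.shape[0]), bounds2, A_ub, b_ub)
    if status2 != "optimal":  # tight face: keep stage-1 solution
        return FluxDistribution(rids, np.asarray(x), float(opt), "optimal")
    return FluxDistribution(rids, np.asarray(x2[:n]), float(opt), "optimal")


def steady_state_residual(model: MetabolicModel, dist: FluxDistribution) -> float:
    """max |S @ v| — should be ~0 for any optimal solution."""
    return float(np.max(np.abs(model.stoichiometric_matrix() @ dist.v)))
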