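import numpy as np
import pytest

from dynafba.fba import (
    Objective,
    solve_bilevel,
    solve_fba,
    solve_parsimonious,
    select_objective,
    steady_state_residual,
)
from dynafba.model import (
    INF,
    ConstraintPatch,
    MetabolicModel,
    Metabolite,
    Reaction,
    apply_anaerobic_constraints,
)
from dynafba.state import FermentationState

from _oracles import brute_force_optimum


def chain_model(ub=10.0):
    """Aext -> A -> B -> Bext, all capacities ub."""
    mets = [
        Metabolite("Aext", compartment="e", mw=1.0, is_extracellular=True),
        Metabolite("Bext", compartment="e", mw=1.0, is_extracellular=True),
        Metabolite("A"),
        Metabolite("B"),
    ]
    rxns = [
        Reaction("EX_A", {"Aext": -1.0}, lb=-ub, ub=0.0),
        Reaction("T_in", {"Aext": -1.0, "A": 1.0}, ub=ub),
        Reaction("CONV", {"A": -1.0, "B": 1.0}, ub=ub),
        Reaction("T_out", {"B": -1.0, "Bext": 1.0}, ub=ub),
        Reaction("EX_B", {"Bext": -1.0}, lb=0.0, ub=ub),
    ]
    return MetabolicModel(mets, rxns)


def branch_model():
    """A 7-reaction branched network with an ATP-like cofactor coupling."""
    mets = [
        Metabolite("Sext", compartment="e", mw=1.0, is_extracellular=True),
        Metabolite("Pext", compartment="e", mw=1.0, is_extracellular=True),
        Metabolite("Qext", compartment="e", mw=1.0, is_extracellular=True),
        Metabolite("S"),
        Metabolite("x"),
    ]
    rxns = [
        Reaction("EX_S", {"Sext": -1.0}, lb=-8.0, ub=0.0),
        Reaction("UP", {"Sext": -1.0, "S": 1.0, "x": 1.0}, ub=8.0),
        Reaction("TO_P", {"S": -1.0, "x": -0.5, "Pext": 1.0}, ub=6.0),
        Reaction("TO_Q", {"S": -1.0, "x": -2.0, "Qext": 1.0}, ub=6.0),
        Reaction("XDUMP", {"x": -1.0}, ub=4.0),
        Reaction("EX_P", {"Pext": -1.0}, lb=0.0, ub=INF),
        Reaction("EX_Q", {"Qext": -1.0}, lb=0.0, ub=INF),
    ]
    return MetabolicModel(mets, rxns)


class TestSolveFba:
    def test_linear_chain_bottleneck(self):
        model = chain_model()
        dist = solve_fba(model, None, Objective("max", "EX_B"))
        assert dist.optimal
        assert dist.objective_value == pytest.approx(10.0)

    def test_optimum_matches_vertex_enumeration_oracle(self):
        for model, objective in [
            (chain_model(), Objective("max", "EX_B")),
            (branch_model(), Objective("max", "EX_P")),
            (branch_model(), Objective("max", "EX_Q")),
            (branch_model(), Objective("min", "EX_S")),
        ]:
            dist = solve_fba(model, None, objective)
            S = model.stoichiometric_matrix()
            lb, ub = model.bounds_arrays(None)
            c = np.zeros(len(model.reactions))
            c[model.reaction_index(objective.reaction_id)] = 1.0
            expected = brute_force_optimum(S, lb, ub, c, sense=objective.sense)
            assert dist.optimal
            assert dist.objective_value == pytest.approx(expected, abs=1e-8)

    def test_lb_above_ub_reports_infeasible_without_raising(self):
        model = chain_model()
        patch = ConstraintPatch("dynamic", {"CONV": (5.0, 5.0), "T_in": (0.0, 1.0)})
        # contradictory: CONV forced to 5 but feed capped at 1
        dist = solve_fba(model, [patch], Objective("max", "EX_B"))
        assert dist.status == "infeasible"
        bad = ConstraintPatch("dynamic")
        bad.bounds["CONV"] = (5.0, 1.0)  # lb > ub injected directly
        dist = solve_fba(model, [bad], Objective("max", "EX_B"))
        assert dist.status == "infeasible"

    def test_steady_state_residual_small(self, toy_model):
        patch = apply_anaerobic_constraints(toy_model)
        dyn = ConstraintPatch("dynamic", {"EX_glc": (-4.0, -4.0), "EX_nh4": (-1.0, 0.0),
                                          "EX_aa": (-1.0, 0.0), "ATPM": (1.2, INF)})
        dist = solve_parsimonious(toy_model, [patch, dyn], Objective("max", "BIOMASS"))
        assert dist.optimal
        assert steady_state_residual(toy_model, dist) <= 1e-7

    def test_deterministic(self, toy_model):
        patch = apply_anaerobic_constraints(toy_model)
        dyn = ConstraintPatch("dynamic", {"EX_glc": (-4.0, -4.0), "EX_nh4": (-1.0, 0.0)})
        a = solve_parsimonious(toy_model, [patch, dyn], Objective("max", "BIOMASS"))
        b = solve_parsimonious(toy_model, [patch, dyn], Objective("max", "BIOMASS"))
        assert np.array_equal(a.v, b.v)

    def test_added_constraints_never_increase_maximum(self):
        rng = np.random.default_rng(42)
        model = branch_model()
        best = solve_fba(model, None, Objective("max", "EX_P")).objective_value
        patches = []
        for _ in range(10):
            rxn = model.reactions[rng.integers(len(model.reactions))]
            hi = float(rng.uniform(0, rxn.ub if np.isfinite(rxn.ub) else 8.0))
            patches.append(ConstraintPatch("dynamic", {rxn.id: (max(rxn.lb, 0.0) if rxn.lb >= 0 else rxn.lb, hi)}))
            dist = solve_fba(model, patches, Objective("max", "EX_P"))
            if dist.optimal:
                assert dist.objective_value <= best + 1e-9
                best_now = dist.objective_value
                assert best_now <= best + 1e-9
                best = min(best, best_now)


class TestObjectiveSwitching:
    class Config:
        nitrogen_species = ["nh4", "aa"]
        N_exhaust = 1.0
        biomass_reaction = "BIOMASS"
        maintenance_reaction = "ATPM"

    def make_state(self, yan):
        return FermentationState(t=0, T=28, X_V=1.0, M_EX={"nh4": yan})

    def test_nitrogen_rich_maximizes_growth(self):
        obj = select_objective(self.make_state(300.0), self.Config)
        assert (obj.sense, obj.reaction_id, obj.clamp_growth) == ("max", "BIOMASS", False)

    def test_exhausted_minimizes_maintenance_with_growth_clamped(self):
        obj = select_objective(self.make_state(0.0), self.Config)
        assert (obj.sense, obj.reaction_id, obj.clamp_growth) == ("min", "ATPM", True)

    def test_boundary_is_closed_on_the_stationary_side(self):
        obj = select_objective(self.make_state(1.0), self.Config)
        assert obj.sense == "min"


class TestBilevel:
    def test_secondary_preserves_primary_optimum(self):
        model = branch_model()
        dist = solve_bilevel(model, None, Objective("max", "EX_P"), Objective("max", "EX_Q"))
        single = solve_fba(model, None, Objective("max", "EX_P"))
        assert dist.optimal
        assert dist["EX_P"] >= single.objective_value * (1 - 1e-5) - 1e-9

    def test_secondary_at_least_as_good_as_perturbed_primary_solves(self, toy_model):
        """Ethanol from the bi-level solve dominates the ethanol flux of any
        stage-1 optimal solution found under random cost perturbations."""
        patches = [apply_anaerobic_constraints(toy_model),
                   ConstraintPatch("dynamic", {"EX_glc": (-4.0, -4.0), "EX_fru": (-3.0, -3.0),
                                               "EX_nh4": (-0.8, 0.0), "EX_aa": (-0.8, 0.0),
                                               "ATPM": (1.2, INF)})]
        bi = solve_bilevel(toy_model, patches, Objective("max", "BIOMASS"), Objective("max", "EX_etoh"))
        assert bi.optimal
        mu_star = bi["BIOMASS"]
        rng = np.random.default_rng(7)
        S = toy_model.stoichiometric_matrix()
        lb, ub = toy_model.bounds_arrays(patches)
        from dynafba.fba import DEFAULT_BACKEND

        j = toy_model.reaction_index("BIOMASS")
        je = toy_model.reaction_index("EX_etoh")
        for _ in range(20):
            c = rng.normal(scale=1e-6, size=len(lb))
            c[j] = -1.0
            status, x, _ = DEFAULT_BACKEND.solve(c, S, np.zeros(S.shape[0]), list(zip(lb, ub)))
            assert status == "optimal"
            if x[j] >= mu_star * (1 - 1e-5):  # stage-1-optimal vertex
                assert bi["EX_etoh"] >= x[je] - 1e-6

    def test_unique_optimum_equals_single_level(self):
        model = chain_model()
        bi = solve_bilevel(model, None, Objective("max", "EX_B"), Objective("min", "CONV"))
        single = solve_fba(model, None, Objective("max", "EX_B"))
        assert np.allclose(bi.v, single.v, atol=1e-7)

    def test_stage1_infeasibility_propagates(self):
        model = chain_model()
        bad = ConstraintPatch("dynamic")
        bad.bounds["CONV"] = (5.0, 1.0)
        dist = solve_bilevel(model, [bad], Objective("max", "EX_B"), Objective("max", "EX_B"))
        assert dist.status == "infeasible"


def test_cross_check_against_cobrapy(toy_model):
    """Dual-route check: our simplex path vs cobrapy on the identical LP."""
    cobra = pytest.importorskip("cobra")
    patches = [apply_anaerobic_constraints(toy_model),
               ConstraintPatch("dynamic", {"EX_glc": (-4.0, -4.0), "EX_fru": (-3.0, -3.0),
                                           "EX_nh4": (-0.8, 0.0), "EX_aa": (-0.8, 0.0),
                                           "ATPM": (1.2, INF)})]
    ours = solve_fba(toy_model, patches, Objective("max", "BIOMASS"))

    cm = cobra.Model("toy")
    cmet = {m.id: cobra.Metabolite(m.id) for m in toy_model.metabolites}
    lb, ub = toy_model.bounds_arrays(patches)
    crxns = []
    for j, r in enumerate(toy_model.reactions):
        cr = cobra.Reaction(r.id, lower_bound=float(lb[j]), upper_bound=float(ub[j]))
        crxns.append(cr)
    cm.add_reactions(crxns)
    for j, r in enumerate(toy_model.reactions):
        cm.reactions.get_by_id(r.id).add_metabolites(
            {cmet[m]: c for m, c in r.stoichiometry.items()}
        )
    cm.objective = "BIOMASS"
    sol = cm.optimize()
    assert sol.status == "optimal"
    assert ours.objective_value == pytest.approx(sol.objective_value, abs=1e-6)
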