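import warnings

import pytest

from dynafba.errors import (
    BiomassDeletionError,
    DuplicateIdError,
    InvalidBoundsError,
    UnknownMetaboliteError,
    UnknownTargetError,
)
from dynafba.model import (
    INF,
    ConstraintPatch,
    GeneticModification,
    MetabolicModel,
    Metabolite,
    Reaction,
    apply_anaerobic_constraints,
    apply_genetic_modifications,
    evaluate_gene_rule,
    load_model,
    parse_equation,
    write_model,
)


def small_model():
    mets = [
        Metabolite("A", compartment="e", mw=10.0, is_extracellular=True),
        Metabolite("B", compartment="e", mw=10.0, is_extracellular=True),
        Metabolite("a"),
    ]
    rxns = [
        Reaction("EX_A", {"A": -1.0}, lb=-INF, ub=0.0),
        Reaction("EX_B", {"B": -1.0}, lb=0.0, ub=INF),
        Reaction("T1", {"A": -1.0, "a": 1.0}, ub=10.0),
        Reaction("T2", {"a": -1.0, "B": 1.0}, ub=10.0, genes="G1 or G2"),
    ]
    return MetabolicModel(mets, rxns)


class TestModelIO:
    def test_tsv_round_trip_preserves_everything(self, toy_model, tmp_path):
        path = tmp_path / "toy.tsv"
        write_model(toy_model, path)
        again = load_model(path)
        assert [r.id for r in again.reactions] == [r.id for r in toy_model.reactions]
        for r in toy_model.reactions:
            r2 = again.reaction(r.id)
            assert r2.stoichiometry == r.stoichiometry
            assert (r2.lb, r2.ub, r2.genes, r2.tags) == (r.lb, r.ub, r.genes, r.tags)
        for m in toy_model.metabolites:
            assert again.metabolite(m.id) == m
        assert again.exchange_map == toy_model.exchange_map

    def test_unknown_metabolite_raises(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "metabolite_id\tname\tcompartment\tformula\tmw\textracellular\n"
            "A\t\te\t\t10\t1\n\n"
            "reaction_id\tname\tequation\tlb\tub\tgenes\ttags\n"
            "R1\t\tA -> Zz\t0\t10\t\t\n"
        )
        with pytest.raises(UnknownMetaboliteError):
            load_model(path)

    def test_duplicate_reaction_id_raises(self):
        mets = [Metabolite("A")]
        rxns = [Reaction("R", {"A": -1.0}), Reaction("R", {"A": 1.0})]
        with pytest.raises(DuplicateIdError):
            MetabolicModel(mets, rxns)

    @pytest.mark.parametrize(
        "equation, stoich, reversible",
        [
            ("A -> B", {"A": -1.0, "B": 1.0}, False),
            ("2 A + 3 B <-> C", {"A": -2.0, "B": -3.0, "C": 1.0}, True),
            ("0.5 A -> 1.5 C", {"A": -0.5, "C": 1.5}, False),
        ],
    )
    def test_equation_parsing(self, equation, stoich, reversible):
        assert parse_equation(equation) == (stoich, reversible)


class TestAnaerobicConstraints:
    def test_patch_pins_oxygen_tca_quinones_and_relaxes_sterols(self, toy_model):
        patch = apply_anaerobic_constraints(toy_model)
        assert patch.bounds["EX_o2"] == (0.0, 0.0)
        assert patch.bounds["SDH"] == (0.0, 0.0)
        assert patch.bounds["SCL"] == (0.0, 0.0)
        assert patch.bounds["QNADH"] == (0.0, 0.0)
        assert patch.bounds["QFADH"] == (0.0, 0.0)
        assert patch.bounds["STEROLt"][1] == INF

    def test_idempotent(self, toy_model):
        assert apply_anaerobic_constraints(toy_model).bounds == apply_anaerobic_constraints(toy_model).bounds

    def test_untagged_model_gives_empty_patch_and_warning(self):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            patch = apply_anaerobic_constraints(small_model())
        assert len(patch) == 0
        assert any("oxygen" in str(w.message) for w in caught)

    def test_contradictory_positive_lb_raises(self):
        mets = [Metabolite("A"), Metabolite("o2")]
        rxns = [
            Reaction("SRC", {"A": 1.0}),
            Reaction("O2t", {"o2": 1.0, "A": -1.0}, lb=1.0, ub=5.0, tags={"oxygen_uptake"}),
            Reaction("SNK", {"o2": -1.0}),
        ]
        with pytest.raises(InvalidBoundsError):
            apply_anaerobic_constraints(MetabolicModel(mets, rxns))


class TestGeneticModifications:
    def test_no_mods_is_identity(self, toy_model):
        patch, model = apply_genetic_modifications(toy_model, [])
        assert len(patch) == 0
        assert model is toy_model

    def test_isozyme_rule_requires_both_deletions(self, toy_model):
        patch, _ = apply_genetic_modifications(
            toy_model, [GeneticModification("GPD1", "deletion")]
        )
        assert "GPD" not in patch  # GPD2 still covers the reaction
        patch, _ = apply_genetic_modifications(
            toy_model,
            [GeneticModification("GPD1", "deletion"), GeneticModification("GPD2", "deletion")],
        )
        assert patch.bounds["GPD"] == (0.0, 0.0)

    def test_direct_reaction_deletion(self, toy_model):
        patch, _ = apply_genetic_modifications(toy_model, [GeneticModification("GPD", "deletion")])
        assert patch.bounds["GPD"] == (0.0, 0.0)

    def test_unknown_target_raises(self, toy_model):
        with pytest.raises(UnknownTargetError):
            apply_genetic_modifications(toy_model, [GeneticModification("NOPE", "deletion")])

    def test_biomass_deletion_refused(self, toy_model):
        with pytest.raises(BiomassDeletionError):
            apply_genetic_modifications(toy_model, [GeneticModification("BIOMASS", "deletion")])

    def test_insertion_extends_and_revalidates(self, toy_model):
        new = Reaction("MHPF", {"ac": -1.0, "nadh": -2.0, "h": -2.0, "atp": -1.0,
                                "etoh": 1.0, "nad": 2.0, "adp": 1.0, "pi": 1.0})
        patch, model = apply_genetic_modifications(
            toy_model, [GeneticModification("MHPF", "insertion", added_reaction=new)]
        )
        assert model.has_reaction("MHPF")
        assert len(model.reactions) == len(toy_model.reactions) + 1
        imb = model.element_imbalances()
        assert all(abs(x) < 1e-9 for x in imb["MHPF"].values())

    def test_overexpression_scales_bounds(self, toy_model):
        patch, _ = apply_genetic_modifications(
            toy_model, [GeneticModification("SDH1", "overexpression", factor=5.0)]
        )
        sdh = toy_model.reaction("SDH")
        assert patch.bounds["SDH"] == (sdh.lb * 5.0, sdh.ub * 5.0)

    def test_expression_factor_validation(self):
        with pytest.raises(Exception):
            GeneticModification("X", "downregulation", factor=2.0)
        with pytest.raises(Exception):
            GeneticModification("X", "overexpression", factor=0.5)


class TestPatchComposition:
    def test_later_patches_override_earlier(self, toy_model):
        p1 = ConstraintPatch("fixed", {"GPD": (0.0, 5.0)})
        p2 = ConstraintPatch("dynamic", {"GPD": (0.0, 7.0)})
        lb, ub = toy_model.bounds_arrays([p1, p2])
        assert ub[toy_model.reaction_index("GPD")] == 7.0

    def test_genetic_zero_never_relaxed_by_dynamic(self, toy_model):
        knock = ConstraintPatch("genetic", {"GPD": (0.0, 0.0)})
        dyn = ConstraintPatch("dynamic", {"GPD": (0.0, 10.0)})
        lb, ub = toy_model.bounds_arrays([knock, dyn])
        j = toy_model.reaction_index("GPD")
        assert (lb[j], ub[j]) == (0.0, 0.0)

    def test_patch_entry_with_lb_above_ub_rejected(self):
        with pytest.raises(InvalidBoundsError):
            ConstraintPatch("dynamic").set("R", 1.0, 0.0)


class TestGeneRules:
    @pytest.mark.parametrize(
        "rule, deleted, alive",
        [
            ("G1 or G2", {"G1"}, True),
            ("G1 or G2", {"G1", "G2"}, False),
            ("G1 and G2", {"G2"}, False),
            ("(G1 and G2) or G3", {"G1"}, True),
            ("(G1 and G2) or G3", {"G2", "G3"}, False),
        ],
    )
    def test_boolean_rules(self, rule, deleted, alive):
        assert evaluate_gene_rule(rule, deleted) is alive


def test_toy_elemental_balance_exact(toy_model):
    """Every non-exchange, non-biomass toy reaction conserves C, H, O, N."""
    imbalances = toy_model.element_imbalances()
    assert imbalances  # audit actually ran
    for rid, net in imbalances.items():
        for element, amount in net.items():
            assert abs(amount) < 1e-9, f"{rid} unbalanced in {element}: {amount}"


def test_exchange_map_is_bijection(toy_model):
    assert len(set(toy_model.exchange_map.values())) == len(toy_model.exchange_map)
    for species, rid in toy_model.exchange_map.items():
        assert toy_model.reaction(rid).stoichiometry == {species: -1.0}
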