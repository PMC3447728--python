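"""Reconstruction operations: exchanges, biomass, maintenance, edits."""

import pytest

from fluxdraft.fba import solve_fba
from fluxdraft.model import (
    MetabolicModel,
    ObjectiveSpec,
    Reaction,
    ReactionKind,
)
from fluxdraft.reconstruction import (
    BIOMASS_REACTION_ID,
    MAINTENANCE_REACTION_ID,
    BiomassComposition,
    EditError,
    EditScript,
    add_inflow,
    add_outflow,
    add_reaction,
    apply_edit_script,
    knockout,
    modify_reaction,
    set_biomass,
    set_maintenance,
    set_objective,
)
from fluxdraft.toy import build_toy_model, reconstruct_toy


def chain_with_objective() -> MetabolicModel:
    """A -> B -> C chain with outflow on C; infeasible until A has a source."""
    m = MetabolicModel(id="chain")
    m.add_reaction(Reaction(id="r1", stoichiometry={"A": -1.0, "B": 1.0}),
                   register_metabolites=True)
    m.add_reaction(Reaction(id="r2", stoichiometry={"B": -1.0, "C": 1.0}),
                   register_metabolites=True)
    m = add_outflow(m, "C", "out_C")
    return set_objective(m, {"out_C": 1.0})


class TestExchanges:
    def test_fixed_inflow_pins_both_bounds(self, toy_model):
        rxn = toy_model.reactions["glc_in"]
        assert rxn.kind is ReactionKind.INFLOW
        assert rxn.lower_bound == rxn.upper_bound == 11.0
        assert rxn.stoichiometry == {"G6P": 1.0}

    def test_fixed_outflow_pins_both_bounds(self, toy_model):
        rxn = toy_model.reactions["ac_out"]
        assert rxn.kind is ReactionKind.OUTFLOW
        assert rxn.lower_bound == rxn.upper_bound == 6.4
        assert rxn.stoichiometry == {"ACCOA": -1.0}

    def test_inflow_makes_chain_feasible_with_positive_flux(self):
        m = chain_with_objective()
        assert solve_fba(m).objective_value == pytest.approx(0.0)
        fed = add_inflow(m, "A", "in_A", upper_bound=5.0)
        sol = solve_fba(fed)
        assert sol.optimal
        assert sol.objective_value == pytest.approx(5.0)

    def test_inflow_fixed_zero_carries_no_flux(self):
        m = add_inflow(chain_with_objective(), "A", "in_A", fixed=0.0)
        sol = solve_fba(m)
        assert sol.fluxes["in_A"] == pytest.approx(0.0)

    def test_outflow_on_unproduced_metabolite_stays_solvable(self):
        m = add_outflow(chain_with_objective(), "B", "leak_B")
        sol = solve_fba(m)
        assert sol.optimal
        assert sol.fluxes["leak_B"] == pytest.approx(0.0)

    def test_duplicate_exchange_id_rejected(self, toy_model):
        with pytest.raises(EditError):
            add_inflow(toy_model, "G6P", "glc_in")

    def test_input_model_is_not_mutated(self):
        m = chain_with_objective()
        before = len(m.reactions)
        add_inflow(m, "A", "in_A")
        assert len(m.reactions) == before


class TestKnockoutAndAddition:
    def test_knockout_zeroes_bounds_but_keeps_reaction(self, toy_model):
        ko = knockout(toy_model, "pgi")
        assert ko.reactions["pgi"].lower_bound == 0.0
        assert ko.reactions["pgi"].upper_bound == 0.0
        assert "pgi" in ko.reactions

    def test_knockout_unknown_id_lists_it(self, toy_model):
        with pytest.raises(EditError, match="ghost"):
            knockout(toy_model, ["pgi", "ghost"])

    def test_knockout_is_idempotent(self, toy_model):
        once = knockout(toy_model, "pgi")
        twice = knockout(once, "pgi")
        assert once.equals(twice)

    def test_biomass_knockout_zeroes_growth(self, toy_model):
        sol = solve_fba(knockout(toy_model, BIOMASS_REACTION_ID))
        # the fixed acetate outflow keeps carbon balance satisfiable
        assert sol.optimal and sol.objective_value == pytest.approx(0.0)

    def test_sole_inflow_knockout_kills_the_model(self, toy_model):
        sol = solve_fba(knockout(toy_model, "glc_in"))
        # fixed acetate outflow without any carbon source is unsatisfiable
        assert sol.status == "infeasible"

    def test_add_then_knockout_restores_baseline_optimum(self, toy_model):
        base = solve_fba(toy_model).objective_value
        extra = Reaction(id="shunt", stoichiometry={"PYR": -1.0, "ACCOA": 1.0},
                         kind=ReactionKind.HETEROLOGOUS)
        grown = add_reaction(toy_model, extra)
        reverted = knockout(grown, "shunt")
        assert solve_fba(reverted).objective_value == pytest.approx(base, rel=1e-9)

    def test_redundant_parallel_path_knockout_leaves_optimum(self):
        m = add_inflow(chain_with_objective(), "A", "in_A", upper_bound=5.0)
        m = add_reaction(m, Reaction(id="r1b", stoichiometry={"A": -1.0, "B": 1.0}))
        base = solve_fba(m).objective_value
        assert solve_fba(knockout(m, "r1b")).objective_value == pytest.approx(base)


class TestModifyReaction:
    def test_reversible_to_forward_zeroes_lower_bound(self, toy_model):
        out = modify_reaction(toy_model, "pgi", new_direction="forward")
        assert not out.reactions["pgi"].reversible
        assert out.reactions["pgi"].lower_bound == 0.0

    def test_backward_negates_stoichiometry(self):
        m = MetabolicModel(id="m")
        m.add_reaction(Reaction(id="r", stoichiometry={"A": -1.0, "B": 1.0}),
                       register_metabolites=True)
        out = modify_reaction(m, "r", new_direction="backward")
        assert out.reactions["r"].stoichiometry == {"A": 1.0, "B": -1.0}
        assert out.reactions["r"].lower_bound == 0.0

    def test_participant_edit_changes_coefficient(self, toy_model):
        out = modify_reaction(toy_model, "pfk_ald", participant_edits={"GAP": 1.5})
        assert out.reactions["pfk_ald"].stoichiometry["GAP"] == 1.5

    def test_removing_all_products_rejected(self, toy_model):
        with pytest.raises(EditError, match="substrate and >=1 product"):
            modify_reaction(toy_model, "pgi", participant_edits={"F6P": None})

    def test_direction_tightening_never_increases_optimum(self, toy_model):
        base = solve_fba(toy_model).objective_value
        for direction in ("forward", "backward"):
            tightened = modify_reaction(toy_model, "mdh", new_direction=direction)
            sol = solve_fba(tightened)
            tightened_opt = sol.objective_value if sol.optimal else 0.0
            assert tightened_opt <= base + 1e-9


def energy_chain_model(uptake: float = 10.0) -> MetabolicModel:
    """Substrate -> 1 ATP each; growth spends GAM ATP: growth = U/(d+gam)."""
    m = MetabolicModel(id="energy")
    m.add_reaction(
        Reaction(id="catab", stoichiometry={"s": -1.0, "adp": -1.0, "pi": -1.0,
                                            "atp": 1.0}),
        register_metabolites=True,
    )
    m = add_inflow(m, "s", "in_s", upper_bound=uptake)
    m = add_inflow(m, "h2o", "in_h2o")
    return m


class TestBiomassAndMaintenance:
    COMP = BiomassComposition(demands={"s": 2.0}, gam=18.0, atp_id="atp",
                              adp_id="adp", pi_id="pi", h2o_id="h2o")

    def test_biomass_reaction_carries_gam_energy_couple(self):
        m = set_biomass(energy_chain_model(), self.COMP)
        stoich = m.reactions[BIOMASS_REACTION_ID].stoichiometry
        assert stoich["s"] == -2.0
        assert stoich["atp"] == -18.0 and stoich["h2o"] == -18.0
        assert stoich["adp"] == 18.0 and stoich["pi"] == 18.0
        assert stoich["biomass"] == 1.0

    def test_zero_gam_has_no_energy_terms(self):
        comp = BiomassComposition(demands={"s": 2.0}, gam=0.0)
        m = set_biomass(energy_chain_model(), comp)
        stoich = m.reactions[BIOMASS_REACTION_ID].stoichiometry
        assert "atp" not in stoich and "adp" not in stoich

    def test_growth_matches_closed_form(self):
        m = set_biomass(energy_chain_model(), self.COMP)
        sol = solve_fba(m)
        assert sol.objective_value == pytest.approx(10.0 / (2.0 + 18.0), rel=1e-6)

    def test_doubling_demands_halves_growth(self):
        comp0 = BiomassComposition(demands={"s": 2.0}, gam=0.0)
        comp2 = BiomassComposition(demands={"s": 4.0}, gam=0.0)
        g0 = solve_fba(set_biomass(energy_chain_model(), comp0)).objective_value
        g2 = solve_fba(set_biomass(energy_chain_model(), comp2)).objective_value
        assert g2 == pytest.approx(g0 / 2.0, rel=1e-9)

    def test_missing_energy_couple_is_an_error(self):
        m = MetabolicModel(id="m")
        m.add_reaction(Reaction(id="r", stoichiometry={"s": -1.0, "p": 1.0}),
                       register_metabolites=True)
        with pytest.raises(EditError, match="energy-couple"):
            set_biomass(m, BiomassComposition(demands={"s": 1.0}, gam=5.0))

    def test_maintenance_flux_is_pinned(self):
        m = set_biomass(energy_chain_model(), self.COMP)
        m = set_maintenance(m, 3.0, atp_id="atp", adp_id="adp", pi_id="pi",
                            h2o_id="h2o")
        sol = solve_fba(m)
        assert sol.fluxes[MAINTENANCE_REACTION_ID] == pytest.approx(3.0)

    def test_raising_ngam_never_increases_growth(self):
        m = set_biomass(energy_chain_model(), self.COMP)
        growths = []
        for ngam in (0.0, 2.0, 5.0):
            sol = solve_fba(set_maintenance(m, ngam, atp_id="atp", adp_id="adp",
                                            pi_id="pi", h2o_id="h2o"))
            growths.append(sol.objective_value)
        assert growths == sorted(growths, reverse=True)

    def test_negative_ngam_rejected(self):
        with pytest.raises(EditError):
            set_maintenance(energy_chain_model(), -1.0, atp_id="atp", adp_id="adp",
                            pi_id="pi", h2o_id="h2o")


TOY_WALKTHROUGH = """
edits:
  - op: add_inflow
    metabolite: G6P
    reaction_id: glc_in
    fixed: 11.0
  - op: add_outflow
    metabolite: ACCOA
    reaction_id: ac_out
    fixed: 6.4
  - op: set_objective
    coefficients:
      biomass_production: 1.0
"""


class TestEditScripts:
    def test_empty_script_is_identity(self, toy_model):
        out = apply_edit_script(toy_model, EditScript([]))
        assert out.equals(toy_model)

    def test_toy_walkthrough_reproduces_reconstruction(self):
        scripted = apply_edit_script(
            build_toy_model(), EditScript.from_yaml(TOY_WALKTHROUGH)
        )
        assert scripted.equals(reconstruct_toy())
        sol = solve_fba(scripted)
        assert sol.objective_value == pytest.approx(
            solve_fba(reconstruct_toy()).objective_value
        )

    def test_failure_is_atomic_and_cites_position(self, toy_model):
        script = EditScript([
            {"op": "knockout", "reaction_ids": ["pgi"]},
            {"op": "knockout", "reaction_ids": ["zwf"]},
            {"op": "knockout", "reaction_ids": ["ghost"]},
            {"op": "knockout", "reaction_ids": ["pyk"]},
        ])
        with pytest.raises(EditError, match="directive 2"):
            apply_edit_script(toy_model, script)
        assert toy_model.reactions["pgi"].upper_bound > 0  # untouched

    def test_yaml_without_edits_key_rejected(self):
        with pytest.raises(EditError):
            EditScript.from_yaml("knockouts: []")

    def test_unknown_op_rejected_at_parse(self):
        with pytest.raises(EditError, match="unknown op"):
            EditScript.from_yaml("edits:\n  - op: teleport\n")
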