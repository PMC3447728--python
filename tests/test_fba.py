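"""FBA solving, GAM fitting, envelopes, scenario analysis."""

import numpy as np
import pytest

from conftest import fba_ready_fixture_model, oracle_optimum

from fluxdraft.fba import (
    FluxAnalysisError,
    constrain_and_resolve,
    fit_gam,
    fix_flux,
    production_envelope,
    solve_fba,
)
from fluxdraft.model import (
    MetabolicModel,
    ObjectiveSpec,
    Reaction,
    build_stoichiometric_matrix,
)
from fluxdraft.reconstruction import (
    BIOMASS_REACTION_ID,
    BiomassComposition,
    add_inflow,
    add_outflow,
    add_reaction,
    knockout,
    set_biomass,
    set_objective,
)
from test_reconstruction import chain_with_objective, energy_chain_model


def assert_steady_state(model, solution, tol=1e-6):
    S = build_stoichiometric_matrix(model)
    v = np.array([solution.fluxes[rid] for rid in S.reaction_ids])
    assert np.abs(S.matrix @ v).max() <= tol
    for rid in S.reaction_ids:
        rxn = model.reactions[rid]
        assert rxn.lower_bound - 1e-9 <= solution.fluxes[rid] <= rxn.upper_bound + 1e-9


class TestSolveFBA:
    def test_bound_limited_chain(self):
        m = add_inflow(chain_with_objective(), "A", "in_A", upper_bound=5.0)
        sol = solve_fba(m)
        assert sol.optimal
        assert sol.objective_value == pytest.approx(5.0)
        assert all(f == pytest.approx(5.0) for f in sol.fluxes.values())

    def test_toy_matches_independent_oracle(self, toy_model):
        ours = solve_fba(toy_model)
        status, oracle = oracle_optimum(toy_model)
        assert ours.optimal and status == "optimal"
        assert ours.objective_value == pytest.approx(oracle, rel=1e-6)
        assert_steady_state(toy_model, ours)

    def test_inflow_into_dead_end_is_infeasible(self):
        m = MetabolicModel(id="m")
        m.add_reaction(Reaction(id="r", stoichiometry={"A": -1.0, "B": 1.0}),
                       register_metabolites=True)
        m = add_inflow(m, "A", "in_A", fixed=11.0)
        m = set_objective(m, {"r": 1.0})
        assert solve_fba(m).status == "infeasible"

    def test_unbounded_objective_reported(self):
        m = MetabolicModel(id="m")
        m.add_reaction(
            Reaction(id="spin", stoichiometry={"A": -1.0, "B": 1.0},
                     reversible=True, lower_bound=float("-inf"),
                     upper_bound=float("inf")),
            register_metabolites=True,
        )
        m.add_reaction(
            Reaction(id="back", stoichiometry={"B": -1.0, "A": 1.0},
                     reversible=True, lower_bound=float("-inf"),
                     upper_bound=float("inf")),
        )
        m = set_objective(m, {"spin": 1.0})
        assert solve_fba(m).status == "unbounded"

    def test_missing_objective_is_an_error(self):
        m = chain_with_objective()
        m.objective = None
        with pytest.raises(FluxAnalysisError, match="objective"):
            solve_fba(m)

    @pytest.mark.parametrize("seed", range(6))
    def test_small_models_match_oracle(self, seed):
        model = fba_ready_fixture_model(seed)
        ours = solve_fba(model)
        status, oracle = oracle_optimum(model)
        assert ours.status == status
        if ours.optimal:
            assert ours.objective_value == pytest.approx(oracle, rel=1e-6, abs=1e-6)
            assert_steady_state(model, ours)


class TestFixFlux:
    def test_fix_pins_every_solution(self, toy_model):
        m = fix_flux(toy_model, "zwf", 0.9)
        assert solve_fba(m).fluxes["zwf"] == pytest.approx(0.9)

    def test_fix_at_zero_equals_knockout(self, toy_model):
        fixed = solve_fba(fix_flux(toy_model, "zwf", 0.0))
        ko = solve_fba(knockout(toy_model, "zwf"))
        assert fixed.objective_value == pytest.approx(ko.objective_value)

    def test_negative_fix_on_irreversible_rejected(self, toy_model):
        with pytest.raises(FluxAnalysisError):
            fix_flux(toy_model, "glc_in", -1.0)

    def test_unknown_reaction_rejected(self, toy_model):
        with pytest.raises(FluxAnalysisError):
            fix_flux(toy_model, "ghost", 1.0)


class TestFitGam:
    def test_recovers_hand_derived_gam(self):
        # growth(gam) = U / (d + gam) with U = 10, d = 2 => gam(0.5) = 18
        comp = BiomassComposition(demands={"s": 2.0}, gam=0.0, atp_id="atp",
                                  adp_id="adp", pi_id="pi", h2o_id="h2o")
        m = set_biomass(energy_chain_model(uptake=10.0), comp)
        fit = fit_gam(m, target_growth=0.5, gam_range=(0.0, 100.0))
        assert fit.gam == pytest.approx(18.0, abs=0.05)
        assert fit.growth == pytest.approx(0.5, abs=1e-4)

    def test_target_at_lower_bracket_returns_it(self):
        comp = BiomassComposition(demands={"s": 2.0}, gam=0.0, atp_id="atp",
                                  adp_id="adp", pi_id="pi", h2o_id="h2o")
        m = set_biomass(energy_chain_model(uptake=10.0), comp)
        fit = fit_gam(m, target_growth=5.0, gam_range=(0.0, 100.0))
        assert fit.gam == 0.0

    def test_unreachable_target_reports_achievable_range(self):
        comp = BiomassComposition(demands={"s": 2.0}, gam=0.0, atp_id="atp",
                                  adp_id="adp", pi_id="pi", h2o_id="h2o")
        m = set_biomass(energy_chain_model(uptake=10.0), comp)
        with pytest.raises(FluxAnalysisError, match="achievable"):
            fit_gam(m, target_growth=9.0, gam_range=(0.0, 100.0))

    def test_growth_is_monotone_in_gam(self):
        comp = BiomassComposition(demands={"s": 2.0}, gam=0.0, atp_id="atp",
                                  adp_id="adp", pi_id="pi", h2o_id="h2o")
        m = set_biomass(energy_chain_model(uptake=10.0), comp)
        fit = fit_gam(m, target_growth=0.5, gam_range=(0.0, 100.0))
        growths = [g for _, g in fit.curve]
        assert growths == sorted(growths, reverse=True)


def branch_point_model() -> MetabolicModel:
    """One branch point: inflow A splits between biomass and product P."""
    m = MetabolicModel(id="branch")
    m.add_reaction(Reaction(id=BIOMASS_REACTION_ID, stoichiometry={"A": -1.0},
                            kind="biomass"),
                   register_metabolites=True)
    m = add_inflow(m, "A", "in_A", upper_bound=10.0)
    m = add_outflow(m, "A", "p_out")
    return set_objective(m, {BIOMASS_REACTION_ID: 1.0})


class TestProductionEnvelope:
    def test_strict_tradeoff_matches_hand_derived_line(self):
        curve = production_envelope(branch_point_model(), "p_out", n_points=11)
        for mu, flux in curve.points:
            assert flux == pytest.approx(10.0 - mu, abs=1e-8)
        assert curve.growth_rates[0] == 0.0
        assert curve.growth_rates[-1] == pytest.approx(10.0)

    def test_biomass_target_gives_identity_line(self, toy_model):
        curve = production_envelope(toy_model, BIOMASS_REACTION_ID, n_points=7)
        for mu, flux in curve.points:
            assert flux == pytest.approx(mu, abs=1e-8)

    def test_growth_grid_is_strictly_increasing(self, toy_model):
        curve = production_envelope(toy_model, "ac_out", n_points=9)
        diffs = np.diff(curve.growth_rates)
        assert (diffs > 0).all()

    def test_envelope_is_concave_along_the_grid(self, toy_model):
        curve = production_envelope(toy_model, "zwf", n_points=9)
        f = curve.fluxes
        for i in range(1, len(f) - 1):
            assert f[i] >= 0.5 * (f[i - 1] + f[i + 1]) - 1e-7

    def test_unknown_target_rejected(self, toy_model):
        with pytest.raises(FluxAnalysisError):
            production_envelope(toy_model, "ghost")


class TestConstrainAndResolve:
    def test_empty_fixes_equals_plain_solve(self, toy_model):
        a = solve_fba(toy_model)
        b = constrain_and_resolve(toy_model, {})
        assert b.objective_value == pytest.approx(a.objective_value)

    def test_model_is_bit_identical_afterwards(self, toy_model):
        snapshot = toy_model.copy()
        constrain_and_resolve(toy_model, {"zwf": (0.0, 0.1)})
        assert toy_model.equals(snapshot)

    def test_tightening_any_upper_bound_is_non_increasing(self, toy_model):
        base = solve_fba(toy_model).objective_value
        sol = solve_fba(toy_model)
        for rid in ("pgi", "pyk", "zwf", "cit_akg"):
            tight = constrain_and_resolve(
                toy_model, {rid: (toy_model.reactions[rid].lower_bound,
                                  abs(sol.fluxes[rid]) * 0.5)}
            )
            value = tight.objective_value if tight.optimal else 0.0
            assert value <= base + 1e-9


class TestMonotonicityProperties:
    @pytest.mark.parametrize("seed", range(8))
    def test_knockout_non_increasing_addition_non_decreasing(self, seed):
        model = fba_ready_fixture_model(seed)
        base_sol = solve_fba(model)
        base = base_sol.objective_value if base_sol.optimal else 0.0
        rids = sorted(set(model.reactions) - {"substrate_in", "product_out"})
        victim = rids[seed % len(rids)]
        ko_sol = solve_fba(knockout(model, victim))
        ko = ko_sol.objective_value if ko_sol.optimal else 0.0
        assert ko <= base + 1e-7
        mets = sorted(model.metabolites)
        extra = Reaction(
            id="extra_path",
            stoichiometry={mets[seed % len(mets)]: -1.0,
                           mets[(seed + 3) % len(mets)]: 1.0},
        )
        if len(set(extra.stoichiometry)) == 2:
            grown_sol = solve_fba(add_reaction(model, extra))
            grown = grown_sol.objective_value if grown_sol.optimal else 0.0
            assert grown >= base - 1e-7
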