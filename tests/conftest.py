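"""Shared fixtures and the independent LP oracle.

The oracle rebuilds a model inside COBRApy and solves it with GLPK via
optlang — a completely separate formulation and solver path from the
package's own scipy/HiGHS implementation — so agreement between the two
is meaningful evidence of correctness, not a tautology.
"""

from __future__ import annotations

import json
from importlib import resources

import pytest
from hypothesis import settings

from fluxdraft.fixtures import generate_fixture_organism
from fluxdraft.model import MetabolicModel, ObjectiveSpec
from fluxdraft.reconstruction import add_inflow, add_outflow, set_objective
from fluxdraft.surrogate import build_x514_surrogate
from fluxdraft.toy import reconstruct_toy

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def oracle_optimum(
    model: MetabolicModel, objective: ObjectiveSpec | None = None
) -> tuple[str, float | None]:
    """Solve the same FBA problem with COBRApy + GLPK."""
    import cobra

    obj = objective or model.objective
    assert obj is not None
    cm = cobra.Model("oracle")
    cm.solver = "glpk"
    mets = {
        mid: cobra.Metabolite(mid)
        for mid, met in model.metabolites.items()
        if not met.external
    }
    pending = []
    for rid, rxn in model.reactions.items():
        cr = cobra.Reaction(rid)
        cr.lower_bound = rxn.lower_bound
        cr.upper_bound = rxn.upper_bound
        pending.append(
            (cr, {mets[m]: c for m, c in rxn.stoichiometry.items() if m in mets})
        )
    cm.add_reactions([cr for cr, _ in pending])
    for cr, stoich in pending:
        cr.add_metabolites(stoich)
    expr = sum(
        coeff * cm.reactions.get_by_id(rid).flux_expression
        for rid, coeff in obj.coefficients.items()
    )
    cm.objective = cm.problem.Objective(
        expr, direction="max" if obj.direction == "maximize" else "min"
    )
    sol = cm.optimize()
    if sol.status != "optimal":
        return sol.status, None
    return "optimal", float(sol.objective_value)


def fba_ready_fixture_model(seed: int) -> MetabolicModel:
    """A random fixture network wired for FBA: substrate inflow, product
    outflow, maximize the outflow."""
    org = generate_fixture_organism(
        seed, n_pathways=2, n_reactions=30, overlap_fraction=0.1
    )
    model = org.model.copy()
    model = add_inflow(model, org.annotations.substrate, "substrate_in", upper_bound=10.0)
    model = add_outflow(model, org.annotations.product, "product_out")
    return set_objective(model, {"product_out": 1.0})


@pytest.fixture(scope="session")
def toy_model() -> MetabolicModel:
    return reconstruct_toy()


@pytest.fixture(scope="session")
def surrogate_model() -> MetabolicModel:
    return build_x514_surrogate()


@pytest.fixture(scope="session")
def surrogate_gold() -> dict:
    text = (
        resources.files("fluxdraft") / "data" / "x514_surrogate_gold.json"
    ).read_text()
    return json.loads(text)
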