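"""A small central-metabolism demonstration model ("TOY").

Synthetic stand-in covering glycolysis, the pentose phosphate pathway, a
lumped TCA route and the anaplerotic node: 10 metabolites; after
reconstruction (glucose inflow, acetate outflow) the model has 16
reactions including a lumped biomass sink.  Glucose is the carbon
substrate, acetate (drained directly from the acetyl-CoA node) the
extracellular product.  Precursor demands follow conventional bacterial
building-block requirements in mmol per g DCW, so the biomass flux is the
specific growth rate in 1/h.
"""

from __future__ import annotations

from .model import MetabolicModel, ObjectiveSpec, Reaction, ReactionKind
from .reconstruction import BIOMASS_REACTION_ID, add_inflow, add_outflow

#: default chemostat rates, mmol/g DCW/h
DEFAULT_GLUCOSE_INFLOW = 11.0
DEFAULT_ACETATE_OUTFLOW = 6.4

GLUCOSE_INFLOW_ID = "glc_in"
ACETATE_OUTFLOW_ID = "ac_out"

_METABOLITE_NAMES = {
    "G6P": "glucose 6-phosphate",
    "F6P": "fructose 6-phosphate",
    "GAP": "glyceraldehyde 3-phosphate",
    "PEP": "phosphoenolpyruvate",
    "PYR": "pyruvate",
    "ACCOA": "acetyl-CoA",
    "AKG": "2-oxoglutarate",
    "OAA": "oxaloacetate",
    "MAL": "malate",
    "P5P": "pentose 5-phosphate",
}

#: conventional precursor demands, mmol per g DCW
BIOMASS_DEMANDS = {
    "G6P": 0.205,
    "F6P": 0.071,
    "P5P": 0.898,
    "GAP": 0.129,
    "PEP": 2.015,
    "PYR": 2.833,
    "ACCOA": 3.748,
    "AKG": 1.079,
    "OAA": 1.787,
}


def build_toy_model() -> MetabolicModel:
    """The loaded TOY model: intracellular routes plus the lumped biomass
    sink, no exchanges yet."""
    model = MetabolicModel(id="toy", organism="toy")
    reactions = [
        ("pgi", {"G6P": -1, "F6P": +1}, True),
        ("pfk_ald", {"F6P": -1, "GAP": +2}, False),
        ("gap_pep", {"GAP": -1, "PEP": +1}, True),
        ("pyk", {"PEP": -1, "PYR": +1}, False),
        ("pdh", {"PYR": -1, "ACCOA": +1}, False),
        ("cit_akg", {"ACCOA": -1, "OAA": -1, "AKG": +1}, False),
        ("akg_mal", {"AKG": -1, "MAL": +1}, False),
        ("mdh", {"MAL": -1, "OAA": +1}, True),
        ("ppc", {"PEP": -1, "OAA": +1}, False),
        ("mae", {"MAL": -1, "PYR": +1}, False),
        ("pck", {"OAA": -1, "PEP": +1}, False),
        ("zwf", {"G6P": -1, "P5P": +1}, False),
        ("tkt", {"P5P": -3, "F6P": +2, "GAP": +1}, True),
    ]
    for rid, stoich, reversible in reactions:
        model.add_reaction(
            Reaction(
                id=rid,
                stoichiometry={m: float(c) for m, c in stoich.items()},
                reversible=reversible,
            ),
            register_metabolites=True,
        )
    for mid, name in _METABOLITE_NAMES.items():
        model.metabolites[mid].name = name
    model.add_reaction(
        Reaction(
            id=BIOMASS_REACTION_ID,
            name="lumped biomass production",
            stoichiometry={m: -v for m, v in BIOMASS_DEMANDS.items()},
            reversible=False,
            kind=ReactionKind.BIOMASS,
        )
    )
    model.objective = ObjectiveSpec({BIOMASS_REACTION_ID: 1.0})
    return model


def reconstruct_toy(
    inflow: float = DEFAULT_GLUCOSE_INFLOW,
    outflow: float = DEFAULT_ACETATE_OUTFLOW,
) -> MetabolicModel:
    """The reconstructed TOY model: glucose inflow into G6P and acetate
    outflow from acetyl-CoA, both pinned to measured rates; maximize
    biomass."""
    model = build_toy_model()
    model = add_inflow(model, "G6P", GLUCOSE_INFLOW_ID, fixed=inflow)
    model = add_outflow(model, "ACCOA", ACETATE_OUTFLOW_ID, fixed=outflow)
    return model
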