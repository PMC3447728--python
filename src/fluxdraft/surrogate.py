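"""Synthetic medium-scale anaerobe model ("X514-like" surrogate).

A packaged stand-in for a drafted *Thermoanaerobacter*-class ethanologen:
a thermophilic anaerobe fermenting glucose to ethanol, acetate and
lactate with H2 evolution.  The model is synthetic — built in code, not
parsed from a genome database — but is sized and organised like a real
medium-scale draft: 196 species and 229 reactions, of which 161 are
intracellular conversions plus 1 ATP maintenance reaction, 19 are
inflow/outflow reactions, 39 are gap-filling exchange reactions for
metabolites shared with pathways outside the model scope (UTP and
friends), and 9 build biomass (7 building-block syntheses, the biomass
reaction and its sink).

Energetics: glycolysis nets 2 ATP and 2 NADH per glucose; pyruvate:
ferredoxin oxidoreductase transfers electrons to ferredoxin; acetate
kinase yields 1 ATP per acetate; the bifunctional alcohol dehydrogenase
spends 2 NADH per ethanol; and a lumped membrane energy-converting
hydrogenase couples ferredoxin reoxidation to H2 evolution with a
non-integer ATP stoichiometry (0.233 ATP per ferredoxin pair, a
chemiosmotic H+/ATP ratio), chosen so the model reproduces the high
maintenance-energy phenotype reported for this class of organism.
Default chemostat condition: glucose uptake 3.92 mmol/g DCW/h, NGAM
7.6 mmol ATP/g DCW/h, GAM 220 mmol ATP/g DCW.
"""

from __future__ import annotations

from .model import MetabolicModel, Metabolite, ObjectiveSpec, Reaction, ReactionKind
from .reconstruction import (
    BiomassComposition,
    add_inflow,
    add_outflow,
    set_biomass,
    set_maintenance,
)

GLUCOSE_INFLOW_ID = "glc_in"
ETHANOL_OUTFLOW_ID = "etoh_out"
ACETATE_OUTFLOW_ID = "ace_out"

DEFAULT_GLUCOSE_UPTAKE = 3.92  # mmol/g DCW/h
DEFAULT_NGAM = 7.6  # mmol ATP/g DCW/h
DEFAULT_GAM = 220.0  # mmol ATP/g DCW

#: ATP formed per reduced ferredoxin reoxidised by the membrane
#: hydrogenase (lumped chemiosmotic coupling)
ECH_ATP_PER_FD = 0.233

_CORE_METABOLITES = {
    "glc": "glucose",
    "g6p": "glucose 6-phosphate",
    "f6p": "fructose 6-phosphate",
    "fbp": "fructose 1,6-bisphosphate",
    "gap": "glyceraldehyde 3-phosphate",
    "pg3": "3-phosphoglycerate",
    "pep": "phosphoenolpyruvate",
    "pyr": "pyruvate",
    "accoa": "acetyl-CoA",
    "coa": "coenzyme A",
    "ace": "acetate",
    "etoh": "ethanol",
    "lac": "lactate",
    "cit": "citrate",
    "akg": "2-oxoglutarate",
    "oaa": "oxaloacetate",
    "co2": "carbon dioxide",
    "h2": "hydrogen",
    "h2o": "water",
    "atp": "ATP",
    "adp": "ADP",
    "pi": "orthophosphate",
    "nad": "NAD+",
    "nadh": "NADH",
    "fdox": "oxidised ferredoxin",
    "fdred": "reduced ferredoxin",
}

_CORE_REACTIONS = [
    ("hex", "hexokinase", {"glc": -1, "atp": -1, "g6p": +1, "adp": +1}, False),
    ("pgi", "phosphoglucose isomerase", {"g6p": -1, "f6p": +1}, True),
    ("pfk", "phosphofructokinase", {"f6p": -1, "atp": -1, "fbp": +1, "adp": +1}, False),
    ("ald", "aldolase + triose isomerase", {"fbp": -1, "gap": +2}, False),
    (
        "gapdh",
        "GAPDH + phosphoglycerate kinase",
        {"gap": -1, "nad": -1, "adp": -1, "pi": -1, "pg3": +1, "nadh": +1, "atp": +1},
        True,
    ),
    ("eno", "phosphoglycerate mutase + enolase", {"pg3": -1, "pep": +1}, True),
    ("pyk", "pyruvate kinase", {"pep": -1, "adp": -1, "pyr": +1, "atp": +1}, False),
    (
        "pfor",
        "pyruvate:ferredoxin oxidoreductase",
        {"pyr": -1, "coa": -1, "fdox": -1, "accoa": +1, "co2": +1, "fdred": +1},
        False,
    ),
    (
        "ptack",
        "phosphotransacetylase + acetate kinase",
        {"accoa": -1, "adp": -1, "pi": -1, "ace": +1, "atp": +1, "coa": +1},
        False,
    ),
    (
        "adhE",
        "bifunctional aldehyde/alcohol dehydrogenase",
        {"accoa": -1, "nadh": -2, "etoh": +1, "nad": +2, "coa": +1},
        False,
    ),
    ("ldh", "lactate dehydrogenase", {"pyr": -1, "nadh": -1, "lac": +1, "nad": +1}, False),
    (
        "ech",
        "energy-converting membrane hydrogenase (lumped with ATP synthase)",
        {
            "fdred": -1,
            "adp": -ECH_ATP_PER_FD,
            "pi": -ECH_ATP_PER_FD,
            "fdox": +1,
            "h2": +1,
            "atp": +ECH_ATP_PER_FD,
            "h2o": +ECH_ATP_PER_FD,
        },
        False,
    ),
    (
        "nfn",
        "ferredoxin:NAD+ oxidoreductase",
        {"fdred": -1, "nad": -1, "fdox": +1, "nadh": +1},
        False,
    ),
    ("h2ase", "NADH-dependent hydrogenase", {"nadh": -1, "nad": +1, "h2": +1}, False),
    (
        "cs_re",
        "Re-type citrate synthase",
        {"accoa": -1, "oaa": -1, "cit": +1, "coa": +1},
        False,
    ),
    (
        "idh",
        "aconitase + isocitrate dehydrogenase",
        {"cit": -1, "nad": -1, "akg": +1, "co2": +1, "nadh": +1},
        False,
    ),
    ("ppc", "PEP carboxylase", {"pep": -1, "co2": -1, "oaa": +1}, False),
]

# 7 building-block syntheses feeding the biomass reaction; CoA carried on
# acetyl groups is returned to the pool
_BLOCK_REACTIONS = [
    ("bb_protein", {"pyr": -2.0, "akg": -1.0, "oaa": -1.0, "protein": +1.0}),
    ("bb_nucleotide", {"g6p": -1.0, "pg3": -1.0, "nucleotide": +1.0}),
    ("bb_lipid", {"accoa": -2.0, "gap": -0.5, "lipid": +1.0, "coa": +2.0}),
    ("bb_wall", {"f6p": -1.0, "accoa": -1.0, "pep": -0.5, "wall": +1.0, "coa": +1.0}),
    ("bb_glycogen", {"g6p": -1.0, "glycogen": +1.0}),
    ("bb_solute", {"pg3": -1.0, "pyr": -0.5, "solute": +1.0}),
    ("bb_cofactor", {"akg": -0.5, "accoa": -0.5, "cofactor": +1.0, "coa": +0.5}),
]

#: mmol of building block per g DCW
BLOCK_DEMANDS = {
    "protein": 0.90,
    "nucleotide": 0.35,
    "lipid": 0.35,
    "wall": 0.30,
    "glycogen": 0.25,
    "solute": 0.30,
    "cofactor": 0.10,
}

# gap-filled metabolites: shared with pathways outside the model scope,
# represented by reversible exchange reactions (the UTP principle)
_GAP_METABOLITES = [
    "utp", "gtp", "ctp", "ttp", "amp", "gmp", "cmp", "ump",
    "nadp", "nadph", "fad", "fadh2", "thf", "sam", "plp", "tpp",
] + [f"xpool{i:02d}" for i in range(1, 24)]

# alternate-route chains: 18 of length 7 and 3 of length 6, duplicating
# energy-neutral conversions of the core network
_CHAIN_SPECS = [("g6p", "f6p")] * 9 + [("pg3", "pep")] * 9 + [
    ("g6p", "f6p"),
    ("pg3", "pep"),
    ("g6p", "f6p"),
]
_CHAIN_LENGTHS = [7] * 18 + [6] * 3

EXPECTED_SPECIES = 196
EXPECTED_REACTIONS = 229


def build_x514_surrogate(
    glucose_uptake: float = DEFAULT_GLUCOSE_UPTAKE,
    ngam: float = DEFAULT_NGAM,
    gam: float = DEFAULT_GAM,
) -> MetabolicModel:
    """Build the surrogate model, ready for FBA (maximize biomass)."""
    model = MetabolicModel(id="x514_surrogate", organism="tex-like")
    for mid, name in _CORE_METABOLITES.items():
        model.add_metabolite(Metabolite(id=mid, name=name))
    for rid, name, stoich, reversible in _CORE_REACTIONS:
        kind = (
            ReactionKind.HETEROLOGOUS if rid == "cs_re" else ReactionKind.INTRACELLULAR
        )
        model.add_reaction(
            Reaction(
                id=rid,
                name=name,
                stoichiometry={m: float(c) for m, c in stoich.items()},
                reversible=reversible,
                kind=kind,
            )
        )

    # alternate-route chains (peripheral pathway padding)
    chain_first_intermediates = []
    for i, ((start, end), length) in enumerate(zip(_CHAIN_SPECS, _CHAIN_LENGTHS)):
        prev = start
        for j in range(1, length):
            node = f"alt{i:02d}_{j}"
            model.add_metabolite(Metabolite(id=node))
            model.add_reaction(
                Reaction(
                    id=f"altr{i:02d}_{j}",
                    stoichiometry={prev: -1.0, node: +1.0},
                )
            )
            if j == 1:
                chain_first_intermediates.append(node)
            prev = node
        model.add_reaction(
            Reaction(id=f"altr{i:02d}_{length}", stoichiometry={prev: -1.0, end: +1.0})
        )

    # building blocks + biomass
    for rid, stoich in _BLOCK_REACTIONS:
        for mid in stoich:
            if mid not in model.metabolites:
                model.add_metabolite(Metabolite(id=mid))
        model.add_reaction(
            Reaction(
                id=rid,
                stoichiometry=dict(stoich),
                kind=ReactionKind.BIOMASS,
            )
        )
    model = set_biomass(
        model,
        BiomassComposition(
            demands=dict(BLOCK_DEMANDS),
            gam=gam,
            atp_id="atp",
            adp_id="adp",
            pi_id="pi",
            h2o_id="h2o",
        ),
    )
    model = set_maintenance(
        model, ngam, atp_id="atp", adp_id="adp", pi_id="pi", h2o_id="h2o"
    )

    # gap-filling exchanges (metabolite-exchange principle)
    for mid in _GAP_METABOLITES:
        model.add_metabolite(Metabolite(id=mid))
        model.add_reaction(
            Reaction(
                id=f"gap_{mid}",
                name=f"gap-filling exchange of {mid}",
                stoichiometry={mid: -1.0},
                reversible=True,
                kind=ReactionKind.GAP_FILL,
            )
        )

    # inflows/outflows (19): transporters with published evidence are
    # open; speculative ones are present but closed (bounds [0, 0])
    model = add_inflow(model, "glc", GLUCOSE_INFLOW_ID, upper_bound=glucose_uptake)
    model = add_inflow(model, "h2o", "h2o_in")
    # mineral phosphate uptake balances the phosphate exported inside
    # phosphorylated biomass precursors
    model = add_inflow(model, "pi", "pi_in")
    model = add_outflow(model, "h2o", "h2o_out")
    model = add_outflow(model, "ace", ACETATE_OUTFLOW_ID)
    model = add_outflow(model, "etoh", ETHANOL_OUTFLOW_ID)
    model = add_outflow(model, "lac", "lac_out")
    model = add_outflow(model, "co2", "co2_out")
    model = add_outflow(model, "h2", "h2_out")
    for k, mid in enumerate(chain_first_intermediates[:10]):
        model = add_outflow(model, mid, f"minor_out{k:02d}", upper_bound=0.0)

    model.objective = ObjectiveSpec({"biomass_production": 1.0})
    assert len(model.metabolites) == EXPECTED_SPECIES, len(model.metabolites)
    assert len(model.reactions) == EXPECTED_REACTIONS, len(model.reactions)
    model.validate()
    return model
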