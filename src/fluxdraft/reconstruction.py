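"""Model customization: exchanges, biomass, maintenance, knockouts, edits.

Every operation is pure: it validates against the input model, then
returns an edited deep copy, so callers can diff before/after and batch
edits are trivially atomic.

Unit conventions: exchange and intracellular fluxes are mmol/g DCW/h;
biomass demands are mmol of building block per g DCW, which makes the
biomass reaction flux the specific growth rate in 1/h; GAM is mmol ATP
per g DCW (growth-associated), NGAM is mmol ATP/g DCW/h (a constant
hydrolysis flux).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable

import yaml

from .model import (
    DEFAULT_FLUX_BOUND,
    MetabolicModel,
    Metabolite,
    ModelError,
    ObjectiveSpec,
    Reaction,
    ReactionKind,
)

BIOMASS_SPECIES_ID = "biomass"
BIOMASS_REACTION_ID = "biomass_production"
BIOMASS_SINK_ID = "biomass_out"
MAINTENANCE_REACTION_ID = "atp_maintenance"


class EditError(ModelError):
    """Invalid reconstruction directive."""


@dataclass
class BiomassComposition:
    """Building-block demands plus the growth-associated ATP cost.

    ``demands`` maps metabolite id -> mmol required per g DCW formed.
    ``gam`` mmol ATP hydrolysed per g DCW formed, realised as
    gam ATP + gam H2O -> gam ADP + gam Pi inside the biomass reaction.
    """

    demands: dict[str, float]
    gam: float = 0.0
    atp_id: str = "C00002"
    adp_id: str = "C00008"
    pi_id: str = "C00009"
    h2o_id: str = "C00001"

    def __post_init__(self) -> None:
        if not self.demands:
            raise EditError("biomass composition needs at least one demand")
        if any(v < 0 for v in self.demands.values()):
            raise EditError("biomass demands must be >= 0")
        if not (self.gam >= 0):
            raise EditError("gam must be a finite value >= 0")


def _fresh_id(model: MetabolicModel, reaction_id: str) -> None:
    if reaction_id in model.reactions:
        raise EditError(f"reaction id {reaction_id!r} already exists")


def add_inflow(
    model: MetabolicModel,
    target_metabolite: str,
    reaction_id: str,
    upper_bound: float = DEFAULT_FLUX_BOUND,
    fixed: float | None = None,
) -> MetabolicModel:
    """Add a nutrient source reaction (emptyset -> target).

    ``fixed`` pins the uptake rate (lb = ub = fixed), the usual way of
    imposing a measured substrate consumption rate.
    """
    _fresh_id(model, reaction_id)
    out = model.copy()
    if target_metabolite not in out.metabolites:
        out.add_metabolite(Metabolite(id=target_metabolite))
    lb, ub = (0.0, upper_bound) if fixed is None else (fixed, fixed)
    out.add_reaction(
        Reaction(
            id=reaction_id,
            name=f"inflow of {target_metabolite}",
            stoichiometry={target_metabolite: +1.0},
            reversible=False,
            lower_bound=lb,
            upper_bound=ub,
            kind=ReactionKind.INFLOW,
        )
    )
    return out


def add_outflow(
    model: MetabolicModel,
    source_metabolite: str,
    reaction_id: str,
    upper_bound: float = DEFAULT_FLUX_BOUND,
    fixed: float | None = None,
    kind: ReactionKind = ReactionKind.OUTFLOW,
) -> MetabolicModel:
    """Add a secretion/sink reaction (source -> emptyset)."""
    _fresh_id(model, reaction_id)
    out = model.copy()
    if source_metabolite not in out.metabolites:
        out.add_metabolite(Metabolite(id=source_metabolite))
    lb, ub = (0.0, upper_bound) if fixed is None else (fixed, fixed)
    out.add_reaction(
        Reaction(
            id=reaction_id,
            name=f"outflow of {source_metabolite}",
            stoichiometry={source_metabolite: -1.0},
            reversible=False,
            lower_bound=lb,
            upper_bound=ub,
            kind=kind,
        )
    )
    return out


def add_reaction(
    model: MetabolicModel,
    reaction: Reaction,
) -> MetabolicModel:
    """Add a heterologous or gap-fill reaction; new metabolites are
    auto-registered."""
    _fresh_id(model, reaction.id)
    out = model.copy()
    out.add_reaction(reaction.copy(), register_metabolites=True)
    return out


def knockout(model: MetabolicModel, reaction_ids: list[str] | str) -> MetabolicModel:
    """Zero the bounds of the named reactions (kept for reporting)."""
    if isinstance(reaction_ids, str):
        reaction_ids = [reaction_ids]
    unknown = [rid for rid in reaction_ids if rid not in model.reactions]
    if unknown:
        raise EditError(f"cannot knock out unknown reaction(s): {unknown}")
    out = model.copy()
    for rid in reaction_ids:
        rxn = out.reactions[rid]
        rxn.lower_bound = 0.0
        rxn.upper_bound = 0.0
    return out


def set_bounds(
    model: MetabolicModel, reaction_id: str, lower: float, upper: float
) -> MetabolicModel:
    if reaction_id not in model.reactions:
        raise EditError(f"unknown reaction {reaction_id!r}")
    if lower > upper:
        raise EditError(f"lower bound {lower} > upper bound {upper}")
    out = model.copy()
    rxn = out.reactions[reaction_id]
    if not rxn.reversible and lower < 0:
        raise EditError(
            f"reaction {reaction_id!r} is irreversible; lower bound must be >= 0"
        )
    rxn.lower_bound = lower
    rxn.upper_bound = upper
    return out


def modify_reaction(
    model: MetabolicModel,
    reaction_id: str,
    new_direction: str | None = None,
    participant_edits: dict[str, float | None] | None = None,
) -> MetabolicModel:
    """Retune a reaction's direction and/or participants.

    ``new_direction``: "forward" (irreversible as written), "backward"
    (stoichiometry negated, then irreversible — stored coefficients always
    read left-to-right forward) or "reversible".  ``participant_edits``
    maps metabolite id -> new signed coefficient, or None to delete the
    participant.  Edits must leave at least one substrate and one product.
    """
    if reaction_id not in model.reactions:
        raise EditError(f"unknown reaction {reaction_id!r}")
    out = model.copy()
    rxn = out.reactions[reaction_id]
    if participant_edits:
        stoich = dict(rxn.stoichiometry)
        for mid, coeff in participant_edits.items():
            if coeff is None:
                stoich.pop(mid, None)
            elif coeff == 0:
                raise EditError(f"zero coefficient for {mid!r}; delete instead")
            else:
                stoich[mid] = float(coeff)
                if mid not in out.metabolites:
                    out.add_metabolite(Metabolite(id=mid))
        if not any(c < 0 for c in stoich.values()) or not any(
            c > 0 for c in stoich.values()
        ):
            raise EditError(
                f"edits to {reaction_id!r} must leave >=1 substrate and >=1 product"
            )
        rxn.stoichiometry = stoich
    if new_direction is not None:
        if new_direction == "forward":
            rxn.reversible = False
            rxn.lower_bound = max(0.0, rxn.lower_bound)
        elif new_direction == "backward":
            rxn.stoichiometry = {m: -c for m, c in rxn.stoichiometry.items()}
            rxn.reversible = False
            rxn.lower_bound = 0.0
            rxn.upper_bound = abs(rxn.upper_bound) or DEFAULT_FLUX_BOUND
        elif new_direction == "reversible":
            rxn.reversible = True
            rxn.lower_bound = min(rxn.lower_bound, -DEFAULT_FLUX_BOUND)
        else:
            raise EditError(f"unknown direction {new_direction!r}")
    return out


def set_biomass(
    model: MetabolicModel, composition: BiomassComposition
) -> MetabolicModel:
    """Install the biomass pseudo-reaction and its sink.

    The reaction consumes each demanded building block (mmol/g DCW) plus
    gam ATP and gam H2O, produces gam ADP and gam Pi, and produces one
    unit of a synthetic biomass species which a paired sink drains; the
    flux through it is the specific growth rate (1/h).  Replaces any
    previous biomass reaction, and becomes the model objective if none is
    set.
    """
    missing = [m for m in composition.demands if m not in model.metabolites]
    if missing:
        raise EditError(f"biomass demands unknown metabolite(s): {missing}")
    out = model.copy()
    stoich: dict[str, float] = {m: -v for m, v in composition.demands.items() if v > 0}
    if composition.gam > 0:
        couple = (
            composition.atp_id,
            composition.adp_id,
            composition.pi_id,
            composition.h2o_id,
        )
        missing = [m for m in couple if m not in out.metabolites]
        if missing:
            raise EditError(
                f"gam > 0 but energy-couple metabolite(s) missing: {missing}"
            )
        atp, adp, pi, h2o = couple
        stoich[atp] = stoich.get(atp, 0.0) - composition.gam
        stoich[h2o] = stoich.get(h2o, 0.0) - composition.gam
        stoich[adp] = stoich.get(adp, 0.0) + composition.gam
        stoich[pi] = stoich.get(pi, 0.0) + composition.gam
    if BIOMASS_SPECIES_ID not in out.metabolites:
        out.add_metabolite(Metabolite(id=BIOMASS_SPECIES_ID, name="biomass"))
    stoich[BIOMASS_SPECIES_ID] = stoich.get(BIOMASS_SPECIES_ID, 0.0) + 1.0
    out.reactions.pop(BIOMASS_REACTION_ID, None)
    out.reactions.pop(BIOMASS_SINK_ID, None)
    out.add_reaction(
        Reaction(
            id=BIOMASS_REACTION_ID,
            name="biomass production",
            stoichiometry={m: c for m, c in stoich.items() if c != 0},
            reversible=False,
            kind=ReactionKind.BIOMASS,
        )
    )
    out.add_reaction(
        Reaction(
            id=BIOMASS_SINK_ID,
            name="biomass sink",
            stoichiometry={BIOMASS_SPECIES_ID: -1.0},
            reversible=False,
            kind=ReactionKind.BIOMASS,
        )
    )
    out.biomass_composition = composition
    if out.objective is None:
        out.objective = ObjectiveSpec({BIOMASS_REACTION_ID: 1.0})
    return out


def set_maintenance(
    model: MetabolicModel,
    ngam: float,
    atp_id: str = "C00002",
    adp_id: str = "C00008",
    pi_id: str = "C00009",
    h2o_id: str = "C00001",
) -> MetabolicModel:
    """Install the non-growth-associated maintenance reaction
    ATP + H2O -> ADP + Pi with lb = ub = ngam (mmol ATP/g DCW/h)."""
    if ngam < 0:
        raise EditError("ngam must be >= 0")
    couple = (atp_id, adp_id, pi_id, h2o_id)
    missing = [m for m in couple if m not in model.metabolites]
    if missing:
        raise EditError(f"energy-couple metabolite(s) missing: {missing}")
    out = model.copy()
    out.reactions.pop(MAINTENANCE_REACTION_ID, None)
    out.add_reaction(
        Reaction(
            id=MAINTENANCE_REACTION_ID,
            name="non-growth-associated maintenance",
            stoichiometry={atp_id: -1.0, h2o_id: -1.0, adp_id: +1.0, pi_id: +1.0},
            reversible=False,
            lower_bound=ngam,
            upper_bound=ngam,
            kind=ReactionKind.MAINTENANCE,
        )
    )
    return out


def set_objective(
    model: MetabolicModel,
    coefficients: dict[str, float],
    direction: str = "maximize",
) -> MetabolicModel:
    unknown = [rid for rid in coefficients if rid not in model.reactions]
    if unknown:
        raise EditError(f"objective references unknown reaction(s): {unknown}")
    out = model.copy()
    out.objective = ObjectiveSpec(dict(coefficients), direction)
    return out


# -- edit scripts ---------------------------------------------------------

_DIRECTIVES: dict[str, Callable[..., MetabolicModel]] = {}


def _directive(name: str):
    def register(fn):
        _DIRECTIVES[name] = fn
        return fn

    return register


@_directive("add_inflow")
def _d_add_inflow(model, p):
    return add_inflow(
        model,
        p["metabolite"],
        p["reaction_id"],
        upper_bound=p.get("upper_bound", DEFAULT_FLUX_BOUND),
        fixed=p.get("fixed"),
    )


@_directive("add_outflow")
def _d_add_outflow(model, p):
    return add_outflow(
        model,
        p["metabolite"],
        p["reaction_id"],
        upper_bound=p.get("upper_bound", DEFAULT_FLUX_BOUND),
        fixed=p.get("fixed"),
        kind=ReactionKind(p.get("kind", "outflow")),
    )


@_directive("add_reaction")
def _d_add_reaction(model, p):
    return add_reaction(
        model,
        Reaction(
            id=p["reaction_id"],
            name=p.get("name", ""),
            stoichiometry={m: float(c) for m, c in p["stoichiometry"].items()},
            reversible=bool(p.get("reversible", False)),
            lower_bound=p.get("lower_bound"),
            upper_bound=p.get("upper_bound"),
            kind=ReactionKind(p.get("kind", "heterologous")),
        ),
    )


@_directive("knockout")
def _d_knockout(model, p):
    return knockout(model, p["reaction_ids"])


@_directive("modify_reaction")
def _d_modify(model, p):
    return modify_reaction(
        model,
        p["reaction_id"],
        new_direction=p.get("direction"),
        participant_edits=p.get("participants"),
    )


@_directive("set_bounds")
def _d_set_bounds(model, p):
    return set_bounds(model, p["reaction_id"], float(p["lower"]), float(p["upper"]))


@_directive("set_biomass")
def _d_set_biomass(model, p):
    return set_biomass(
        model,
        BiomassComposition(
            demands={m: float(v) for m, v in p["demands"].items()},
            gam=float(p.get("gam", 0.0)),
            atp_id=p.get("atp_id", "C00002"),
            adp_id=p.get("adp_id", "C00008"),
            pi_id=p.get("pi_id", "C00009"),
            h2o_id=p.get("h2o_id", "C00001"),
        ),
    )


@_directive("set_maintenance")
def _d_set_maintenance(model, p):
    return set_maintenance(
        model,
        float(p["ngam"]),
        atp_id=p.get("atp_id", "C00002"),
        adp_id=p.get("adp_id", "C00008"),
        pi_id=p.get("pi_id", "C00009"),
        h2o_id=p.get("h2o_id", "C00001"),
    )


@_directive("set_objective")
def _d_set_objective(model, p):
    return set_objective(
        model,
        {rid: float(c) for rid, c in p["coefficients"].items()},
        direction=p.get("direction", "maximize"),
    )


@dataclass
class EditScript:
    """Ordered, atomic batch of reconstruction directives."""

    directives: list[dict[str, Any]] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, text: str) -> "EditScript":
        doc = yaml.safe_load(text)
        if not isinstance(doc, dict) or "edits" not in doc:
            raise EditError("edit script must be a mapping with an 'edits' list")
        edits = doc["edits"]
        if not isinstance(edits, list):
            raise EditError("'edits' must be a list of directives")
        for i, d in enumerate(edits):
            if not isinstance(d, dict) or "op" not in d:
                raise EditError(f"directive {i}: missing 'op'")
            if d["op"] not in _DIRECTIVES:
                raise EditError(f"directive {i}: unknown op {d['op']!r}")
        return cls(directives=list(edits))


def apply_edit_script(model: MetabolicModel, script: EditScript) -> MetabolicModel:
    """Apply directives in order; atomic.

    The whole script is applied to a working copy, so the first failing
    directive (reported with its position) leaves the input model
    untouched.
    """
    current = model
    for i, d in enumerate(script.directives):
        op = d.get("op")
        handler = _DIRECTIVES.get(op)
        if handler is None:
            raise EditError(f"directive {i}: unknown op {op!r}")
        params = {k: v for k, v in d.items() if k != "op"}
        try:
            current = handler(current, params)
        except (EditError, ModelError, KeyError, TypeError, ValueError) as exc:
            raise EditError(f"directive {i} ({op}): {exc}") from exc
    return current
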