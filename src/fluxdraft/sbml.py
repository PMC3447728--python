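"""SBML import/export.

Writes SBML Level 3 Version 1 with the flux-balance-constraints (fbc v2)
package: species carry ``boundaryCondition`` for external metabolites,
reactions carry fbc flux bounds, and the model carries an fbc objective.
Reads both that dialect and the legacy Level 2 encoding used by
2012-era constraint-based models, where bounds and objective coefficients
live in kinetic-law parameters named LOWER_BOUND / UPPER_BOUND /
OBJECTIVE_COEFFICIENT, with model notes as a last resort.

Ids that are not valid SBML SIds (leading digit, odd characters) are
sanitized on export; the original id is embedded in the entity notes so a
round trip restores it exactly.
"""

from __future__ import annotations

import logging
import re

import libsbml

from .fba import FluxDistribution
from .model import (
    DEFAULT_FLUX_BOUND,
    MetabolicModel,
    Metabolite,
    ModelError,
    ObjectiveSpec,
    Reaction,
    ReactionKind,
)

logger = logging.getLogger(__name__)

_SID_OK = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")
_PLAIN_FORMULA = re.compile(r"^(?:[A-Z][a-z]?\d*)+$")
_NOTE_FIELD = re.compile(r"<p>\s*([a-z_]+)\s*:\s*(.*?)\s*</p>", re.IGNORECASE)


class SBMLError(ValueError):
    """Unreadable or invalid SBML input."""


def sanitize_id(raw: str, taken: set[str]) -> str:
    sid = re.sub(r"[^A-Za-z0-9_]", "_", raw)
    if not sid or not re.match(r"^[A-Za-z_]", sid):
        sid = "_" + sid
    base = sid
    n = 2
    while sid in taken:
        sid = f"{base}_{n}"
        n += 1
    taken.add(sid)
    return sid


def _notes_body(fields: dict[str, str]) -> str:
    ps = "".join(f"<p>{k}: {v}</p>" for k, v in fields.items())
    return f'<body xmlns="http://www.w3.org/1999/xhtml">{ps}</body>'


def _read_note_fields(node) -> dict[str, str]:
    if not node.isSetNotes():
        return {}
    text = node.getNotesString()
    return {k.lower(): v for k, v in _NOTE_FIELD.findall(text)}


def _check(status, what: str) -> None:
    if status not in (None, libsbml.LIBSBML_OPERATION_SUCCESS):
        raise SBMLError(f"libsbml error while setting {what}: status {status}")


def write_sbml(
    model: MetabolicModel,
    fluxes: FluxDistribution | None = None,
    path: str | None = None,
) -> str:
    """Serialize a model (optionally with a flux solution embedded in
    per-reaction notes) to SBML L3V1 + fbc v2; returns the document text
    and writes it to ``path`` when given."""
    model.validate()
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    taken: set[str] = set()
    _check(sm.setId(sanitize_id(model.id or "model", taken)), "model id")
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(False)
    if model.organism:
        sm.setNotes(_notes_body({"organism": model.organism}))

    comp = sm.createCompartment()
    comp.setId("cell")
    comp.setConstant(True)
    comp.setSize(1.0)
    taken.add("cell")

    species_sid: dict[str, str] = {}
    for mid in sorted(model.metabolites):
        met = model.metabolites[mid]
        sid = sanitize_id(mid, taken)
        species_sid[mid] = sid
        sp = sm.createSpecies()
        _check(sp.setId(sid), f"species id {mid}")
        if met.name:
            sp.setName(met.name)
        sp.setCompartment("cell")
        sp.setBoundaryCondition(met.external)
        sp.setHasOnlySubstanceUnits(False)
        sp.setConstant(False)
        if met.formula and _PLAIN_FORMULA.match(met.formula):
            sp.getPlugin("fbc").setChemicalFormula(met.formula)
        note_fields = {}
        if sid != mid:
            note_fields["original_id"] = mid
        if note_fields:
            sp.setNotes(_notes_body(note_fields))

    # one shared parameter per distinct bound value
    bound_param: dict[float, str] = {}

    def bound_id(value: float) -> str:
        if value not in bound_param:
            pid = sanitize_id(f"fb_{len(bound_param)}", taken)
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_param[value] = pid
        return bound_param[value]

    reaction_sid: dict[str, str] = {}
    for rid in sorted(model.reactions):
        rxn = model.reactions[rid]
        sid = sanitize_id(rid, taken)
        reaction_sid[rid] = sid
        sr = sm.createReaction()
        _check(sr.setId(sid), f"reaction id {rid}")
        if rxn.name:
            sr.setName(rxn.name)
        sr.setReversible(rxn.reversible)
        sr.setFast(False)
        for mid in sorted(rxn.stoichiometry):
            coeff = rxn.stoichiometry[mid]
            ref = sr.createReactant() if coeff < 0 else sr.createProduct()
            ref.setSpecies(species_sid[mid])
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        rplug = sr.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_id(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_id(rxn.upper_bound))
        note_fields = {"kind": rxn.kind.value}
        if sid != rid:
            note_fields["original_id"] = rid
        if fluxes is not None and rid in fluxes.fluxes:
            note_fields["flux"] = f"{fluxes.fluxes[rid]:.17g}"
        sr.setNotes(_notes_body(note_fields))

    if model.objective is not None:
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType(model.objective.direction)
        for rid in sorted(model.objective.coefficients):
            coeff = model.objective.coefficients[rid]
            if coeff == 0:
                continue
            fo = obj.createFluxObjective()
            fo.setReaction(reaction_sid[rid])
            fo.setCoefficient(coeff)
        mplug.setActiveObjectiveId("obj")

    text = libsbml.writeSBMLToString(doc)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def _legacy_kinetic_params(sr) -> dict[str, float]:
    params: dict[str, float] = {}
    kl = sr.getKineticLaw()
    if kl is None:
        return params
    for i in range(kl.getNumParameters()):
        p = kl.getParameter(i)
        params[p.getId().upper()] = p.getValue()
    return params


def read_sbml(source: str) -> tuple[MetabolicModel, FluxDistribution | None]:
    """Read a model from an SBML file path or document string.

    Returns the model plus the embedded flux distribution if the document
    carries per-reaction flux notes, else None.  Missing bounds fall back
    to the package defaults (reversible +-M, irreversible [0, M]) with a
    warning.
    """
    if "<sbml" in source:
        doc = libsbml.readSBMLFromString(source)
    else:
        doc = libsbml.readSBMLFromFile(source)
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            raise SBMLError(f"SBML read error: {err.getMessage().strip()}")
    sm = doc.getModel()
    if sm is None:
        raise SBMLError("document contains no SBML model")

    model = MetabolicModel(id=sm.getId() or "model")
    model_notes = _read_note_fields(sm)
    model.organism = model_notes.get("organism", "")

    global_params: dict[str, float] = {}
    for i in range(sm.getNumParameters()):
        p = sm.getParameter(i)
        global_params[p.getId()] = p.getValue()

    sid_to_original: dict[str, str] = {}
    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        fields = _read_note_fields(sp)
        mid = fields.get("original_id", sp.getId())
        sid_to_original[sp.getId()] = mid
        formula = None
        fplug = sp.getPlugin("fbc")
        if fplug is not None and fplug.isSetChemicalFormula():
            formula = fplug.getChemicalFormula()
        model.add_metabolite(
            Metabolite(
                id=mid,
                name=sp.getName() or "",
                formula=formula,
                external=bool(sp.getBoundaryCondition()),
            )
        )

    mplug = sm.getPlugin("fbc")
    fluxes: dict[str, float] = {}
    legacy_objective: dict[str, float] = {}
    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        fields = _read_note_fields(sr)
        rid = fields.get("original_id", sr.getId())
        stoich: dict[str, float] = {}
        for j in range(sr.getNumReactants()):
            ref = sr.getReactant(j)
            mid = sid_to_original.get(ref.getSpecies(), ref.getSpecies())
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for j in range(sr.getNumProducts()):
            ref = sr.getProduct(j)
            mid = sid_to_original.get(ref.getSpecies(), ref.getSpecies())
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        stoich = {m: c for m, c in stoich.items() if c != 0}
        if not stoich:
            logger.warning("reaction %s has empty net stoichiometry; skipped", rid)
            continue
        reversible = bool(sr.getReversible())

        lb = ub = None
        rplug = sr.getPlugin("fbc")
        if rplug is not None and rplug.isSetLowerFluxBound():
            lb = global_params.get(rplug.getLowerFluxBound())
        if rplug is not None and rplug.isSetUpperFluxBound():
            ub = global_params.get(rplug.getUpperFluxBound())
        if lb is None or ub is None:
            legacy = _legacy_kinetic_params(sr)
            lb = legacy.get("LOWER_BOUND", lb)
            ub = legacy.get("UPPER_BOUND", ub)
            if legacy.get("OBJECTIVE_COEFFICIENT"):
                legacy_objective[rid] = legacy["OBJECTIVE_COEFFICIENT"]
        if lb is None and "lower_bound" in fields:
            lb = float(fields["lower_bound"])
        if ub is None and "upper_bound" in fields:
            ub = float(fields["upper_bound"])
        if lb is None or ub is None:
            logger.warning(
                "reaction %s: no flux bounds found; using defaults", rid
            )
            if lb is None:
                lb = -DEFAULT_FLUX_BOUND if reversible else 0.0
            if ub is None:
                ub = DEFAULT_FLUX_BOUND
        kind = fields.get("kind", "intracellular")
        try:
            kind = ReactionKind(kind)
        except ValueError:
            kind = ReactionKind.INTRACELLULAR
        model.add_reaction(
            Reaction(
                id=rid,
                name=sr.getName() or "",
                stoichiometry=stoich,
                reversible=reversible,
                lower_bound=float(lb),
                upper_bound=float(ub),
                kind=kind,
            ),
            register_metabolites=True,
        )
        if "flux" in fields:
            fluxes[rid] = float(fields["flux"])

    reaction_sid_to_original = {}
    for i in range(sm.getNumReactions()):
        sr = sm.getReaction(i)
        fields = _read_note_fields(sr)
        reaction_sid_to_original[sr.getId()] = fields.get("original_id", sr.getId())

    objective = None
    if mplug is not None and mplug.getNumObjectives() > 0:
        obj = mplug.getActiveObjective() or mplug.getObjective(0)
        coeffs = {}
        for j in range(obj.getNumFluxObjectives()):
            fo = obj.getFluxObjective(j)
            rid = reaction_sid_to_original.get(fo.getReaction(), fo.getReaction())
            coeffs[rid] = fo.getCoefficient()
        if coeffs:
            objective = ObjectiveSpec(coeffs, obj.getType())
    if objective is None and legacy_objective:
        objective = ObjectiveSpec(legacy_objective, "maximize")
    model.objective = objective

    model.validate()
    embedded = (
        FluxDistribution(status="optimal", objective_value=None, fluxes=fluxes)
        if fluxes
        else None
    )
    return model, embedded


def validate_document(text: str) -> int:
    """Number of SBML consistency errors (warnings excluded)."""
    doc = libsbml.readSBMLFromString(text)
    doc.checkConsistency()
    n = 0
    for i in range(doc.getNumErrors()):
        if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            n += 1
    return n
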