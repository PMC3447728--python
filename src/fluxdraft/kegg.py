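"""KGML pathway parsing, LIGAND-style reaction tables, and draft assembly.

The drafting strategy mirrors genome-annotation-driven model building:
organism-specific pathway maps (KGML) say *which* reactions an organism
carries and in which direction, while the general reaction database
(LIGAND-style equation strings over C-number compound ids) supplies the
full stoichiometry including cofactors.  The union of reactions across the
organism's maps, each resolved against its equation, is the seed model.
"""

from __future__ import annotations

import logging
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

from .model import MetabolicModel, Metabolite, ModelError, Reaction, ReactionKind

logger = logging.getLogger(__name__)

_REACTION_ID = re.compile(r"^R\d{5}$")
_COMPOUND_TERM = re.compile(r"^(?:(\d+(?:\.\d+)?)\s+)?(C\d{5})$")


class KGMLParseError(ValueError):
    """Malformed KGML document."""


class EquationParseError(ValueError):
    """Equation outside the supported LIGAND grammar."""


@dataclass
class KGMLReaction:
    id: str
    reversible: bool
    substrates: list[str]
    products: list[str]


@dataclass
class KGMLPathway:
    pathway_id: str
    organism: str
    reactions: list[KGMLReaction]


def _strip_prefix(token: str, prefix: str) -> str:
    return token[len(prefix):] if token.startswith(prefix) else token


def parse_kgml(document: str) -> KGMLPathway:
    """Parse one KGML pathway document.

    Every ``<reaction>`` element yields one record per reaction id in its
    ``name`` attribute (KGML packs several "rn:R#####" ids into one
    element when a map edge is catalysed by several reactions).  A missing
    ``type`` attribute defaults to reversible with a logged warning.
    """
    try:
        root = ET.fromstring(document)
    except ET.ParseError as exc:
        raise KGMLParseError(f"malformed KGML: {exc}") from exc
    if root.tag != "pathway":
        raise KGMLParseError(f"not a KGML document (root <{root.tag}>)")
    pathway_id = _strip_prefix(root.get("name", ""), "path:")
    organism = root.get("org", "")
    reactions: list[KGMLReaction] = []
    for elem in root.iter("reaction"):
        rtype = elem.get("type")
        if rtype is None:
            logger.warning(
                "KGML %s: reaction %s has no type attribute; assuming reversible",
                pathway_id, elem.get("name"),
            )
            rtype = "reversible"
        substrates = [
            _strip_prefix(s.get("name", ""), "cpd:")
            for s in elem.findall("substrate")
        ]
        products = [
            _strip_prefix(p.get("name", ""), "cpd:")
            for p in elem.findall("product")
        ]
        for token in (elem.get("name") or "").split():
            rid = _strip_prefix(token, "rn:")
            if not _REACTION_ID.match(rid):
                raise KGMLParseError(
                    f"KGML {pathway_id}: invalid reaction id {token!r}"
                )
            reactions.append(
                KGMLReaction(
                    id=rid,
                    reversible=(rtype == "reversible"),
                    substrates=list(substrates),
                    products=list(products),
                )
            )
    return KGMLPathway(pathway_id=pathway_id, organism=organism, reactions=reactions)


def parse_equation(equation: str) -> dict[str, float]:
    """Parse a LIGAND equation string into a signed stoichiometry map.

    Grammar: terms ``[coef] C#####`` joined by `` + ``, sides joined by
    ``<=>`` (or ``=>``).  Left-side terms are negative, right-side
    positive; an omitted coefficient is 1; a compound on both sides nets
    out (and is dropped if the net is zero).  Non-numeric coefficients
    (``n``, ``(n+1)``) and glycan ``G#####`` terms raise
    EquationParseError — such reactions are excluded from drafting rather
    than approximated.
    """
    for arrow in ("<=>", "=>"):
        if arrow in equation:
            left, right = equation.split(arrow, 1)
            break
    else:
        raise EquationParseError(f"no arrow in equation: {equation!r}")
    stoich: dict[str, float] = {}

    def _accumulate(side: str, sign: float) -> None:
        for term in side.split(" + "):
            term = term.strip()
            if not term:
                raise EquationParseError(f"empty term in equation: {equation!r}")
            match = _COMPOUND_TERM.match(term)
            if not match:
                raise EquationParseError(
                    f"unsupported term {term!r} in equation: {equation!r}"
                )
            coef_text, compound = match.groups()
            coef = float(coef_text) if coef_text else 1.0
            stoich[compound] = stoich.get(compound, 0.0) + sign * coef

    _accumulate(left, -1.0)
    _accumulate(right, +1.0)
    stoich = {c: v for c, v in stoich.items() if v != 0.0}
    if not stoich:
        raise EquationParseError(f"equation nets to nothing: {equation!r}")
    return stoich


@dataclass
class ReactionDefinition:
    reaction_id: str
    name: str = ""
    equation: str = ""
    parsed_stoichiometry: dict[str, float] = field(default_factory=dict)
    parse_ok: bool = False
    parse_error: str = ""


def _make_definition(reaction_id: str, name: str, equation: str) -> ReactionDefinition:
    try:
        stoich = parse_equation(equation)
    except EquationParseError as exc:
        logger.warning("reaction %s: %s", reaction_id, exc)
        return ReactionDefinition(
            reaction_id, name, equation, parse_ok=False, parse_error=str(exc)
        )
    return ReactionDefinition(
        reaction_id, name, equation, parsed_stoichiometry=stoich, parse_ok=True
    )


def parse_reaction_table(text: str) -> list[ReactionDefinition]:
    """Parse reaction definitions from LIGAND flat-file records
    (ENTRY/NAME/EQUATION, records terminated by ``///``) or, as a
    fallback, from a 3-column TSV (id, name, equation).

    Parse failures are flagged on the definition, never fatal; a duplicate
    reaction id keeps the first occurrence with a logged warning.
    """
    definitions: list[ReactionDefinition] = []
    seen: set[str] = set()

    def _push(reaction_id: str, name: str, equation: str) -> None:
        if reaction_id in seen:
            logger.warning("duplicate reaction id %s: keeping first", reaction_id)
            return
        seen.add(reaction_id)
        definitions.append(_make_definition(reaction_id, name, equation))

    stripped = text.strip()
    if not stripped:
        return []
    if "ENTRY" in stripped:
        for record in stripped.split("///"):
            record = record.strip("\n")
            if not record.strip():
                continue
            fields: dict[str, str] = {}
            current = None
            for line in record.splitlines():
                if not line.strip():
                    continue
                if line[:1].isspace():  # continuation line
                    if current:
                        fields[current] += " " + line.strip()
                    continue
                key, _, value = line.partition(" ")
                current = key
                fields[current] = value.strip()
            entry = fields.get("ENTRY", "").split()
            if not entry:
                logger.warning("flat-file record without ENTRY skipped")
                continue
            _push(entry[0], fields.get("NAME", ""), fields.get("EQUATION", ""))
    else:
        for line in stripped.splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                logger.warning("TSV line with <3 columns skipped: %r", line)
                continue
            _push(parts[0].strip(), parts[1].strip(), parts[2].strip())
    return definitions


@dataclass
class DraftReport:
    """What the drafting step left out, and why."""

    skipped: dict[str, str] = field(default_factory=dict)  # reaction id -> reason
    orientation_warnings: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "skipped": dict(sorted(self.skipped.items())),
            "orientation_warnings": list(self.orientation_warnings),
        }

    def as_text(self) -> str:
        lines = [f"skipped reactions: {len(self.skipped)}"]
        for rid, reason in sorted(self.skipped.items()):
            lines.append(f"  {rid}\t{reason}")
        for w in self.orientation_warnings:
            lines.append(f"  orientation: {w}")
        return "\n".join(lines)


def assemble_draft(
    pathways: list[KGMLPathway],
    definitions: list[ReactionDefinition],
    organism: str,
    model_id: str | None = None,
) -> MetabolicModel:
    """Cross-reference pathway maps against reaction definitions into a
    seed model.

    Reaction ids are deduplicated across maps (each appears once); the
    stoichiometry comes from the matching definition (KGML substrate and
    product lists carry no coefficients and omit cofactors, so they are
    used only for orientation sanity checks); if maps disagree on
    reversibility the reaction is kept reversible (least restrictive).
    Reactions with no definition or an unparsable equation are skipped and
    listed in ``model.draft_report``.
    """
    for pw in pathways:
        if pw.organism and pw.organism != organism:
            raise ModelError(
                f"pathway {pw.pathway_id} is for organism {pw.organism!r}, "
                f"not {organism!r}"
            )
    def_by_id = {}
    for d in definitions:
        def_by_id.setdefault(d.reaction_id, d)

    reversibility: dict[str, bool] = {}
    kgml_sides: dict[str, tuple[set[str], set[str]]] = {}
    order: list[str] = []
    for pw in pathways:
        for rec in pw.reactions:
            if rec.id not in reversibility:
                reversibility[rec.id] = rec.reversible
                kgml_sides[rec.id] = (set(rec.substrates), set(rec.products))
                order.append(rec.id)
            elif reversibility[rec.id] != rec.reversible:
                # conflict across maps: least restrictive wins
                reversibility[rec.id] = True

    report = DraftReport()
    model = MetabolicModel(
        id=model_id or f"{organism}_draft", organism=organism
    )
    for rid in order:
        definition = def_by_id.get(rid)
        if definition is None:
            report.skipped[rid] = "no reaction definition"
            continue
        if not definition.parse_ok:
            report.skipped[rid] = f"unparsable equation: {definition.parse_error}"
            continue
        stoich = dict(definition.parsed_stoichiometry)
        subs, prods = kgml_sides[rid]
        eq_subs = {m for m, c in stoich.items() if c < 0}
        eq_prods = {m for m, c in stoich.items() if c > 0}
        if subs and prods and subs <= eq_prods and prods <= eq_subs:
            msg = (
                f"{rid}: KGML orientation is flipped relative to the "
                "equation; keeping equation orientation"
            )
            logger.warning(msg)
            report.orientation_warnings.append(msg)
        model.add_reaction(
            Reaction(
                id=rid,
                name=definition.name,
                stoichiometry=stoich,
                reversible=reversibility[rid],
            ),
            register_metabolites=True,
        )
    if not model.reactions:
        raise ModelError("empty draft: no includable reactions")
    model.draft_report = report
    return model
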