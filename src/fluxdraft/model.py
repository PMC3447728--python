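"""Core domain types for constraint-based metabolic models.

A model is a set of metabolites (KEGG C-number style or free-form ids) and
reactions (signed stoichiometry maps), plus an objective.  The sign
convention is fixed throughout the package: negative coefficient = consumed
(substrate), positive = produced (product).  Flux units are mmol/g DCW/h
except for the biomass pseudo-reaction, whose flux is the specific growth
rate in 1/h.
"""

from __future__ import annotations

import copy as _copy
import math
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import numpy as np

#: Conventional "effectively unbounded" flux cap, mmol/g DCW/h.
DEFAULT_FLUX_BOUND = 1000.0


class ModelError(ValueError):
    """Structural problem in a model, reaction or metabolite."""


class ReactionKind(str, Enum):
    INTRACELLULAR = "intracellular"
    INFLOW = "inflow"
    OUTFLOW = "outflow"
    BIOMASS = "biomass"
    MAINTENANCE = "maintenance"
    GAP_FILL = "gap_fill"
    HETEROLOGOUS = "heterologous"


@dataclass
class Metabolite:
    """A network node, typically identified by a KEGG compound id (C#####).

    ``external`` marks boundary species created by exchange operations;
    their mass balance is not enforced (they are excluded from the rows of
    the stoichiometric matrix) and they map to ``boundaryCondition=true``
    species on SBML export.
    """

    id: str
    name: str = ""
    formula: str | None = None
    external: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelError("metabolite id must be non-empty")


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds.

    ``stoichiometry`` maps metabolite id -> signed coefficient (negative =
    consumed).  ``reversible`` is encoded redundantly with the bounds: an
    irreversible reaction must have ``lower_bound >= 0``.
    """

    id: str
    stoichiometry: dict[str, float]
    name: str = ""
    reversible: bool = False
    lower_bound: float | None = None
    upper_bound: float | None = None
    kind: ReactionKind = ReactionKind.INTRACELLULAR
    ec_numbers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise ModelError(f"reaction {self.id!r}: empty stoichiometry")
        if any(c == 0 for c in self.stoichiometry.values()):
            raise ModelError(f"reaction {self.id!r}: zero coefficient stored")
        self.kind = ReactionKind(self.kind)
        if self.lower_bound is None:
            self.lower_bound = -DEFAULT_FLUX_BOUND if self.reversible else 0.0
        if self.upper_bound is None:
            self.upper_bound = DEFAULT_FLUX_BOUND
        if not self.reversible and self.lower_bound < 0:
            raise ModelError(
                f"reaction {self.id!r}: irreversible but lower_bound < 0"
            )
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id!r}: lower_bound > upper_bound"
            )

    @property
    def substrates(self) -> list[str]:
        return sorted(m for m, c in self.stoichiometry.items() if c < 0)

    @property
    def products(self) -> list[str]:
        return sorted(m for m, c in self.stoichiometry.items() if c > 0)

    def copy(self) -> "Reaction":
        return _copy.deepcopy(self)


@dataclass
class ObjectiveSpec:
    """Linear objective c . v over reaction fluxes."""

    coefficients: dict[str, float]
    direction: str = "maximize"

    def __post_init__(self) -> None:
        if self.direction not in ("maximize", "minimize"):
            raise ModelError(f"bad objective direction {self.direction!r}")
        if not any(c != 0 for c in self.coefficients.values()):
            raise ModelError("objective needs at least one nonzero coefficient")


@dataclass
class MetabolicModel:
    """Reconstructable container: metabolites + reactions + objective."""

    id: str
    organism: str = ""
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    objective: ObjectiveSpec | None = None
    #: set by reconstruction.set_biomass; needed for GAM refitting
    biomass_composition: object | None = None
    #: set by kegg_draft.assemble_draft; lists skipped reactions
    draft_report: object | None = None

    # -- construction -----------------------------------------------------

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ModelError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction, register_metabolites: bool = False) -> None:
        if rxn.id in self.reactions:
            raise ModelError(f"duplicate reaction id {rxn.id!r}")
        for mid in rxn.stoichiometry:
            if mid not in self.metabolites:
                if register_metabolites:
                    self.metabolites[mid] = Metabolite(id=mid)
                else:
                    raise ModelError(
                        f"reaction {rxn.id!r} references unknown metabolite {mid!r}"
                    )
        self.reactions[rxn.id] = rxn

    def copy(self) -> "MetabolicModel":
        return _copy.deepcopy(self)

    # -- queries ----------------------------------------------------------

    def internal_metabolite_ids(self) -> list[str]:
        return sorted(m.id for m in self.metabolites.values() if not m.external)

    def validate(self) -> None:
        """Raise ModelError on any violated structural invariant."""
        for rxn in self.reactions.values():
            for mid in rxn.stoichiometry:
                if mid not in self.metabolites:
                    raise ModelError(
                        f"reaction {rxn.id!r} references unknown metabolite {mid!r}"
                    )
        if self.objective is not None:
            for rid in self.objective.coefficients:
                if rid not in self.reactions:
                    raise ModelError(
                        f"objective references unknown reaction {rid!r}"
                    )
        # external species may appear only in exchange-like reactions
        exchange_kinds = {
            ReactionKind.INFLOW,
            ReactionKind.OUTFLOW,
            ReactionKind.GAP_FILL,
        }
        for rxn in self.reactions.values():
            if rxn.kind in exchange_kinds:
                continue
            for mid in rxn.stoichiometry:
                if self.metabolites[mid].external:
                    raise ModelError(
                        f"external metabolite {mid!r} used in "
                        f"non-exchange reaction {rxn.id!r}"
                    )

    # -- plain-document serialization (internal format) -------------------

    def to_dict(self) -> dict:
        """Plain JSON-compatible document; SBML is the exchange format,
        this is the internal one used by edit-script workflows."""
        doc: dict = {
            "id": self.id,
            "organism": self.organism,
            "metabolites": [
                {
                    "id": m.id,
                    "name": m.name,
                    "formula": m.formula,
                    "external": m.external,
                }
                for m in (self.metabolites[k] for k in sorted(self.metabolites))
            ],
            "reactions": [
                {
                    "id": r.id,
                    "name": r.name,
                    "stoichiometry": dict(sorted(r.stoichiometry.items())),
                    "reversible": r.reversible,
                    "lower_bound": r.lower_bound,
                    "upper_bound": r.upper_bound,
                    "kind": r.kind.value,
                    "ec_numbers": list(r.ec_numbers),
                }
                for r in (self.reactions[k] for k in sorted(self.reactions))
            ],
        }
        if self.objective is not None:
            doc["objective"] = {
                "coefficients": dict(sorted(self.objective.coefficients.items())),
                "direction": self.objective.direction,
            }
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "MetabolicModel":
        model = cls(id=doc["id"], organism=doc.get("organism", ""))
        for m in doc.get("metabolites", []):
            model.add_metabolite(
                Metabolite(
                    id=m["id"],
                    name=m.get("name", ""),
                    formula=m.get("formula"),
                    external=bool(m.get("external", False)),
                )
            )
        for r in doc.get("reactions", []):
            model.add_reaction(
                Reaction(
                    id=r["id"],
                    name=r.get("name", ""),
                    stoichiometry={m: float(c) for m, c in r["stoichiometry"].items()},
                    reversible=bool(r.get("reversible", False)),
                    lower_bound=r.get("lower_bound"),
                    upper_bound=r.get("upper_bound"),
                    kind=ReactionKind(r.get("kind", "intracellular")),
                    ec_numbers=list(r.get("ec_numbers", [])),
                )
            )
        if "objective" in doc:
            model.objective = ObjectiveSpec(
                {k: float(v) for k, v in doc["objective"]["coefficients"].items()},
                doc["objective"].get("direction", "maximize"),
            )
        model.validate()
        return model

    def equals(self, other: "MetabolicModel", tol: float = 0.0) -> bool:
        """Structural equality: same species, stoichiometries, bounds,
        reversibility and objective (names/annotations ignored)."""
        if set(self.metabolites) != set(other.metabolites):
            return False
        for mid, met in self.metabolites.items():
            if met.external != other.metabolites[mid].external:
                return False
        if set(self.reactions) != set(other.reactions):
            return False
        for rid, rxn in self.reactions.items():
            o = other.reactions[rid]
            if rxn.reversible != o.reversible:
                return False
            if set(rxn.stoichiometry) != set(o.stoichiometry):
                return False
            for mid, c in rxn.stoichiometry.items():
                if abs(c - o.stoichiometry[mid]) > tol:
                    return False
            if abs(rxn.lower_bound - o.lower_bound) > tol:
                return False
            if abs(rxn.upper_bound - o.upper_bound) > tol:
                return False
        if (self.objective is None) != (other.objective is None):
            return False
        if self.objective is not None:
            if self.objective.direction != other.objective.direction:
                return False
            a = {k: v for k, v in self.objective.coefficients.items() if v != 0}
            b = {k: v for k, v in other.objective.coefficients.items() if v != 0}
            if set(a) != set(b):
                return False
            if any(abs(a[k] - b[k]) > tol for k in a):
                return False
        return True


@dataclass
class StoichiometricMatrix:
    """Dense stoichiometric matrix S over internal metabolites.

    Rows are internal metabolite ids, columns reaction ids, both in sorted
    order so the construction is deterministic and diffable.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    matrix: np.ndarray

    def coefficient(self, metabolite_id: str, reaction_id: str) -> float:
        i = self.metabolite_ids.index(metabolite_id)
        j = self.reaction_ids.index(reaction_id)
        return float(self.matrix[i, j])


def build_stoichiometric_matrix(model: MetabolicModel) -> StoichiometricMatrix:
    """Assemble S with sorted row/column ordering.

    External (boundary) metabolites are excluded from the rows: their mass
    balance is deliberately not enforced, which is what makes inflow and
    outflow reactions net sources and sinks.
    """
    model.validate()
    rows = model.internal_metabolite_ids()
    cols = sorted(model.reactions)
    row_pos = {m: i for i, m in enumerate(rows)}
    S = np.zeros((len(rows), len(cols)))
    for j, rid in enumerate(cols):
        for mid, coeff in model.reactions[rid].stoichiometry.items():
            i = row_pos.get(mid)
            if i is not None:
                S[i, j] = coeff
    return StoichiometricMatrix(metabolite_ids=rows, reaction_ids=cols, matrix=S)


def find_dead_end_metabolites(model: MetabolicModel) -> list[str]:
    """Internal metabolites that are only produced or only consumed.

    A reversible reaction counts as both producer and consumer of every
    participant.  Dead ends flag network gaps a curator should inspect.
    """
    produced: set[str] = set()
    consumed: set[str] = set()
    for rxn in model.reactions.values():
        for mid, coeff in rxn.stoichiometry.items():
            if rxn.reversible:
                produced.add(mid)
                consumed.add(mid)
            elif coeff > 0:
                produced.add(mid)
            else:
                consumed.add(mid)
    dead = []
    for mid in model.internal_metabolite_ids():
        p, c = mid in produced, mid in consumed
        if (p or c) and not (p and c):
            dead.append(mid)
    return dead


# -- mass balance ---------------------------------------------------------

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

#: periodic-table symbols; rejects KEGG residue markers like bare "R"
_ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co "
    "Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb "
    "Te I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re "
    "Os Ir Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu".split()
)


def parse_formula(formula: str) -> dict[str, int] | None:
    """Parse a plain elemental formula like ``C6H12O6`` into element counts.

    Returns None for anything outside the plain grammar (repeat units such
    as ``(C5H8O4)n``, ``R`` groups, ``*``): those are reported as
    "unchecked" by the balance checker rather than guessed at.
    """
    if not formula:
        return None
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            return None
        element, digits = match.groups()
        if element not in _ELEMENTS:
            return None
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(formula):
        return None
    return counts or None


@dataclass
class MassBalanceReport:
    """Per-element deltas for one reaction; ``status`` is one of
    ``balanced``, ``unbalanced`` or ``unchecked``."""

    reaction_id: str
    status: str
    deltas: dict[str, float] = field(default_factory=dict)

    @property
    def balanced(self) -> bool:
        return self.status == "balanced"


def check_mass_balance(
    reaction: Reaction, formulas: Mapping[str, str | None]
) -> MassBalanceReport:
    """Check elemental balance: per element, sum(coefficient x count).

    Any participant with a missing or unparsable formula makes the whole
    reaction "unchecked" — never a crash, never a guess.
    """
    deltas: dict[str, float] = {}
    for mid, coeff in reaction.stoichiometry.items():
        counts = parse_formula(formulas.get(mid) or "")
        if counts is None:
            return MassBalanceReport(reaction.id, "unchecked")
        for element, n in counts.items():
            deltas[element] = deltas.get(element, 0.0) + coeff * n
    deltas = {e: d for e, d in deltas.items()}
    status = "balanced" if all(
        math.isclose(d, 0.0, abs_tol=1e-9) for d in deltas.values()
    ) else "unbalanced"
    return MassBalanceReport(reaction.id, status, deltas)


def check_model_mass_balance(model: MetabolicModel) -> dict[str, MassBalanceReport]:
    """Balance report for every non-exchange reaction in the model."""
    formulas = {m.id: m.formula for m in model.metabolites.values()}
    skip = {ReactionKind.INFLOW, ReactionKind.OUTFLOW, ReactionKind.BIOMASS}
    return {
        rid: check_mass_balance(rxn, formulas)
        for rid, rxn in sorted(model.reactions.items())
        if rxn.kind not in skip
    }
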