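"""Synthetic KEGG-like organisms with known ground truth.

Real drafting pulls pathway maps and reaction definitions from a genome
database; the tests need the same inputs offline, with every property of
the resulting network known in advance.  ``generate_fixture_organism``
emits syntactically valid KGML documents and a LIGAND-style reaction
table, together with the ground-truth model they must assemble into and
annotations recording exactly which reactions overlap between maps, which
table records were deliberately corrupted, and which metabolites are
dead ends.

Network shape: an irreversible backbone chain from a designated substrate
compound to a designated product compound (so flux analysis is feasible
once exchanges are added), a set of closed cycles (every cycle compound
has both a producer and a consumer), bridge reactions between covered
compounds, and a configurable number of deliberately orphaned metabolites
that appear only as products of dedicated irreversible reactions.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .model import MetabolicModel, Metabolite, Reaction

_BACKBONE_LENGTH = 6  # reactions; backbone has _BACKBONE_LENGTH + 1 compounds


@dataclass
class FixtureAnnotations:
    substrate: str
    product: str
    orphans: list[str]
    dead_ends: list[str]
    corrupted: list[str]
    overlaps: list[str]
    pathway_reactions: dict[str, list[str]]
    n_unique: int


@dataclass
class FixtureOrganism:
    organism: str
    kgml_documents: dict[str, str]
    reaction_table: str
    model: MetabolicModel
    annotations: FixtureAnnotations


@dataclass
class _RxnRecord:
    rid: str
    name: str
    stoich: dict[str, float]
    reversible: bool
    tag: str  # backbone | cycle | bridge | orphan_host


def _format_equation(stoich: dict[str, float]) -> str:
    def side(sign: int) -> str:
        terms = []
        for cid in sorted(c for c, v in stoich.items() if sign * v > 0):
            coef = abs(stoich[cid])
            terms.append(cid if coef == 1 else f"{coef:g} {cid}")
        return " + ".join(terms)

    return f"{side(-1)} <=> {side(+1)}"


def _kgml_document(
    organism: str, number: str, records: list[tuple[_RxnRecord, bool]]
) -> str:
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<pathway name="path:{organism}{number}" org="{organism}" '
        f'number="{number}" title="synthetic pathway {number}">',
    ]
    for n, (rec, reversible) in enumerate(
        sorted(records, key=lambda item: item[0].rid), start=1
    ):
        rtype = "reversible" if reversible else "irreversible"
        lines.append(f'  <reaction id="{n}" name="rn:{rec.rid}" type="{rtype}">')
        for cid in sorted(c for c, v in rec.stoich.items() if v < 0):
            lines.append(f'    <substrate id="0" name="cpd:{cid}"/>')
        for cid in sorted(c for c, v in rec.stoich.items() if v > 0):
            lines.append(f'    <product id="0" name="cpd:{cid}"/>')
        lines.append("  </reaction>")
    lines.append("</pathway>")
    return "\n".join(lines) + "\n"


def generate_fixture_organism(
    seed: int,
    n_pathways: int = 4,
    n_reactions: int = 60,
    overlap_fraction: float = 8 / 60,
    corrupt_fraction: float = 0.0,
    n_orphans: int = 2,
    organism: str = "syn",
) -> FixtureOrganism:
    """Generate a reproducible synthetic organism.

    ``n_reactions`` counts reaction *placements* across all maps; a
    fraction ``overlap_fraction`` of them are duplicate listings of a
    reaction already present in another map, so the assembled draft has
    ``n_reactions - round(overlap_fraction * n_reactions)`` unique
    reactions.  ``corrupt_fraction`` of the unique reactions get a
    deliberately unparsable table equation (polymeric ``n`` coefficient)
    and are therefore absent from the ground-truth model.
    """
    if not 0 <= overlap_fraction <= 1:
        raise ValueError("overlap_fraction must be in [0, 1]")
    if not 0 <= corrupt_fraction <= 1:
        raise ValueError("corrupt_fraction must be in [0, 1]")
    if n_pathways < 1:
        raise ValueError("need at least one pathway")
    n_overlap = round(overlap_fraction * n_reactions)
    n_unique = n_reactions - n_overlap
    n_corrupt = round(corrupt_fraction * n_unique)
    n_bridges = n_unique - _BACKBONE_LENGTH - n_orphans - 1
    # reserve at least one cycle and enough bridges to corrupt
    if n_bridges < max(n_corrupt, 3) + 3:
        raise ValueError(
            f"n_reactions={n_reactions} too small for the requested geometry"
        )

    rng = random.Random(seed)
    compound_counter = 0

    def new_compound() -> str:
        nonlocal compound_counter
        compound_counter += 1
        return f"C{compound_counter:05d}"

    records: list[_RxnRecord] = []

    def new_record(stoich: dict[str, float], reversible: bool, tag: str) -> _RxnRecord:
        rid = f"R{len(records) + 1:05d}"
        rec = _RxnRecord(rid, f"fixture reaction {len(records) + 1}", stoich, reversible, tag)
        records.append(rec)
        return rec

    # backbone: substrate -> ... -> product, all irreversible
    backbone = [new_compound() for _ in range(_BACKBONE_LENGTH + 1)]
    for i in range(_BACKBONE_LENGTH):
        new_record({backbone[i]: -1.0, backbone[i + 1]: +1.0}, False, "backbone")

    # closed cycles: every member compound gets a producer and a consumer
    safe_pool: list[str] = list(backbone[1:-1])
    cycle_budget = max(3, int(0.5 * (n_bridges + 3)))
    used = 0
    while used + 3 <= cycle_budget:
        length = min(rng.randint(3, 6), cycle_budget - used)
        if length < 3:
            break
        members = [new_compound() for _ in range(length)]
        for j in range(length):
            new_record(
                {members[j]: -1.0, members[(j + 1) % length]: +1.0},
                rng.random() < 0.3,
                "cycle",
            )
        safe_pool.extend(members)
        used += length
    n_bridges = n_unique - len(records) - n_orphans
    if n_bridges < max(n_corrupt, 1):
        raise ValueError(
            "not enough bridge reactions for the requested corrupt_fraction"
        )

    # orphan hosts: irreversible, product used nowhere else
    orphans: list[str] = []
    for _ in range(n_orphans):
        host_substrate = rng.choice(safe_pool)
        orphan = new_compound()
        orphans.append(orphan)
        new_record({host_substrate: -1.0, orphan: +1.0}, False, "orphan_host")

    # bridges between already-covered compounds
    bridge_records: list[_RxnRecord] = []
    for _ in range(n_bridges):
        n_subs = 1 if rng.random() < 0.7 else 2
        subs = rng.sample(safe_pool, n_subs)
        prod = rng.choice([c for c in safe_pool if c not in subs])
        stoich: dict[str, float] = {s: -float(rng.choice([1, 1, 1, 2])) for s in subs}
        stoich[prod] = float(rng.choice([1, 1, 2]))
        bridge_records.append(new_record(stoich, rng.random() < 0.3, "bridge"))

    assert len(records) == n_unique

    corrupted = sorted(
        rec.rid for rec in rng.sample(bridge_records, n_corrupt)
    )
    corrupted_set = set(corrupted)

    # distribute unique reactions over pathways
    assignment: dict[str, int] = {
        rec.rid: rng.randrange(n_pathways) for rec in records
    }
    by_rid = {rec.rid: rec for rec in records}

    # duplicate placements (overlaps), possibly with a conflicting type
    overlap_candidates = [
        rec for rec in records if rec.tag in ("cycle", "bridge")
    ]
    n_overlap = min(n_overlap, len(overlap_candidates))
    overlap_recs = rng.sample(overlap_candidates, n_overlap)
    final_reversible = {rec.rid: rec.reversible for rec in records}
    placements: dict[int, list[tuple[_RxnRecord, bool]]] = {
        i: [] for i in range(n_pathways)
    }
    for rec in records:
        placements[assignment[rec.rid]].append((rec, rec.reversible))
    overlaps = []
    for rec in overlap_recs:
        overlaps.append(rec.rid)
        choices = [i for i in range(n_pathways) if i != assignment[rec.rid]]
        target = rng.choice(choices) if choices else assignment[rec.rid]
        flip = rng.random() < 0.5
        dup_rev = (not rec.reversible) if flip else rec.reversible
        if dup_rev != rec.reversible:
            final_reversible[rec.rid] = True  # conflict resolves to reversible
        placements[target].append((rec, dup_rev))
    overlaps.sort()

    # emit KGML documents
    kgml_documents: dict[str, str] = {}
    pathway_reactions: dict[str, list[str]] = {}
    for i in range(n_pathways):
        number = f"{10 + i:05d}"
        pathway_id = f"{organism}{number}"
        kgml_documents[pathway_id] = _kgml_document(organism, number, placements[i])
        pathway_reactions[pathway_id] = sorted({r.rid for r, _ in placements[i]})

    # emit LIGAND-style flat table (rid order)
    chunks = []
    for rec in records:
        equation = _format_equation(rec.stoich)
        if rec.rid in corrupted_set:
            subs = sorted(c for c, v in rec.stoich.items() if v < 0)
            equation = f"n {subs[0]} + " + equation
        chunks.append(
            f"ENTRY       {rec.rid}                      Reaction\n"
            f"NAME        {rec.name}\n"
            f"EQUATION    {equation}\n"
            "///"
        )
    reaction_table = "\n".join(chunks) + "\n"

    # ground-truth model: unique, non-corrupted, conflict-resolved
    model = MetabolicModel(id=f"{organism}_truth", organism=organism)
    for rec in records:
        if rec.rid in corrupted_set:
            continue
        model.add_reaction(
            Reaction(
                id=rec.rid,
                name=rec.name,
                stoichiometry=dict(rec.stoich),
                reversible=final_reversible[rec.rid],
            ),
            register_metabolites=True,
        )

    annotations = FixtureAnnotations(
        substrate=backbone[0],
        product=backbone[-1],
        orphans=sorted(orphans),
        dead_ends=sorted({backbone[0], backbone[-1], *orphans}),
        corrupted=corrupted,
        overlaps=overlaps,
        pathway_reactions=pathway_reactions,
        n_unique=n_unique,
    )
    return FixtureOrganism(
        organism=organism,
        kgml_documents=kgml_documents,
        reaction_table=reaction_table,
        model=model,
        annotations=annotations,
    )
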