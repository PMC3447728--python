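"""Network rendering to SVG 1.1.

Bipartite drawing: circles for metabolites, squares for reaction nodes,
directed edges following the sign convention (substrate -> reaction ->
product).  With a flux solution attached, edge stroke width scales with
|flux| and zero-flux edges are dashed.  Layout comes from a
seed-deterministic force-directed embedding, so the same model and seed
produce a byte-identical document.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET

import networkx as nx

from .fba import FluxDistribution
from .model import MetabolicModel

_CANVAS = 900.0
_MARGIN = 60.0
_LABEL_LIMIT = 2000  # nodes; larger models are drawn without labels


def _layout(model: MetabolicModel, seed: int) -> dict[str, tuple[float, float]]:
    graph = nx.Graph()
    for mid in model.metabolites:
        graph.add_node(("m", mid))
    for rid, rxn in model.reactions.items():
        graph.add_node(("r", rid))
        for mid in rxn.stoichiometry:
            graph.add_edge(("r", rid), ("m", mid))
    pos = nx.spring_layout(graph, seed=seed)
    xs = [p[0] for p in pos.values()] or [0.0]
    ys = [p[1] for p in pos.values()] or [0.0]
    span_x = max(xs) - min(xs) or 1.0
    span_y = max(ys) - min(ys) or 1.0
    scale = _CANVAS - 2 * _MARGIN
    out = {}
    for (ntype, nid), (x, y) in pos.items():
        px = _MARGIN + (x - min(xs)) / span_x * scale
        py = _MARGIN + (y - min(ys)) / span_y * scale
        out[f"{ntype}:{nid}"] = (round(px, 2), round(py, 2))
    return out


def render_network_svg(
    model: MetabolicModel,
    fluxes: FluxDistribution | None = None,
    path: str | None = None,
    seed: int = 0,
) -> str:
    """Render the model to an SVG document string (optionally to a file)."""
    positions = _layout(model, seed)
    n_nodes = len(model.metabolites) + len(model.reactions)
    draw_labels = n_nodes <= _LABEL_LIMIT

    max_flux = 1.0
    if fluxes is not None and fluxes.fluxes:
        max_flux = max((abs(v) for v in fluxes.fluxes.values()), default=1.0) or 1.0

    svg = ET.Element(
        "svg",
        {
            "xmlns": "http://www.w3.org/2000/svg",
            "version": "1.1",
            "width": f"{_CANVAS:g}",
            "height": f"{_CANVAS:g}",
            "viewBox": f"0 0 {_CANVAS:g} {_CANVAS:g}",
        },
    )
    edges = ET.SubElement(svg, "g", {"id": "edges", "stroke": "#555"})
    for rid in sorted(model.reactions):
        rxn = model.reactions[rid]
        rx, ry = positions[f"r:{rid}"]
        flux = fluxes.fluxes.get(rid) if fluxes is not None else None
        if flux is None:
            width, dash = 1.0, None
        elif abs(flux) < 1e-9:
            width, dash = 1.0, "4 3"
        else:
            width, dash = round(1.0 + 4.0 * abs(flux) / max_flux, 2), None
        for mid in sorted(rxn.stoichiometry):
            coeff = rxn.stoichiometry[mid]
            mx, my = positions[f"m:{mid}"]
            # substrate edges point into the reaction node, product edges out
            x1, y1, x2, y2 = (mx, my, rx, ry) if coeff < 0 else (rx, ry, mx, my)
            attrs = {
                "x1": f"{x1:g}",
                "y1": f"{y1:g}",
                "x2": f"{x2:g}",
                "y2": f"{y2:g}",
                "stroke-width": f"{width:g}",
                "class": "substrate" if coeff < 0 else "product",
                "data-reaction": rid,
                "data-metabolite": mid,
            }
            if dash:
                attrs["stroke-dasharray"] = dash
            ET.SubElement(edges, "line", attrs)

    met_group = ET.SubElement(svg, "g", {"id": "metabolites", "fill": "#7fb2e5"})
    for mid in sorted(model.metabolites):
        x, y = positions[f"m:{mid}"]
        ET.SubElement(
            met_group,
            "circle",
            {"cx": f"{x:g}", "cy": f"{y:g}", "r": "7", "data-id": mid},
        )
        if draw_labels:
            label = ET.SubElement(
                met_group,
                "text",
                {"x": f"{x + 9:g}", "y": f"{y - 9:g}", "font-size": "9",
                 "fill": "#222"},
            )
            label.text = mid

    rxn_group = ET.SubElement(svg, "g", {"id": "reactions", "fill": "#e5a87f"})
    for rid in sorted(model.reactions):
        x, y = positions[f"r:{rid}"]
        ET.SubElement(
            rxn_group,
            "rect",
            {
                "x": f"{x - 5:g}",
                "y": f"{y - 5:g}",
                "width": "10",
                "height": "10",
                "data-id": rid,
            },
        )
        if draw_labels:
            label = ET.SubElement(
                rxn_group,
                "text",
                {"x": f"{x + 7:g}", "y": f"{y + 12:g}", "font-size": "8",
                 "fill": "#222"},
            )
            label.text = rid

    text = '<?xml version="1.0" encoding="UTF-8"?>\n' + ET.tostring(
        svg, encoding="unicode"
    )
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
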