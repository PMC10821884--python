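"""View files: spatial projections of a model, decoupled from the model itself.

A view stores node positions and edge endpoints for all or a portion of a
model — enough for a renderer to instantiate the network — and nothing about
the model's mathematics.  The interchange format is Cytoscape's CyJson
(``.cyjs``): nodes under ``elements.nodes[].data.id`` with
``position.x``/``position.y``, edges under
``elements.edges[].data.source``/``.target``.  Coordinates are stored exactly
as read (Cytoscape screen convention, y grows downward); flipping is the
renderer's concern.

Every model in the store has at least one view; models registered without a
curated view get the deterministic grid layout from
:func:`default_grid_layout`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

from .errors import ConsistencyError, StructureError
from .model_store import ModelRecord

__all__ = [
    "ViewNode",
    "ViewEdge",
    "ViewGraph",
    "parse_view",
    "serialize_view",
    "default_grid_layout",
    "group_by_metadata",
]

GRID_SPACING = 100.0  # layout units between adjacent grid nodes


@dataclass(frozen=True)
class ViewNode:
    node_id: str
    label: str
    x: float
    y: float
    node_class: str  # "metabolite" | "reaction"


@dataclass(frozen=True)
class ViewEdge:
    edge_id: str
    source: str
    target: str
    model_element_id: str


@dataclass(frozen=True)
class ViewGraph:
    view_name: str
    model_id: str
    nodes: tuple[ViewNode, ...]
    edges: tuple[ViewEdge, ...]

    @property
    def node_ids(self) -> frozenset[str]:
        return frozenset(n.node_id for n in self.nodes)


def _classify(node_id: str, model: ModelRecord) -> str:
    if node_id in model.species_ids:
        return "metabolite"
    if node_id in model.reaction_ids:
        return "reaction"
    raise ConsistencyError(
        f"view node {node_id!r} matches no species or reaction of model {model.model_id!r}"
    )


def parse_view(view_bytes: bytes, model: ModelRecord, view_name: str = "view") -> ViewGraph:
    """Parse and validate a CyJson document against the model it projects.

    Validation is read-only and two-level: edges must reference nodes present
    in the document (structure), and every node / edge element id must resolve
    to an element of the model (consistency).  A view may cover a strict
    subset of the model.
    """
    try:
        doc = json.loads(view_bytes)
    except json.JSONDecodeError as exc:
        raise StructureError(f"view is not valid JSON: {exc}") from exc
    elements = doc.get("elements", {})
    raw_nodes = elements.get("nodes", [])
    raw_edges = elements.get("edges", [])

    nodes = []
    for rn in raw_nodes:
        data = rn.get("data", {})
        nid = data.get("id")
        if nid is None:
            raise StructureError("node without data.id")
        pos = rn.get("position", {})
        nodes.append(
            ViewNode(
                node_id=nid,
                label=data.get("name", nid),
                x=float(pos.get("x", 0.0)),
                y=float(pos.get("y", 0.0)),
                node_class=_classify(nid, model),
            )
        )
    node_ids = {n.node_id for n in nodes}

    edges = []
    for i, re_ in enumerate(raw_edges):
        data = re_.get("data", {})
        src, tgt = data.get("source"), data.get("target")
        if src not in node_ids or tgt not in node_ids:
            raise StructureError(
                f"edge {data.get('id', i)!r} endpoint missing from nodes: {src!r} -> {tgt!r}"
            )
        element = data.get("model_element_id", data.get("id", f"e{i}"))
        if element not in model.reaction_ids and element not in model.species_ids:
            # fall back: an edge adjacent to a reaction node represents that reaction
            element = src if src in model.reaction_ids else tgt
            if element not in model.reaction_ids:
                raise ConsistencyError(
                    f"edge {data.get('id', i)!r} resolves to no model element"
                )
        edges.append(
            ViewEdge(
                edge_id=str(data.get("id", f"e{i}")),
                source=src,
                target=tgt,
                model_element_id=element,
            )
        )
    return ViewGraph(
        view_name=view_name,
        model_id=model.model_id,
        nodes=tuple(nodes),
        edges=tuple(edges),
    )


def serialize_view(view: ViewGraph) -> bytes:
    """Serialize to CyJson bytes; deterministic (sorted keys, fixed separators)."""
    doc = {
        "format_version": "1.0",
        "generated_by": "fluxvault",
        "data": {"name": view.view_name, "model_id": view.model_id},
        "elements": {
            "nodes": [
                {
                    "data": {"id": n.node_id, "name": n.label, "node_class": n.node_class},
                    "position": {"x": n.x, "y": n.y},
                }
                for n in view.nodes
            ],
            "edges": [
                {
                    "data": {
                        "id": e.edge_id,
                        "source": e.source,
                        "target": e.target,
                        "model_element_id": e.model_element_id,
                    }
                }
                for e in view.edges
            ],
        },
    }
    return json.dumps(doc, sort_keys=True, separators=(", ", ": "), indent=1).encode()


def default_grid_layout(model: ModelRecord) -> ViewGraph:
    """Deterministic full-coverage view: all nodes on a plane, on a √N×√N grid.

    Metabolite and reaction nodes are placed in registration order; edges are
    bipartite, metabolite→reaction for consumed species (negative
    stoichiometry) and reaction→metabolite for produced ones, so the view has
    exactly one edge per nonzero stoichiometric coefficient.
    """
    ids = [s.species_id for s in model.species] + [r.reaction_id for r in model.reactions]
    labels = {s.species_id: s.name for s in model.species}
    labels.update({r.reaction_id: r.name or r.reaction_id for r in model.reactions})
    n = len(ids)
    side = max(1, math.ceil(math.sqrt(n)))
    nodes = tuple(
        ViewNode(
            node_id=nid,
            label=labels[nid],
            x=(i % side) * GRID_SPACING,
            y=(i // side) * GRID_SPACING,
            node_class="metabolite" if nid in model.species_ids else "reaction",
        )
        for i, nid in enumerate(ids)
    )
    edges = []
    for r in model.reactions:
        for sid, coeff in r.stoichiometry.items():
            if coeff == 0:
                continue
            if coeff < 0:
                src, tgt = sid, r.reaction_id
            else:
                src, tgt = r.reaction_id, sid
            edges.append(
                ViewEdge(
                    edge_id=f"{src}__{tgt}",
                    source=src,
                    target=tgt,
                    model_element_id=r.reaction_id,
                )
            )
    return ViewGraph(
        view_name=f"{model.model_id}_default",
        model_id=model.model_id,
        nodes=nodes,
        edges=tuple(edges),
    )


def group_by_metadata(view: ViewGraph, model: ModelRecord) -> dict[str, list[str]]:
    """Detect the groupable parts of a projected model from its metadata.

    Metabolite nodes group by compartment, reaction edges by subsystem;
    elements lacking the metadata land in ``"ungrouped"``.  Keys are
    ``compartment:<c>`` and ``subsystem:<s>``.
    """
    compartments = {s.species_id: s.compartment for s in model.species}
    subsystems = {r.reaction_id: r.subsystem for r in model.reactions}
    groups: dict[str, list[str]] = {}

    for node in view.nodes:
        if node.node_class != "metabolite":
            continue
        comp = compartments.get(node.node_id) or ""
        key = f"compartment:{comp}" if comp else "ungrouped"
        groups.setdefault(key, []).append(node.node_id)

    for edge in view.edges:
        rid = edge.model_element_id
        if rid not in subsystems:
            continue
        sub = subsystems[rid]
        key = f"subsystem:{sub}" if sub else "ungrouped"
        groups.setdefault(key, []).append(edge.edge_id)

    return {k: sorted(v) for k, v in groups.items()}
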