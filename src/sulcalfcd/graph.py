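"""Attributed sulcal graphs: domain types, validation, JSON serialization.

A sulcal graph represents one hemisphere's cortical folds after skeleton
extraction: each node is an elementary fold carrying morphological
descriptors (area, maximal geodesic depth, length, centroid, mean
orientation), and each edge is a geometric/topological relation between two
folds — a direct junction, a neighbourhood geodesic to the brain hull, or a
split of a sulcus induced by a buried gyrus.

Coordinates are millimetres in a right-handed frame with origin at the
hemisphere centroid; no inter-subject registration is assumed or performed.
Orientation vectors are direction-ambiguous (a fold has no intrinsic sign),
so all downstream comparisons use the absolute cosine.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

from .nomenclature import BACKGROUND, CENTRAL_REGION_LABELS, HEMISPHERES

SCHEMA_VERSION = "1"

RELATION_TYPES = ("junction", "geodesic_neighbor", "buried_gyrus_split")

Vec3 = tuple[float, float, float]


def _as_vec3(x: Iterable[float]) -> Vec3:
    v = tuple(float(c) for c in x)
    if len(v) != 3:
        raise ValueError(f"expected a 3-vector, got {len(v)} components")
    return v  # type: ignore[return-value]


def _norm(v: Vec3) -> float:
    return math.sqrt(v[0] * v[0] + v[1] * v[1] + v[2] * v[2])


@dataclass(frozen=True)
class SulcusNode:
    """One elementary cortical fold with its morphological descriptors."""

    node_id: str
    area: float           # mm^2
    max_depth: float      # mm
    length: float         # mm
    centroid: Vec3        # mm, hemisphere-centroid origin
    orientation: Vec3     # unit vector, sign-ambiguous
    true_label: Optional[str] = None      # generator ground truth
    assigned_label: Optional[str] = None  # recognition output

    def with_label(self, label: Optional[str]) -> "SulcusNode":
        return replace(self, assigned_label=label)


@dataclass(frozen=True)
class RelationEdge:
    """A typed relation between two folds.

    ``buried_gyrus_depth`` is meaningful only for ``buried_gyrus_split``
    relations (depth of the gyral passage submerged in the sulcus) and must
    be absent otherwise.
    """

    endpoints: tuple[str, str]
    relation_type: str
    contact_direction: Vec3   # unit vector, sign-ambiguous
    relation_volume: float    # mm^3
    min_distance: float       # mm
    buried_gyrus_depth: Optional[float] = None  # mm

    def other(self, node_id: str) -> str:
        a, b = self.endpoints
        return b if node_id == a else a


@dataclass
class SulcalGraph:
    """One hemisphere's sulcal graph."""

    subject_id: str
    hemisphere: str
    nodes: list[SulcusNode] = field(default_factory=list)
    edges: list[RelationEdge] = field(default_factory=list)

    def node_ids(self) -> list[str]:
        return [n.node_id for n in self.nodes]

    def node(self, node_id: str) -> SulcusNode:
        for n in self.nodes:
            if n.node_id == node_id:
                return n
        raise KeyError(node_id)

    def true_labeling(self) -> dict[str, str]:
        return {n.node_id: n.true_label for n in self.nodes if n.true_label is not None}

    def assigned_labeling(self) -> dict[str, str]:
        return {
            n.node_id: n.assigned_label
            for n in self.nodes
            if n.assigned_label is not None
        }

    def with_labeling(self, labeling: Mapping[str, Optional[str]]) -> "SulcalGraph":
        """Return a copy with ``assigned_label`` set from ``labeling``."""
        nodes = [n.with_label(labeling.get(n.node_id, n.assigned_label)) for n in self.nodes]
        return SulcalGraph(self.subject_id, self.hemisphere, nodes, list(self.edges))


def validate_graph(graph: SulcalGraph) -> list[str]:
    """Check every structural invariant; return human-readable violations.

    An empty list means the graph is well-formed.  This never raises: it is
    a reporting operation used both by tests and as the write-time guard.
    """
    problems: list[str] = []
    if graph.hemisphere not in HEMISPHERES:
        problems.append(f"graph: hemisphere {graph.hemisphere!r} not in {HEMISPHERES}")

    ids = [n.node_id for n in graph.nodes]
    seen_ids = set()
    for i in ids:
        if i in seen_ids:
            problems.append(f"node {i!r}: duplicate node_id")
        seen_ids.add(i)

    valid_labels = set(CENTRAL_REGION_LABELS) | {BACKGROUND}
    assigned_seen: dict[str, str] = {}
    for n in graph.nodes:
        for attr in ("area", "max_depth", "length"):
            if not getattr(n, attr) > 0:
                problems.append(f"node {n.node_id!r}: {attr} must be > 0")
        if abs(_norm(n.orientation) - 1.0) > 1e-9:
            problems.append(f"node {n.node_id!r}: orientation is not unit norm")
        for lab_attr in ("true_label", "assigned_label"):
            lab = getattr(n, lab_attr)
            if lab is not None and lab not in valid_labels:
                problems.append(f"node {n.node_id!r}: {lab_attr} {lab!r} outside nomenclature")
        lab = n.assigned_label
        if lab is not None and lab != BACKGROUND:
            if lab in assigned_seen:
                problems.append(
                    f"node {n.node_id!r}: label {lab!r} already assigned to "
                    f"node {assigned_seen[lab]!r}"
                )
            else:
                assigned_seen[lab] = n.node_id

    for k, e in enumerate(graph.edges):
        tag = f"edge #{k} {e.endpoints}"
        a, b = e.endpoints
        if a == b:
            problems.append(f"{tag}: self-loop")
        for end in e.endpoints:
            if end not in seen_ids:
                problems.append(f"{tag}: endpoint {end!r} references a missing node")
        if e.relation_type not in RELATION_TYPES:
            problems.append(f"{tag}: unknown relation_type {e.relation_type!r}")
        if not e.min_distance >= 0:
            problems.append(f"{tag}: min_distance must be >= 0")
        if abs(_norm(e.contact_direction) - 1.0) > 1e-9:
            problems.append(f"{tag}: contact_direction is not unit norm")
        if e.relation_type == "buried_gyrus_split":
            if e.buried_gyrus_depth is None:
                problems.append(f"{tag}: buried_gyrus_split requires buried_gyrus_depth")
        elif e.buried_gyrus_depth is not None:
            problems.append(f"{tag}: buried_gyrus_depth only valid for buried_gyrus_split")
    return problems


# ---------------------------------------------------------------------------
# JSON serialization

def _node_to_doc(n: SulcusNode) -> dict:
    doc = {
        "node_id": n.node_id,
        "area": n.area,
        "max_depth": n.max_depth,
        "length": n.length,
        "centroid": list(n.centroid),
        "orientation": list(n.orientation),
    }
    if n.true_label is not None:
        doc["true_label"] = n.true_label
    if n.assigned_label is not None:
        doc["assigned_label"] = n.assigned_label
    return doc


def _edge_to_doc(e: RelationEdge) -> dict:
    doc = {
        "endpoints": list(e.endpoints),
        "relation_type": e.relation_type,
        "contact_direction": list(e.contact_direction),
        "relation_volume": e.relation_volume,
        "min_distance": e.min_distance,
    }
    if e.buried_gyrus_depth is not None:
        doc["buried_gyrus_depth"] = e.buried_gyrus_depth
    return doc


class GraphParseError(ValueError):
    """Raised when a graph document is malformed; message names the field."""


def graph_to_doc(graph: SulcalGraph) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "subject_id": graph.subject_id,
        "hemisphere": graph.hemisphere,
        "nodes": [_node_to_doc(n) for n in graph.nodes],
        "edges": [_edge_to_doc(e) for e in graph.edges],
    }


def graph_from_doc(doc: dict) -> SulcalGraph:
    try:
        version = doc["schema_version"]
    except KeyError:
        raise GraphParseError("missing field 'schema_version'")
    if version != SCHEMA_VERSION:
        raise GraphParseError(f"unsupported schema_version {version!r}")
    try:
        nodes = [
            SulcusNode(
                node_id=str(nd["node_id"]),
                area=float(nd["area"]),
                max_depth=float(nd["max_depth"]),
                length=float(nd["length"]),
                centroid=_as_vec3(nd["centroid"]),
                orientation=_as_vec3(nd["orientation"]),
                true_label=nd.get("true_label"),
                assigned_label=nd.get("assigned_label"),
            )
            for nd in doc["nodes"]
        ]
        edges = []
        for ed in doc["edges"]:
            rtype = ed["relation_type"]
            if rtype not in RELATION_TYPES:
                raise GraphParseError(f"unknown relation_type {rtype!r}")
            depth = ed.get("buried_gyrus_depth")
            edges.append(
                RelationEdge(
                    endpoints=(str(ed["endpoints"][0]), str(ed["endpoints"][1])),
                    relation_type=rtype,
                    contact_direction=_as_vec3(ed["contact_direction"]),
                    relation_volume=float(ed["relation_volume"]),
                    min_distance=float(ed["min_distance"]),
                    buried_gyrus_depth=None if depth is None else float(depth),
                )
            )
    except KeyError as exc:
        raise GraphParseError(f"missing field {exc.args[0]!r}") from exc
    return SulcalGraph(
        subject_id=str(doc["subject_id"]),
        hemisphere=str(doc["hemisphere"]),
        nodes=nodes,
        edges=edges,
    )


def write_graph(graph: SulcalGraph, path) -> None:
    """Serialize a validated graph to a JSON document (one per hemisphere)."""
    problems = validate_graph(graph)
    if problems:
        raise ValueError("refusing to write invalid graph: " + "; ".join(problems))
    with open(path, "w") as fh:
        json.dump(graph_to_doc(graph), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_graph(path) -> SulcalGraph:
    with open(path) as fh:
        return graph_from_doc(json.load(fh))


# ---------------------------------------------------------------------------
# Central-region restriction

def central_region_subgraph(graph: SulcalGraph) -> SulcalGraph:
    """Induced subgraph on nodes assigned one of the 13 central-region labels.

    Requires a labeled graph (every node has ``assigned_label``, background
    included); edges survive iff both endpoints survive.  Idempotent.
    """
    unlabeled = [n.node_id for n in graph.nodes if n.assigned_label is None]
    if unlabeled:
        raise ValueError(f"graph has unlabeled nodes: {unlabeled}")
    keep = {n.node_id for n in graph.nodes if n.assigned_label in CENTRAL_REGION_LABELS}
    nodes = [n for n in graph.nodes if n.node_id in keep]
    edges = [e for e in graph.edges if e.endpoints[0] in keep and e.endpoints[1] in keep]
    return SulcalGraph(graph.subject_id, graph.hemisphere, nodes, edges)
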