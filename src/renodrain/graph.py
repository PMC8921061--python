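"""Centerline graph model of the renal collecting system.

A :class:`CollectingSystemGraph` is a graph (normally a tree) whose nodes are
anatomical landmarks — calyx tips, junctions, the renal pelvis, and exactly
one export node at the ureteropelvic junction (UPJ) — and whose edges carry
the centerline geometry as 3D polylines (bed-frame millimetres) plus the
minimum lumen diameter along the edge.  The lumen is modelled as a circular
tube; a spherical stone passes an edge iff its diameter does not exceed the
edge's ``min_lumen_diameter``.

Serialisation is a small versioned JSON schema::

    {"format": "renodrain-graph", "version": 1,
     "nodes": [{"id": 0, "kind": "pelvis", "pos": [x, y, z]}, ...],
     "edges": [{"id": 0, "a": 0, "b": 1,
                "polyline": [[x, y, z], ...],
                "min_lumen_diameter": 4.5}, ...]}
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx
import numpy as np

__all__ = [
    "NODE_KINDS",
    "GraphInvariantError",
    "Node",
    "Edge",
    "Stone",
    "CollectingSystemGraph",
]

NODE_KINDS = ("calyx_tip", "junction", "pelvis", "export")

#: Arc-length bookkeeping tolerance, mm.
LENGTH_ATOL = 1e-6


class GraphInvariantError(ValueError):
    """A structural invariant of the collecting-system graph is violated."""


def polyline_length(polyline: np.ndarray) -> float:
    """Arc length of an (n, 3) polyline in mm."""
    return float(np.sum(np.linalg.norm(np.diff(polyline, axis=0), axis=1)))


@dataclass
class Node:
    id: int
    pos: np.ndarray  # (3,) mm, bed frame
    kind: str

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (3,) or not np.all(np.isfinite(self.pos)):
            raise GraphInvariantError(f"node {self.id}: position must be a finite 3-vector")
        if self.kind not in NODE_KINDS:
            raise GraphInvariantError(f"node {self.id}: unknown kind {self.kind!r}")


@dataclass
class Edge:
    id: int
    a: int
    b: int
    polyline: np.ndarray  # (n, 3) mm; starts at node a's position, ends at b's
    min_lumen_diameter: float

    def __post_init__(self) -> None:
        self.polyline = np.asarray(self.polyline, dtype=float)
        if self.polyline.ndim != 2 or self.polyline.shape[1] != 3 or len(self.polyline) < 2:
            raise GraphInvariantError(f"edge {self.id}: polyline must be (n>=2, 3)")
        if not np.all(np.isfinite(self.polyline)):
            raise GraphInvariantError(f"edge {self.id}: non-finite polyline")
        if not self.min_lumen_diameter > 0:
            raise GraphInvariantError(f"edge {self.id}: min_lumen_diameter must be > 0")

    @property
    def length(self) -> float:
        return polyline_length(self.polyline)


@dataclass(frozen=True)
class Stone:
    """A spherical stone fragment bound to a graph node."""

    diameter: float  # mm
    node: int

    def __post_init__(self) -> None:
        if not self.diameter > 0:
            raise GraphInvariantError("stone diameter must be > 0")


@dataclass
class CollectingSystemGraph:
    """Centerline tree of a pelvicalyceal system with per-edge lumen geometry."""

    nodes: dict[int, Node] = field(default_factory=dict)
    edges: dict[int, Edge] = field(default_factory=dict)
    #: set True for deliberately cyclic test graphs; trees are the norm
    allow_cycles: bool = False

    # -- construction -----------------------------------------------------
    def add_node(self, node_id: int, pos: Iterable[float], kind: str) -> Node:
        if node_id in self.nodes:
            raise GraphInvariantError(f"duplicate node id {node_id}")
        node = Node(node_id, np.asarray(list(pos), dtype=float), kind)
        self.nodes[node_id] = node
        return node

    def add_edge(
        self,
        edge_id: int,
        a: int,
        b: int,
        polyline: Iterable[Iterable[float]] | None = None,
        min_lumen_diameter: float = 4.0,
    ) -> Edge:
        if edge_id in self.edges:
            raise GraphInvariantError(f"duplicate edge id {edge_id}")
        if a not in self.nodes or b not in self.nodes:
            raise GraphInvariantError(f"edge {edge_id}: endpoint node missing")
        if polyline is None:
            polyline = [self.nodes[a].pos, self.nodes[b].pos]
        edge = Edge(edge_id, a, b, np.asarray(list(polyline), dtype=float), min_lumen_diameter)
        if not np.allclose(edge.polyline[0], self.nodes[a].pos, atol=LENGTH_ATOL):
            raise GraphInvariantError(f"edge {edge_id}: polyline must start at node {a}")
        if not np.allclose(edge.polyline[-1], self.nodes[b].pos, atol=LENGTH_ATOL):
            raise GraphInvariantError(f"edge {edge_id}: polyline must end at node {b}")
        self.edges[edge_id] = edge
        return edge

    # -- queries ----------------------------------------------------------
    def as_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        for n in self.nodes.values():
            g.add_node(n.id, kind=n.kind, pos=n.pos)
        for e in self.edges.values():
            g.add_edge(e.a, e.b, key=e.id, edge_id=e.id,
                       length=e.length, min_lumen_diameter=e.min_lumen_diameter)
        return g

    @property
    def export_node(self) -> int:
        exports = [n.id for n in self.nodes.values() if n.kind == "export"]
        if len(exports) != 1:
            raise GraphInvariantError(f"expected exactly one export node, found {len(exports)}")
        return exports[0]

    def calyx_tips(self) -> list[int]:
        return sorted(n.id for n in self.nodes.values() if n.kind == "calyx_tip")

    def degree(self, node_id: int) -> int:
        return sum((e.a == node_id) + (e.b == node_id) for e in self.edges.values())

    def incident_edges(self, node_id: int) -> list[Edge]:
        return [e for e in sorted(self.edges.values(), key=lambda e: e.id)
                if node_id in (e.a, e.b)]

    def total_length(self) -> float:
        return sum(e.length for e in self.edges.values())

    def min_lumen(self) -> float:
        return min(e.min_lumen_diameter for e in self.edges.values())

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        pts = np.vstack([e.polyline for e in self.edges.values()])
        return pts.min(axis=0), pts.max(axis=0)

    def iter_polyline_points(self) -> Iterator[np.ndarray]:
        for e in sorted(self.edges.values(), key=lambda e: e.id):
            yield e.polyline

    # -- validation -------------------------------------------------------
    def validate(self, require_export: bool = True) -> None:
        """Check all structural invariants; raise GraphInvariantError on failure."""
        if not self.nodes:
            raise GraphInvariantError("graph has no nodes")
        g = self.as_networkx()
        if not nx.is_connected(g):
            sizes = sorted((len(c) for c in nx.connected_components(g)), reverse=True)
            raise GraphInvariantError(f"graph is disconnected (component sizes {sizes})")
        exports = [n for n in self.nodes.values() if n.kind == "export"]
        if require_export and len(exports) != 1:
            raise GraphInvariantError(f"expected exactly one export node, found {len(exports)}")
        if not self.allow_cycles and self.edges and len(self.edges) != len(self.nodes) - 1:
            raise GraphInvariantError(
                f"graph is not a tree ({len(self.nodes)} nodes, {len(self.edges)} edges)"
            )
        for e in self.edges.values():
            if not np.allclose(e.polyline[0], self.nodes[e.a].pos, atol=LENGTH_ATOL):
                raise GraphInvariantError(f"edge {e.id}: polyline start != node {e.a} position")
            if not np.allclose(e.polyline[-1], self.nodes[e.b].pos, atol=LENGTH_ATOL):
                raise GraphInvariantError(f"edge {e.id}: polyline end != node {e.b} position")

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format": "renodrain-graph",
            "version": 1,
            "nodes": [
                {"id": n.id, "kind": n.kind, "pos": [round(float(v), 6) for v in n.pos]}
                for n in sorted(self.nodes.values(), key=lambda n: n.id)
            ],
            "edges": [
                {
                    "id": e.id,
                    "a": e.a,
                    "b": e.b,
                    "polyline": [[round(float(v), 6) for v in p] for p in e.polyline],
                    "min_lumen_diameter": round(float(e.min_lumen_diameter), 6),
                }
                for e in sorted(self.edges.values(), key=lambda e: e.id)
            ],
        }

    @classmethod
    def from_dict(cls, data: dict, allow_cycles: bool = False) -> "CollectingSystemGraph":
        if data.get("format") != "renodrain-graph":
            raise GraphInvariantError("not a renodrain graph document")
        if data.get("version") != 1:
            raise GraphInvariantError(f"unsupported graph schema version {data.get('version')}")
        graph = cls(allow_cycles=allow_cycles)
        for n in data["nodes"]:
            graph.add_node(n["id"], n["pos"], n["kind"])
        for e in data["edges"]:
            graph.add_edge(e["id"], e["a"], e["b"], e["polyline"], e["min_lumen_diameter"])
        return graph

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path, allow_cycles: bool = False) -> "CollectingSystemGraph":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text), allow_cycles=allow_cycles)

    def copy(self) -> "CollectingSystemGraph":
        out = CollectingSystemGraph(allow_cycles=self.allow_cycles)
        for n in sorted(self.nodes.values(), key=lambda n: n.id):
            out.add_node(n.id, n.pos.copy(), n.kind)
        for e in sorted(self.edges.values(), key=lambda e: e.id):
            out.add_edge(e.id, e.a, e.b, e.polyline.copy(), e.min_lumen_diameter)
        return out
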