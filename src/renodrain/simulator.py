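"""Quasi-static gravity drainage of a stone along the centerline network.

The stone is modelled as a point constrained to the centerline polylines,
carrying a diameter for the sphere-through-tube passability test.  At a fixed
bed orientation it repeatedly takes the steepest *admissible* polyline step —
one whose direction lies within ``trap_angle`` of the gravity direction in
the bed frame and whose edge lumen admits the stone — until no admissible
step remains (a local trap) or the export node is reached.  With the default
``trap_angle`` of 80° a step must descend at least 10° below horizontal to
drain, a single-threshold abstraction of the friction and wall geometry of a
physical phantom.

Because admissible steps strictly lose height, the walk terminates and the
stone's height is monotonically non-increasing within each orientation; a
stone may legitimately route through branches outside the planned path if
they descend more steeply (passage via another calyx).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .bedframe import BedOrientation, gravity_in_bed_frame
from .graph import CollectingSystemGraph, Stone

__all__ = ["SimConfig", "TrajectoryRecord", "settle", "simulate_plan", "grid_passage_map"]

DEFAULT_TRAP_ANGLE = 80.0  # degrees


@dataclass(frozen=True)
class SimConfig:
    """Drainage thresholds: trap angle (degrees) and a step budget guard."""

    trap_angle: float = DEFAULT_TRAP_ANGLE
    max_steps: int | None = None  # None: 4x the polyline vertex count

    def __post_init__(self) -> None:
        if not (0.0 < self.trap_angle < 90.0):
            raise ValueError("trap_angle must lie strictly between 0 and 90 degrees")


@dataclass
class TrajectoryRecord:
    """Movement record of one simulated plan replay."""

    steps: list[tuple[int, str]] = field(default_factory=list)  # (group index, site label)
    final_site: str = ""
    final_node: int | None = None
    passed: bool = False

    def to_dict(self) -> dict:
        return {
            "steps": [[g, s] for g, s in self.steps],
            "final_site": self.final_site,
            "final_node": self.final_node,
            "passed": self.passed,
        }


class SiteGraph:
    """Flattened polyline-vertex graph used by the drainage walk.

    Sites are all polyline vertices; vertices coincident with graph nodes are
    shared across edges.  Each directed step carries its parent edge id and
    lumen diameter and the target's vertex order inside the edge (tie-break
    key).  Deterministic for a given graph.
    """

    def __init__(self, graph: CollectingSystemGraph):
        self.graph = graph
        self.positions: list[np.ndarray] = []
        self.labels: list[str] = []
        self.node_site: dict[int, int] = {}
        self.site_node: dict[int, int] = {}
        # adjacency: site -> list of (other_site, edge_id, target_vertex_idx, lumen)
        self.adj: dict[int, list[tuple[int, int, int, float]]] = {}

        for nid in sorted(graph.nodes):
            s = self._new_site(graph.nodes[nid].pos, f"n{nid}")
            self.node_site[nid] = s
            self.site_node[s] = nid
        for eid in sorted(graph.edges):
            e = graph.edges[eid]
            poly = e.polyline
            sites = [self.node_site[e.a]]
            for vi in range(1, len(poly) - 1):
                sites.append(self._new_site(poly[vi], f"e{eid}:{vi}"))
            sites.append(self.node_site[e.b])
            for vi in range(len(sites) - 1):
                s0, s1 = sites[vi], sites[vi + 1]
                if np.linalg.norm(poly[vi + 1] - poly[vi]) < 1e-9:
                    continue  # degenerate zero-length step
                self.adj.setdefault(s0, []).append((s1, eid, vi + 1, e.min_lumen_diameter))
                self.adj.setdefault(s1, []).append((s0, eid, vi, e.min_lumen_diameter))
        for k in self.adj:
            self.adj[k].sort(key=lambda t: (t[1], t[2]))

    def _new_site(self, pos: np.ndarray, label: str) -> int:
        self.positions.append(np.asarray(pos, dtype=float))
        self.labels.append(label)
        self.adj.setdefault(len(self.labels) - 1, [])
        return len(self.labels) - 1

    @property
    def n_sites(self) -> int:
        return len(self.labels)


def _default_max_steps(sites: SiteGraph, config: SimConfig) -> int:
    if config.max_steps is not None:
        return config.max_steps
    return max(1000, 4 * sites.n_sites)


def _settle_from(
    sites: SiteGraph,
    start: int,
    diameter: float,
    orientation: BedOrientation,
    config: SimConfig,
) -> tuple[int, list[int]]:
    g = gravity_in_bed_frame(orientation)
    cos_trap = math.cos(math.radians(config.trap_angle))
    export_site = None
    export_ids = [n.id for n in sites.graph.nodes.values() if n.kind == "export"]
    if export_ids:
        export_site = sites.node_site[export_ids[0]]

    cur = start
    visited = [cur]
    budget = _default_max_steps(sites, config)
    for _ in range(budget):
        if cur == export_site:
            break
        best = None  # (descent_cos, -edge_id, -vertex_idx) maximised
        for other, eid, vidx, lumen in sites.adj[cur]:
            if lumen + 1e-9 < diameter:
                continue
            step = sites.positions[other] - sites.positions[cur]
            norm = float(np.linalg.norm(step))
            if norm < 1e-12:
                continue
            descent = float(np.dot(step, g)) / norm  # cos(angle to gravity)
            if descent < cos_trap - 1e-12:
                continue
            key = (descent, -eid, -vidx)
            if best is None or key > best[0]:
                best = (key, other)
        if best is None:
            break
        cur = best[1]
        visited.append(cur)
    else:
        raise RuntimeError(
            f"settle exceeded {budget} steps; cyclic drainage should be impossible"
        )
    return cur, visited


def settle(
    graph: CollectingSystemGraph,
    stone: Stone,
    orientation: BedOrientation,
    config: SimConfig = SimConfig(),
    _sites: SiteGraph | None = None,
) -> tuple[str, list[str]]:
    """Drain the stone at one fixed orientation until it traps or exports.

    Returns ``(final site label, visited site labels)``.  Site labels are
    ``"n<node_id>"`` for graph nodes and ``"e<edge_id>:<vertex>"`` for
    interior polyline vertices.
    """
    sites = _sites or SiteGraph(graph)
    start = sites.node_site[stone.node]
    final, visited = _settle_from(sites, start, stone.diameter, orientation, config)
    return sites.labels[final], [sites.labels[v] for v in visited]


def simulate_plan(
    graph: CollectingSystemGraph,
    stone: Stone,
    plan,
    config: SimConfig = SimConfig(),
) -> TrajectoryRecord:
    """Replay an angle plan group by group; the stone persists between groups.

    ``plan`` may be an :class:`~renodrain.planner.AnglePlan` or a plain
    sequence of :class:`~renodrain.bedframe.BedOrientation`.  A trial passes
    iff the stone's final resting site is the export node.
    """
    orientations = _plan_orientations(plan)
    sites = SiteGraph(graph)
    cur = sites.node_site[stone.node]
    rec = TrajectoryRecord()
    rec.steps.append((-1, sites.labels[cur]))
    for gi, orientation in enumerate(orientations):
        cur, visited = _settle_from(sites, cur, stone.diameter, orientation, config)
        rec.steps.extend((gi, sites.labels[v]) for v in visited[1:])
    rec.final_site = sites.labels[cur]
    rec.final_node = sites.site_node.get(cur)
    export_ids = [n.id for n in graph.nodes.values() if n.kind == "export"]
    rec.passed = bool(export_ids) and rec.final_node == export_ids[0]
    return rec


def _plan_orientations(plan) -> list[BedOrientation]:
    if hasattr(plan, "groups"):
        return [grp.orientation if hasattr(grp, "orientation") else grp[0]
                for grp in plan.groups]
    return list(plan)


def grid_passage_map(
    graph: CollectingSystemGraph,
    stone: Stone,
    resolution: float,
    config: SimConfig = SimConfig(),
):
    """Evaluate single-orientation settling over the full angle grid.

    Returns a pandas DataFrame with columns ``theta_x``, ``theta_y``,
    ``final_site`` and ``reaches_export`` — a brute-force diagnostic of which
    orientations drain the stone.
    """
    import pandas as pd

    if not resolution > 0:
        raise ValueError("grid resolution must be > 0 degrees")
    sites = SiteGraph(graph)
    start = sites.node_site[stone.node]
    export_ids = [n.id for n in graph.nodes.values() if n.kind == "export"]
    export_site = sites.node_site[export_ids[0]] if export_ids else None
    rows = []
    for tx in np.arange(-90.0, 90.0 + 1e-9, resolution):
        for ty in np.arange(-60.0, 60.0 + 1e-9, resolution):
            final, _ = _settle_from(
                sites, start, stone.diameter, BedOrientation(tx, ty), config
            )
            rows.append(
                {
                    "theta_x": float(tx),
                    "theta_y": float(ty),
                    "final_site": sites.labels[final],
                    "reaches_export": final == export_site,
                }
            )
    return pd.DataFrame(rows)
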