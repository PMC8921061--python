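"""Drainage path planning: stone -> export path, split into bed-angle groups.

A drainage plan is an ordered list of *angle groups*: bed orientations, each
held while the stone drains along one segment of the stone-to-export path.
A segment is drainable at an orientation when every polyline step direction
inside it lies within ``cone_angle`` of the gravity direction in the bed
frame; the orientation assigned to a segment is the one minimising the
maximum deviation over its steps (a minimax alignment).  Segmentation is
greedy maximal-prefix: the current segment absorbs path edges while some
in-range orientation keeps the whole accumulated direction bundle inside the
cone.  Because that feasibility predicate only gets harder as a segment
grows, the greedy split uses the fewest possible groups.

The planner keeps ``cone_angle`` at least 5° inside the simulator's trap
angle so a planned step can never sit on the drain/trap boundary, and it
verifies its best candidate plan by replaying it through the quasi-static
simulator before labelling the plan ``feasible`` — under a fixed orientation
a stone follows the steepest admissible branch, which may leave the planned
path, so the replay is what turns "every planned step drains" into "the
stone actually reaches the export".

Plans are ranked by (1) fewest groups, (2) smallest total inversion burden
(sum of head-down angles, a patient-comfort proxy), (3) shortest arc length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import optimize

from .bedframe import (
    THETA_X_LIMIT,
    THETA_Y_LIMIT,
    BedOrientation,
    gravity_grid,
    solve_bed_angles,
)
from .graph import CollectingSystemGraph, Stone
from .simulator import SimConfig, simulate_plan

__all__ = [
    "PlannerConfig",
    "PlanGroup",
    "AnglePlan",
    "enumerate_paths",
    "segment_path",
    "plan_drainage",
    "minimax_orientation",
]

#: Margin (degrees) the planner keeps between its cone and the simulator trap.
TRAP_SLACK = 5.0


@dataclass(frozen=True)
class PlannerConfig:
    """Planner tunables.

    cone_angle : max angle (degrees) between gravity and any step inside one
        segment; must stay ``TRAP_SLACK`` inside the simulator's trap angle
        (cross-validated in :func:`plan_drainage`)
    max_paths : cap on candidate paths considered on cyclic graphs
    comfort_weight : if True, rank equal-group plans by inversion burden
    """

    cone_angle: float = 60.0
    max_paths: int = 10
    comfort_weight: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.cone_angle < 90.0:
            raise ValueError("cone_angle must lie in (0, 90) degrees")
        if self.max_paths < 1:
            raise ValueError("max_paths must be >= 1")


@dataclass
class PlanGroup:
    orientation: BedOrientation
    segment: list[int]  # node path covered while this orientation is held
    max_deviation: float  # worst step angle to gravity, degrees
    feasible: bool  # max_deviation <= cone_angle


@dataclass
class AnglePlan:
    groups: list[PlanGroup] = field(default_factory=list)
    path: list[int] = field(default_factory=list)
    status: str = "infeasible"  # feasible | partial | infeasible

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def to_dict(self) -> dict:
        return {
            "format": "renodrain-plan",
            "version": 1,
            "status": self.status,
            "path": list(self.path),
            "groups": [
                {
                    "theta_x": round(g.orientation.theta_x, 1),
                    "theta_y": round(g.orientation.theta_y, 1),
                    "segment": list(g.segment),
                    "max_deviation": round(g.max_deviation, 2),
                }
                for g in self.groups
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "AnglePlan":
        plan = cls(status=data["status"], path=list(data["path"]))
        for g in data["groups"]:
            plan.groups.append(
                PlanGroup(
                    orientation=BedOrientation(g["theta_x"], g["theta_y"]),
                    segment=list(g["segment"]),
                    max_deviation=float(g.get("max_deviation", 0.0)),
                    feasible=True,
                )
            )
        return plan


# ---------------------------------------------------------------------------
# path enumeration

def _passable_multigraph(graph: CollectingSystemGraph, min_diameter: float) -> nx.MultiGraph:
    g = nx.MultiGraph()
    g.add_nodes_from(graph.nodes)
    for e in sorted(graph.edges.values(), key=lambda e: e.id):
        if e.min_lumen_diameter + 1e-9 >= min_diameter:
            g.add_edge(e.a, e.b, key=e.id, length=e.length)
    return g


def edge_between(
    graph: CollectingSystemGraph, a: int, b: int, min_diameter: float = 0.0
):
    """The lowest-id passable edge joining nodes a and b (None if absent)."""
    for e in sorted(graph.edges.values(), key=lambda e: e.id):
        if {e.a, e.b} == {a, b} and e.min_lumen_diameter + 1e-9 >= min_diameter:
            return e
    return None


def path_arc_length(graph: CollectingSystemGraph, path: list[int],
                    min_diameter: float = 0.0) -> float:
    total = 0.0
    for a, b in zip(path[:-1], path[1:]):
        e = edge_between(graph, a, b, min_diameter)
        if e is None:
            raise ValueError(f"no passable edge between nodes {a} and {b}")
        total += e.length
    return total


def enumerate_paths(
    graph: CollectingSystemGraph,
    stone_node: int,
    export_node: int,
    max_paths: int = 10,
    min_diameter: float = 0.0,
) -> list[list[int]]:
    """All simple stone-to-export node paths passable by the stone.

    Every edge on a returned path has ``min_lumen_diameter >= min_diameter``.
    Trees have at most one; on cyclic graphs the result is capped at
    ``max_paths``, ordered by increasing arc length.  A stone already at the
    export yields the single trivial path ``[[export_node]]``; an unpassable
    stone yields ``[]``.
    """
    if stone_node not in graph.nodes or export_node not in graph.nodes:
        raise KeyError("stone_node and export_node must both be graph nodes")
    if stone_node == export_node:
        return [[export_node]]
    g = _passable_multigraph(graph, min_diameter)
    try:
        paths = list(nx.all_simple_paths(g, stone_node, export_node))
    except nx.NodeNotFound:
        return []
    paths.sort(key=lambda p: (path_arc_length(graph, p, min_diameter), p))
    return paths[:max_paths]


# ---------------------------------------------------------------------------
# minimax orientation of a direction bundle

def _max_deviation_grid(tx: np.ndarray, ty: np.ndarray, dirs: np.ndarray) -> np.ndarray:
    """Max angle (deg) between gravity(tx, ty) and each direction, vectorised."""
    g = gravity_grid(tx, ty)  # (..., 3)
    dots = np.clip(np.tensordot(g, dirs.T, axes=([-1], [0])), -1.0, 1.0)
    return np.degrees(np.arccos(dots)).max(axis=-1)


def minimax_orientation(dirs: np.ndarray) -> tuple[BedOrientation, float]:
    """In-range orientation minimising the worst angle to a direction bundle.

    ``dirs`` is an (n, 3) array of unit step directions.  A coarse vectorised
    grid over the hardware rectangle seeds a Nelder-Mead refinement of the
    (non-smooth) minimax objective.
    """
    dirs = np.atleast_2d(np.asarray(dirs, dtype=float))

    # seed candidates: chord/mean closed-form solves plus a coarse grid
    seeds = []
    mean = dirs.mean(axis=0)
    if np.linalg.norm(mean) > 1e-9:
        sol = solve_bed_angles(mean / np.linalg.norm(mean))
        seeds.append(sol.orientation.as_tuple())
    txg, tyg = np.meshgrid(
        np.arange(-THETA_X_LIMIT, THETA_X_LIMIT + 1e-9, 5.0),
        np.arange(-THETA_Y_LIMIT, THETA_Y_LIMIT + 1e-9, 5.0),
        indexing="ij",
    )
    devs = _max_deviation_grid(txg, tyg, dirs)
    i, j = np.unravel_index(np.argmin(devs), devs.shape)
    seeds.append((float(txg[i, j]), float(tyg[i, j])))

    def objective(x: np.ndarray) -> float:
        tx = float(np.clip(x[0], -THETA_X_LIMIT, THETA_X_LIMIT))
        ty = float(np.clip(x[1], -THETA_Y_LIMIT, THETA_Y_LIMIT))
        penalty = abs(x[0] - tx) + abs(x[1] - ty)
        return float(_max_deviation_grid(np.array(tx), np.array(ty), dirs)) + penalty

    best_x, best_f = None, math.inf
    for seed in seeds:
        res = optimize.minimize(
            objective, np.asarray(seed, dtype=float), method="Nelder-Mead",
            options={"xatol": 0.01, "fatol": 0.005, "maxiter": 300},
        )
        if res.fun < best_f:
            best_f, best_x = float(res.fun), res.x
    tx = float(np.clip(best_x[0], -THETA_X_LIMIT, THETA_X_LIMIT))
    ty = float(np.clip(best_x[1], -THETA_Y_LIMIT, THETA_Y_LIMIT))
    dev = float(_max_deviation_grid(np.array(tx), np.array(ty), dirs))
    return BedOrientation(tx, ty), dev


# ---------------------------------------------------------------------------
# segmentation

def _path_edge_dirs(
    graph: CollectingSystemGraph, path: list[int], min_diameter: float = 0.0
) -> list[np.ndarray]:
    """Per path edge: the (k, 3) array of unit polyline step directions."""
    out = []
    for a, b in zip(path[:-1], path[1:]):
        e = edge_between(graph, a, b, min_diameter)
        if e is None:
            raise ValueError(f"no passable edge between nodes {a} and {b}")
        poly = e.polyline if e.a == a else e.polyline[::-1]
        steps = np.diff(poly, axis=0)
        norms = np.linalg.norm(steps, axis=1)
        keep = norms > 1e-9
        out.append(steps[keep] / norms[keep, None])
    return out


def segment_feasible(dirs: np.ndarray, cone_angle: float) -> tuple[BedOrientation, float, bool]:
    """Minimax orientation of a bundle and whether it fits inside the cone."""
    orientation, dev = minimax_orientation(dirs)
    return orientation, dev, dev <= cone_angle + 1e-9


def segment_path(
    graph: CollectingSystemGraph,
    path: list[int],
    config: PlannerConfig = PlannerConfig(),
    min_diameter: float = 0.0,
    boundaries: set[int] | None = None,
) -> list[PlanGroup]:
    """Greedy maximal-prefix split of a node path into angle groups.

    Each group covers a consecutive run of path edges whose pooled polyline
    step directions fit within ``config.cone_angle`` of gravity at some
    in-range orientation; the group's orientation is the minimax alignment
    over its steps.  ``boundaries`` optionally forces segment breaks at the
    given nodes.  A single-node path yields no groups.  An edge impossible
    even on its own still becomes a (infeasible) group, flagged via
    ``PlanGroup.feasible``.
    """
    if len(path) < 2:
        return []
    edge_dirs = _path_edge_dirs(graph, path, min_diameter)
    groups: list[PlanGroup] = []
    i = 0
    n = len(edge_dirs)
    while i < n:
        # grow the segment edge by edge while the bundle stays inside the cone
        j = i + 1
        orientation, dev, ok = segment_feasible(np.vstack(edge_dirs[i:j]), config.cone_angle)
        best = (orientation, dev, ok)
        while j < n and not (boundaries and path[j] in boundaries):
            cand = segment_feasible(np.vstack(edge_dirs[i:j + 1]), config.cone_angle)
            if not cand[2]:
                break
            best = cand
            j += 1
        groups.append(
            PlanGroup(
                orientation=best[0],
                segment=path[i:j + 1],
                max_deviation=best[1],
                feasible=best[2],
            )
        )
        i = j
    return groups


# ---------------------------------------------------------------------------
# planning

def _inversion_burden(groups: list[PlanGroup]) -> float:
    return sum(max(0.0, -g.orientation.theta_x) for g in groups)


def plan_drainage(
    graph: CollectingSystemGraph,
    stone: Stone,
    config: PlannerConfig = PlannerConfig(),
    sim_config: SimConfig = SimConfig(),
) -> AnglePlan:
    """Best angle plan relocating the stone to the export node.

    Candidate paths are segmented and ranked by fewest groups, then total
    inversion burden, then arc length.  The winning plan is verified by
    quasi-static replay: ``status='feasible'`` guarantees the simulated stone
    reaches the export under ``sim_config``.  If the replay diverts (the
    stone drops into a steeper side branch), the planner retries with segment
    breaks forced at path junctions; failing that the plan is ``'partial'``.
    ``status='infeasible'`` means no lumen-passable path exists.
    """
    if config.cone_angle > sim_config.trap_angle - TRAP_SLACK + 1e-9:
        raise ValueError(
            f"cone_angle ({config.cone_angle}) must be at least {TRAP_SLACK} deg "
            f"inside the simulator trap angle ({sim_config.trap_angle})"
        )
    export = graph.export_node
    if stone.node == export:
        return AnglePlan(groups=[], path=[export], status="feasible")

    paths = enumerate_paths(
        graph, stone.node, export, max_paths=config.max_paths, min_diameter=stone.diameter
    )
    if not paths:
        return AnglePlan(groups=[], path=[], status="infeasible")

    candidates = []
    for path in paths:
        groups = segment_path(graph, path, config, min_diameter=stone.diameter)
        burden = _inversion_burden(groups) if config.comfort_weight else 0.0
        candidates.append(
            (len(groups), burden, path_arc_length(graph, path, stone.diameter), path, groups)
        )
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    _, _, _, path, groups = candidates[0]

    plan = AnglePlan(groups=groups, path=path, status="partial")
    all_ok = all(g.feasible for g in groups)
    if all_ok and simulate_plan(graph, stone, plan, sim_config).passed:
        plan.status = "feasible"
        return plan

    # fallback: force breaks at junction nodes (calyx->pelvis, pelvis->export
    # style staging) and retry
    junctions = {n for n in path[1:-1] if graph.degree(n) >= 3}
    if junctions:
        alt = segment_path(graph, path, config, min_diameter=stone.diameter,
                           boundaries=junctions)
        alt_plan = AnglePlan(groups=alt, path=path, status="partial")
        if all(g.feasible for g in alt) and simulate_plan(graph, stone, alt_plan,
                                                          sim_config).passed:
            alt_plan.status = "feasible"
            return alt_plan
    return plan
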