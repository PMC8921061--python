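"""Centerline extraction: binary collecting-system mask -> centerline graph.

The segmented lumen volume is thinned to a one-voxel curve skeleton, the
skeleton voxels are assembled into a graph (degree-1 voxels are calyx-tip
candidates, clusters of degree>=3 voxels are junctions), short terminal spurs
are pruned, nearby junctions merged, and each edge's minimum lumen diameter
is read off the Euclidean distance transform sampled along its polyline.
Anisotropic volumes are resampled to isotropic voxels before thinning.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np
from scipy import ndimage

from .graph import CollectingSystemGraph, GraphInvariantError, Stone

__all__ = [
    "ReconstructionError",
    "extract_centerline",
    "set_export",
    "label_calyx_groups",
    "snap_stone",
]

DEFAULT_MIN_BRANCH_LENGTH = 3.0  # mm


class ReconstructionError(ValueError):
    """The input volume cannot be reconstructed into a centerline graph."""


_OFFSETS26 = np.array(
    [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
)


def _spacing_from_affine(affine: np.ndarray) -> np.ndarray:
    return np.linalg.norm(np.asarray(affine)[:3, :3], axis=0)


def _to_mm(idx: np.ndarray, affine: np.ndarray) -> np.ndarray:
    return idx @ np.asarray(affine)[:3, :3].T + np.asarray(affine)[:3, 3]


def _smooth_polyline(pts: np.ndarray, iterations: int = 2) -> np.ndarray:
    """Moving-average smoothing of interior vertices (endpoints fixed).

    Removes the staircase jitter of voxel-center chains so arc lengths are
    not systematically inflated by the digital path.
    """
    out = pts.copy()
    for _ in range(iterations):
        if len(out) < 3:
            break
        out[1:-1] = 0.25 * out[:-2] + 0.5 * out[1:-1] + 0.25 * out[2:]
    return out


def extract_centerline(
    volume: np.ndarray,
    affine: np.ndarray,
    min_branch_length: float = DEFAULT_MIN_BRANCH_LENGTH,
    junction_merge_length: float | None = None,
) -> CollectingSystemGraph:
    """Thin a binary lumen mask into a :class:`CollectingSystemGraph`.

    Parameters
    ----------
    volume : binary array indexed (x, y, z) with a single foreground component
    affine : 4x4 voxel-index -> mm map
    min_branch_length : terminal spurs shorter than this (mm) are pruned
    junction_merge_length : junction clusters closer than this (mm) are merged
        into one node (thinning splits a 4-way branch point inside a wide
        lumen into nearby 3-way points); default 2 x min_branch_length

    Node kinds: degree-1 nodes become ``calyx_tip`` candidates, the
    highest-degree node is marked ``pelvis``, the rest are ``junction``.  The
    export node is unassigned until :func:`set_export`.
    """
    from skimage.morphology import skeletonize

    vol = np.asarray(volume).astype(bool)
    affine = np.asarray(affine, dtype=float)
    if vol.sum() == 0:
        raise ReconstructionError("empty volume: no foreground voxels")
    labels, ncomp = ndimage.label(vol, structure=np.ones((3, 3, 3), dtype=int))
    if ncomp != 1:
        sizes = sorted(np.bincount(labels.ravel())[1:].tolist(), reverse=True)
        raise ReconstructionError(
            f"volume has {ncomp} foreground components (sizes {sizes}); expected one"
        )

    spacing = _spacing_from_affine(affine)
    if not np.allclose(spacing, spacing[0], rtol=1e-3):
        # resample to isotropic voxels at the finest spacing before thinning
        iso = float(spacing.min())
        zoom = spacing / iso
        vol = ndimage.zoom(vol.astype(np.uint8), zoom, order=0).astype(bool)
        new_affine = np.eye(4)
        new_affine[:3, :3] = np.asarray(affine)[:3, :3] @ np.diag(1.0 / zoom)
        new_affine[:3, 3] = affine[:3, 3]
        affine = new_affine
        spacing = _spacing_from_affine(affine)
    voxel_mm = float(spacing[0])

    skel = skeletonize(vol)
    if skel.sum() == 0:  # degenerate tiny blob: thinning consumed everything
        raise ReconstructionError("skeletonization produced no voxels")
    edt = ndimage.distance_transform_edt(vol, sampling=spacing)

    coords = np.argwhere(skel)
    index_of = {tuple(c): i for i, c in enumerate(coords)}
    nvox = len(coords)
    neighbors: list[list[int]] = [[] for _ in range(nvox)]
    for i, c in enumerate(coords):
        for off in _OFFSETS26:
            j = index_of.get(tuple(c + off))
            if j is not None:
                neighbors[i].append(j)
    degree = np.array([len(n) for n in neighbors])

    # node voxels: endpoints (deg 1, or isolated) and junction voxels (deg >= 3)
    is_node_voxel = (degree != 2)
    # cluster mutually adjacent junction voxels into single nodes
    cluster_of = np.full(nvox, -1, dtype=int)
    clusters: list[list[int]] = []
    for i in range(nvox):
        if not is_node_voxel[i] or cluster_of[i] >= 0:
            continue
        if degree[i] < 3:
            cluster_of[i] = len(clusters)
            clusters.append([i])
            continue
        stack, members = [i], []
        cluster_of[i] = len(clusters)
        while stack:
            v = stack.pop()
            members.append(v)
            for w in neighbors[v]:
                if degree[w] >= 3 and cluster_of[w] < 0:
                    cluster_of[w] = len(clusters)
                    stack.append(w)
        clusters.append(sorted(members))

    # trace polyline edges between node clusters through degree-2 chains
    raw_edges: list[tuple[int, int, list[int]]] = []  # (cluster_a, cluster_b, voxel path)
    seen_chain = np.zeros(nvox, dtype=bool)
    seen_pair: set[tuple[int, ...]] = set()
    for ci, members in enumerate(clusters):
        for v in members:
            for w in neighbors[v]:
                if is_node_voxel[w]:
                    cj = cluster_of[w]
                    if cj == ci:
                        continue
                    key = (min(ci, cj), max(ci, cj), min(v, w), max(v, w))
                    if key in seen_pair:
                        continue
                    seen_pair.add(key)
                    raw_edges.append((ci, cj, [v, w]))
                    continue
                if seen_chain[w]:
                    continue
                # walk the chain
                path = [v, w]
                seen_chain[w] = True
                prev, cur = v, w
                while not is_node_voxel[cur]:
                    nxt = [x for x in neighbors[cur] if x != prev]
                    # at a corner a chain voxel can touch >2 skeleton voxels
                    # diagonally; prefer an unvisited chain voxel, else a node
                    nxt_chain = [x for x in nxt if not is_node_voxel[x] and not seen_chain[x]]
                    nxt_node = [x for x in nxt if is_node_voxel[x]]
                    if nxt_chain:
                        prev, cur = cur, nxt_chain[0]
                        seen_chain[cur] = True
                    elif nxt_node:
                        prev, cur = cur, nxt_node[0]
                    else:
                        break  # dead end inside a chain (should not happen)
                    path.append(cur)
                if is_node_voxel[cur]:
                    raw_edges.append((ci, cluster_of[cur], path))

    # cluster centroids in mm
    centroid = {
        ci: _to_mm(coords[members].astype(float).mean(axis=0), affine)
        for ci, members in enumerate(clusters)
    }

    # assemble a mutable adjacency structure for pruning/merging
    edges: dict[int, dict] = {}
    for eid, (ca, cb, path) in enumerate(raw_edges):
        pts = _to_mm(coords[path].astype(float), affine)
        pts = np.vstack([centroid[ca], pts, centroid[cb]])
        # lumen from the EDT along the chain, excluding one tube radius at
        # each end where the chain can graze cap/junction boundary voxels
        edts = [float(edt[tuple(coords[p])]) for p in path]
        skip = int(math.ceil(max(edts) / voxel_mm))
        interior = edts[skip:-skip] if len(edts) > 2 * skip else edts
        lumen = 2.0 * min(interior)
        edges[eid] = {"a": ca, "b": cb, "pts": pts, "lumen": max(lumen, voxel_mm)}

    def node_degree() -> dict[int, int]:
        d: dict[int, int] = defaultdict(int)
        for e in edges.values():
            d[e["a"]] += 1
            d[e["b"]] += 1
        return d

    def seglen(pts: np.ndarray) -> float:
        return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))

    merge_length = (
        2.0 * min_branch_length if junction_merge_length is None else junction_merge_length
    )

    # 1) prune short terminal spurs (leaf edges off a junction)
    changed = True
    while changed:
        changed = False
        deg = node_degree()
        for eid in sorted(edges):
            e = edges[eid]
            if e["a"] == e["b"]:
                continue
            for leaf, other in ((e["a"], e["b"]), (e["b"], e["a"])):
                if deg[leaf] == 1 and deg[other] >= 3 and seglen(e["pts"]) < min_branch_length:
                    del edges[eid]
                    changed = True
                    break
            if changed:
                break

    # 2) iterate junction merging, pass-through dissolution and short-loop
    # removal to a fixpoint: each step can expose new work for the others
    # (e.g. dissolving a degree-2 node can create a new short
    # junction-junction edge that must then be merged)

    def _merge_one() -> bool:
        deg = node_degree()
        for eid in sorted(edges):
            e = edges[eid]
            # a branch point inside a wide lumen cannot be localised better
            # than about one lumen diameter: thinning splits an X-junction
            # into two nearby Y-junctions, so the merge threshold scales with
            # the connecting chain's lumen
            thresh = max(merge_length, 2.0 * e["lumen"])
            if e["a"] != e["b"] and deg[e["a"]] >= 3 and deg[e["b"]] >= 3 \
                    and seglen(e["pts"]) < thresh:
                keep, drop = e["a"], e["b"]
                # place the merged node at the chain midpoint and graft each
                # chain half onto the incident edges, conserving arc length
                chain = e["pts"]  # runs keep -> drop
                cum = np.concatenate(
                    [[0.0], np.cumsum(np.linalg.norm(np.diff(chain, axis=0), axis=1))]
                )
                mid = int(np.searchsorted(cum, cum[-1] / 2.0))
                mid = min(max(mid, 0), len(chain) - 1)
                half_a = chain[: mid + 1]  # keep-side half, ends at new centre
                half_b = chain[mid:][::-1]  # drop-side half reversed: drop -> centre
                new_pos = chain[mid]
                del edges[eid]
                for f in edges.values():
                    if f["a"] == drop and f["b"] == drop:  # becomes a self-loop
                        f["a"] = f["b"] = keep
                        f["pts"] = np.vstack([half_b[::-1], f["pts"][1:-1], half_b])
                        continue
                    if f["a"] == keep and f["b"] == keep:  # existing self-loop
                        f["pts"] = np.vstack([half_a[::-1], f["pts"][1:-1], half_a])
                        continue
                    if f["a"] == drop:
                        f["a"] = keep
                        f["pts"] = np.vstack([half_b[::-1], f["pts"][1:]])
                    elif f["b"] == drop:
                        f["b"] = keep
                        f["pts"] = np.vstack([f["pts"][:-1], half_b])
                    elif f["a"] == keep:
                        f["pts"] = np.vstack([half_a[::-1], f["pts"][1:]])
                    elif f["b"] == keep:
                        f["pts"] = np.vstack([f["pts"][:-1], half_a])
                centroid[keep] = new_pos
                return True
        return False

    def _dissolve_one() -> bool:
        deg = node_degree()
        for node, d in deg.items():
            if d != 2:
                continue
            inc = [eid for eid, e in sorted(edges.items()) if node in (e["a"], e["b"])]
            if len(inc) != 2 or inc[0] == inc[1]:
                continue
            e1, e2 = edges[inc[0]], edges[inc[1]]
            p1 = e1["pts"] if e1["b"] == node else e1["pts"][::-1]
            p2 = e2["pts"] if e2["a"] == node else e2["pts"][::-1]
            merged = {
                "a": e1["a"] if e1["b"] == node else e1["b"],
                "b": e2["b"] if e2["a"] == node else e2["a"],
                "pts": np.vstack([p1, p2[1:]]),
                "lumen": min(e1["lumen"], e2["lumen"]),
            }
            del edges[inc[1]]
            edges[inc[0]] = merged
            return True
        return False

    def _drop_short_loop_one() -> bool:
        # parallel chains inside a wide junction blob survive merging as
        # self-loops; a short thin loop is a thinning artifact, not anatomy
        for eid in sorted(edges):
            e = edges[eid]
            if e["a"] == e["b"] and seglen(e["pts"]) < max(merge_length, 2.0 * e["lumen"]):
                del edges[eid]
                return True
        return False

    while _merge_one() or _dissolve_one() or _drop_short_loop_one():
        pass

    if not edges:
        raise ReconstructionError(
            "no centerline edges survive pruning; volume too small or spurs only"
        )

    # 4) re-anchor terminal branches at the tube ends: the centerline endpoint
    # sits one lumen radius behind the cap apex, but thinning may retract
    # further (round caps) or not at all (flat resampled caps).  March along
    # the terminal tangent to the foreground boundary and place the endpoint
    # one local tube radius short of it.
    inv = np.linalg.inv(affine)

    def _inside(p_mm: np.ndarray) -> bool:
        ijk = np.round(inv[:3, :3] @ p_mm + inv[:3, 3]).astype(int)
        if np.any(ijk < 0) or np.any(ijk >= np.array(vol.shape)):
            return False
        return bool(vol[tuple(ijk)])

    def _edt_at(p_mm: np.ndarray) -> float:
        ijk = np.round(inv[:3, :3] @ p_mm + inv[:3, 3]).astype(int)
        ijk = np.clip(ijk, 0, np.array(vol.shape) - 1)
        return float(edt[tuple(ijk)])

    deg = node_degree()
    for e in edges.values():
        for end, other in (("a", "b"), ("b", "a")):
            if deg[e[end]] != 1:
                continue
            pts = e["pts"] if end == "b" else e["pts"][::-1]
            k = min(len(pts) - 1, 6)
            tangent = pts[-1] - pts[-1 - k]
            tn = float(np.linalg.norm(tangent))
            if tn < 1e-9:
                continue
            tangent /= tn
            tip = pts[-1]
            step = voxel_mm / 2.0
            travelled = 0.0
            while travelled < 30.0 and _inside(tip + (travelled + step) * tangent):
                travelled += step
            # local tube radius from the chain interior (EDT at the very end
            # voxel can be near zero on a flat cap)
            tail = pts[max(0, len(pts) - 9):]
            r_tube = max(_edt_at(p) for p in tail)
            ext = travelled - r_tube
            if abs(ext) <= step:
                continue
            new_tip = tip + ext * tangent
            if ext > 0:
                trimmed = e["pts"]
            else:
                # retraction: drop trailing vertices inside the cap zone
                pts_o = e["pts"] if end == "b" else e["pts"][::-1]
                keep = np.linalg.norm(pts_o - tip, axis=1) > abs(ext)
                last = np.max(np.nonzero(keep)) if keep.any() else 0
                pts_o = pts_o[: last + 1]
                trimmed = pts_o if end == "b" else pts_o[::-1]
            if end == "b":
                e["pts"] = np.vstack([trimmed, new_tip])
            else:
                e["pts"] = np.vstack([new_tip, trimmed])
            centroid[e[end]] = new_tip

    # build the final graph with deterministic ids (sorted by position)
    used = sorted({e["a"] for e in edges.values()} | {e["b"] for e in edges.values()})
    deg = node_degree()
    order = sorted(used, key=lambda c: tuple(np.round(centroid[c], 6)))
    remap = {c: i for i, c in enumerate(order)}
    pelvis_cluster = max(used, key=lambda c: (deg[c], -remap[c]))

    graph = CollectingSystemGraph(allow_cycles=True)
    for c in order:
        if c == pelvis_cluster and deg[c] >= 3:
            kind = "pelvis"
        elif deg[c] == 1:
            kind = "calyx_tip"
        else:
            kind = "junction"
        graph.add_node(remap[c], centroid[c], kind)
    for new_id, eid in enumerate(sorted(edges)):
        e = edges[eid]
        graph.add_edge(new_id, remap[e["a"]], remap[e["b"]],
                       _smooth_polyline(e["pts"]), e["lumen"])
    _refit_branch_points(graph)
    if len(graph.edges) == len(graph.nodes) - 1:
        graph.allow_cycles = False
    graph.validate(require_export=False)
    return graph


def _refit_branch_points(graph: CollectingSystemGraph) -> None:
    """Relocate junction nodes to the intersection of incident centerlines.

    Thinning displaces a branch point into the widest of the meeting tubes by
    up to a lumen radius.  Each incident polyline is clean outside the branch
    zone, so the true branch point is re-estimated as the least-squares
    intersection of lines fitted to the polylines just outside that zone; the
    polylines are then trimmed of their in-zone detour and re-anchored.
    """
    for node in graph.nodes.values():
        incident = graph.incident_edges(node.id)
        if len(incident) < 3:
            continue
        lines = []
        zones = {}
        for e in incident:
            pts = e.polyline if e.b == node.id else e.polyline[::-1]
            d = np.linalg.norm(pts - node.pos, axis=1)
            zone = 1.5 * e.min_lumen_diameter / 2.0 + 2.0
            zones[e.id] = zone
            sel = (d > zone) & (d < zone + 8.0)
            if np.count_nonzero(sel) >= 2:
                p_sel = pts[sel]
                c = p_sel.mean(axis=0)
                t = np.linalg.svd(p_sel - c)[2][0]
                lines.append((c, t))
        if len(lines) < 2:
            continue
        a_mat = np.zeros((3, 3))
        b_vec = np.zeros(3)
        for c, t in lines:
            m = np.eye(3) - np.outer(t, t)
            a_mat += m
            b_vec += m @ c
        try:
            new_pos = np.linalg.solve(a_mat, b_vec)
        except np.linalg.LinAlgError:
            continue
        if np.linalg.norm(new_pos - node.pos) > 10.0:
            continue  # fit ran away (nearly parallel lines); keep the voxel estimate
        for e in incident:
            toward_end = e.b == node.id
            pts = e.polyline if toward_end else e.polyline[::-1]
            d = np.linalg.norm(pts - node.pos, axis=1)
            keep = d > zones[e.id]
            if not keep.any():
                trimmed = pts[:1]
            else:
                last = np.max(np.nonzero(keep))
                trimmed = pts[: last + 1]
            pts = np.vstack([trimmed, new_pos])
            e.polyline = pts if toward_end else pts[::-1]
        node.pos = new_pos


def set_export(graph: CollectingSystemGraph, approx_position) -> CollectingSystemGraph:
    """Designate the degree-1 node nearest ``approx_position`` as the export.

    Returns a modified copy.  Any previously designated export is demoted to
    a calyx tip.  Ties in distance are broken by the lowest node id.
    """
    if not graph.nodes:
        raise GraphInvariantError("cannot set export on an empty graph")
    p = np.asarray(approx_position, dtype=float)
    out = graph.copy()
    leaves = [n for n in out.nodes.values() if out.degree(n.id) <= 1]
    if not leaves:
        leaves = list(out.nodes.values())
    best = min(leaves, key=lambda n: (float(np.linalg.norm(n.pos - p)), n.id))
    for n in out.nodes.values():
        if n.kind == "export":
            n.kind = "calyx_tip"
    best.kind = "export"
    return out


def label_calyx_groups(graph: CollectingSystemGraph) -> dict[int, str]:
    """Partition calyx tips into upper/middle/lower by craniocaudal tertiles.

    The tips are sorted by descending Y (cranial first) and split into three
    groups of (near-)equal size; ties in Y are broken by node id.  This is a
    geometric proxy for the radiological upper/middle/lower assignment.
    """
    tips = sorted(graph.calyx_tips(), key=lambda n: (-graph.nodes[n].pos[1], n))
    if not tips:
        return {}
    parts = np.array_split(np.array(tips, dtype=int), 3)
    labels = {}
    for name, part in zip(("upper", "middle", "lower"), parts):
        for n in part:
            labels[int(n)] = name
    return labels


def snap_stone(graph: CollectingSystemGraph, position, diameter: float) -> Stone:
    """Bind a stone to the nearest centerline polyline vertex.

    If the nearest vertex is interior to an edge, the edge is split in place:
    a new junction node is inserted at that vertex and the edge is replaced by
    two sub-edges sharing its lumen diameter (total arc length is conserved
    exactly, since the split lies on an existing vertex).  The input graph is
    modified in place; the bound :class:`Stone` is returned.
    """
    p = np.asarray(position, dtype=float)
    best: tuple[float, int, int] | None = None  # (dist, edge_id, vertex_idx)
    for e in sorted(graph.edges.values(), key=lambda e: e.id):
        d = np.linalg.norm(e.polyline - p, axis=1)
        i = int(np.argmin(d))
        if best is None or d[i] < best[0] - 1e-12:
            best = (float(d[i]), e.id, i)
    if best is None:
        raise GraphInvariantError("graph has no edges to snap a stone onto")
    _, eid, vi = best
    edge = graph.edges[eid]
    if vi == 0:
        return Stone(diameter=diameter, node=edge.a)
    if vi == len(edge.polyline) - 1:
        return Stone(diameter=diameter, node=edge.b)

    new_node = max(graph.nodes) + 1
    graph.add_node(new_node, edge.polyline[vi].copy(), "junction")
    e1, e2 = max(graph.edges) + 1, max(graph.edges) + 2
    del graph.edges[eid]
    graph.add_edge(e1, edge.a, new_node, edge.polyline[: vi + 1], edge.min_lumen_diameter)
    graph.add_edge(e2, new_node, edge.b, edge.polyline[vi:], edge.min_lumen_diameter)
    return Stone(diameter=diameter, node=new_node)
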