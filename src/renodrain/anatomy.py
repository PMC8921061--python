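"""Synthetic pelvicalyceal anatomy: seeded tree generator, voxel phantom, mesh.

Real inputs to postural-drainage planning are segmented CT-urography volumes
of patient collecting systems.  This module generates anatomically structured
stand-ins so the whole pipeline is testable without patient data: a renal
pelvis near the origin, an export node (the ureteropelvic junction) caudal
and anterior to it, and three calyx groups — upper (cranial), middle
(lateral) and lower (caudal) — joined to the pelvis by infundibula whose
lengths and lumen diameters are drawn from configurable ranges.

Geometry conventions (see :mod:`renodrain.bedframe`): coordinates are bed-frame
millimetres, X-hat lateral (patient's right), Y-hat cranial, Z-hat up for the
prone patient (so +Z is the patient's posterior).  Lower-pole infundibula
descend caudally below the pelvis, so with the bed neutral a lower-calyx
stone sits in a gravity trap — the clinically difficult configuration that
motivates individualized inversion angles.

Default infundibulum diameters (2–8 mm) deliberately straddle the 4 mm stone
used throughout, so generated kidneys contain both passable and impassable
branches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .graph import CollectingSystemGraph

__all__ = ["AnatomyParams", "generate_tree", "voxelize", "export_mesh", "VoxelizationError"]


class VoxelizationError(ValueError):
    """Voxel spacing incompatible with the graph's lumen geometry."""


@dataclass(frozen=True)
class AnatomyParams:
    """Parameters of the synthetic pelvicalyceal tree generator.

    calyces_per_group : number of calyces in the (upper, middle, lower) groups
    infundibulum_length_range : mm, uniform sampling range of calyx neck lengths
    infundibulum_diameter_range : mm, uniform sampling range of neck lumen diameters
    pelvis_radius : mm, lumen radius of the pelvis trunk tubes
    craniocaudal_span : mm, approximate cranial-to-caudal extent of the tree
    lower_pole_angle_range : degrees below horizontal that lower infundibula descend
    seed : RNG seed; the generator is fully deterministic given the seed
    """

    calyces_per_group: tuple[int, int, int] = (2, 2, 2)
    infundibulum_length_range: tuple[float, float] = (10.0, 25.0)
    infundibulum_diameter_range: tuple[float, float] = (2.0, 8.0)
    pelvis_radius: float = 3.0
    craniocaudal_span: float = 90.0
    lower_pole_angle_range: tuple[float, float] = (20.0, 45.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("infundibulum_length_range", "infundibulum_diameter_range",
                     "lower_pole_angle_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be positive and ordered, got ({lo}, {hi})")
        if any(k < 1 for k in self.calyces_per_group):
            raise ValueError("calyces_per_group entries must each be >= 1")
        if not self.pelvis_radius > 0:
            raise ValueError("pelvis_radius must be > 0")
        if not self.craniocaudal_span > 0:
            raise ValueError("craniocaudal_span must be > 0")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _bent_polyline(a: np.ndarray, b: np.ndarray, bow: np.ndarray, n: int = 5) -> np.ndarray:
    """Quadratic-Bezier-like polyline from a to b bowed by the offset vector."""
    t = np.linspace(0.0, 1.0, n)[:, None]
    mid = 0.5 * (a + b) + bow
    pts = (1 - t) ** 2 * a + 2 * t * (1 - t) * mid + t**2 * b
    pts[0], pts[-1] = a, b
    return pts


# Trunk junction layout, in units of (craniocaudal_span / 90) mm.
_TRUNK_OFFSETS = {
    "upper": np.array([6.0, 30.0, 7.0]),
    "middle": np.array([25.0, 2.0, 5.0]),
    "lower": np.array([7.0, -27.0, -9.0]),
}
_EXPORT_OFFSET = np.array([-10.0, -28.0, -14.0])


def generate_tree(params: AnatomyParams) -> CollectingSystemGraph:
    """Generate a seeded synthetic collecting-system centerline tree.

    The result satisfies all :class:`CollectingSystemGraph` invariants, has
    exactly one export node, and its lower-pole calyx tips lie below the
    pelvis (negative Z relative to it), so they are gravity-trapped at the
    neutral bed orientation.  A ``metadata`` attribute on the returned graph
    records the ground-truth calyx-group assignment of every tip (not part of
    the serialised schema; used by round-trip tests).
    """
    rng = np.random.default_rng(params.seed)
    scale = params.craniocaudal_span / 90.0
    g = CollectingSystemGraph()

    pelvis = g.add_node(0, (0.0, 0.0, 0.0), "pelvis")
    export = g.add_node(1, _EXPORT_OFFSET * scale, "export")
    next_node = 2
    next_edge = 0

    # pelvis -> export (UPJ) trunk, wide lumen, bowed anteriorly
    bow = np.array([1.0, 0.0, -2.0]) * scale
    g.add_edge(next_edge, 0, 1, _bent_polyline(pelvis.pos, export.pos, bow),
               min_lumen_diameter=2.0 * params.pelvis_radius)
    next_edge += 1

    lo_len, hi_len = params.infundibulum_length_range
    lo_d, hi_d = params.infundibulum_diameter_range
    lo_ang, hi_ang = params.lower_pole_angle_range
    groups = ("upper", "middle", "lower")
    truth: dict[int, str] = {}

    for gi, (group, k) in enumerate(zip(groups, params.calyces_per_group)):
        jitter = rng.uniform(-2.0, 2.0, size=3) * scale
        jpos = _TRUNK_OFFSETS[group] * scale + jitter
        junction = g.add_node(next_node, jpos, "junction")
        next_node += 1
        bow = rng.uniform(-1.5, 1.5, size=3) * scale
        g.add_edge(next_edge, 0, junction.id, _bent_polyline(pelvis.pos, jpos, bow),
                   min_lumen_diameter=2.0 * params.pelvis_radius)
        next_edge += 1

        for ci in range(k):
            # draws are consumed in a fixed order so that the same seed yields
            # the same underlying uniforms regardless of the range values
            u_len = rng.uniform()
            u_dia = rng.uniform()
            u_ang = rng.uniform()
            az_jit = rng.uniform(-8.0, 8.0)
            bow_jit = rng.uniform(-1.0, 1.0, size=3)

            length = lo_len + u_len * (hi_len - lo_len)
            diameter = lo_d + u_dia * (hi_d - lo_d)
            # fan the calyces of a group apart in azimuth
            fan = (ci - (k - 1) / 2.0) * (70.0 / max(k - 1, 1) if k > 1 else 0.0)
            az = math.radians(fan + az_jit)

            if group == "upper":
                direction = _unit(np.array([0.75 * math.sin(az) + 0.12,
                                            0.85,
                                            0.45 * math.cos(az)]))
            elif group == "middle":
                direction = _unit(np.array([0.90,
                                            0.80 * math.sin(az),
                                            0.70 * math.cos(az)]))
            else:  # lower: descend caudally below horizontal by the pole angle
                pole = math.radians(lo_ang + u_ang * (hi_ang - lo_ang))
                horiz = _unit(np.array([0.9 * math.sin(az), -math.cos(az), 0.0]))
                direction = horiz * math.cos(pole) + np.array([0.0, 0.0, -math.sin(pole)])

            tip_pos = jpos + direction * length
            tip = g.add_node(next_node, tip_pos, "calyx_tip")
            truth[tip.id] = group
            next_node += 1
            perp = np.cross(direction, [0.0, 0.0, 1.0])
            if np.linalg.norm(perp) < 1e-6:
                perp = np.array([1.0, 0.0, 0.0])
            bow = _unit(perp) * 0.08 * length + bow_jit * 0.5
            g.add_edge(next_edge, junction.id, tip.id,
                       _bent_polyline(jpos, tip_pos, bow),
                       min_lumen_diameter=diameter)
            next_edge += 1

    g.validate()
    g.metadata = {"calyx_groups": truth, "params": params}  # type: ignore[attr-defined]
    return g


# ---------------------------------------------------------------------------
# voxelization

def _segment_distance_field(centers_shape, origin, spacing, p0, p1):
    """Distances from voxel centers in a local box to the segment p0-p1."""
    i0, j0, k0 = origin
    ni, nj, nk = centers_shape
    xs = (np.arange(i0, i0 + ni) * spacing[0])[:, None, None]
    ys = (np.arange(j0, j0 + nj) * spacing[1])[None, :, None]
    zs = (np.arange(k0, k0 + nk) * spacing[2])[None, None, :]
    d = p1 - p0
    L2 = float(np.dot(d, d))
    px = xs - p0[0]
    py = ys - p0[1]
    pz = zs - p0[2]
    if L2 < 1e-12:
        return np.sqrt(px**2 + py**2 + pz**2)
    t = (px * d[0] + py * d[1] + pz * d[2]) / L2
    t = np.clip(t, 0.0, 1.0)
    return np.sqrt((px - t * d[0]) ** 2 + (py - t * d[1]) ** 2 + (pz - t * d[2]) ** 2)


def _bridge_6_connected(mask: np.ndarray, a: np.ndarray, b: np.ndarray) -> None:
    """Mark a 6-connected voxel staircase between voxel indices a and b."""
    cur = a.copy()
    mask[tuple(cur)] = True
    while not np.array_equal(cur, b):
        axis = int(np.argmax(np.abs(b - cur)))
        cur[axis] += int(np.sign(b[axis] - cur[axis]))
        mask[tuple(cur)] = True


def voxelize(
    graph: CollectingSystemGraph, spacing: float | tuple[float, float, float] = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterise the centerline tree into a binary tube phantom.

    Voxels whose centers fall within the local lumen radius (edge
    ``min_lumen_diameter / 2``) of any centerline polyline become foreground.
    The centerline itself is additionally burned in as a 6-connected voxel
    path, so foreground is 6-connected along every edge.

    Returns ``(volume, affine)``: a uint8 array indexed (x, y, z) and the 4x4
    affine mapping 0-based voxel indices to bed-frame mm.

    Raises :class:`VoxelizationError` if any spacing component exceeds the
    smallest lumen radius in the graph (the rasterised lumen could become
    disconnected).
    """
    sp = np.asarray([spacing] * 3 if np.isscalar(spacing) else spacing, dtype=float)
    if np.any(sp <= 0):
        raise VoxelizationError("spacing must be positive")
    min_radius = graph.min_lumen() / 2.0
    if np.any(sp > min_radius):
        raise VoxelizationError(
            f"spacing {tuple(sp)} exceeds the smallest lumen radius "
            f"({min_radius:.2f} mm); the rasterised lumen would disconnect"
        )

    max_radius = max(e.min_lumen_diameter for e in graph.edges.values()) / 2.0
    lo, hi = graph.bounds()
    pad = max_radius + 2.0 * sp
    origin_mm = lo - pad
    shape = np.ceil((hi + pad - origin_mm) / sp).astype(int) + 1
    vol = np.zeros(tuple(shape), dtype=bool)

    for edge in sorted(graph.edges.values(), key=lambda e: e.id):
        r = edge.min_lumen_diameter / 2.0
        poly = edge.polyline - origin_mm
        for p0, p1 in zip(poly[:-1], poly[1:]):
            box_lo = np.maximum(np.floor((np.minimum(p0, p1) - r) / sp).astype(int), 0)
            box_hi = np.minimum(np.ceil((np.maximum(p0, p1) + r) / sp).astype(int) + 1, shape)
            if np.any(box_hi <= box_lo):
                continue
            dist = _segment_distance_field(tuple(box_hi - box_lo), box_lo, sp, p0, p1)
            sub = vol[box_lo[0]:box_hi[0], box_lo[1]:box_hi[1], box_lo[2]:box_hi[2]]
            sub |= dist <= r
        # burn in the centerline as a 6-connected path
        step = float(np.min(sp)) / 2.0
        for p0, p1 in zip(poly[:-1], poly[1:]):
            seg_len = float(np.linalg.norm(p1 - p0))
            n = max(int(math.ceil(seg_len / step)), 1)
            samples = p0 + np.linspace(0.0, 1.0, n + 1)[:, None] * (p1 - p0)
            idx = np.clip(np.round(samples / sp).astype(int), 0, shape - 1)
            for a, b in zip(idx[:-1], idx[1:]):
                _bridge_6_connected(vol, a, b)

    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = sp
    affine[:3, 3] = origin_mm
    return vol.astype(np.uint8), affine


def export_mesh(graph: CollectingSystemGraph, spacing: float | None = None):
    """Watertight triangle surface of the lumen (tube sweep), in mm.

    The surface is extracted by marching cubes from a fine voxelization of the
    tube union, then mapped through the affine, yielding a closed mesh
    suitable for STL/OBJ phantom export.
    """
    import trimesh
    from skimage.measure import marching_cubes

    if spacing is None:
        spacing = min(0.8, graph.min_lumen() / 3.0)
    vol, affine = voxelize(graph, spacing)
    padded = np.pad(vol, 1)
    verts, faces, _, _ = marching_cubes(padded.astype(np.float32), level=0.5)
    verts = (verts - 1.0) * np.diag(affine)[:3] + affine[:3, 3]
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    if not mesh.is_watertight:
        mesh.fill_holes()
    if mesh.volume < 0:  # marching-cubes axis order can flip the winding
        mesh.invert()
    return mesh
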