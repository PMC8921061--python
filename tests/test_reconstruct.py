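"""Mask -> centerline graph reconstruction and graph editing operations."""

import numpy as np
import pytest

from conftest import degree_multiset, match_edges
from renodrain.anatomy import AnatomyParams, generate_tree, voxelize
from renodrain.graph import CollectingSystemGraph
from renodrain.reconstruct import (
    ReconstructionError,
    extract_centerline,
    label_calyx_groups,
    set_export,
    snap_stone,
)


class TestExtractCenterline:
    def test_single_straight_tube(self, straight_tube_graph):
        vol, affine = voxelize(straight_tube_graph, 0.5)
        g = extract_centerline(vol, affine)
        assert len(g.edges) == 1
        assert len(g.nodes) == 2
        e = next(iter(g.edges.values()))
        # recovered lumen within two voxel spacings of the true 4 mm
        assert e.min_lumen_diameter == pytest.approx(4.0, abs=1.0)
        assert e.length == pytest.approx(30.0, rel=0.1)

    def test_empty_volume_rejected(self):
        with pytest.raises(ReconstructionError, match="empty"):
            extract_centerline(np.zeros((10, 10, 10), dtype=np.uint8), np.eye(4))

    def test_disjoint_components_rejected_with_sizes(self):
        vol = np.zeros((30, 10, 10), dtype=np.uint8)
        vol[2:8, 3:7, 3:7] = 1
        vol[20:28, 3:7, 3:7] = 1
        with pytest.raises(ReconstructionError, match="2 foreground components"):
            extract_centerline(vol, np.eye(4))

    def test_anisotropic_volume_resampled(self, straight_tube_graph):
        vol, affine = voxelize(straight_tube_graph, (0.5, 0.5, 1.0))
        g = extract_centerline(vol, affine)
        assert len(g.edges) == 1
        assert next(iter(g.edges.values())).length == pytest.approx(30.0, rel=0.1)

    @pytest.mark.parametrize("seed", [1, 6, 11, 17])
    def test_round_trip_topology_and_lengths(self, seed):
        tree = generate_tree(AnatomyParams(seed=seed))
        vol, affine = voxelize(tree, 0.5)
        recon = extract_centerline(vol, affine)
        assert degree_multiset(recon) == degree_multiset(tree)
        assert len(recon.edges) == len(tree.edges)
        errors = [
            abs(f.length - e.length) / e.length for e, f, _ in match_edges(tree, recon)
        ]
        assert float(np.mean(errors)) <= 0.10

    def test_skeleton_is_inside_the_foreground(self, tree_factory):
        tree = tree_factory(seed=3)
        vol, affine = voxelize(tree, 0.5)
        recon = extract_centerline(vol, affine)
        inv = np.linalg.inv(affine)
        for e in recon.edges.values():
            # interior vertices (endpoints may be refitted branch estimates)
            for p in e.polyline[2:-2]:
                ijk = np.round(inv[:3, :3] @ p + inv[:3, 3]).astype(int)
                assert vol[tuple(ijk)]


class TestSetExport:
    def test_exact_endpoint_and_midway_coordinates(self, tree_factory):
        tree = tree_factory(seed=1)
        tip = tree.calyx_tips()[0]
        g = set_export(tree, tree.nodes[tip].pos)
        assert g.nodes[tip].kind == "export"
        assert g.export_node == tip
        # previous export demoted: still exactly one export node
        assert sum(n.kind == "export" for n in g.nodes.values()) == 1

    def test_tie_broken_by_lowest_node_id(self):
        g = CollectingSystemGraph()
        g.add_node(0, (0, 0, 0), "junction")
        g.add_node(1, (-10, 0, 0), "calyx_tip")
        g.add_node(2, (10, 0, 0), "calyx_tip")
        g.add_edge(0, 0, 1)
        g.add_edge(1, 0, 2)
        out = set_export(g, (0.0, 5.0, 0.0))  # equidistant from nodes 1 and 2
        assert out.export_node == 1


class TestLabelCalyxGroups:
    def test_three_tips_by_craniocaudal_position(self):
        g = CollectingSystemGraph()
        g.add_node(0, (0, 0, 0), "pelvis")
        for nid, y in ((1, 40.0), (2, 0.0), (3, -40.0)):
            g.add_node(nid, (10.0, y, 0.0), "calyx_tip")
            g.add_edge(nid - 1, 0, nid)
        labels = label_calyx_groups(g)
        assert labels == {1: "upper", 2: "middle", 3: "lower"}

    def test_six_tips_split_two_per_group(self, tree_factory):
        g = tree_factory(seed=1)
        labels = label_calyx_groups(g)
        from collections import Counter

        assert Counter(labels.values()) == {"upper": 2, "middle": 2, "lower": 2}

    @pytest.mark.parametrize("seed", range(1, 21))
    def test_agreement_with_generator_ground_truth(self, seed):
        g = generate_tree(AnatomyParams(seed=seed))
        truth = g.metadata["calyx_groups"]
        labels = label_calyx_groups(g)
        agree = sum(labels[n] == truth[n] for n in truth)
        assert agree / len(truth) >= 0.9


class TestSnapStone:
    def test_position_on_a_tip_binds_that_node(self, tree_factory):
        g = tree_factory(seed=1)
        tip = g.calyx_tips()[0]
        stone = snap_stone(g, g.nodes[tip].pos, 4.0)
        assert stone.node == tip
        assert stone.diameter == 4.0

    def test_midway_position_splits_edge_and_conserves_length(self, tree_factory):
        g = tree_factory(seed=1)
        total_before = g.total_length()
        n_edges = len(g.edges)
        e = g.edges[0]
        mid_vertex = e.polyline[len(e.polyline) // 2]
        stone = snap_stone(g, mid_vertex + 0.3, 4.0)
        assert len(g.edges) == n_edges + 1
        assert g.total_length() == pytest.approx(total_before, abs=1e-6)
        assert np.allclose(g.nodes[stone.node].pos, mid_vertex)
        g.validate()

    def test_snapped_vertex_is_brute_force_nearest(self, tree_factory):
        g = tree_factory(seed=4)
        rng = np.random.default_rng(11)
        all_vertices = np.vstack([e.polyline for e in g.edges.values()])
        for _ in range(10):
            probe = all_vertices[rng.integers(len(all_vertices))] + rng.normal(
                scale=0.5, size=3
            )
            fresh = g.copy()
            stone = snap_stone(fresh, probe, 4.0)
            d_true = np.min(np.linalg.norm(all_vertices - probe, axis=1))
            d_got = np.linalg.norm(fresh.nodes[stone.node].pos - probe)
            assert d_got == pytest.approx(d_true, abs=0.5)  # within a voxel spacing
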