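import numpy as np
import pytest

from renodrain.anatomy import AnatomyParams, generate_tree
from renodrain.graph import CollectingSystemGraph


@pytest.fixture
def tree_factory():
    """Seeded synthetic pelvicalyceal trees (defaults: 2/2/2 calyces)."""

    def make(seed: int = 1, **kwargs) -> CollectingSystemGraph:
        return generate_tree(AnatomyParams(seed=seed, **kwargs))

    return make


@pytest.fixture
def straight_tube_graph():
    """A single vertical 30 mm tube, pelvis on top, export at the bottom."""
    g = CollectingSystemGraph()
    g.add_node(0, (0.0, 0.0, 0.0), "pelvis")
    g.add_node(1, (0.0, 0.0, -30.0), "export")
    g.add_edge(0, 0, 1, min_lumen_diameter=4.0)
    return g


def degree_multiset(graph: CollectingSystemGraph) -> list[int]:
    return sorted(graph.degree(n) for n in graph.nodes)


def match_edges(true_graph: CollectingSystemGraph, recon: CollectingSystemGraph):
    """Pair each generating-tree edge with the nearest recovered edge by
    summed endpoint distance; yields (true_edge, recovered_edge, endpoint_d)."""
    for e in true_graph.edges.values():
        pa, pb = true_graph.nodes[e.a].pos, true_graph.nodes[e.b].pos
        best = None
        for f in recon.edges.values():
            qa, qb = recon.nodes[f.a].pos, recon.nodes[f.b].pos
            d = min(
                np.linalg.norm(pa - qa) + np.linalg.norm(pb - qb),
                np.linalg.norm(pa - qb) + np.linalg.norm(pb - qa),
            )
            if best is None or d < best[1]:
                best = (f, d)
        yield e, best[0], best[1]
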