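"""Tree rooting, orientation, pruning and flow-based cycle resolution."""

import math

import networkx as nx
import numpy as np
import pytest

from hepatree.phantom import (TreeSpec, corrupt_mask, random_tree_spec,
                              rasterize_tree)
from hepatree.skeletonize import thin
from hepatree.topo_graph import build_graph
from hepatree.vessel_tree import (compute_angles, orient, remove_irrelevant,
                                  remove_redundant, select_root,
                                  tree_to_json_dict, tree_to_newick)
from oracles import best_flow_subset


def hand_graph(radii_ends):
    """Path graph with two end vertices with given (radius, mean_radius)."""
    g = nx.MultiGraph(spacing=(1.0, 1.0, 1.0))
    (ra, mra), (rb, mrb) = radii_ends
    a, m, b = (0, 0, 0), (0, 0, 10), (0, 0, 20)
    g.add_node(a, kind="end", radius=ra, position_mm=(0., 0., 0.))
    g.add_node(m, kind="branch", radius=2.0, position_mm=(0., 0., 10.))
    g.add_node(b, kind="end", radius=rb, position_mm=(0., 0., 20.))
    g.add_edge(a, m, mean_radius=mra, path=[a, m], length=10.0,
               distance=10.0, edge_id=0)
    g.add_edge(m, b, mean_radius=mrb, path=[m, b], length=10.0,
               distance=10.0, edge_id=1)
    return g, a, b


class TestSelectRoot:
    def test_argmax_of_radius_plus_mean_radius(self):
        g, a, b = hand_graph([(3.0, 2.5), (1.0, 1.2)])  # 5.5 vs 2.2
        assert select_root(g) == a

    def test_single_end_voxel(self):
        g, a, b = hand_graph([(1.0, 1.0), (1.0, 1.0)])
        g.remove_node(b)
        g.nodes[a]["kind"] = "end"
        assert select_root(g) == a

    def test_tie_breaks_to_lowest_coordinate(self):
        g, a, b = hand_graph([(2.0, 2.0), (2.0, 2.0)])
        assert select_root(g) == min(a, b)

    def test_pure_loop_raises(self):
        g = nx.MultiGraph(spacing=(1, 1, 1))
        v = (0, 0, 0)
        g.add_node(v, kind="branch", radius=1.0, position_mm=(0., 0., 0.))
        g.add_edge(v, v, mean_radius=1.0, path=[v, v], length=2.0,
                   distance=0.0, edge_id=0)
        with pytest.raises(ValueError, match="root"):
            select_root(g)


class TestOrient:
    def test_path_graph_edges_point_away_from_root(self):
        g, a, b = hand_graph([(3.0, 2.5), (1.0, 1.2)])
        t = orient(g, a)
        assert all(u != b for u, w in t.edges())
        assert t.graph["root"] == a
        assert not any(d["cyclic"] for _, _, d in t.edges(data=True))

    def test_bridged_phantom_flags_cycle_rank_edges(self, y_volume):
        c = corrupt_mask(y_volume, 0.0, 1, seed=5)
        g = build_graph(thin(c), c, (1, 1, 1))
        rank = (g.number_of_edges() - g.number_of_nodes()
                + nx.number_connected_components(g))
        t = orient(g, select_root(g))
        flagged = sum(1 for _, _, d in t.edges(data=True) if d["cyclic"])
        assert flagged == rank >= 1

    def test_deterministic(self, y_volume, y_skeleton):
        g = build_graph(y_skeleton, y_volume, (1, 1, 1))
        r = select_root(g)
        e1 = sorted(orient(g, r).edges(keys=True))
        e2 = sorted(orient(g, r).edges(keys=True))
        assert e1 == e2

    def test_disconnected_raises(self):
        g, a, b = hand_graph([(1.0, 1.0), (1.0, 1.0)])
        lone = (9, 9, 9)
        g.add_node(lone, kind="end", radius=1.0, position_mm=(9., 9., 9.))
        with pytest.raises(ValueError, match="disconnected"):
            orient(g, a)


class TestRemoveRedundant:
    def test_identity_without_redundancy(self, y_volume, y_skeleton):
        g = build_graph(y_skeleton, y_volume, (1, 1, 1))
        t = orient(g, select_root(g))
        t2 = remove_redundant(t)
        assert sorted(t.edges()) == sorted(t2.edges())

    def test_self_loop_removed(self):
        g, a, b = hand_graph([(3.0, 2.5), (1.0, 1.2)])
        m = (0, 0, 10)
        g.add_edge(m, m, mean_radius=0.5, path=[m, m], length=2.0,
                   distance=0.0, edge_id=2)
        t = remove_redundant(orient(g, a))
        assert all(u != w for u, w in t.edges())

    def test_one_voxel_spur_removed(self):
        # spur voxel adjacent to the mid (branch) vertex
        g, a, b = hand_graph([(3.0, 2.5), (1.0, 1.2)])
        m, s = (0, 0, 10), (1, 1, 10)
        g.add_node(s, kind="end", radius=0.5, position_mm=(1., 1., 10.))
        g.add_edge(m, s, mean_radius=0.3, path=[m, s],
                   length=math.sqrt(2), distance=math.sqrt(2), edge_id=3)
        t = remove_redundant(orient(g, a))
        assert s not in t
        assert t.number_of_edges() == 2

    def test_long_limb_kept(self):
        g, a, b = hand_graph([(3.0, 2.5), (1.0, 1.2)])
        m = (0, 0, 10)
        tip = (0, 9, 10)
        g.add_node(tip, kind="end", radius=1.0, position_mm=(0., 9., 10.))
        path = [(0, i, 10) for i in range(10)]
        g.add_edge(m, tip, mean_radius=1.0, path=path, length=9.0,
                   distance=9.0, edge_id=4)
        t = remove_redundant(orient(g, a))
        assert tip in t


class TestRemoveIrrelevant:
    def make_junction(self, r_in, noncyclic, cyclic):
        """Star: root -> v, then non-cyclic and cyclic outflows."""
        g = nx.MultiDiGraph(spacing=(1.0, 1.0, 1.0))
        root, v = (0, 0, 0), (0, 0, 5)
        g.graph["root"] = root
        order = [root, v]
        for n in (root, v):
            g.add_node(n, kind="end", radius=1.0,
                       position_mm=tuple(map(float, n)))
        g.add_edge(root, v, mean_radius=r_in, cyclic=False,
                   path=[root, v], length=5.0, distance=5.0, edge_id=0)
        eid = 1
        for i, r in enumerate(noncyclic):
            w = (0, 2 + i, 10)
            g.add_node(w, kind="end", radius=1.0,
                       position_mm=tuple(map(float, w)))
            g.add_edge(v, w, mean_radius=r, cyclic=False, path=[v, w],
                       length=5.0, distance=5.0, edge_id=eid)
            order.append(w)
            eid += 1
        cyc_edges = []
        for i, r in enumerate(cyclic):
            w = (5, i, 10)
            g.add_node(w, kind="end", radius=1.0,
                       position_mm=tuple(map(float, w)))
            g.add_edge(v, w, mean_radius=r, cyclic=True, path=[v, w],
                       length=5.0, distance=5.0, edge_id=eid)
            cyc_edges.append((v, w))
            order.append(w)
            eid += 1
        g.graph["bfs_order"] = order
        return g, cyc_edges

    def test_worked_example(self):
        # inflow 5, non-cyclic 3, cyclic {4, 2, 1.5}: target 16, keep {4}
        g, cyc = self.make_junction(5.0, [3.0], [4.0, 2.0, 1.5])
        t = remove_irrelevant(g)
        kept = sorted(d["mean_radius"] for _, _, d in t.edges(data=True))
        assert kept == [3.0, 4.0, 5.0]

    def test_no_cyclic_candidates_identity(self):
        g, _ = self.make_junction(5.0, [3.0, 4.0], [])
        t = remove_irrelevant(g)
        assert t.number_of_edges() == 3

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_exhaustive_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        m = int(rng.integers(1, 9))
        r_in = float(rng.uniform(2.0, 6.0))
        noncyclic = [float(r) for r in rng.uniform(0.5, 3.0,
                                                   rng.integers(0, 3))]
        cyclic = [float(r) for r in rng.uniform(0.5, 3.0, m)]
        g, cyc_edges = self.make_junction(r_in, noncyclic, cyclic)
        t = remove_irrelevant(g)
        keep = best_flow_subset(r_in, noncyclic, cyclic)
        kept_targets = {cyc_edges[i][1] for i in keep}
        surviving = {w for _, w, d in t.edges(data=True)
                     if w[0] == 5}  # cyclic targets live at z = 5
        assert surviving == kept_targets

    def test_bridged_phantoms_become_trees(self):
        for seed in (1, 4):
            spec = random_tree_spec(seed)
            vol, _ = rasterize_tree(spec)
            c = corrupt_mask(vol, 0.0, 2, seed=seed + 50)
            g = build_graph(thin(c), c, spec.spacing)
            t = remove_irrelevant(remove_redundant(
                orient(g, select_root(g))))
            assert nx.is_directed_acyclic_graph(t)
            assert t.number_of_edges() == t.number_of_nodes() - 1
            assert all(t.in_degree(v) == 1 for v in t
                       if v != t.graph["root"])


class TestAngles:
    def test_collinear_zero_perpendicular_ninety(self):
        g = nx.MultiDiGraph(spacing=(1.0, 1.0, 1.0))
        a, b, c, d = (0, 0, 0), (0, 0, 5), (0, 0, 10), (0, 5, 5)
        for n in (a, b, c, d):
            g.add_node(n, kind="end", radius=1.0,
                       position_mm=tuple(map(float, n)))
        g.graph["root"] = a
        g.add_edge(a, b, mean_radius=1.0, cyclic=False, path=[a, b],
                   length=5.0, distance=5.0, edge_id=0)
        g.add_edge(b, c, mean_radius=1.0, cyclic=False, path=[b, c],
                   length=5.0, distance=5.0, edge_id=1)
        g.add_edge(b, d, mean_radius=1.0, cyclic=False, path=[b, d],
                   length=5.0, distance=5.0, edge_id=2)
        t = compute_angles(g)
        angles = {w: d_["angle"] for _, w, d_ in t.edges(data=True)}
        assert angles[b] is None                      # root edge
        assert angles[c] == pytest.approx(0.0)        # collinear
        assert angles[d] == pytest.approx(90.0)       # perpendicular

    def test_y_phantom_limb_angles(self, y_spec, y_volume, y_skeleton):
        g = build_graph(y_skeleton, y_volume, y_spec.spacing)
        t = compute_angles(remove_irrelevant(remove_redundant(
            orient(g, select_root(g)))))
        limb_angles = [d["angle"] for _, _, d in t.edges(data=True)
                       if d["angle"] is not None]
        assert len(limb_angles) == 2
        for ang in limb_angles:
            assert abs(ang - 45.0) <= 5.0


class TestExport:
    def test_json_and_newick(self, y_volume, y_skeleton):
        g = build_graph(y_skeleton, y_volume, (1, 1, 1))
        t = remove_irrelevant(remove_redundant(orient(g, select_root(g))))
        doc = tree_to_json_dict(t)
        assert len(doc["vertices"]) == t.number_of_nodes()
        roots = [v for v in doc["vertices"] if v["parent"] is None]
        assert len(roots) == 1
        nwk = tree_to_newick(t)
        assert nwk.endswith(";") and nwk.count("(") == nwk.count(")")
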