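"""Rooted, directed, acyclic portal-vein tree from the undirected graph.

The root is the end-vertex with the largest ``Radius(v) + MeanRadius(edge)``
— the main portal trunk enters the liver as the thickest terminal.  The
graph is oriented by breadth-first search from the root; edges that close a
cycle are flagged cyclic.  Redundant branches (self-loops and spurs whose
voxels all belong to a single junction's neighborhood) are dropped, and
irrelevant cyclic branches are removed by inflow/outflow matching: at each
ramification the blood inflow should equal the outflow, flow being
approximated by the squared branch radius (cross-sectional area), so among
the cyclic outflow candidates the subset whose area best balances the
ramification is kept and the rest deleted.
"""

from __future__ import annotations

import itertools
import math
import warnings
from collections import deque

import networkx as nx
import numpy as np

__all__ = [
    "select_root",
    "orient",
    "remove_redundant",
    "remove_irrelevant",
    "compute_angles",
    "tree_to_json_dict",
    "tree_to_newick",
]

#: above this many cyclic candidates at one ramification, subset
#: enumeration falls back to greedy largest-first matching
SUBSET_ENUMERATION_CAP = 16


def select_root(g: nx.MultiGraph):
    """End-vertex maximizing ``Radius(v) + MeanRadius(incident edge)``.

    Ties go to the lexicographically smallest voxel coordinate.  Raises if
    the graph has no end-vertex (a pure loop): prune cycles first or pick a
    root manually.
    """
    best = None
    best_score = -math.inf
    for v, data in sorted(g.nodes(data=True)):
        if data.get("kind") != "end" or g.degree(v) == 0:
            continue
        mean_r = max(d["mean_radius"] for _, _, d in g.edges(v, data=True))
        score = data["radius"] + mean_r
        if score > best_score:
            best, best_score = v, score
    if best is None:
        raise ValueError(
            "graph has no end-vertex to root at; remove cyclic branches "
            "first or supply a root explicitly")
    return best


def orient(g: nx.MultiGraph, root) -> nx.MultiDiGraph:
    """Direct every edge away from ``root`` along BFS layers.

    Non-tree edges (closing a cycle) are kept but flagged ``cyclic=True``.
    Deterministic: vertices and parallel edges are visited in sorted order.
    Raises on a disconnected graph.
    """
    if root not in g:
        raise ValueError(f"root {root} not in graph")
    if g.number_of_nodes() and not nx.is_connected(g):
        raise ValueError("graph is disconnected; select one component first")
    t = nx.MultiDiGraph(**g.graph)
    t.graph["root"] = root
    for v, data in g.nodes(data=True):
        t.add_node(v, **data)
    visited = {root}
    used = set()
    queue = deque([root])
    order = [root]
    while queue:
        u = queue.popleft()
        for _, w, k, data in sorted(g.edges(u, keys=True, data=True),
                                    key=lambda e: (e[1], e[2])):
            ek = frozenset(((u, w, k),)) if u == w else (min(u, w), max(u, w), k)
            if ek in used:
                continue
            used.add(ek)
            cyclic = w in visited or u == w
            t.add_edge(u, w, key=k, **{**data, "cyclic": cyclic})
            if not cyclic:
                visited.add(w)
                order.append(w)
                queue.append(w)
    t.graph["bfs_order"] = order
    return t


def remove_redundant(t: nx.MultiDiGraph) -> nx.MultiDiGraph:
    """Drop self-loop edges and single-junction spur branches.

    A leaf edge is a spur when every path voxel other than the leaf tip
    has the junction vertex as its nearest topological vertex (vacuously
    true for a one-voxel spur) and the whole branch sits within the
    junction's local caliber (tip within ``2 * Radius(junction)`` plus one
    voxel diagonal) — i.e. the branch never leaves the vessel lumen at the
    junction.  Vertices left isolated are removed; the root is never
    treated as a spur tip.
    """
    t = t.copy()
    sp = np.asarray(t.graph.get("spacing", (1.0, 1.0, 1.0)), float)
    diag = float(np.linalg.norm(sp))
    root = t.graph.get("root")
    vertices = sorted(t.nodes)
    vpos = np.asarray(vertices, float) * sp

    def nearest_vertex(p):
        d = np.linalg.norm(vpos - np.asarray(p, float) * sp, axis=1)
        return vertices[int(np.argmin(d))]  # argmin -> lowest lex on ties

    to_remove = []
    for u, w, k, data in t.edges(keys=True, data=True):
        if u == w:
            to_remove.append((u, w, k))
            continue
        # spur: leaf edge fully inside its junction's territory
        if t.out_degree(w) == 0 and t.degree(w) == 1 and w != root:
            junction, tip, path = u, w, data["path"]
        elif t.degree(u) == 1 and t.out_degree(u) <= 1 and u != root:
            junction, tip, path = w, u, list(reversed(data["path"]))
        else:
            continue
        reach = 2.0 * float(t.nodes[junction].get("radius", 0.0)) + diag
        tip_dist = float(np.linalg.norm(
            (np.asarray(tip, float) - np.asarray(junction, float)) * sp))
        body = path[:-1]  # all voxels except the leaf tip
        if (tip_dist <= reach and body
                and all(nearest_vertex(p) == junction for p in body)):
            to_remove.append((u, w, k))
    t.remove_edges_from(to_remove)
    root = t.graph.get("root")
    t.remove_nodes_from([v for v in list(t.nodes)
                         if t.degree(v) == 0 and v != root])
    return t


def _best_subset(target: float, radii: list[float]) -> tuple[int, ...]:
    """Indices of the subset of ``radii`` whose summed squares best match
    ``target`` (minimum absolute difference; ties to smaller, earlier
    subsets)."""
    best = None
    best_key = None
    for size in range(len(radii) + 1):
        for comb in itertools.combinations(range(len(radii)), size):
            diff = abs(target - sum(radii[i] ** 2 for i in comb))
            key = (diff, size, comb)
            if best_key is None or key < best_key:
                best, best_key = comb, key
    return best


def _greedy_subset(target: float, radii: list[float]) -> tuple[int, ...]:
    order = sorted(range(len(radii)), key=lambda i: -radii[i])
    acc = 0.0
    chosen = []
    for i in order:
        if abs(target - (acc + radii[i] ** 2)) < abs(target - acc):
            acc += radii[i] ** 2
            chosen.append(i)
    return tuple(sorted(chosen))


def remove_irrelevant(t: nx.MultiDiGraph) -> nx.MultiDiGraph:
    """Resolve cyclic branches by inflow/outflow matching and return a tree.

    Ramifications are processed in BFS order from the root.  At a vertex
    with inflow edge of mean radius ``r_in``, non-cyclic outflow radii
    ``r_j`` and cyclic outflow candidates ``c_i``, the subset of candidates
    minimizing ``|r_in^2 - sum r_j^2 - sum c_i^2|`` is kept and the other
    cyclic candidates are deleted.  Any cycle that survives (subsets can
    interact across junctions) is broken at its smallest-mean-radius edge.
    The result is re-oriented from the root: a rooted directed tree with
    ``#edges = #vertices - 1``.
    """
    t = t.copy()
    root = t.graph["root"]
    bfs = [v for v in t.graph.get("bfs_order", sorted(t.nodes)) if v in t]
    for v in bfs:
        cyclic_out = [(v, w, k, d) for _, w, k, d in
                      t.out_edges(v, keys=True, data=True) if d["cyclic"]]
        if not cyclic_out:
            continue
        in_edges = [d for _, _, d in t.in_edges(v, data=True)
                    if not d["cyclic"]]
        if not in_edges:
            continue  # no inflow to balance (root-side ramification)
        r_in = in_edges[0]["mean_radius"]
        noncyclic_out = [d["mean_radius"] for _, _, d in
                         t.out_edges(v, data=True) if not d["cyclic"]]
        target = r_in ** 2 - sum(r ** 2 for r in noncyclic_out)
        radii = [d["mean_radius"] for _, _, _, d in cyclic_out]
        if len(radii) > SUBSET_ENUMERATION_CAP:
            warnings.warn(
                f"{len(radii)} cyclic candidates at {v}: falling back to "
                "greedy largest-first matching")
            keep = set(_greedy_subset(target, radii))
        else:
            keep = set(_best_subset(target, radii))
        for i, (u, w, k, _) in enumerate(cyclic_out):
            if i not in keep:
                t.remove_edge(u, w, key=k)

    # guard: break any surviving cycle at its weakest edge
    und = nx.MultiGraph()
    und.add_nodes_from(t.nodes)
    for u, w, k, d in t.edges(keys=True, data=True):
        und.add_edge(u, w, key=(u, w, k), mean_radius=d["mean_radius"])
    while True:
        try:
            cycle = nx.find_cycle(und)
        except nx.NetworkXNoCycle:
            break
        weakest = min(cycle, key=lambda e: (und.edges[e]["mean_radius"], e[2]))
        und.remove_edge(weakest[0], weakest[1], key=weakest[2])
        t.remove_edge(*weakest[2])

    t.remove_nodes_from([v for v in list(t.nodes)
                         if t.degree(v) == 0 and v != root])

    # re-orient from the root so that every edge points downstream
    und2 = nx.MultiGraph(**t.graph)
    for v, data in t.nodes(data=True):
        und2.add_node(v, **data)
    for u, w, k, d in t.edges(keys=True, data=True):
        und2.add_edge(u, w, key=k, **d)
    tree = orient(und2, root)
    for _, _, d in tree.edges(data=True):
        d["cyclic"] = False
    n_v, n_e = tree.number_of_nodes(), tree.number_of_edges()
    if n_e != n_v - 1:
        raise AssertionError(
            f"pruning left {n_e} edges for {n_v} vertices; not a tree")
    return tree


def compute_angles(t: nx.MultiDiGraph) -> nx.MultiDiGraph:
    """Angle (degrees, [0, 180]) between each edge's chord and its parent
    edge's chord at the shared vertex; missing for the root edges and for
    zero-length chords."""
    t = t.copy()
    sp = np.asarray(t.graph.get("spacing", (1.0, 1.0, 1.0)), float)

    def chord(u, w):
        return (np.asarray(w, float) - np.asarray(u, float)) * sp

    for u, w, k, data in t.edges(keys=True, data=True):
        parents = list(t.in_edges(u, data=True))
        if not parents:
            data["angle"] = None
            continue
        pu, pv, _ = parents[0]
        a, b = chord(pu, pv), chord(u, w)
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0 or nb == 0:
            data["angle"] = None
            continue
        cosang = float(np.clip(a @ b / (na * nb), -1.0, 1.0))
        data["angle"] = math.degrees(math.acos(cosang))
    return t


# ---------------------------------------------------------------------------
# export


def tree_to_json_dict(t: nx.MultiDiGraph) -> dict:
    """JSON-serializable tree with explicit parent pointers."""
    parent = {}
    for u, w in t.edges():
        parent[w] = u
    return {
        "root": list(t.graph["root"]),
        "spacing": list(t.graph.get("spacing", (1.0, 1.0, 1.0))),
        "vertices": [
            {"id": list(v), "kind": d.get("kind"),
             "radius": d.get("radius"),
             "position_mm": list(d.get("position_mm", ())),
             "parent": list(parent[v]) if v in parent else None}
            for v, d in sorted(t.nodes(data=True))
        ],
        "edges": [
            {"from": list(u), "to": list(w), "edge_id": d.get("edge_id"),
             "length": d.get("length"), "distance": d.get("distance"),
             "mean_radius": d.get("mean_radius"),
             "volume": d.get("volume"), "angle": d.get("angle"),
             "label": d.get("label")}
            for u, w, d in sorted(t.edges(data=True),
                                  key=lambda e: (e[0], e[1]))
        ],
    }


def tree_to_newick(t: nx.MultiDiGraph) -> str:
    """Newick-like rendering of the tree topology (vertex = z.y.x)."""
    root = t.graph["root"]

    def name(v):
        return ".".join(str(int(c)) for c in v)

    def rec(v):
        children = sorted(w for _, w in t.out_edges(v))
        if not children:
            return name(v)
        return "(" + ",".join(rec(w) for w in children) + ")" + name(v)

    return rec(root) + ";"
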