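"""Hierarchical division of the vessel tree into blood-supply branches.

Branch radii of a portal tree form two populations: a few thick trunk
branches (First Subtree) and many thin distal branches (Second Subtree).
A two-component Gaussian mixture fitted to the branch-radius sample
separates them; with ``mu`` the mean of the small-radius component and
``Min`` the smallest observed radius, the Second Subtree occupies
``[Min, 2*mu - Min]``, so the separation threshold is ``theta = 2*mu - Min``
(fallback ``theta = 0.5 * Max`` when the fit is degenerate or the sample
too small).  Second-Subtree edges decompose into connected subtrees; those
with at most five vertices (Micro Subtrees) are trivial structure and are
pruned; the surviving subtree roots are clustered with k-means++ into
``K = 8`` groups — one per Couinaud segment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

__all__ = [
    "RadiusModel",
    "Subtree",
    "BranchDivision",
    "fit_radius_threshold",
    "split_subtrees",
    "prune_micro",
    "cluster_branches",
]

#: subtrees with at most this many vertices are Micro Subtrees
MICRO_SUBTREE_MAX_VERTICES = 5


@dataclass
class RadiusModel:
    """Two-component radius mixture and the derived split threshold."""

    mu1: float      # large-radius component mean (mm)
    sigma1: float
    mu2: float      # small-radius component mean (mm)
    sigma2: float
    r_min: float
    r_max: float
    theta: float    # separation threshold (mm)
    fallback: bool = False

    def __post_init__(self) -> None:
        if self.mu2 > self.mu1 + 1e-12:
            raise ValueError("mu2 (small component) must not exceed mu1")
        if not (self.r_min - 1e-12 <= self.theta <= self.r_max + 1e-12):
            raise ValueError("theta must lie within [r_min, r_max]")


@dataclass
class Subtree:
    """A connected Second-Subtree piece with its root vertex."""

    root: tuple
    vertices: list
    edges: list          # (u, w, key) of the parent tree
    graph: nx.MultiDiGraph = field(repr=False)


@dataclass
class BranchDivision:
    """Preserved subtrees with their cluster labels (1..K)."""

    subtrees: list
    labels: list
    K: int
    centers: np.ndarray = field(repr=False, default=None)

    def groups(self) -> dict[int, list]:
        out: dict[int, list] = {}
        for st, lab in zip(self.subtrees, self.labels):
            out.setdefault(int(lab), []).append(st)
        return out


def fit_radius_threshold(radii, seed: int = 0) -> RadiusModel:
    """Fit the two-component radius mixture and derive ``theta``.

    Falls back to ``theta = 0.5 * Max`` (with a warning) when fewer than 4
    radii are given, or when the fit is degenerate: component means closer
    than 1e-3 or a component weight below 0.05.
    """
    r = np.asarray(sorted(radii), float)
    if r.size and (np.any(~np.isfinite(r)) or np.any(r <= 0)):
        raise ValueError("radii must be finite and positive")
    r_min = float(r.min()) if r.size else 0.0
    r_max = float(r.max()) if r.size else 0.0

    def fallback_model():
        theta = 0.5 * r_max
        theta = min(max(theta, r_min), r_max)
        return RadiusModel(mu1=r_max, sigma1=0.0, mu2=r_min, sigma2=0.0,
                           r_min=r_min, r_max=r_max, theta=theta,
                           fallback=True)

    if r.size < 4:
        warnings.warn("fewer than 4 branch radii; falling back to "
                      "theta = 0.5 * Max")
        return fallback_model()

    gm = GaussianMixture(n_components=2, random_state=seed, n_init=5)
    gm.fit(r.reshape(-1, 1))
    means = gm.means_.ravel()
    sigmas = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    lo, hi = int(np.argmin(means)), int(np.argmax(means))
    if abs(means[hi] - means[lo]) < 1e-3 or weights.min() < 0.05:
        warnings.warn("degenerate radius mixture; falling back to "
                      "theta = 0.5 * Max")
        return fallback_model()
    mu = float(means[lo])
    theta = 2.0 * mu - r_min
    theta = min(max(theta, r_min), r_max)
    return RadiusModel(mu1=float(means[hi]), sigma1=float(sigmas[hi]),
                       mu2=mu, sigma2=float(sigmas[lo]),
                       r_min=r_min, r_max=r_max, theta=theta)


def split_subtrees(t: nx.MultiDiGraph, theta: float
                   ) -> tuple[list, list[Subtree]]:
    """Partition tree edges at ``theta`` and group the small-radius edges
    into maximal connected subtrees.

    Returns ``(first_edges, second_subtrees)``: edges with mean radius
    above ``theta`` belong to the First Subtree; the rest form connected
    directed subtrees whose root is the vertex closest to the main root
    (the unique minimum-depth vertex, since ``t`` is a tree).
    """
    root = t.graph["root"]
    depth = nx.shortest_path_length(nx.DiGraph(t), root)
    first, second = [], []
    for u, w, k, d in t.edges(keys=True, data=True):
        (second if d["mean_radius"] <= theta else first).append((u, w, k))
    sub = nx.MultiDiGraph()
    sub.add_nodes_from((v, t.nodes[v]) for v in t.nodes)
    for u, w, k in second:
        sub.add_edge(u, w, key=k, **t.edges[u, w, k])
    subtrees = []
    for comp in sorted(nx.weakly_connected_components(sub), key=sorted):
        comp = set(comp)
        edges = [(u, w, k) for u, w, k in second if u in comp]
        if not edges:
            continue
        st_root = min(comp, key=lambda v: (depth[v], v))
        subtrees.append(Subtree(
            root=st_root, vertices=sorted(comp), edges=sorted(edges),
            graph=sub.subgraph(comp).copy()))
    return sorted(first), subtrees


def prune_micro(subtrees: list[Subtree]) -> list[Subtree]:
    """Remove Micro Subtrees (at most five vertices).

    Raises if every subtree is micro — the threshold is then too low for
    this tree.
    """
    kept = [st for st in subtrees
            if len(st.vertices) > MICRO_SUBTREE_MAX_VERTICES]
    if subtrees and not kept:
        raise ValueError(
            "all Second Subtrees are Micro Subtrees; lower theta or refine "
            "the vessel segmentation")
    return kept


def cluster_branches(subtrees: list[Subtree], K: int = 8, seed: int = 0
                     ) -> BranchDivision:
    """Cluster subtree root positions with k-means++ into ``K`` branch
    groups (labels 1..K).

    If fewer subtrees than ``K`` exist, ``K`` is lowered with a warning.
    Deterministic for a fixed seed (10 restarts, best inertia kept).
    """
    if not subtrees:
        raise ValueError("no subtrees to cluster")
    if len(subtrees) < K:
        warnings.warn(
            f"only {len(subtrees)} subtrees; lowering K from {K}")
        K = len(subtrees)
    pts = np.asarray([st.graph.nodes[st.root]["position_mm"]
                      for st in subtrees], float)
    km = KMeans(n_clusters=K, init="k-means++", n_init=10,
                random_state=seed)
    raw = km.fit_predict(pts)
    # relabel deterministically: clusters numbered by first appearance
    remap: dict[int, int] = {}
    labels = []
    for lab in raw:
        if int(lab) not in remap:
            remap[int(lab)] = len(remap) + 1
        labels.append(remap[int(lab)])
    centers = np.asarray([km.cluster_centers_[
        [k for k, v in remap.items() if v == i + 1][0]] for i in range(K)])
    return BranchDivision(subtrees=subtrees, labels=labels, K=K,
                          centers=centers)
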