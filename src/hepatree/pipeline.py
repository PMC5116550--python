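"""End-to-end pipeline: vessel mask -> skeleton -> tree -> segments -> report.

Chains the stages with their defaults, logging voxel/vertex/edge counts per
stage, and returns every intermediate product so callers can inspect or
re-run parts.  Randomness (mixture fit, k-means++) is controlled by a
single seed.
"""

from __future__ import annotations

import logging

import numpy as np

from . import annotate as _annotate
from . import hierarchy as _hierarchy
from . import skeletonize as _skeletonize
from . import topo_graph as _topo_graph
from . import vessel_enhance as _enhance
from . import vessel_tree as _vessel_tree
from .annotate import SEGMENT_NAMES

log = logging.getLogger("hepatree")

__all__ = ["run_pipeline"]


def run_pipeline(
    liver: np.ndarray,
    vessels: np.ndarray,
    spacing=(1.0, 1.0, 1.0),
    tumors: np.ndarray | None = None,
    seed: int = 0,
    K: int = 8,
    theta: float | None = None,
    relabel: dict[int, str] | None = None,
    vertices_only: bool = False,
) -> dict:
    """Run the full annotation pipeline on binary liver/vessel volumes.

    Returns a dict with the portal mask, skeleton, graph, tree, radius
    model, branch division, segment map, attribute/lobe tables and the
    relabel map used.
    """
    liver = np.asarray(liver).astype(bool)
    vessels = np.asarray(vessels).astype(bool)
    if tumors is not None:
        tumors = np.asarray(tumors).astype(bool)

    portal = _enhance.select_portal_component(vessels)
    log.info("portal component: %d voxels", int(portal.sum()))

    skel = _skeletonize.thin(portal)
    log.info("skeleton: %d voxels", int(skel.sum()))

    graph = _topo_graph.build_graph(skel, portal, spacing)
    log.info("graph: %d vertices, %d edges",
             graph.number_of_nodes(), graph.number_of_edges())

    root = _vessel_tree.select_root(graph)
    oriented = _vessel_tree.orient(graph, root)
    oriented = _vessel_tree.remove_redundant(oriented)
    tree = _vessel_tree.remove_irrelevant(oriented)
    tree = _vessel_tree.compute_angles(tree)
    log.info("tree: root %s, %d vertices, %d edges",
             root, tree.number_of_nodes(), tree.number_of_edges())

    radii = [d["mean_radius"] for _, _, d in tree.edges(data=True)]
    model = _hierarchy.fit_radius_threshold(radii, seed=seed)
    theta_used = float(theta) if theta is not None else model.theta
    first, subtrees = _hierarchy.split_subtrees(tree, theta_used)
    preserved = _hierarchy.prune_micro(subtrees)
    log.info("theta=%.3f mm: %d First-Subtree edges, %d subtrees "
             "(%d preserved)", theta_used, len(first), len(subtrees),
             len(preserved))

    division = _hierarchy.cluster_branches(preserved, K=K, seed=seed)
    seg = _annotate.classify_voxels(liver, division, spacing,
                                    vertices_only=vertices_only)
    attrs = _annotate.segment_attributes(
        seg, tumors=tumors, spacing=spacing)
    if relabel is None:
        relabel = {int(l): SEGMENT_NAMES[int(l) - 1]
                   for l in attrs["label"]}
    lobes = _annotate.lobe_report(attrs, relabel)
    log.info("segments: %s",
             ", ".join(f"{r.label}:{r.n_seg}" for r in attrs.itertuples()))

    return {
        "portal": portal,
        "skeleton": skel,
        "graph": graph,
        "root": root,
        "tree": tree,
        "radius_model": model,
        "theta": theta_used,
        "first_edges": first,
        "subtrees": subtrees,
        "division": division,
        "segment_map": seg,
        "attributes": attrs,
        "lobes": lobes,
        "relabel": relabel,
    }
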