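"""Synthetic vessel/liver phantoms with known ground-truth topology.

A phantom is described by a :class:`TreeSpec` — a rooted tree of 3D node
positions with one tube radius per edge — and rasterized into a binary
volume of capsules (cylinders with hemispherical caps, so junctions are
watertight and free of spurious cavities).  An ellipsoidal "liver" mask and
ball "tumors" can be wrapped around the vessels, and a clean mask can be
corrupted with interior cavities and thin bridges to emulate the defects of
real vessel segmentations.

Conventions: voxel indices are 0-based ``(z, y, x)``; the physical position
of a voxel center is ``index * spacing`` in millimetres.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .euler import STRUCT_26

__all__ = [
    "TreeSpec",
    "rasterize_tree",
    "make_liver_phantom",
    "corrupt_mask",
    "random_tree_spec",
    "couinaud_phantom_spec",
]


@dataclass
class TreeSpec:
    """Ground-truth description of a tubular branching tree.

    Parameters
    ----------
    nodes : list of ``(id, (z, y, x))``
        Node identifiers with physical coordinates in mm.
    edges : list of ``(parent_id, child_id, radius_mm)``
        Directed tree edges; every edge carries the tube radius.
    spacing : per-axis voxel size ``(z, y, x)`` in mm.
    shape : voxel grid dimensions ``(z, y, x)``.
    seed : RNG seed used to generate the spec (bookkeeping only).
    """

    nodes: list[tuple[int, tuple[float, float, float]]]
    edges: list[tuple[int, int, float]]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- structure queries ------------------------------------------------

    def node_positions(self) -> dict[int, np.ndarray]:
        return {i: np.asarray(p, float) for i, p in self.nodes}

    @property
    def root(self) -> int:
        children = {c for _, c, _ in self.edges}
        roots = [i for i, _ in self.nodes if i not in children]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {roots}")
        return roots[0]

    def degree_one_nodes(self) -> list[int]:
        """Tube tips: nodes of total degree one (leaves, plus the root when
        it has a single child).  Each corresponds to one skeleton end-voxel."""
        deg: dict[int, int] = {i: 0 for i, _ in self.nodes}
        for p, c, _ in self.edges:
            deg[p] += 1
            deg[c] += 1
        return [i for i, d in deg.items() if d == 1]

    def validate(self) -> None:
        ids = [i for i, _ in self.nodes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate node ids")
        pos = self.node_positions()
        children = set()
        adj: dict[int, set[int]] = {i: set() for i in ids}
        for p, c, r in self.edges:
            if p not in pos or c not in pos:
                raise ValueError(f"edge ({p}, {c}) references unknown node")
            if c in children:
                raise ValueError(f"node {c} has more than one parent")
            children.add(c)
            adj[p].add(c)
            adj[c].add(p)
            if r <= 0:
                raise ValueError(f"edge ({p}, {c}) has non-positive radius")
            if any(r / s < 1.0 for s in self.spacing):
                raise ValueError(
                    f"edge ({p}, {c}): radius {r} mm is thinner than one "
                    f"voxel for spacing {self.spacing}")
        roots = [i for i in ids if i not in children]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        # connectivity
        if ids:
            seen = {roots[0]}
            stack = [roots[0]]
            while stack:
                for n in adj[stack.pop()]:
                    if n not in seen:
                        seen.add(n)
                        stack.append(n)
            if seen != set(ids):
                raise ValueError("edges do not form a connected tree")
        extent = [(s - 1) * sp for s, sp in zip(self.shape, self.spacing)]
        for i, p in self.nodes:
            if any(x < 0 or x > e for x, e in zip(p, extent)):
                raise ValueError(
                    f"node {i} at {p} lies outside the grid extent {extent}")

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({
            "nodes": [[i, list(p)] for i, p in self.nodes],
            "edges": [[p, c, r] for p, c, r in self.edges],
            "spacing": list(self.spacing),
            "shape": list(self.shape),
            "seed": self.seed,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TreeSpec":
        d = json.loads(text)
        return cls(
            nodes=[(int(i), tuple(p)) for i, p in d["nodes"]],
            edges=[(int(p), int(c), float(r)) for p, c, r in d["edges"]],
            spacing=tuple(d["spacing"]),
            shape=tuple(d["shape"]),
            seed=int(d.get("seed", 0)),
        )


def _capsule_voxels(shape, spacing, p, q, radius):
    """Boolean mask of voxels whose center lies within ``radius`` of the
    segment p-q (a capsule), computed on the segment's bounding box."""
    spacing = np.asarray(spacing, float)
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    lo_mm = np.minimum(p, q) - radius
    hi_mm = np.maximum(p, q) + radius
    lo = np.maximum(np.floor(lo_mm / spacing).astype(int), 0)
    hi = np.minimum(np.ceil(hi_mm / spacing).astype(int) + 1,
                    np.asarray(shape))
    if np.any(lo >= hi):
        return None, None
    grids = np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)],
                        indexing="ij")
    pts = np.stack(grids, axis=-1) * spacing  # physical centers
    d = q - p
    dd = float(d @ d)
    if dd == 0.0:
        dist = np.linalg.norm(pts - p, axis=-1)
    else:
        t = np.clip(((pts - p) @ d) / dd, 0.0, 1.0)
        proj = p + t[..., None] * d
        dist = np.linalg.norm(pts - proj, axis=-1)
    return tuple(slice(a, b) for a, b in zip(lo, hi)), dist <= radius


def rasterize_tree(spec: TreeSpec) -> tuple[np.ndarray, TreeSpec]:
    """Rasterize a :class:`TreeSpec` into a binary capsule volume.

    Returns the binary volume and the (echoed) ground-truth spec.  Raises
    ``ValueError`` naming the offending edge if a tube rasterizes thinner
    than one voxel (no foreground), and if the union is not a single
    26-connected component.
    """
    spec.validate()
    pos = spec.node_positions()
    vol = np.zeros(spec.shape, dtype=bool)
    for p_id, c_id, r in spec.edges:
        sl, cap = _capsule_voxels(spec.shape, spec.spacing,
                                  pos[p_id], pos[c_id], r)
        if sl is None or not cap.any():
            raise ValueError(
                f"edge ({p_id}, {c_id}) rasterizes to no voxels "
                "(tube thinner than one voxel)")
        vol[sl] |= cap
    if spec.edges:
        _, n = ndimage.label(vol, structure=STRUCT_26)
        if n != 1:
            raise ValueError(
                f"rasterized tree has {n} connected components, expected 1")
    return vol, spec


def make_liver_phantom(
    spec: TreeSpec,
    tumor_centers: list[tuple[float, float, float]] | None = None,
    tumor_radii: list[float] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Wrap a rasterized tree in an ellipsoidal liver mask with ball tumors.

    The liver is the ellipsoid inscribed in the grid.  Tumor balls are
    clipped to the liver.  Raises ``ValueError`` if any vessel voxel falls
    outside the ellipsoid.
    """
    tumor_centers = tumor_centers or []
    tumor_radii = tumor_radii or []
    if len(tumor_centers) != len(tumor_radii):
        raise ValueError("tumor_centers and tumor_radii lengths differ")
    vessels, _ = rasterize_tree(spec)
    spacing = np.asarray(spec.spacing, float)
    extent = (np.asarray(spec.shape) - 1) * spacing
    center = extent / 2.0
    semi = extent / 2.0
    grids = np.meshgrid(*[np.arange(s) for s in spec.shape], indexing="ij")
    pts = np.stack(grids, axis=-1) * spacing
    liver = (((pts - center) / semi) ** 2).sum(axis=-1) <= 1.0
    if np.any(vessels & ~liver):
        bad = np.argwhere(vessels & ~liver)[0]
        raise ValueError(
            f"vessel voxel {tuple(int(i) for i in bad)} lies outside the "
            "ellipsoidal liver")
    tumors = np.zeros(spec.shape, dtype=bool)
    for c, r in zip(tumor_centers, tumor_radii):
        tumors |= np.linalg.norm(pts - np.asarray(c, float), axis=-1) <= r
    tumors &= liver
    return liver, vessels, tumors


def corrupt_mask(mask: np.ndarray, cavity_rate: float, bridge_count: int,
                 seed: int) -> np.ndarray:
    """Inject segmentation-like defects into a binary vessel mask.

    Deletes a fraction ``cavity_rate`` of strictly interior voxels (chosen
    pairwise non-adjacent, so each deletion opens an isolated cavity) and
    adds ``bridge_count`` thin straight bridges between nearby surface
    voxels across background, each closing a cycle.  Deterministic in
    ``seed``; the foreground remains a single 26-connected component.
    """
    if not 0 <= cavity_rate < 0.5:
        raise ValueError("cavity_rate must be in [0, 0.5)")
    m = np.asarray(mask).astype(bool).copy()
    if cavity_rate == 0 and bridge_count == 0:
        return m
    rng = np.random.default_rng(seed)

    interior = ndimage.binary_erosion(m, structure=STRUCT_26)
    coords = np.argwhere(interior)
    n_del = int(round(cavity_rate * len(coords)))
    if n_del:
        order = rng.permutation(len(coords))
        chosen: list[np.ndarray] = []
        for i in order:
            c = coords[i]
            if all(np.abs(c - o).max() > 1 for o in chosen):
                chosen.append(c)
                if len(chosen) == n_del:
                    break
        for c in chosen:
            m[tuple(c)] = False

    if bridge_count:
        surface = m & ~ndimage.binary_erosion(m, structure=STRUCT_26)
        surf = np.argwhere(surface)
        added = 0
        for _ in range(500 * bridge_count):
            if added == bridge_count:
                break
            a, b = surf[rng.integers(len(surf))], surf[rng.integers(len(surf))]
            gap = np.linalg.norm(a - b)
            if not 4.0 <= gap <= 30.0:
                continue
            n_steps = int(math.ceil(gap * 3))
            line = np.unique(np.round(
                np.linspace(a, b, n_steps + 1)).astype(int), axis=0)
            inner = [tuple(v) for v in line
                     if tuple(v) != tuple(a) and tuple(v) != tuple(b)]
            if not inner or any(m[v] for v in inner):
                continue
            for v in inner:
                m[v] = True
            added += 1
        if added < bridge_count:
            raise ValueError(
                f"could not place {bridge_count} bridges (placed {added}); "
                "bridging impossible within the grid")
    return m


# ---------------------------------------------------------------------------
# randomized phantom trees


def _rotate_towards(direction: np.ndarray, polar: float, azimuth: float
                    ) -> np.ndarray:
    """Unit vector at angle ``polar`` (rad) from ``direction``, rotated by
    ``azimuth`` around it."""
    d = direction / np.linalg.norm(direction)
    # build an orthonormal frame around d
    helper = np.array([1.0, 0.0, 0.0])
    if abs(d @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(d, helper)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return (math.cos(polar) * d
            + math.sin(polar) * (math.cos(azimuth) * u + math.sin(azimuth) * v))


def _segment_distance(p1, q1, p2, q2) -> float:
    """Minimum distance between segments p1-q1 and p2-q2 (sampled)."""
    t = np.linspace(0.0, 1.0, 12)
    a = p1 + t[:, None] * (q1 - p1)
    b = p2 + t[:, None] * (q2 - p2)
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    return float(d.min())


def random_tree_spec(
    seed: int,
    shape: tuple[int, int, int] = (64, 64, 64),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    levels: int = 2,
    branching: int = 2,
    trunk_radius: float = 2.2,
    radius_decay: float = 0.65,
    trunk_length: float = 18.0,
    length_decay: float = 0.75,
    separation_factor: float = 4.0,
    margin: float = 3.0,
) -> TreeSpec:
    """Grow a randomized rooted tree with well-separated limbs.

    The trunk starts near one face of the grid and children branch off at
    25-50 degrees from the parent direction with spread azimuths.  A new
    segment is accepted only if it keeps ``separation_factor * trunk_radius``
    clearance from all non-adjacent existing segments and stays inside the
    inscribed ellipsoid with a safety margin; branches that cannot be placed
    after a bounded number of attempts are dropped, so the returned spec is
    always a valid tree whose topology is the ground truth.
    """
    rng = np.random.default_rng(seed)
    spacing_a = np.asarray(spacing, float)
    extent = (np.asarray(shape) - 1) * spacing_a
    center = extent / 2.0
    semi = extent / 2.0 - margin

    def inside(p: np.ndarray, r: float) -> bool:
        return float((((p - center) / (semi - r)) ** 2).sum()) <= 1.0

    start = center.copy()
    start[1] = margin + trunk_radius + 1.0
    direction = np.array([0.0, 1.0, 0.0])

    nodes: list[tuple[int, tuple[float, float, float]]] = [(0, tuple(start))]
    edges: list[tuple[int, int, float]] = []
    segments: list[tuple[np.ndarray, np.ndarray, int, int]] = []
    next_id = 1
    sep = separation_factor * trunk_radius

    def clear_of_others(parent_id: int, p: np.ndarray, qs: list[np.ndarray]
                        ) -> bool:
        for s_p, s_q, s_pid, s_cid in segments:
            if parent_id in (s_pid, s_cid):
                continue  # parent and sibling tubes meet at the junction
            for q in qs:
                if _segment_distance(p, q, s_p, s_q) < sep:
                    return False
        return True

    def add_edge(parent_id: int, q: np.ndarray, radius: float,
                 p: np.ndarray) -> int:
        nonlocal next_id
        nid = next_id
        next_id += 1
        nodes.append((nid, tuple(q)))
        edges.append((parent_id, nid, radius))
        segments.append((p, q, parent_id, nid))
        return nid

    # junctions are placed symmetrically (one polar angle, evenly spread
    # azimuths) so that the thinned skeleton forms a single compact branch
    # point per ground-truth node.
    frontier = [(0, start, direction, trunk_length, trunk_radius, 0)]
    for _level in range(levels + 1):
        new_frontier = []
        for pid, p, d, length, radius, lvl in frontier:
            if lvl == 0:
                q = p + d * length
                if inside(q, radius) and clear_of_others(pid, p, [q]):
                    nid = add_edge(pid, q, radius, p)
                    new_frontier.append(
                        (nid, q, d, length * length_decay,
                         max(radius * radius_decay, max(spacing) * 1.05),
                         lvl + 1))
                continue
            for _ in range(40):
                polar = math.radians(rng.uniform(28.0, 45.0))
                base = rng.uniform(0.0, 2 * math.pi)
                dirs = [
                    _rotate_towards(d, polar,
                                    base + k * 2 * math.pi / branching)
                    for k in range(branching)
                ]
                qs = [p + nd * length for nd in dirs]
                if not all(inside(q, radius) for q in qs):
                    continue
                if not clear_of_others(pid, p, qs):
                    continue
                for nd, q in zip(dirs, qs):
                    nid = add_edge(pid, q, radius, p)
                    if lvl < levels:
                        new_frontier.append(
                            (nid, q, nd, length * length_decay,
                             max(radius * radius_decay,
                                 max(spacing) * 1.05),
                             lvl + 1))
                break
        frontier = new_frontier
        if not frontier:
            break

    spec = TreeSpec(nodes=nodes, edges=edges, spacing=tuple(spacing),
                    shape=tuple(shape), seed=seed)
    return spec


def couinaud_phantom_spec(
    seed: int = 0,
    shape: tuple[int, int, int] = (112, 128, 112),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    n_limbs: int = 8,
    trunk_radius: float = 3.0,
) -> TreeSpec:
    """Portal-vein-like phantom with a trunk and ``n_limbs`` limb systems.

    Emulates the anatomy the annotation pipeline targets: one thick trunk
    crossing the liver with eight distal branch systems ("bottle brush"),
    each a three-level subtree of thin tubes, attached at spread azimuths
    so the thinned skeleton recovers one subtree per limb.  Designed so
    the branch-radius mixture separates trunk from limbs and each limb
    subtree has more than five vertices (it survives micro-pruning), which
    yields exactly ``n_limbs`` blood-supply branch groups downstream.
    """
    rng = np.random.default_rng(seed)
    spacing_a = np.asarray(spacing, float)
    extent = (np.asarray(shape) - 1) * spacing_a
    center = extent / 2.0
    semi = extent / 2.0 - 2.0

    def inside(p: np.ndarray, r: float) -> bool:
        return float((((p - center) / (semi - r)) ** 2).sum()) <= 1.0

    # keep the last attachment far enough from the ellipsoid dome that a
    # full limb system still fits radially
    y0, y1 = 12.0, extent[1] - 52.0
    trunk_top = np.array([center[0], y0, center[2]])
    nodes: list[tuple[int, tuple[float, float, float]]] = [(0, tuple(trunk_top))]
    edges: list[tuple[int, int, float]] = []
    segments: list[tuple[np.ndarray, np.ndarray, int, int]] = []
    next_id = 1

    def add(parent, q, radius):
        nonlocal next_id
        nid = next_id
        next_id += 1
        nodes.append((nid, tuple(q)))
        edges.append((parent, nid, radius))
        segments.append((np.asarray(dict(nodes)[parent], float),
                         np.asarray(q, float), parent, nid))
        return nid

    def clear(parent, p, q, sep):
        for s_p, s_q, s_pid, s_cid in segments:
            if parent in (s_pid, s_cid):
                continue
            if _segment_distance(p, q, s_p, s_q) < sep:
                return False
        return True

    # trunk with one attachment node per limb
    attach_y = np.linspace(y0 + 12.0, y1, n_limbs)
    prev = 0
    attach_ids = []
    for y in attach_y:
        q = np.array([center[0], y, center[2]])
        nid = add(prev, q, trunk_radius)
        attach_ids.append(nid)
        prev = nid

    # limb systems at golden-angle azimuths, tilted downstream
    base_azimuth = rng.uniform(0.0, 2 * math.pi)
    trunk_dir = np.array([0.0, 1.0, 0.0])
    # distal radii are kept nearly uniform so the branch-radius mixture
    # splits trunk vs limbs cleanly and theta covers every limb edge
    level_par = [(18.0, 1.15, math.radians(55)),
                 (15.0, 1.10, math.radians(38)),
                 (12.0, 1.10, math.radians(38))]
    for i, aid in enumerate(attach_ids):
        azim = base_azimuth + i * math.radians(137.5)
        p = np.asarray(dict(nodes)[aid], float)
        length, radius, polar = level_par[0]
        placed = None
        for jit in range(24):
            a = azim + rng.normal(0.0, 0.15) + jit * math.radians(15)
            d = _rotate_towards(trunk_dir, polar, a)
            q = p + d * length
            if inside(q, radius) and clear(aid, p, q, 5.0):
                placed = (add(aid, q, radius), q, d)
                break
        if placed is None:
            continue
        frontier = [placed]
        for lvl in (1, 2):
            length, radius, polar = level_par[lvl]
            new_frontier = []
            for pid, pp, pd in frontier:
                done = False
                for attempt in range(80):
                    base = rng.uniform(0.0, 2 * math.pi)
                    pol = polar * rng.uniform(0.95, 1.15)
                    ds = [_rotate_towards(pd, pol, base + k * math.pi)
                          for k in range(2)]
                    lg = length * (0.8 if attempt >= 40 else 1.0)
                    qs = [pp + nd * lg for nd in ds]
                    if not all(inside(q, radius) for q in qs):
                        continue
                    if not all(clear(pid, pp, q, 4.5) for q in qs):
                        continue
                    for nd, q in zip(ds, qs):
                        nid = add(pid, q, radius)
                        new_frontier.append((nid, q, nd))
                    done = True
                    break
                if not done:
                    # keep the limb but record that it is short; callers
                    # relying on full limbs can regenerate with a new seed
                    continue
            frontier = new_frontier
    return TreeSpec(nodes=nodes, edges=edges, spacing=tuple(spacing),
                    shape=tuple(shape), seed=seed)
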