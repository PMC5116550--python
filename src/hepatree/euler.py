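"""Euler characteristic and topology counts for 3D binary volumes.

The foreground is read with 26-adjacency and the background with
6-adjacency, the usual complementary pair for curve thinning.  Under this
convention the Euler characteristic satisfies

    chi = objects - tunnels + cavities

and it equals the combinatorial Euler characteristic V - E + F - C of the
cubical complex formed by the union of the closed unit cubes of the
foreground voxels (corner- and edge-touching cubes are connected, which is
exactly foreground 26-adjacency; the open complement decomposes into
6-connected background regions).

These functions count cells directly and make no use of the octant lookup
table that drives the thinning pass, so they serve as an independent check
of it.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import ndimage

#: 26-connectivity structuring element for the foreground.
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)
#: 6-connectivity structuring element for the background.
STRUCT_6 = ndimage.generate_binary_structure(3, 1)


def euler_characteristic(mask: np.ndarray) -> int:
    """Euler characteristic of a 3D binary object under (26, 6) topology.

    Computed as V - E + F - C over the cubical complex of the union of the
    closed unit voxels.  A k-cell of the lattice belongs to the complex iff
    at least one of its incident voxels is foreground.
    """
    m = np.asarray(mask).astype(bool)
    if m.ndim != 3:
        raise ValueError("expected a 3D volume")
    if not m.any():
        return 0
    padded = np.pad(m, 1)
    chi = 0
    for k in range(4):
        for span in combinations(range(3), k):
            a = padded
            # pool with OR along every axis the cell does not span: a cell
            # is present iff any incident voxel is foreground.
            for ax in range(3):
                if ax not in span:
                    lo = [slice(None)] * 3
                    hi = [slice(None)] * 3
                    lo[ax] = slice(None, -1)
                    hi[ax] = slice(1, None)
                    a = a[tuple(lo)] | a[tuple(hi)]
            chi += (-1) ** k * int(a.sum())
    return chi


def topology_counts(mask: np.ndarray) -> tuple[int, int, int, int]:
    """Return ``(objects, tunnels, cavities, chi)`` of a binary volume.

    Objects are 26-connected foreground components; cavities are 6-connected
    background components that do not reach the volume border; tunnels
    (handles) follow from ``chi = objects - tunnels + cavities``.
    """
    m = np.asarray(mask).astype(bool)
    if m.ndim != 3:
        raise ValueError("expected a 3D volume")
    _, objects = ndimage.label(m, structure=STRUCT_26)
    bg = ~np.pad(m, 1)
    lab, n_bg = ndimage.label(bg, structure=STRUCT_6)
    # everything 6-connected to the padded border is the outside
    cavities = n_bg - 1 if n_bg else 0
    chi = euler_characteristic(m)
    tunnels = objects + cavities - chi
    return objects, tunnels, cavities, chi
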