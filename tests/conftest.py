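import numpy as np
import pytest

from hepatree.phantom import TreeSpec, rasterize_tree


@pytest.fixture(scope="session")
def tube_spec():
    """Straight y-aligned tube, radius 2 mm, length 20 mm."""
    return TreeSpec(nodes=[(0, (10.0, 4.0, 10.0)), (1, (10.0, 24.0, 10.0))],
                    edges=[(0, 1, 2.0)], spacing=(1.0, 1.0, 1.0),
                    shape=(21, 30, 21))


@pytest.fixture(scope="session")
def y_spec():
    """Symmetric Y: trunk plus two 45-degree limbs."""
    import math
    L = 12.0
    s, c = math.sin(math.radians(45)), math.cos(math.radians(45))
    nodes = [(0, (16.0, 4.0, 16.0)), (1, (16.0, 20.0, 16.0)),
             (2, (16.0 + L * s, 20.0 + L * c, 16.0)),
             (3, (16.0 - L * s, 20.0 + L * c, 16.0))]
    return TreeSpec(nodes=nodes,
                    edges=[(0, 1, 2.0), (1, 2, 1.4), (1, 3, 1.4)],
                    spacing=(1.0, 1.0, 1.0), shape=(40, 40, 33))


@pytest.fixture(scope="session")
def tube_volume(tube_spec):
    vol, _ = rasterize_tree(tube_spec)
    return vol


@pytest.fixture(scope="session")
def y_volume(y_spec):
    vol, _ = rasterize_tree(y_spec)
    return vol


@pytest.fixture(scope="session")
def y_skeleton(y_volume):
    from hepatree.skeletonize import thin
    return thin(y_volume)


def straight_line(n=9, axis=2, shape=None):
    """1-voxel-wide straight line of n voxels."""
    if shape is None:
        shape = [5, 5, 5]
        shape[axis] = n + 2
    m = np.zeros(shape, bool)
    idx = [2, 2, 2]
    for i in range(n):
        idx[axis] = 1 + i
        m[tuple(idx)] = True
    return m


def square_loop(side=7):
    """Closed single-voxel square loop in one z-plane."""
    m = np.zeros((3, side + 2, side + 2), bool)
    m[1, 1:side + 1, 1] = True
    m[1, 1:side + 1, side] = True
    m[1, 1, 1:side + 1] = True
    m[1, side, 1:side + 1] = True
    return m
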