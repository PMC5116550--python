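"""Hessian-based tubular enhancement and vessel extraction.

The vesselness of a voxel is judged from the eigenvalues of the
Gaussian-smoothed Hessian, ordered ``|l1| <= |l2| <= |l3|``.  A bright
tube has ``l1 ~ 0`` and ``l2, l3 << 0``; the response is

    V = 0                                   if l2 >= 0 or l3 >= 0
    V = (1 - exp(-Ra^2 / 2 alpha^2))
        * exp(-Rb^2 / 2 beta^2)
        * (1 - exp(-Rc^2 / 2 c^2))          otherwise

with ``Ra = l2/l3`` (plate vs line), ``Rb = l1/sqrt(l2*l3)`` (blob
deviation) and ``Rc = sqrt(l1^2 + l2^2 + l3^2)`` (structure strength).
Defaults ``alpha = 0.3``, ``beta = 0.7`` and ``c = I_max / 2`` where
``I_max`` is the brightest vessel intensity (empirically, the 99th
percentile of the liver region).  The enhanced volume is binarized by
26-connected region growing from the strongest response, closed
morphologically to fill small cavities, and reduced to the largest
connected component as the portal-vein mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .euler import STRUCT_26

__all__ = [
    "VesselnessParams",
    "HessianEigenvalues",
    "hessian_eigenvalues",
    "vesselness",
    "multiscale_vesselness",
    "segment_vessels",
    "select_portal_component",
]


@dataclass
class VesselnessParams:
    """Sensitivity parameters of the vesselness measure."""

    alpha: float = 0.3
    beta: float = 0.7
    c: float | None = None      # defaults to i_max / 2
    i_max: float | None = None  # brightest vessel intensity
    scales: tuple[float, ...] = (1.0,)

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.c is None:
            if self.i_max is None:
                raise ValueError("either c or i_max must be given")
            self.c = self.i_max / 2.0
        if self.c <= 0:
            raise ValueError("c must be positive")
        if not self.scales or any(s <= 0 for s in self.scales):
            raise ValueError("scales must be nonempty and positive")

    @classmethod
    def from_image(cls, image, liver=None, alpha=0.3, beta=0.7,
                   scales=(1.0,)) -> "VesselnessParams":
        """Parameters with ``i_max`` as the 99th-percentile intensity of
        the (liver-masked) image."""
        img = np.asarray(image, float)
        vals = img[np.asarray(liver, bool)] if liver is not None else img
        i_max = float(np.percentile(vals, 99.0))
        return cls(alpha=alpha, beta=beta, i_max=i_max,
                   scales=tuple(scales))


@dataclass
class HessianEigenvalues:
    """Per-voxel Hessian eigenvalues ordered ``|l1| <= |l2| <= |l3|``."""

    lambda1: np.ndarray
    lambda2: np.ndarray
    lambda3: np.ndarray
    scale: float = 1.0

    def __post_init__(self) -> None:
        a1 = np.abs(self.lambda1)
        a2 = np.abs(self.lambda2)
        a3 = np.abs(self.lambda3)
        if not (np.all(a1 <= a2 + 1e-9) and np.all(a2 <= a3 + 1e-9)):
            raise ValueError("eigenvalues must be ordered by magnitude")


def hessian_eigenvalues(image: np.ndarray, scale: float,
                        spacing=(1.0, 1.0, 1.0)) -> HessianEigenvalues:
    """Eigenvalues of the Gaussian-smoothed Hessian at ``scale`` (mm).

    The Hessian is symmetric, so the eigenvalues are real; they are sorted
    by absolute value per voxel.  Non-finite input is an error.
    """
    img = np.asarray(image, float)
    if img.ndim != 3:
        raise ValueError("expected a 3D volume")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    if scale <= 0:
        raise ValueError("scale must be positive")
    sp = np.asarray(spacing, float)
    sigma = scale / sp  # physical scale -> per-axis voxel sigmas
    h = np.empty(img.shape + (3, 3))
    for i in range(3):
        for j in range(i, 3):
            order = [0, 0, 0]
            order[i] += 1
            order[j] += 1
            # wide truncation keeps the discrete derivative kernels
            # exact on constant images
            d = ndimage.gaussian_filter(img, sigma, order=order,
                                        truncate=8.0)
            # derivatives w.r.t. physical mm, not voxel index
            d /= sp[i] * sp[j]
            h[..., i, j] = d
            h[..., j, i] = d
    eig = np.linalg.eigvalsh(h)  # ascending by value
    order = np.argsort(np.abs(eig), axis=-1)
    eig = np.take_along_axis(eig, order, axis=-1)
    return HessianEigenvalues(lambda1=eig[..., 0], lambda2=eig[..., 1],
                              lambda3=eig[..., 2], scale=float(scale))


def vesselness(eig: HessianEigenvalues, p: VesselnessParams) -> np.ndarray:
    """Tubularity response in ``[0, 1)`` from ordered eigenvalues.

    Zero wherever ``l2 >= 0`` or ``l3 >= 0`` (dark or non-tubular
    structure); the degenerate ``l3 = 0, l2 < 0`` voxel cannot occur under
    the magnitude ordering, and ``l3 < 0`` makes the ratios well defined.
    """
    l1, l2, l3 = eig.lambda1, eig.lambda2, eig.lambda3
    out = np.zeros(l1.shape, float)
    ok = (l2 < 0) & (l3 < 0)
    if not ok.any():
        return out
    l1o, l2o, l3o = l1[ok], l2[ok], l3[ok]
    ra = l2o / l3o
    # Rb^2 = l1^2 / (l2 * l3), formed from bounded ratios so that tiny
    # eigenvalues cannot underflow the product to zero
    rb2 = (l1o / l2o) * (l1o / l3o)
    rc2 = l1o ** 2 + l2o ** 2 + l3o ** 2
    out[ok] = ((1.0 - np.exp(-ra ** 2 / (2.0 * p.alpha ** 2)))
               * np.exp(-rb2 / (2.0 * p.beta ** 2))
               * (1.0 - np.exp(-rc2 / (2.0 * p.c ** 2))))
    return out


def multiscale_vesselness(image: np.ndarray, p: VesselnessParams,
                          spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Voxelwise maximum of the vesselness response over ``p.scales``."""
    out = None
    for s in p.scales:
        v = vesselness(hessian_eigenvalues(image, s, spacing), p)
        out = v if out is None else np.maximum(out, v)
    return out


def segment_vessels(vness: np.ndarray, liver: np.ndarray,
                    grow_threshold: float | None = None) -> np.ndarray:
    """Region-grow the vessel mask from the strongest response.

    26-connected growth from the global-maximum vesselness voxel inside
    the liver, accepting voxels with response at or above
    ``grow_threshold`` (default: Otsu threshold of the nonzero responses);
    then one pass of morphological closing with a 3x3x3 cube to fill small
    cavities.  The result is clipped to the liver mask.
    """
    v = np.asarray(vness, float)
    lv = np.asarray(liver).astype(bool)
    if not lv.any():
        raise ValueError("liver mask is empty")
    v = np.where(lv, v, 0.0)
    if grow_threshold is None:
        nz = v[v > 0]
        if nz.size == 0:
            warnings.warn("no positive vesselness inside the liver; "
                          "returning an empty mask")
            return np.zeros(lv.shape, bool)
        grow_threshold = float(threshold_otsu(nz)) if nz.size > 1 else 0.0
    accept = lv & (v >= grow_threshold) & (v > 0)
    if not accept.any():
        warnings.warn("no voxel above the growing threshold; "
                      "returning an empty mask")
        return np.zeros(lv.shape, bool)
    seed = np.unravel_index(int(np.argmax(v)), v.shape)
    lab, _ = ndimage.label(accept, structure=STRUCT_26)
    if lab[seed] == 0:
        # seed not in an accepted region (cannot happen when threshold <= max)
        warnings.warn("seed voxel below threshold; returning empty mask")
        return np.zeros(lv.shape, bool)
    grown = lab == lab[seed]
    closed = ndimage.binary_closing(grown, structure=np.ones((3, 3, 3), bool))
    return (closed | grown) & lv


def select_portal_component(vessels: np.ndarray) -> np.ndarray:
    """Largest 26-connected component of the vessel mask.

    Size ties break toward the component containing the lexicographically
    smallest voxel index.
    """
    v = np.asarray(vessels).astype(bool)
    if not v.any():
        raise ValueError("vessel mask is empty")
    lab, n = ndimage.label(v, structure=STRUCT_26)
    sizes = np.bincount(lab.ravel())[1:]
    best = np.flatnonzero(sizes == sizes.max()) + 1
    if len(best) > 1:
        # tie: first label encountered in scan order wins; ndimage.label
        # assigns labels in lexicographic scan order, so the smallest
        # label contains the smallest voxel index among the tied ones
        winners = sorted(
            best, key=lambda b: tuple(np.argwhere(lab == b)[0]))
        choice = winners[0]
    else:
        choice = int(best[0])
    return lab == choice
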