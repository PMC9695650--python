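"""Intranodular mask validation and perinodular ring construction.

The perinodular ring is the set of voxels outside the nodule whose
Euclidean distance *in millimetres* (voxel centre to nearest nodule voxel
centre, using the per-axis spacing) is at most ``distance_mm``.  Distance
is physical, not voxel-count: with 2.5-3 mm slices an isotropic voxel
dilation would reach much further through-plane than in-plane.

The ring is deliberately NOT masked to lung parenchyma; chest wall or
vessels inside the 15 mm shell are included if present.  This mirrors a
plain geometric dilation of the nodule contour and is logged as a caveat
for real data.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .volume_io import ImageVolume, RoiMask

logger = logging.getLogger("noduleomics.roi")

#: default radial extent of the perinodular shell, millimetres
DEFAULT_RING_MM = 15.0

_CONN26 = np.ones((3, 3, 3), dtype=bool)


def perinodular_ring(
    intra: RoiMask, volume: ImageVolume, distance_mm: float = DEFAULT_RING_MM
) -> RoiMask:
    """Construct the perinodular ring by spacing-aware dilation.

    Parameters
    ----------
    intra : RoiMask
        Nonempty nodule mask aligned with ``volume``.
    volume : ImageVolume
        Supplies grid shape and per-axis spacing in mm.
    distance_mm : float
        Radial extent of the ring.  ``0`` yields an empty ring (but a
        fully clipped ring — a nodule filling the grid — is an error).

    Returns
    -------
    RoiMask with role ``peri``; disjoint from ``intra`` by construction.
    """
    if intra.shape != volume.shape:
        raise ValueError(f"mask shape {intra.shape} != volume shape {volume.shape}")
    if intra.count() == 0:
        raise ValueError("intranodular mask is empty")
    if distance_mm < 0:
        raise ValueError("distance_mm must be >= 0")
    # distance of every outside voxel to the nearest intra voxel centre, mm
    dist = ndimage.distance_transform_edt(~intra.voxels, sampling=volume.spacing_mm)
    ring = (~intra.voxels) & (dist <= distance_mm)
    if distance_mm > 0 and not ring.any():
        raise ValueError("perinodular ring is empty after clipping to the grid")
    return RoiMask(voxels=ring, role="peri")


def largest_component(mask: RoiMask) -> RoiMask:
    """Keep the largest 26-connected component of a mask.

    A solitary nodule should be a single component; extra components are
    logged.  Size ties are broken deterministically by the smallest linear
    (C-order) voxel index of the component.
    """
    if mask.count() == 0:
        raise ValueError("mask is empty")
    labels, n = ndimage.label(mask.voxels, structure=_CONN26)
    if n == 1:
        return mask
    logger.info("mask has %d connected components; keeping the largest", n)
    sizes = np.bincount(labels.ravel())[1:]  # skip background
    best = sizes.max()
    candidates = np.flatnonzero(sizes == best) + 1
    if len(candidates) == 1:
        keep = candidates[0]
    else:
        flat = labels.ravel()
        first_index = {
            lab: int(np.flatnonzero(flat == lab)[0]) for lab in candidates
        }
        keep = min(candidates, key=lambda lab: first_index[lab])
    return RoiMask(voxels=labels == keep, role=mask.role)
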