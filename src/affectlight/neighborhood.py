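"""Sphere neighborhoods on a voxel mask.

Membership is squared Euclidean distance on integer voxel offsets:
voxel j belongs to the sphere centred at i iff ``|i - j|^2 <= radius^2``.
Spheres are truncated at mask edges — centres are exactly the in-mask voxels
and members are restricted to the mask, with no padding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def sphere_offsets(radius: float) -> np.ndarray:
    """Integer offset triples with squared norm <= radius^2, lexicographic order."""
    r = int(np.floor(radius))
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    offs = np.stack([dx.ravel(), dy.ravel(), dz.ravel()], axis=1)
    return offs[(offs**2).sum(axis=1) <= radius**2]


@dataclass
class SphereNeighborhood:
    """Per-voxel sphere membership lists on an in-mask index space.

    ``members[k]`` lists, for the k-th in-mask voxel (mask scanned in C order),
    the in-mask voxel indices within ``radius`` of it, ordered by offset.
    """

    radius: float
    mask: np.ndarray = field(repr=False)
    members: list[np.ndarray] = field(repr=False)

    @property
    def n_centers(self) -> int:
        return len(self.members)

    def sizes(self) -> np.ndarray:
        return np.array([m.size for m in self.members])


def build_neighborhood(mask: np.ndarray, radius: float) -> SphereNeighborhood:
    """Build sphere neighborhoods for every in-mask voxel.

    Parameters
    ----------
    mask : numpy.ndarray
        Boolean 3-D analysis mask.
    radius : float
        Sphere radius in voxel units (Euclidean); 0 gives singleton spheres.
    """
    mask = np.asarray(mask, dtype=bool)
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if mask.ndim != 3 or not mask.any():
        raise ValueError("mask must be 3-D and non-empty")

    coords = np.argwhere(mask)  # C order: matches mask[mask] flattening
    index_vol = np.full(mask.shape, -1, dtype=np.int64)
    index_vol[mask] = np.arange(coords.shape[0])
    offs = sphere_offsets(radius)
    shape = np.asarray(mask.shape)

    members = []
    for c in coords:
        pts = c + offs
        ok = np.all((pts >= 0) & (pts < shape), axis=1)
        pts = pts[ok]
        idx = index_vol[pts[:, 0], pts[:, 1], pts[:, 2]]
        members.append(idx[idx >= 0])
    return SphereNeighborhood(radius=radius, mask=mask, members=members)
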