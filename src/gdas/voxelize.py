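"""Parity scan-conversion of closed surfaces onto voxel grids."""

from __future__ import annotations

import numpy as np

from .image import BinarySegmentation
from .mesh import TriSurface

__all__ = ["voxelize_mask", "voxelize"]


def voxelize_mask(surface: TriSurface, shape, affine) -> np.ndarray:
    """Boolean inside-mask of a closed surface at the voxel centers of a grid.

    Scan conversion: rays along the third index axis through each (i, j)
    voxel-column; a center is foreground when an odd number of surface
    crossings lies above it.  Vertices are nudged by a tiny fixed offset
    in index space so rays never hit vertices or edges exactly.
    """
    if not surface.is_closed():
        raise ValueError("voxelization requires a closed surface")
    inv = np.linalg.inv(np.asarray(affine, float))
    v = surface.vertices @ inv[:3, :3].T + inv[:3, 3]
    v = v + np.array([1.737e-7, 2.113e-7, 0.0])  # deterministic degeneracy guard
    tri = v[surface.faces]  # (M, 3, 3) in continuous index coords

    ni, nj, nk = shape
    cols: dict[tuple[int, int], list[float]] = {}
    for p in tri:
        t2 = p[:, :2]
        lo = np.ceil(t2.min(axis=0)).astype(int)
        hi = np.floor(t2.max(axis=0)).astype(int)
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, [ni - 1, nj - 1])
        if np.any(hi < lo):
            continue
        ii, jj = np.meshgrid(
            np.arange(lo[0], hi[0] + 1), np.arange(lo[1], hi[1] + 1), indexing="ij"
        )
        pts = np.stack([ii.ravel(), jj.ravel()], axis=1).astype(float)
        # barycentric coordinates in the (i, j) projection
        d0 = t2[1] - t2[0]
        d1 = t2[2] - t2[0]
        det = d0[0] * d1[1] - d0[1] * d1[0]
        if det == 0.0:
            continue  # triangle edge-on to the ray direction
        rel = pts - t2[0]
        u = (rel[:, 0] * d1[1] - rel[:, 1] * d1[0]) / det
        w = (d0[0] * rel[:, 1] - d0[1] * rel[:, 0]) / det
        hit = (u >= 0.0) & (w >= 0.0) & (u + w <= 1.0)
        if not hit.any():
            continue
        kc = p[0, 2] + u[hit] * (p[1, 2] - p[0, 2]) + w[hit] * (p[2, 2] - p[0, 2])
        for (ci, cj), ck in zip(pts[hit].astype(int), kc):
            cols.setdefault((int(ci), int(cj)), []).append(float(ck))

    mask = np.zeros(shape, dtype=bool)
    kgrid = np.arange(nk)
    for (ci, cj), crossings in cols.items():
        c = np.sort(crossings)
        if len(c) % 2:  # grazing degeneracy: drop the tightest crossing pair
            gaps = np.diff(c)
            c = np.delete(c, int(np.argmin(gaps)) if len(gaps) else 0)
        for lo_c, hi_c in zip(c[0::2], c[1::2]):
            mask[ci, cj, (kgrid > lo_c) & (kgrid < hi_c)] = True
    return mask


def voxelize(surface: TriSurface, spacing, padding: float = 3.0) -> BinarySegmentation:
    """Scan-convert a closed surface to a binary volume.

    ``spacing`` is the isotropic or per-axis voxel size in mm; ``padding``
    (mm) of guaranteed-background margin is added around the bounding box.
    """
    spacing = np.broadcast_to(np.asarray(spacing, float), 3).copy()
    if np.any(spacing <= 0):
        raise ValueError("spacing must be positive")
    lo, hi = surface.bounding_box()
    origin = lo - padding
    shape = np.ceil((hi - lo + 2 * padding) / spacing).astype(int) + 1
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    affine[:3, 3] = origin + spacing / 2.0
    mask = voxelize_mask(surface, tuple(shape), affine)
    return BinarySegmentation(mask, affine)
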