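"""Small shared mesh helpers."""

from __future__ import annotations

import numpy as np
from skimage.measure import marching_cubes

import trimesh

__all__ = ["marching_mesh"]


def marching_mesh(values: np.ndarray, level: float, origin, spacing) -> trimesh.Trimesh:
    """Marching-cubes isosurface as a clean, outward-oriented Trimesh.

    ``values`` is sampled at voxel centres; vertex ``(i, j, k)`` maps to
    world coordinates ``origin + index * spacing``. Duplicate vertices are
    merged exactly and zero-area faces dropped, which leaves marching-cubes
    output watertight and manifold.
    """
    verts, faces, _, _ = marching_cubes(values, level=level)
    verts = np.asarray(origin) + verts * np.broadcast_to(np.asarray(spacing, float), (3,))
    vv, inv = np.unique(verts.round(9), axis=0, return_inverse=True)
    ff = inv[faces]
    ok = (ff[:, 0] != ff[:, 1]) & (ff[:, 1] != ff[:, 2]) & (ff[:, 0] != ff[:, 2])
    mesh = trimesh.Trimesh(vertices=vv, faces=ff[ok], process=False)
    trimesh.repair.fix_normals(mesh)
    if mesh.is_watertight and mesh.volume < 0:
        mesh.invert()
    return mesh
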