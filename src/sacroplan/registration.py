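"""Rigid registration: closed-form landmark fit and ICP refinement.

The landmark stage is the orthogonal-Procrustes / Kabsch solution with
reflections excluded; the refinement stage is a trimmed point-to-plane
iterative-closest-point loop between surface samples.
"""

from __future__ import annotations

import numpy as np

import trimesh

from .meshquery import MeshQuery
from .spatial import RigidTransform

__all__ = ["landmark_register", "refine_register"]


def landmark_register(source_pts: np.ndarray, target_pts: np.ndarray
                      ) -> tuple[RigidTransform, float]:
    """Least-squares rigid fit mapping source landmarks onto target landmarks.

    Returns the transform and the RMS residual (mm). Raises on degenerate
    (fewer than 3, or collinear) correspondences. Reflections are excluded:
    the returned rotation always has determinant +1.
    """
    P = np.asarray(source_pts, float)
    Q = np.asarray(target_pts, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[0] < 3 or P.shape[1] != 3:
        raise ValueError("need >= 3 corresponding 3D point pairs")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-9 * max(S[0], 1.0):
        raise ValueError("landmarks are collinear: rotation is not determined")
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    tf = RigidTransform(R, t)
    rms = float(np.sqrt(np.mean(np.sum((tf.apply(P) - Q) ** 2, axis=1))))
    return tf, rms


def refine_register(source_mesh: trimesh.Trimesh, target_mesh: trimesh.Trimesh,
                    init: RigidTransform | None = None,
                    max_iterations: int = 50, trim: float = 0.9,
                    tol: float = 1e-4, n_samples: int = 1500, seed: int = 0
                    ) -> tuple[RigidTransform, float]:
    """Trimmed point-to-plane ICP from ``source_mesh`` onto ``target_mesh``.

    Keeps the best ``trim`` fraction of correspondences each iteration,
    stops when the RMS change drops below ``tol`` mm, and raises if the RMS
    grows five iterations in a row (divergence). Returns (transform, RMS).
    """
    tf = init or RigidTransform.identity()
    rng = np.random.default_rng(seed)
    src, _ = trimesh.sample.sample_surface(source_mesh, n_samples, seed=int(rng.integers(2**31)))
    src = np.asarray(src)
    tq = MeshQuery(target_mesh)
    normals = np.asarray(target_mesh.face_normals)

    diag = float(np.linalg.norm(source_mesh.extents))
    prev_rms = np.inf
    grow = 0
    for it in range(max_iterations):
        cur = tf.apply(src)
        d, cp, tri = tq.closest(cur, return_tri=True)
        if it == 0 and float(np.median(d)) > 0.5 * diag:
            raise ValueError("insufficient initial overlap between the meshes")
        keep = np.argsort(d)[: max(int(np.ceil(trim * len(d))), 6)]
        p = cur[keep]
        q = cp[keep]
        n = normals[tri[keep]]
        rms = float(np.sqrt(np.mean(d[keep] ** 2)))
        if rms > prev_rms + 1e-12:
            grow += 1
            if grow >= 5:
                raise RuntimeError("ICP diverging: residual grew 5 consecutive iterations")
        else:
            grow = 0
        if abs(prev_rms - rms) < tol:
            prev_rms = rms
            break
        prev_rms = rms
        # linearized point-to-plane: minimize sum(((p + w x p + t - q) . n)^2)
        c = np.cross(p, n)
        A = np.hstack([c, n])                      # (m, 6)
        b = -np.einsum("ij,ij->i", p - q, n)
        x, *_ = np.linalg.lstsq(A, b, rcond=None)
        w, t = x[:3], x[3:]
        R = _rotation_from_small_angles(w)
        tf = RigidTransform(R, R @ np.zeros(3) + t).compose(tf)
    if not np.isfinite(prev_rms):
        raise RuntimeError("ICP produced no valid residual")
    return tf, prev_rms


def _rotation_from_small_angles(w: np.ndarray) -> np.ndarray:
    """Exact rotation for the linearized axis-angle update ``w``."""
    theta = np.linalg.norm(w)
    if theta < 1e-14:
        return np.eye(3)
    a = w / theta
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)
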