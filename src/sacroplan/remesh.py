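"""Incremental isotropic surface remeshing with feature preservation.

The classic split / collapse / flip / tangential-relax loop: edges longer
than 4/3 of the target are split at their midpoint, edges shorter than 4/5
are collapsed, flips equalize vertex valences, and vertices are relaxed and
re-projected onto the input surface. Edges whose dihedral angle exceeds the
sharp-angle threshold are feature constraints: feature vertices move only
along their feature polyline (and are re-projected onto the input feature
segments), corner vertices (feature valence != 2) never move. This keeps
e.g. the 90-degree edges of a box exactly in place while the rest of the
surface is made uniform.
"""

from __future__ import annotations

import numpy as np

import trimesh

from .meshquery import MeshQuery

__all__ = ["isotropic_remesh", "detect_feature_edges"]

FREE, FEATURE, CORNER = 0, 1, 2


def detect_feature_edges(mesh: trimesh.Trimesh, sharp_angle_deg: float) -> np.ndarray:
    """Vertex-index pairs of edges with dihedral above the threshold."""
    ang = mesh.face_adjacency_angles  # 0 for coplanar neighbours
    sharp = ang > np.deg2rad(sharp_angle_deg) - 1e-9
    return np.asarray(mesh.face_adjacency_edges)[sharp]


def isotropic_remesh(mesh: trimesh.Trimesh, target: float, sharp_angle_deg: float = 60.0,
                     iterations: int = 10) -> trimesh.Trimesh:
    rm = _Remesher(mesh, target, sharp_angle_deg)
    for i in range(iterations):
        ops = rm.split_pass() + rm.collapse_pass()
        rm.flip_pass()
        rm.smooth_pass()
        if ops == 0 and i >= 2:
            break
    return rm.build()


class _Remesher:
    def __init__(self, mesh: trimesh.Trimesh, target: float, sharp_angle_deg: float):
        self.target = float(target)
        self.hi = 4.0 / 3.0 * self.target
        self.lo = 4.0 / 5.0 * self.target
        self.query = MeshQuery(mesh)
        self.V: list[np.ndarray] = [np.array(v, float) for v in mesh.vertices]
        self.F: list[list[int]] = [list(f) for f in mesh.faces]
        self.alive: list[bool] = [True] * len(self.F)
        self.v2f: dict[int, set[int]] = {}
        for fi, f in enumerate(self.F):
            for v in f:
                self.v2f.setdefault(v, set()).add(fi)
        feat = detect_feature_edges(mesh, sharp_angle_deg)
        self.fedges: set[frozenset] = {frozenset(map(int, e)) for e in feat}
        self.vflag = np.zeros(len(self.V), int)
        deg = np.zeros(len(self.V), int)
        for e in self.fedges:
            for v in e:
                deg[v] += 1
        self.vflag[deg > 0] = FEATURE
        self.vflag[(deg > 0) & (deg != 2)] = CORNER
        # original feature polyline segments, for re-projection
        self.feat_segs = (np.asarray(mesh.vertices)[feat] if len(feat)
                          else np.zeros((0, 2, 3)))

    # -- helpers -----------------------------------------------------------

    def _edges(self) -> dict[frozenset, list[int]]:
        e2f: dict[frozenset, list[int]] = {}
        for fi, ok in enumerate(self.alive):
            if not ok:
                continue
            a, b, c = self.F[fi]
            for e in (frozenset((a, b)), frozenset((b, c)), frozenset((c, a))):
                e2f.setdefault(e, []).append(fi)
        return e2f

    def _len(self, e) -> float:
        a, b = tuple(e)
        return float(np.linalg.norm(self.V[a] - self.V[b]))

    def _add_vertex(self, pos: np.ndarray, flag: int) -> int:
        self.V.append(np.asarray(pos, float))
        self.vflag = np.append(self.vflag, flag)
        return len(self.V) - 1

    def _add_face(self, f: list[int]) -> int:
        self.F.append(f)
        self.alive.append(True)
        fi = len(self.F) - 1
        for v in f:
            self.v2f.setdefault(v, set()).add(fi)
        return fi

    def _kill_face(self, fi: int) -> None:
        self.alive[fi] = False
        for v in self.F[fi]:
            self.v2f.get(v, set()).discard(fi)

    def _alive_faces(self) -> int:
        return sum(self.alive)

    # -- passes ------------------------------------------------------------

    def split_pass(self) -> int:
        e2f = self._edges()
        created: set[int] = set()
        n_ops = 0
        for e, faces in sorted(e2f.items(), key=lambda kv: -self._len(kv[0])):
            if self._len(e) <= self.hi or len(faces) != 2:
                continue
            if any(not self.alive[fi] or fi in created for fi in faces):
                continue
            a, b = tuple(e)
            is_feat = e in self.fedges
            m = self._add_vertex(0.5 * (self.V[a] + self.V[b]),
                                 FEATURE if is_feat else FREE)
            if is_feat:
                self.fedges.discard(e)
                self.fedges.add(frozenset((a, m)))
                self.fedges.add(frozenset((m, b)))
            for fi in faces:
                fa = self.F[fi]
                i = next(k for k in range(3) if {fa[k], fa[(k + 1) % 3]} == {a, b})
                p, q, r = fa[i], fa[(i + 1) % 3], fa[(i + 2) % 3]
                self._kill_face(fi)
                created.add(self._add_face([p, m, r]))
                created.add(self._add_face([m, q, r]))
            n_ops += 1
        return n_ops

    def collapse_pass(self) -> int:
        candidates = sorted(self._edges(), key=self._len)
        n_alive = self._alive_faces()
        n_ops = 0
        for e in candidates:
            if n_alive <= 8:
                break
            a, b = tuple(e)
            faces = [fi for fi in self.v2f.get(a, set()) & self.v2f.get(b, set())
                     if self.alive[fi]]
            if len(faces) != 2 or self._len(e) >= self.lo:
                continue
            if not (self.v2f.get(a) and self.v2f.get(b)):
                continue
            fa_, fb_ = self.vflag[a], self.vflag[b]
            is_feat = e in self.fedges
            if is_feat:
                if fa_ == CORNER and fb_ == CORNER:
                    continue
                if fa_ == CORNER:
                    keep, drop, pos = a, b, self.V[a]
                elif fb_ == CORNER:
                    keep, drop, pos = b, a, self.V[b]
                else:
                    keep, drop, pos = a, b, 0.5 * (self.V[a] + self.V[b])
            else:
                if fa_ != FREE and fb_ != FREE:
                    continue  # would pinch two separate features together
                if fa_ != FREE:
                    keep, drop, pos = a, b, self.V[a]
                elif fb_ != FREE:
                    keep, drop, pos = b, a, self.V[b]
                else:
                    keep, drop, pos = a, b, 0.5 * (self.V[a] + self.V[b])
            # link condition: one-rings share exactly the two opposite vertices
            na = {v for fi in self.v2f[a] for v in self.F[fi]} - {a}
            nb = {v for fi in self.v2f[b] for v in self.F[fi]} - {b}
            opp = {v for fi in faces for v in self.F[fi]} - {a, b}
            if na & nb != opp:
                continue
            # geometric guard: no degenerate or flipped surviving triangle
            ok = True
            touched = (self.v2f[a] | self.v2f[b]) - set(faces)
            for fi in touched:
                if not self.alive[fi]:
                    continue
                old = [self.V[v] for v in self.F[fi]]
                new = [pos if v in (a, b) else self.V[v] for v in self.F[fi]]
                n_old = np.cross(old[1] - old[0], old[2] - old[0])
                n_new = np.cross(new[1] - new[0], new[2] - new[0])
                if np.linalg.norm(n_new) < 1e-12 or np.dot(n_old, n_new) <= 0:
                    ok = False
                    break
            if not ok:
                continue
            # apply
            self.V[keep] = pos
            for fi in faces:
                self._kill_face(fi)
            for fi in list(self.v2f.get(drop, set())):
                f = self.F[fi]
                self.v2f[drop].discard(fi)
                self.F[fi] = [keep if v == drop else v for v in f]
                self.v2f.setdefault(keep, set()).add(fi)
            # update feature edge set
            if self.fedges:
                updated = set()
                for fe in self.fedges:
                    if drop in fe:
                        other = next(iter(fe - {drop}))
                        if other != keep:
                            updated.add(frozenset((keep, other)))
                    else:
                        updated.add(fe)
                self.fedges = updated
            n_alive -= 2
            n_ops += 1
        return n_ops

    def flip_pass(self) -> None:
        val = self._valences()
        for e in list(self._edges()):
            if e in self.fedges:
                continue
            a, b = tuple(e)
            faces = [fi for fi in self.v2f.get(a, set()) & self.v2f.get(b, set())
                     if self.alive[fi]]
            if len(faces) != 2:
                continue
            opp = [next(v for v in self.F[fi] if v not in e) for fi in faces]
            c, d = opp
            if c == d:
                continue
            if any(self.alive[fi] for fi in self.v2f.get(c, set()) & self.v2f.get(d, set())):
                continue  # edge (c, d) already exists
            before = sum(abs(val[v] - 6) for v in (a, b, c, d))
            after = (abs(val[a] - 1 - 6) + abs(val[b] - 1 - 6)
                     + abs(val[c] + 1 - 6) + abs(val[d] + 1 - 6))
            if after >= before:
                continue
            f0, f1 = faces
            n_old = sum(np.cross(self.V[self.F[fi][1]] - self.V[self.F[fi][0]],
                                 self.V[self.F[fi][2]] - self.V[self.F[fi][0]])
                        for fi in faces)
            # orientation-consistent flip: f0 = (a,b,c) order unknown; rebuild
            fa = self.F[f0]
            i = next(k for k in range(3) if {fa[k], fa[(k + 1) % 3]} == {a, b})
            p, q = fa[i], fa[(i + 1) % 3]  # directed edge p->q in f0, opposite c
            c = fa[(i + 2) % 3]
            d = next(v for v in self.F[f1] if v not in (p, q))
            new0 = [p, d, c]
            new1 = [d, q, c]
            n0 = np.cross(self.V[new0[1]] - self.V[new0[0]], self.V[new0[2]] - self.V[new0[0]])
            n1 = np.cross(self.V[new1[1]] - self.V[new1[0]], self.V[new1[2]] - self.V[new1[0]])
            if (np.linalg.norm(n0) < 1e-12 or np.linalg.norm(n1) < 1e-12
                    or np.dot(n0, n_old) <= 0 or np.dot(n1, n_old) <= 0):
                continue
            self._kill_face(f0)
            self._kill_face(f1)
            self._add_face(new0)
            self._add_face(new1)
            val[a] -= 1
            val[b] -= 1
            val[c] += 1
            val[d] += 1

    def smooth_pass(self, relax: float = 0.5) -> None:
        nbrs: dict[int, set[int]] = {}
        for fi, ok in enumerate(self.alive):
            if not ok:
                continue
            a, b, c = self.F[fi]
            nbrs.setdefault(a, set()).update((b, c))
            nbrs.setdefault(b, set()).update((a, c))
            nbrs.setdefault(c, set()).update((a, b))
        free_idx, free_pos = [], []
        feat_idx, feat_pos = [], []
        for v, nb in nbrs.items():
            flag = self.vflag[v]
            if flag == CORNER or not nb:
                continue
            if flag == FEATURE:
                fnb = [u for u in nb if frozenset((v, u)) in self.fedges]
                if len(fnb) != 2:
                    continue
                cent = 0.5 * (self.V[fnb[0]] + self.V[fnb[1]])
                feat_idx.append(v)
                feat_pos.append(self.V[v] + relax * (cent - self.V[v]))
            else:
                cent = np.mean([self.V[u] for u in nb], axis=0)
                free_idx.append(v)
                free_pos.append(self.V[v] + relax * (cent - self.V[v]))
        if free_idx:
            _, proj = self.query.closest(np.asarray(free_pos))
            for v, p in zip(free_idx, proj):
                self.V[v] = p
        if feat_idx and len(self.feat_segs):
            proj = _project_to_segments(np.asarray(feat_pos), self.feat_segs)
            for v, p in zip(feat_idx, proj):
                self.V[v] = p

    def _valences(self) -> dict[int, int]:
        val: dict[int, int] = {}
        for e in self._edges():
            for v in e:
                val[v] = val.get(v, 0) + 1
        return val

    def build(self) -> trimesh.Trimesh:
        faces = [self.F[fi] for fi, ok in enumerate(self.alive) if ok]
        used = sorted({v for f in faces for v in f})
        remap = {v: i for i, v in enumerate(used)}
        verts = np.asarray([self.V[v] for v in used])
        out = trimesh.Trimesh(verts, np.asarray([[remap[v] for v in f] for f in faces]),
                              process=False)
        trimesh.repair.fix_normals(out)
        if out.is_watertight and out.volume < 0:
            out.invert()
        return out


def _project_to_segments(points: np.ndarray, segs: np.ndarray) -> np.ndarray:
    """Closest point on any of the segments, per query point."""
    p0 = segs[:, 0]
    d = segs[:, 1] - segs[:, 0]
    L2 = np.einsum("ij,ij->i", d, d)
    out = np.empty_like(points)
    for i, p in enumerate(points):
        t = np.clip(np.einsum("ij,ij->i", p[None] - p0, d) / np.maximum(L2, 1e-18), 0, 1)
        cand = p0 + t[:, None] * d
        j = np.argmin(np.linalg.norm(cand - p, axis=1))
        out[i] = cand[j]
    return out
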