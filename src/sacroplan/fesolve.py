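"""Linear-elastic statics on 10-node tetrahedra.

Straight-edged isoparametric tet10 elements (midside nodes at edge
midpoints, so the Jacobian is constant per element), 4-point Gauss
quadrature, sparse symmetric assembly and a direct solve. Pull-out
stiffness is the applied load magnitude divided by the mean displacement
magnitude of the screw-head measurement nodes.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .femesh import NodeSets, TetMesh

__all__ = ["LoadCase", "FEResult", "solve_static", "compute_stiffness",
           "convergence_sweep", "export_inp", "read_inp"]

# 4-point rule on the tetrahedron (degree 2), barycentric coordinates
_QA = 0.5854101966249685
_QB = 0.1381966011250105
_GAUSS = np.array([
    [_QA, _QB, _QB, _QB],
    [_QB, _QA, _QB, _QB],
    [_QB, _QB, _QA, _QB],
    [_QB, _QB, _QB, _QA],
])
_WEIGHTS = np.full(4, 0.25)


def _shape_gradients_natural() -> np.ndarray:
    """d N_i / d (xi, eta, zeta) at the 4 Gauss points -> (4, 10, 3).

    Natural coordinates (xi, eta, zeta) = (L2, L3, L4); L1 = 1 - xi - eta - zeta.
    Corner i: N = L_i (2 L_i - 1); midside on (a, b): N = 4 L_a L_b with the
    C3D10 edge order (12, 23, 31, 14, 24, 34).
    """
    out = np.zeros((4, 10, 3))
    dL = np.array([[-1.0, -1.0, -1.0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])  # dL_i/dg
    edge = [(0, 1), (1, 2), (2, 0), (0, 3), (1, 3), (2, 3)]
    for g, L in enumerate(_GAUSS):
        for i in range(4):
            out[g, i] = (4 * L[i] - 1) * dL[i]
        for e, (a, b) in enumerate(edge):
            out[g, 4 + e] = 4 * (L[a] * dL[b] + L[b] * dL[a])
    return out


_DNDG = _shape_gradients_natural()


@dataclass
class LoadCase:
    """Total tensile force on the screw head, along the screw axis."""

    magnitude: float = 500.0  # N
    direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ValueError("magnitude must be non-negative")
        d = np.asarray(self.direction, float).reshape(3)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("direction must be nonzero")
        self.direction = d / n


@dataclass
class FEResult:
    displacement: np.ndarray      # (n, 3) mm
    mean_u_head: float            # mm
    stiffness: float              # N/mm
    diagnostics: dict


def assemble_stiffness(mesh: TetMesh, chunk: int = 4000) -> sp.csr_matrix:
    """Global stiffness matrix (3n x 3n) in N/mm (E in MPa, lengths in mm)."""
    if np.any(mesh.young <= 0):
        raise ValueError("all elements need a positive Young's modulus")
    n_nodes = len(mesh.nodes)
    rows, cols, vals = [], [], []
    E = mesh.young
    nu = mesh.poisson_ratio
    lam_all = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu_all = E / (2 * (1 + nu))
    for s in range(0, len(mesh.elements), chunk):
        el = mesh.elements[s:s + chunk]
        c = mesh.nodes[el[:, :4]]
        J = c[:, 1:] - c[:, :1]                      # rows = d x / d g
        detJ = np.linalg.det(J)
        vol = np.abs(detJ) / 6.0
        Jinv = np.linalg.inv(J)
        # x(g) = c0 + g @ J, so dg/dx = J^{-1} and dN/dx = dN/dg @ J^{-T}
        dNdx = np.einsum("gnd,edf->egnf", _DNDG, np.transpose(Jinv, (0, 2, 1)))
        lam = lam_all[s:s + chunk]
        mu = mu_all[s:s + chunk]
        w = vol[:, None] * _WEIGHTS[None, :]        # (e, gp)
        # K block (i,a),(j,b) = sum_gp w [ lam dNi_a dNj_b + mu dNi_b dNj_a
        #                                  + mu delta_ab dNi.dNj ]
        t1 = np.einsum("eg,egia,egjb->eiajb", w, dNdx, dNdx)          # dNi_a dNj_b
        t2 = np.transpose(t1, (0, 1, 4, 3, 2))                        # dNi_b dNj_a
        dot = np.einsum("eg,egic,egjc->eij", w, dNdx, dNdx)
        ke = lam[:, None, None, None, None] * t1 + mu[:, None, None, None, None] * t2
        ke[:, :, 0, :, 0] += mu[:, None, None] * dot
        ke[:, :, 1, :, 1] += mu[:, None, None] * dot
        ke[:, :, 2, :, 2] += mu[:, None, None] * dot
        ke = ke.reshape(len(el), 30, 30)
        dof = (3 * el[:, :, None] + np.arange(3)[None, None, :]).reshape(len(el), 30)
        rows.append(np.repeat(dof, 30, axis=1).ravel())
        cols.append(np.tile(dof, (1, 30)).ravel())
        vals.append(ke.ravel())
    K = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(3 * n_nodes, 3 * n_nodes),
    ).tocsr()
    return K


def solve_static(mesh: TetMesh, sets: NodeSets, load: LoadCase,
                 solver: str = "direct", cg_tol: float = 1e-9,
                 load_distribution: str = "equal") -> FEResult:
    """Static solve of the pull-out load case.

    With ``load_distribution='equal'`` the total force is split equally over
    the ``head_load`` nodes along the load direction (the convention for the
    screw head, whose loaded patch is only figural). ``'consistent'``
    distributes a uniform traction consistently over the boundary faces whose
    nodes all belong to ``head_load`` (for quadratic triangles: zero at
    corners, one third per midside) — the right choice for verification
    problems with an exact uniform-stress solution.
    """
    t0 = time.perf_counter()
    n = len(mesh.nodes)
    fixed_nodes = sets.fixed
    if fixed_nodes.size == 0:
        raise ValueError("no fixed nodes: the system has rigid-body modes")
    K = assemble_stiffness(mesh)
    f = np.zeros(3 * n)
    if load_distribution == "equal":
        per_node = load.magnitude / len(sets.head_load)
        for c in range(3):
            f[3 * sets.head_load + c] = per_node * load.direction[c]
    elif load_distribution == "consistent":
        faces6 = mesh.boundary_faces6()
        in_set = np.isin(faces6, sets.head_load).all(axis=1)
        faces6 = faces6[in_set]
        if len(faces6) == 0:
            raise ValueError("no boundary face lies fully inside head_load")
        v = mesh.nodes[faces6[:, :3]]
        areas = 0.5 * np.linalg.norm(np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1)
        traction = load.magnitude / areas.sum()
        for fa, ar in zip(faces6, areas):
            for mid in fa[3:]:
                for c in range(3):
                    f[3 * mid + c] += traction * ar / 3.0 * load.direction[c]
    else:
        raise ValueError(f"unknown load_distribution {load_distribution!r}")

    fixed_dofs = (3 * fixed_nodes[:, None] + np.arange(3)).ravel()
    free = np.ones(3 * n, bool)
    free[fixed_dofs] = False
    free_idx = np.flatnonzero(free)

    u = np.zeros(3 * n)
    if load.magnitude > 0:
        Kff = K[free_idx][:, free_idx].tocsc()
        ff = f[free_idx]
        if solver == "direct":
            # symmetric-mode minimum-degree ordering: much lower fill than
            # the default COLAMD on these SPD elasticity systems
            lu = spla.splu(Kff, permc_spec="MMD_AT_PLUS_A",
                           options=dict(SymmetricMode=True))
            uf = lu.solve(ff)
        elif solver == "cg":
            ilu = spla.spilu(Kff, drop_tol=1e-5, fill_factor=10)
            M = spla.LinearOperator(Kff.shape, ilu.solve)
            uf, info = spla.cg(Kff, ff, rtol=cg_tol, maxiter=20000, M=M)
            if info != 0:
                raise RuntimeError(f"CG failed to converge (info={info})")
        else:
            raise ValueError(f"unknown solver {solver!r}")
        if not np.all(np.isfinite(uf)):
            raise RuntimeError("singular system: solver returned non-finite values")
        resid = np.linalg.norm(Kff @ uf - ff) / np.linalg.norm(ff)
        if resid > 1e-6:
            raise RuntimeError(f"solve did not converge (relative residual {resid:.2e})")
        u[free_idx] = uf
    else:
        resid = 0.0

    U = u.reshape(n, 3)
    mean_u = float(np.linalg.norm(U[sets.head_measure], axis=1).mean())
    reactions = (K @ u - f).reshape(n, 3)
    diag = {
        "n_elements": len(mesh.elements),
        "n_dof": int(free.sum()),
        "residual": float(resid),
        "wall_time_s": time.perf_counter() - t0,
        "reaction_sum": reactions[fixed_nodes].sum(axis=0),
        "applied_force": load.magnitude * load.direction,
    }
    stiffness = load.magnitude / mean_u if mean_u > 0 else float("nan")
    return FEResult(displacement=U, mean_u_head=mean_u, stiffness=stiffness,
                    diagnostics=diag)


def compute_stiffness(result: FEResult, load: LoadCase) -> float:
    """k = F / mean |u| over the head measurement nodes (N/mm)."""
    if load.magnitude > 0 and result.mean_u_head == 0:
        raise ValueError("zero head displacement under load: model is over-constrained")
    if result.mean_u_head == 0:
        return float("nan")
    return load.magnitude / result.mean_u_head


def convergence_sweep(model_factory, sizes, load: LoadCase, tol: float = 0.02):
    """h-refinement study over element sizes (mm).

    ``model_factory(size) -> (TetMesh, NodeSets)`` builds the model at one
    size. Returns a DataFrame (one row per size, coarse to fine) and marks
    convergence when the relative change of mean head displacement between
    consecutive refinements drops below ``tol``. Failures are recorded and
    the sweep continues.
    """
    import pandas as pd

    if len(sizes) < 2:
        raise ValueError("need at least two sizes")
    rows = []
    for size in sorted(sizes, reverse=True):
        try:
            mesh, sets = model_factory(size)
            res = solve_static(mesh, sets, load)
            rows.append({"size_mm": size, "n_elements": len(mesh.elements),
                         "n_dof": res.diagnostics["n_dof"],
                         "mean_u_head_mm": res.mean_u_head,
                         "stiffness_n_per_mm": res.stiffness,
                         "solve_time_s": res.diagnostics["wall_time_s"],
                         "error": ""})
        except Exception as exc:  # recorded, sweep continues
            rows.append({"size_mm": size, "n_elements": np.nan, "n_dof": np.nan,
                         "mean_u_head_mm": np.nan, "stiffness_n_per_mm": np.nan,
                         "solve_time_s": np.nan, "error": str(exc)})
    df = pd.DataFrame(rows)
    conv = np.full(len(df), False)
    u = df["mean_u_head_mm"].to_numpy()
    for i in range(1, len(df)):
        if np.isfinite(u[i]) and np.isfinite(u[i - 1]) and u[i - 1] != 0:
            conv[i] = abs(u[i] - u[i - 1]) / abs(u[i - 1]) < tol
    df["converged"] = conv
    return df


# -- Abaqus INP export ------------------------------------------------------

def export_inp(mesh: TetMesh, sets: NodeSets, load: LoadCase, path) -> None:
    """Write the model as an Abaqus input deck (C3D10) for cross-validation.

    Elements are grouped into material bins by Young's modulus rounded to 6
    significant digits (export only; the in-memory model keeps per-element
    values).
    """
    def sig6(x: float) -> float:
        return float(f"{x:.6g}")

    keys = [(sig6(e), round(float(nu), 6)) for e, nu in zip(mesh.young, mesh.poisson_ratio)]
    bins: dict[tuple, list[int]] = {}
    for i, k in enumerate(keys):
        bins.setdefault(k, []).append(i)

    with open(path, "w") as fh:
        fh.write("*HEADING\nsacroplan pull-out model\n")
        fh.write("*NODE\n")
        for i, (x, y, z) in enumerate(mesh.nodes, start=1):
            fh.write(f"{i}, {x:.9g}, {y:.9g}, {z:.9g}\n")
        for b, (key, els) in enumerate(sorted(bins.items()), start=1):
            fh.write(f"*ELEMENT, TYPE=C3D10, ELSET=MAT{b}\n")
            for e in els:
                conn = ", ".join(str(v + 1) for v in mesh.elements[e])
                fh.write(f"{e + 1}, {conn}\n")
        for b, (key, _els) in enumerate(sorted(bins.items()), start=1):
            fh.write(f"*MATERIAL, NAME=MAT{b}\n*ELASTIC\n{key[0]:.6g}, {key[1]}\n")
            fh.write(f"*SOLID SECTION, ELSET=MAT{b}, MATERIAL=MAT{b}\n")
        for name, nodes in [("FIXED", sets.fixed), ("HEADLOAD", sets.head_load),
                            ("HEADMEAS", sets.head_measure)]:
            fh.write(f"*NSET, NSET={name}\n")
            ids = [str(v + 1) for v in nodes]
            for i in range(0, len(ids), 8):
                fh.write(", ".join(ids[i:i + 8]) + "\n")
        fh.write("*BOUNDARY\nFIXED, 1, 3, 0.\n")
        fh.write("*STEP\n*STATIC\n*CLOAD\n")
        per = load.magnitude / len(sets.head_load)
        for c in range(3):
            comp = per * load.direction[c]
            if comp != 0:
                fh.write(f"HEADLOAD, {c + 1}, {comp:.9g}\n")
        fh.write("*END STEP\n")


def read_inp(path) -> tuple[np.ndarray, np.ndarray]:
    """Parse *NODE and *ELEMENT blocks back (round-trip check)."""
    nodes, elements = [], []
    mode = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("*"):
                up = line.upper()
                if up.startswith("*NODE"):
                    mode = "node"
                elif up.startswith("*ELEMENT"):
                    mode = "elem"
                else:
                    mode = None
                continue
            if not line:
                continue
            parts = [p.strip() for p in line.split(",")]
            if mode == "node":
                nodes.append([float(v) for v in parts[1:4]])
            elif mode == "elem":
                elements.append([int(v) - 1 for v in parts[1:]])
    return np.asarray(nodes), np.asarray(elements, int)
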