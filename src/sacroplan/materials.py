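"""QCT calibration and density-elasticity material mapping.

The two-step mapping used throughout quantitative-CT bone modelling:

1. HU -> apparent density (g/cm^3), a linear law calibrated against the
   in-scan phantom rods of known equivalent BMD. The clinical reference fit
   is rho_app = -0.0829 + 0.0026 * HU.
2. apparent density -> Young's modulus (MPa) via the Kopperdahl-type
   correlation E = -34.7 + 3230 * rho_app, with Poisson's ratio 0.3.

Because the modulus law crosses zero near rho_app ~ 0.0107 g/cm^3, mapped
moduli are clamped below at ``e_min`` to keep the assembled stiffness matrix
positive definite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "LinearLaw",
    "DensityModulusModel",
    "CalibrationSamples",
    "SCREW_E_MPA",
    "SCREW_POISSON",
    "sample_rods",
    "fit_hu_to_density",
    "density_to_modulus",
    "assign_element_materials",
]

#: titanium-alloy implant elastic constants used for all screw elements
SCREW_E_MPA = 114_000.0
SCREW_POISSON = 0.3

#: reference clinical HU->density calibration (g/cm^3 per HU)
REFERENCE_HU_TO_DENSITY = None  # set below, after LinearLaw definition
#: reference trabecular density->modulus correlation (MPa per g/cm^3)
REFERENCE_DENSITY_TO_MODULUS = None


@dataclass(frozen=True)
class LinearLaw:
    """y = intercept + slope * x with unit-carrying labels."""

    intercept: float
    slope: float
    input_name: str = "x"
    output_name: str = "y"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.intercept) and np.isfinite(self.slope)):
            raise ValueError("law coefficients must be finite")

    def __call__(self, x):
        return self.intercept + self.slope * np.asarray(x, float)

    def inverse(self) -> "LinearLaw":
        if self.slope == 0:
            raise ValueError("law is not invertible (zero slope)")
        return LinearLaw(-self.intercept / self.slope, 1.0 / self.slope,
                         self.output_name, self.input_name)

    def to_dict(self) -> dict:
        return {"intercept": self.intercept, "slope": self.slope,
                "input": self.input_name, "output": self.output_name}

    @classmethod
    def from_dict(cls, d: dict) -> "LinearLaw":
        return cls(d["intercept"], d["slope"], d.get("input", "x"), d.get("output", "y"))


REFERENCE_HU_TO_DENSITY = LinearLaw(-0.0829, 0.0026, "HU", "rho_app[g/cm3]")
REFERENCE_DENSITY_TO_MODULUS = LinearLaw(-34.7, 3230.0, "rho_app[g/cm3]", "E[MPa]")


@dataclass
class DensityModulusModel:
    """The full HU -> density -> modulus chain with clamping policy."""

    hu_to_density: LinearLaw = REFERENCE_HU_TO_DENSITY
    density_to_modulus: LinearLaw = REFERENCE_DENSITY_TO_MODULUS
    e_min: float = 0.01  # MPa floor; keeps K positive definite
    poisson: float = 0.3

    def __post_init__(self) -> None:
        if self.e_min <= 0:
            raise ValueError("e_min must be positive")
        if not 0 < self.poisson < 0.5:
            raise ValueError("poisson must be in (0, 0.5)")

    def modulus_from_hu(self, hu) -> np.ndarray:
        e, _ = density_to_modulus(self, self.hu_to_density(hu))
        return e

    def to_dict(self) -> dict:
        return {"hu_to_density": self.hu_to_density.to_dict(),
                "density_to_modulus": self.density_to_modulus.to_dict(),
                "e_min": self.e_min, "poisson": self.poisson}

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "DensityModulusModel":
        d = json.loads(Path(path).read_text())
        return cls(LinearLaw.from_dict(d["hu_to_density"]),
                   LinearLaw.from_dict(d["density_to_modulus"]),
                   d["e_min"], d["poisson"])


@dataclass
class CalibrationSamples:
    """Per-rod (mean HU, known density) pairs from the calibration phantom."""

    mean_hu: np.ndarray
    known_density: np.ndarray
    voxel_counts: np.ndarray

    def __post_init__(self) -> None:
        self.mean_hu = np.asarray(self.mean_hu, float)
        self.known_density = np.asarray(self.known_density, float)
        self.voxel_counts = np.asarray(self.voxel_counts, int)
        if len(self.mean_hu) < 2:
            raise ValueError("need at least two rods")


def sample_rods(volume, rod_geometry, erode_voxels: int = 1) -> CalibrationSamples:
    """Mean HU over the eroded interior of each calibration rod.

    ``rod_geometry`` is a sequence of ``(center, axis, radius, length, density)``
    tuples in mm / g/cm^3 (as recorded in ``PhantomTruth.rods``). Eroding the
    nominal radius by ``erode_voxels`` voxel widths keeps partial-volume
    voxels at the rod wall out of the mean.
    """
    cx, cy, cz = volume.voxel_centers()
    X, Y, Z = np.meshgrid(cx, cy, cz, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)
    erode_mm = erode_voxels * float(np.max(volume.spacing))
    means, dens, counts = [], [], []
    for center, axis, radius, length, density in rod_geometry:
        c = np.asarray(center, float)
        a = np.asarray(axis, float)
        a = a / np.linalg.norm(a)
        v = pts - c
        t = v @ a
        r = np.linalg.norm(v - t[..., None] * a, axis=-1)
        mask = (r <= radius - erode_mm) & (np.abs(t) <= length / 2 - erode_mm)
        if not mask.any():
            raise ValueError(f"rod at {center} has an empty eroded interior")
        means.append(float(volume.voxels[mask].mean()))
        dens.append(float(density))
        counts.append(int(mask.sum()))
    return CalibrationSamples(np.array(means), np.array(dens), np.array(counts))


def fit_hu_to_density(samples: CalibrationSamples) -> tuple[LinearLaw, dict]:
    """Ordinary least-squares line density = a + b * HU, with R^2 diagnostics."""
    x = samples.mean_hu
    y = samples.known_density
    if len(np.unique(x)) < 2:
        raise ValueError("rod mean HU values are degenerate (all equal)")
    A = np.column_stack([np.ones_like(x), x])
    coef, res, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < 2:
        raise ValueError("degenerate calibration: rod HU values do not span a line")
    yhat = A @ coef
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    law = LinearLaw(float(coef[0]), float(coef[1]), "HU", "rho_app[g/cm3]")
    return law, {"r_squared": r2, "rmse": float(np.sqrt(ss_res / len(x))), "n_rods": len(x)}


def density_to_modulus(model: DensityModulusModel, rho) -> tuple[np.ndarray, np.ndarray]:
    """Map apparent density to Young's modulus, clamped below at ``model.e_min``.

    Returns ``(E_MPa, clamped)`` where ``clamped`` flags values that hit the floor.
    """
    raw = model.density_to_modulus(rho)
    clamped = raw < model.e_min
    return np.where(clamped, model.e_min, raw), clamped


def assign_element_materials(mesh, volume, model: DensityModulusModel,
                             metal_hu: float = 2000.0, air_hu: float = 0.0,
                             strategy: str = "voxel_mean"):
    """Per-element modulus assignment from the calibrated volume.

    Bone elements get ``E = model(mean HU)`` over the voxels whose centres fall
    inside the element (tet4 hull of the corner nodes); elements containing no
    voxel centre fall back to trilinear interpolation at the centroid. Voxels
    at or above ``metal_hu`` are excluded from bone means so implant metal
    does not inflate neighbouring bone stiffness; voxels below ``air_hu``
    (air / soft tissue outside the bone) are excluded so surface elements are
    not diluted towards zero density. Screw/fragment elements get the implant
    constants regardless of HU.

    Returns the mesh (modified in place) and a per-element report dict.
    """
    import pandas as pd

    if strategy not in {"voxel_mean", "centroid"}:
        raise ValueError(f"unknown strategy {strategy!r}")

    corners = mesh.nodes[mesh.elements[:, :4]]  # (ne, 4, 3)
    centroids = corners.mean(axis=1)
    vlo = volume.origin - 0.5 * volume.spacing
    vhi = volume.origin + (np.array(volume.shape) - 0.5) * volume.spacing
    # coarse grids may overhang the scan by part of a cell; only an element
    # whose centroid leaves the volume is unmappable
    bad = np.flatnonzero(np.any(centroids < vlo - 1e-6, axis=1)
                         | np.any(centroids > vhi + 1e-6, axis=1))
    if bad.size:
        raise ValueError(f"elements outside the volume bounds: {bad[:20].tolist()}"
                         + ("..." if bad.size > 20 else ""))
    hu_elem = np.empty(len(mesh.elements))
    n_vox = np.zeros(len(mesh.elements), int)

    if strategy == "voxel_mean":
        cx, cy, cz = volume.voxel_centers()
        hu = volume.voxels
        excluded = (hu >= metal_hu) | (hu < air_hu)
        for e in range(len(mesh.elements)):
            c = corners[e]
            i0 = np.searchsorted(cx, c[:, 0].min() - 1e-9)
            i1 = np.searchsorted(cx, c[:, 0].max() + 1e-9)
            j0 = np.searchsorted(cy, c[:, 1].min() - 1e-9)
            j1 = np.searchsorted(cy, c[:, 1].max() + 1e-9)
            k0 = np.searchsorted(cz, c[:, 2].min() - 1e-9)
            k1 = np.searchsorted(cz, c[:, 2].max() + 1e-9)
            if i1 <= i0 or j1 <= j0 or k1 <= k0:
                continue
            gx, gy, gz = np.meshgrid(cx[i0:i1], cy[j0:j1], cz[k0:k1], indexing="ij")
            p = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
            inside = _points_in_tet(p, c)
            ok = inside & ~excluded[i0:i1, j0:j1, k0:k1].reshape(-1)
            if ok.any():
                hu_elem[e] = hu[i0:i1, j0:j1, k0:k1].reshape(-1)[ok].mean()
                n_vox[e] = int(ok.sum())
    # centroid fallback (and the whole 'centroid' strategy)
    need = n_vox == 0 if strategy == "voxel_mean" else np.ones(len(mesh.elements), bool)
    if need.any():
        hu_elem[need] = volume.sample_at(centroids[need])

    rho = model.hu_to_density(hu_elem)
    e_mapped, clamped = density_to_modulus(model, rho)

    is_bone = mesh.part_labels == "bone"
    mesh.young = np.where(is_bone, e_mapped, SCREW_E_MPA)
    mesh.poisson_ratio = np.where(is_bone, model.poisson, SCREW_POISSON)

    report = pd.DataFrame({
        "element": np.arange(len(mesh.elements)),
        "part": mesh.part_labels,
        "mean_hu": hu_elem,
        "rho_app": rho,
        "E_MPa": mesh.young,
        "clamped": np.where(is_bone, clamped, False),
        "n_voxels": n_vox,
    })
    return mesh, report


def _points_in_tet(p: np.ndarray, tet: np.ndarray) -> np.ndarray:
    """Vectorized barycentric containment of points in one tetrahedron."""
    T = np.column_stack([tet[1] - tet[0], tet[2] - tet[0], tet[3] - tet[0]])
    try:
        lam = np.linalg.solve(T, (p - tet[0]).T).T
    except np.linalg.LinAlgError:
        return np.zeros(len(p), bool)
    s = lam.sum(axis=1)
    return (lam >= -1e-12).all(axis=1) & (s <= 1 + 1e-12)
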