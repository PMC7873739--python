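"""Rigid transforms and 3D lines (screw/drill axes)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RigidTransform", "Line3D", "rotation_about_axis"]


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (not necessarily unit) axis."""
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    th = np.deg2rad(angle_deg)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t in mm."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, float).reshape(3, 3)
        self.translation = np.asarray(self.translation, float).reshape(3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det = +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation

    def apply_vector(self, vec: np.ndarray) -> np.ndarray:
        return np.asarray(vec, float) @ self.rotation.T

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self ∘ other (apply ``other`` first)."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_axis_angle(cls, axis, angle_deg: float, translation=(0.0, 0.0, 0.0),
                        center=None) -> "RigidTransform":
        R = rotation_about_axis(axis, angle_deg)
        t = np.asarray(translation, float)
        if center is not None:
            c = np.asarray(center, float)
            t = t + c - R @ c
        return cls(R, t)

    @classmethod
    def random(cls, rng: np.random.Generator, max_angle_deg: float = 30.0,
               max_translation: float = 20.0) -> "RigidTransform":
        axis = rng.normal(size=3)
        angle = rng.uniform(-max_angle_deg, max_angle_deg)
        t = rng.uniform(-max_translation, max_translation, size=3)
        return cls.from_axis_angle(axis, angle, t)


@dataclass
class Line3D:
    """Infinite line through ``point`` along unit ``direction`` (v and -v equivalent)."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, float).reshape(3)
        d = np.asarray(self.direction, float).reshape(3)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("direction must be nonzero")
        self.direction = d / n

    def at(self, t) -> np.ndarray:
        return self.point + np.multiply.outer(np.asarray(t, float), self.direction)

    def distance_to_point(self, p: np.ndarray) -> np.ndarray:
        v = np.atleast_2d(p) - self.point
        t = v @ self.direction
        d = np.linalg.norm(v - np.outer(t, self.direction), axis=1)
        return d if np.asarray(p).ndim == 2 else float(d[0])

    def transformed(self, tf: RigidTransform) -> "Line3D":
        return Line3D(tf.apply(self.point), tf.apply_vector(self.direction))
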