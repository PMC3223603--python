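"""Rigid-body transforms (proper rotation + translation)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation


@dataclass(frozen=True)
class RigidTransform:
    """``x -> R x + t`` with R orthonormal, det(R) = +1."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)
        self.validate()

    def validate(self, tol: float = 1e-6) -> None:
        r = self.rotation
        if not np.allclose(r @ r.T, np.eye(3), atol=tol):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(r) < 0:
            raise ValueError("rotation matrix is improper (det < 0)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotvec(cls, rotvec: np.ndarray, translation: np.ndarray) -> "RigidTransform":
        return cls(Rotation.from_rotvec(rotvec).as_matrix(), translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def quaternion(self) -> np.ndarray:
        """Canonical scalar-first quaternion (first nonzero component > 0)."""
        q = Rotation.from_matrix(self.rotation).as_quat()  # x, y, z, w
        q = np.array([q[3], q[0], q[1], q[2]])
        for c in q:
            if abs(c) > 1e-12:
                if c < 0:
                    q = -q
                break
        return q
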