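"""Rigid and affine spatial transforms in world (mm) coordinates.

Transforms map points from a *source* space to a *target* space, e.g. a
DWI->CT rigid transform maps DWI world coordinates onto CT world coordinates.
All transforms are invertible and composable; serialization is a JSON 4x4
homogeneous matrix in mm (RAS convention).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ValidationError

EULER_ORDER = "xyz"  # intrinsic rotations about x, then y, then z


@dataclass
class AffineTransform:
    """General invertible 4x4 homogeneous transform (mm)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValidationError(f"transform matrix must be 4x4, got {self.matrix.shape}")
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ValidationError("transform is not invertible (determinant ~ 0)")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    @classmethod
    def reflection_x(cls, plane_x_mm: float = 0.0) -> "AffineTransform":
        """Reflection about the plane x = ``plane_x_mm``."""
        m = np.eye(4)
        m[0, 0] = -1.0
        m[0, 3] = 2.0 * plane_x_mm
        return cls(m)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]
        return out if np.asarray(points).ndim > 1 else out[0]

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    def compose(self, other: "AffineTransform | RigidTransform") -> "AffineTransform":
        """Return ``self o other`` (``other`` is applied first)."""
        return AffineTransform(self.matrix @ as_matrix(other))

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {"type": "affine", "matrix_mm": self.matrix.tolist(), "convention": "RAS"}

    @classmethod
    def from_dict(cls, d: dict) -> "AffineTransform":
        return cls(np.asarray(d["matrix_mm"], dtype=float))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "AffineTransform":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class RigidTransform:
    """6-DOF rigid transform: rotation (degrees) about a centre, then translation (mm).

    A point ``p`` maps to ``R @ (p - c) + c + t`` with ``R`` the rotation
    matrix for intrinsic x-y-z Euler angles, ``c`` the centre and ``t`` the
    translation.
    """

    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center_mm: tuple[float, float, float] = field(default=(0.0, 0.0, 0.0))

    def __post_init__(self) -> None:
        self.rotation_deg = tuple(float(v) for v in self.rotation_deg)  # type: ignore[assignment]
        self.translation_mm = tuple(float(v) for v in self.translation_mm)  # type: ignore[assignment]
        self.center_mm = tuple(float(v) for v in self.center_mm)  # type: ignore[assignment]
        for name in ("rotation_deg", "translation_mm", "center_mm"):
            if len(getattr(self, name)) != 3:
                raise ValidationError(f"{name} must have 3 components")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @property
    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_euler(EULER_ORDER, self.rotation_deg, degrees=True).as_matrix()

    @property
    def matrix(self) -> np.ndarray:
        r = self.rotation_matrix
        c = np.asarray(self.center_mm)
        t = np.asarray(self.translation_mm)
        m = np.eye(4)
        m[:3, :3] = r
        m[:3, 3] = c + t - r @ c
        return m

    @classmethod
    def from_matrix(cls, matrix: np.ndarray,
                    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> "RigidTransform":
        matrix = np.asarray(matrix, dtype=float)
        r = matrix[:3, :3]
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-5) or np.linalg.det(r) < 0:
            raise ValidationError("matrix is not a proper rotation")
        angles = Rotation.from_matrix(r).as_euler(EULER_ORDER, degrees=True)
        c = np.asarray(center_mm, dtype=float)
        t = matrix[:3, 3] + r @ c - c
        return cls(tuple(angles), tuple(t), tuple(c))

    def as_affine(self) -> AffineTransform:
        return AffineTransform(self.matrix)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.as_affine().apply(points)

    def inverse(self) -> "RigidTransform":
        return RigidTransform.from_matrix(np.linalg.inv(self.matrix), self.center_mm)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        return RigidTransform.from_matrix(self.matrix @ other.matrix, self.center_mm)

    # -- geometry helpers ---------------------------------------------------
    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation (geodesic angle), degrees."""
        return float(Rotation.from_matrix(self.rotation_matrix).magnitude() * 180.0 / np.pi)

    def translation_magnitude_mm(self) -> float:
        return float(np.linalg.norm(self.translation_mm))

    def deviation_from(self, other: "RigidTransform") -> tuple[float, float]:
        """(rotation deg, translation mm) by which ``self`` differs from ``other``.

        The translation part is evaluated as the residual displacement at the
        shared rotation centre, so the two components are decoupled.
        """
        delta = np.linalg.inv(as_matrix(other)) @ self.matrix
        rot = float(Rotation.from_matrix(delta[:3, :3]).magnitude() * 180.0 / np.pi)
        c = np.append(np.asarray(self.center_mm), 1.0)
        trans = float(np.linalg.norm((delta @ c - c)[:3]))
        return rot, trans

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "type": "rigid",
            "rotation_deg": list(self.rotation_deg),
            "translation_mm": list(self.translation_mm),
            "center_mm": list(self.center_mm),
            "matrix_mm": self.matrix.tolist(),
            "convention": "RAS",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            tuple(d["rotation_deg"]), tuple(d["translation_mm"]), tuple(d["center_mm"])
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "RigidTransform":
        return cls.from_dict(json.loads(Path(path).read_text()))


AnyTransform = AffineTransform | RigidTransform


def as_matrix(t: "AnyTransform | np.ndarray") -> np.ndarray:
    """4x4 matrix of a transform (accepts raw matrices for convenience)."""
    if isinstance(t, AffineTransform):
        return t.matrix
    if isinstance(t, RigidTransform):
        return t.matrix
    m = np.asarray(t, dtype=float)
    if m.shape != (4, 4):
        raise ValidationError(f"expected a transform or 4x4 matrix, got shape {m.shape}")
    return m


def load_transform(path: str | Path) -> AnyTransform:
    d = json.loads(Path(path).read_text())
    if d.get("type") == "rigid":
        return RigidTransform.from_dict(d)
    return AffineTransform.from_dict(d)
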