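"""Volumetric image and segmentation-mask containers.

A :class:`VolumeImage` is a 3-D scalar grid together with a 4x4 voxel-to-world
affine (RAS millimetres).  CT volumes carry Hounsfield units; DWI volumes carry
arbitrary signal intensity.  A :class:`SegmentationMask` is a binary grid on
the same geometry with a semantic role (lesion, contralateral, brain,
thalamus).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import AlignmentError, ValidationError

MODALITIES = ("CT", "DWI")
MASK_ROLES = ("lesion", "contralateral", "brain", "thalamus")


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValidationError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValidationError("affine voxel->world matrix is singular")
    return affine


@dataclass
class VolumeImage:
    """3-D scalar volume with physical geometry.

    Parameters
    ----------
    data
        3-D array; HU for CT, arbitrary intensity for DWI.
    affine
        4x4 voxel-index -> world-mm matrix (RAS).
    modality
        ``"CT"`` or ``"DWI"``.
    """

    data: np.ndarray
    affine: np.ndarray
    modality: str = "CT"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(
                f"volume must be 3-D, got {self.data.ndim} dimension(s)"
            )
        self.affine = _check_affine(self.affine)
        if self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality {self.modality!r}")
        if np.any(self.spacing <= 0):
            raise ValidationError("voxel spacing must be positive on all axes")
        d = self.direction
        if not np.allclose(d.T @ d, np.eye(3), atol=1e-6):
            raise ValidationError("orientation matrix is not orthonormal up to sign")

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def origin(self) -> np.ndarray:
        return self.affine[:3, 3].copy()

    @property
    def direction(self) -> np.ndarray:
        """Unit direction-cosine matrix (columns = voxel axes in world space)."""
        return self.affine[:3, :3] / self.spacing

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def ijk_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (N x 3) to world mm coordinates."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def mm_to_ijk(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def corners_mm(self) -> np.ndarray:
        """World coordinates of the 8 grid corners."""
        n = np.array(self.shape) - 1
        ijk = np.array(
            [[i, j, k] for i in (0, n[0]) for j in (0, n[1]) for k in (0, n[2])],
            dtype=float,
        )
        return self.ijk_to_mm(ijk)

    def same_grid_as(self, other: "VolumeImage | SegmentationMask", atol: float = 1e-3) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def with_data(self, data: np.ndarray, modality: str | None = None) -> "VolumeImage":
        return replace(self, data=data, modality=modality or self.modality)


@dataclass
class SegmentationMask:
    """Binary mask aligned to a reference :class:`VolumeImage` grid."""

    data: np.ndarray
    affine: np.ndarray
    role: str = "lesion"
    allow_empty: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValidationError(f"mask must be 3-D, got {arr.ndim} dimension(s)")
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValidationError(
                f"mask values must be in {{0,1}}, found {vals[:5].tolist()}"
            )
        self.data = arr.astype(np.uint8)
        self.affine = _check_affine(self.affine)
        if self.role not in MASK_ROLES:
            raise ValidationError(f"unknown mask role {self.role!r}")
        if not self.allow_empty and self.count == 0:
            raise ValidationError(f"{self.role} mask is empty")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def count(self) -> int:
        return int(self.data.sum())

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def volume_mm3(self) -> float:
        return self.count * float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def volume_cm3(self) -> float:
        return self.volume_mm3 / 1000.0

    def indices(self) -> np.ndarray:
        """Voxel indices (N x 3) of foreground voxels."""
        return np.argwhere(self.data > 0)

    def coords_mm(self) -> np.ndarray:
        """World coordinates (N x 3) of foreground voxel centres."""
        idx = self.indices().astype(float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def check_aligned(self, img: "VolumeImage | SegmentationMask", atol: float = 1e-3) -> None:
        if self.shape != img.shape or not np.allclose(self.affine, img.affine, atol=atol):
            raise AlignmentError(
                f"{self.role} mask grid {self.shape} does not match reference grid {img.shape}"
            )

    def boolean(self) -> np.ndarray:
        return self.data.astype(bool)

    def with_data(self, data: np.ndarray, role: str | None = None,
                  allow_empty: bool | None = None) -> "SegmentationMask":
        return SegmentationMask(
            data=data,
            affine=self.affine,
            role=role or self.role,
            allow_empty=self.allow_empty if allow_empty is None else allow_empty,
        )


def dice(a: SegmentationMask | np.ndarray, b: SegmentationMask | np.ndarray) -> float:
    """Dice overlap coefficient between two binary masks on the same grid."""
    aa = a.boolean() if isinstance(a, SegmentationMask) else np.asarray(a, bool)
    bb = b.boolean() if isinstance(b, SegmentationMask) else np.asarray(b, bool)
    if aa.shape != bb.shape:
        raise AlignmentError(f"mask shapes differ: {aa.shape} vs {bb.shape}")
    denom = aa.sum() + bb.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float(np.logical_and(aa, bb).sum()) / float(denom)
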