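"""Synthetic CT/DWI head phantoms with known ground truth.

The phantom emulates the statistical structure of a thin-slice stroke-CT
cohort with a single unilateral thalamic infarct: a bilaterally symmetric
ellipsoidal brain inside a skull shell, two mirror-symmetric thalami
(default mean attenuation 33.3 HU, within-thalamus texture SD 2.6 HU), and an
ellipsoidal lesion of configurable volume (default 0.35 cm^3) whose
attenuation is reduced by a configurable net-water-uptake fraction.  The DWI
channel shows the same head on its own (typically coarser) grid, rigidly
misaligned from the CT by a known perturbation, with a hyperintense lesion.

Everything is analytic: masks are exact ellipsoid indicators evaluated on the
voxel grid, so downstream contracts (mirroring, registration, NWU recovery)
can be checked against exact ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .images import SegmentationMask, VolumeImage
from .transforms import RigidTransform

# -- fixed head geometry (mm, world origin at brain centre) -----------------
BRAIN_SEMI_AXES = (58.0, 73.0, 48.0)
SKULL_OUTER_SEMI_AXES = (64.0, 79.0, 54.0)
THALAMUS_SEMI_AXES = (8.0, 10.0, 8.0)
THALAMUS_OFFSET_MM = (12.0, -8.0, 0.0)  # lateral, posterior, axial offset

SKULL_HU = 900.0
AIR_HU = -1000.0
DWI_SKULL_INTENSITY = 20.0
DWI_AIR_INTENSITY = 0.0

DEFAULT_GRID_SHAPE = (96, 112, 80)
DEFAULT_VOXEL_MM = 1.5


def thalamus_volume_cm3() -> float:
    a, b, c = THALAMUS_SEMI_AXES
    return 4.0 / 3.0 * math.pi * a * b * c / 1000.0


@dataclass
class PhantomSpec:
    """Parameters of one synthetic case.

    Defaults reproduce the cohort conditions the package targets: 33.3 HU
    contralateral thalamus with 2.6 HU texture, a 0.35 cm^3 lesion, 1 HU CT
    noise, 1.5 mm CT voxels and a 1 x 1 x 3 mm DWI grid.
    """

    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE
    voxel_size_mm: float = DEFAULT_VOXEL_MM
    thalamus_mean_hu: float = 33.3
    thalamus_sd_hu: float = 2.6
    lesion_nwu_pct: float = 10.0
    lesion_volume_cm3: float = 0.35
    noise_sd_hu: float = 1.0
    misalignment: RigidTransform = field(
        default_factory=lambda: RigidTransform((2.0, -2.0, 3.0), (3.0, -2.0, 2.0))
    )
    lesion_side: str = "left"
    seed: int = 0
    brain_mean_hu: float = 30.0
    round_to_int_hu: bool = False
    dwi_voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 3.0)
    dwi_brain_intensity: float = 100.0
    dwi_lesion_intensity: float = 130.0
    dwi_noise_sd: float = 5.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0.0 <= self.lesion_nwu_pct < 100.0):
            raise ValidationError(
                f"lesion_nwu_pct must be in [0, 100), got {self.lesion_nwu_pct}"
            )
        if not self.lesion_volume_cm3 > 0:
            raise ValidationError(
                f"lesion_volume_cm3 must be positive, got {self.lesion_volume_cm3}"
            )
        if self.lesion_volume_cm3 >= thalamus_volume_cm3():
            raise ValidationError(
                "lesion_volume_cm3 must be smaller than one thalamus "
                f"({thalamus_volume_cm3():.2f} cm^3), got {self.lesion_volume_cm3}"
            )
        if self.noise_sd_hu < 0:
            raise ValidationError(f"noise_sd_hu must be >= 0, got {self.noise_sd_hu}")
        if self.thalamus_sd_hu < 0:
            raise ValidationError(f"thalamus_sd_hu must be >= 0, got {self.thalamus_sd_hu}")
        if self.lesion_side not in ("left", "right"):
            raise ValidationError(f"lesion_side must be 'left' or 'right', got {self.lesion_side!r}")
        if len(self.grid_shape) != 3 or any(int(n) < 8 for n in self.grid_shape):
            raise ValidationError(f"grid_shape must be 3 positive sizes, got {self.grid_shape}")
        if self.voxel_size_mm <= 0:
            raise ValidationError(f"voxel_size_mm must be positive, got {self.voxel_size_mm}")
        # the whole head (skull shell) must fit in the field of view …
        fov = np.asarray(self.grid_shape, float) * self.voxel_size_mm
        if np.any(fov / 2.0 < np.asarray(SKULL_OUTER_SEMI_AXES) + self.voxel_size_mm):
            raise ValidationError(
                f"grid_shape {self.grid_shape} at {self.voxel_size_mm} mm cannot contain the "
                f"head (needs half-extent >= {SKULL_OUTER_SEMI_AXES} mm plus one voxel)"
            )
        # … and the thalami must sit well inside the brain at this resolution
        margin = 5.0 * self.voxel_size_mm
        off = np.abs(np.asarray(THALAMUS_OFFSET_MM))
        if np.any(off + np.asarray(THALAMUS_SEMI_AXES) + margin > np.asarray(BRAIN_SEMI_AXES)):
            raise ValidationError(
                "voxel_size_mm too coarse: thalami need a 5-voxel margin to the brain boundary"
            )
        if any(s <= 0 for s in self.dwi_voxel_size_mm):
            raise ValidationError(f"dwi_voxel_size_mm must be positive, got {self.dwi_voxel_size_mm}")
        if self.dwi_lesion_intensity < self.dwi_brain_intensity + 5.0 * self.dwi_noise_sd:
            raise ValidationError(
                "dwi_lesion_intensity must be >= dwi_brain_intensity + 5 x dwi_noise_sd"
            )

    @property
    def lesion_hu(self) -> float:
        return self.thalamus_mean_hu * (1.0 - self.lesion_nwu_pct / 100.0)

    def lesion_semi_axes(self) -> np.ndarray:
        """Lesion ellipsoid semi-axes (mm): thalamus shape scaled to the volume."""
        scale = (self.lesion_volume_cm3 / thalamus_volume_cm3()) ** (1.0 / 3.0)
        return np.asarray(THALAMUS_SEMI_AXES) * scale

    def thalamus_center(self, side: str) -> np.ndarray:
        sign = -1.0 if side == "left" else 1.0
        off = np.asarray(THALAMUS_OFFSET_MM)
        return np.array([sign * abs(off[0]), off[1], off[2]])


@dataclass
class PhantomBundle:
    """One synthetic case: volumes, ground-truth masks, transform and NWU."""

    ct: VolumeImage
    dwi: VolumeImage
    truth_lesion_mask_dwi: SegmentationMask
    truth_lesion_mask_ct: SegmentationMask
    truth_contralateral_mask_ct: SegmentationMask
    truth_brain_mask_ct: SegmentationMask
    truth_transform: RigidTransform  # DWI world -> CT world
    truth_nwu_pct: float
    ct_noise_free: VolumeImage
    dwi_noise_free: VolumeImage
    spec: PhantomSpec


def _centered_affine(shape: tuple[int, int, int], spacing: tuple[float, float, float]) -> np.ndarray:
    """Axis-aligned RAS affine putting the grid centre at world (0,0,0)."""
    affine = np.eye(4)
    for ax in range(3):
        affine[ax, ax] = spacing[ax]
        affine[ax, 3] = -(shape[ax] - 1) / 2.0 * spacing[ax]
    return affine


def _world_coords(shape: tuple[int, int, int], spacing: tuple[float, float, float]):
    """Sparse broadcastable world-coordinate arrays (x, y, z)."""
    return tuple(
        ((np.arange(shape[ax]) - (shape[ax] - 1) / 2.0) * spacing[ax]).reshape(
            [-1 if a == ax else 1 for a in range(3)]
        )
        for ax in range(3)
    )


def _inside_ellipsoid(x, y, z, center, semi_axes):
    cx, cy, cz = center
    a, b, c = semi_axes
    return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 + ((z - cz) / c) ** 2 <= 1.0


class _Anatomy:
    """Analytic tissue model evaluated at arbitrary world coordinates."""

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        self.lesion_center = spec.thalamus_center(spec.lesion_side)
        self.contra_center = spec.thalamus_center(
            "right" if spec.lesion_side == "left" else "left"
        )
        self.lesion_axes = spec.lesion_semi_axes()

    def masks(self, x, y, z) -> dict[str, np.ndarray]:
        return {
            "head": _inside_ellipsoid(x, y, z, (0, 0, 0), SKULL_OUTER_SEMI_AXES),
            "brain": _inside_ellipsoid(x, y, z, (0, 0, 0), BRAIN_SEMI_AXES),
            "thal_lesion_side": _inside_ellipsoid(
                x, y, z, self.lesion_center, THALAMUS_SEMI_AXES
            ),
            "thal_contra_side": _inside_ellipsoid(
                x, y, z, self.contra_center, THALAMUS_SEMI_AXES
            ),
            "lesion": _inside_ellipsoid(x, y, z, self.lesion_center, self.lesion_axes),
            "contra": _inside_ellipsoid(x, y, z, self.contra_center, self.lesion_axes),
        }

    def ct_clean(self, x, y, z) -> np.ndarray:
        s = self.spec
        m = self.masks(x, y, z)
        shape = np.broadcast_shapes(x.shape, y.shape, z.shape)
        out = np.full(shape, AIR_HU)
        out[m["head"]] = SKULL_HU
        out[m["brain"]] = s.brain_mean_hu
        out[m["thal_lesion_side"] | m["thal_contra_side"]] = s.thalamus_mean_hu
        out[m["lesion"]] = s.lesion_hu
        return out

    def dwi_clean(self, x, y, z) -> np.ndarray:
        s = self.spec
        m = self.masks(x, y, z)
        shape = np.broadcast_shapes(x.shape, y.shape, z.shape)
        out = np.full(shape, DWI_AIR_INTENSITY)
        out[m["head"]] = DWI_SKULL_INTENSITY
        out[m["brain"]] = s.dwi_brain_intensity
        out[m["lesion"]] = s.dwi_lesion_intensity
        return out


def _mirror_symmetrize(arr: np.ndarray) -> np.ndarray:
    """Make a field exactly mirror-symmetric about the mid-sagittal voxel plane."""
    out = arr.copy()
    half = arr.shape[0] // 2
    out[:half] = np.flip(arr, axis=0)[:half]
    return out


def generate_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Generate one seeded CT/DWI phantom pair with ground truth.

    Deterministic given ``spec.seed``.  The noise-free CT channel is exactly
    mirror-symmetric about the mid-sagittal plane except for the lesion, and
    the mean HU inside the true lesion mask equals
    ``thalamus_mean_hu x (1 - lesion_nwu_pct/100)`` exactly (the mirrored
    within-thalamus texture is demeaned over the lesion footprint, so the
    lesion and its mirror image keep exact sample means while texture variance
    is preserved elsewhere).
    """
    spec.validate()
    anat = _Anatomy(spec)
    rng = np.random.default_rng(spec.seed)

    # -- CT channel ---------------------------------------------------------
    shape = tuple(int(n) for n in spec.grid_shape)
    spacing = (spec.voxel_size_mm,) * 3
    x, y, z = _world_coords(shape, spacing)
    masks = anat.masks(x, y, z)
    ct_clean = anat.ct_clean(x, y, z)

    thal_both = masks["thal_lesion_side"] | masks["thal_contra_side"]
    if spec.thalamus_sd_hu > 0:
        texture = _mirror_symmetrize(rng.normal(0.0, spec.thalamus_sd_hu, size=shape))
        texture[~thal_both] = 0.0
        lesion = masks["lesion"]
        if lesion.any():
            texture[thal_both] -= texture[lesion].mean()
            texture[~thal_both] = 0.0
        ct_clean = ct_clean + texture

    ct_noisy = ct_clean
    if spec.noise_sd_hu > 0:
        ct_noisy = ct_clean + rng.normal(0.0, spec.noise_sd_hu, size=shape)
    if spec.round_to_int_hu:
        ct_noisy = np.round(ct_noisy)

    ct_affine = _centered_affine(shape, spacing)
    ct = VolumeImage(ct_noisy, ct_affine, "CT")
    ct_noise_free = VolumeImage(ct_clean, ct_affine, "CT")

    lesion_ct = SegmentationMask(masks["lesion"].astype(np.uint8), ct_affine, "lesion")
    contra_ct = SegmentationMask(
        masks["contra"].astype(np.uint8), ct_affine, "contralateral"
    )
    brain_ct = SegmentationMask(masks["brain"].astype(np.uint8), ct_affine, "brain")

    # -- DWI channel (misaligned grid, anatomy evaluated analytically) ------
    fov = np.asarray(shape, float) * spec.voxel_size_mm
    dwi_shape = tuple(int(math.ceil(fov[ax] / spec.dwi_voxel_size_mm[ax])) for ax in range(3))
    dwi_affine = _centered_affine(dwi_shape, spec.dwi_voxel_size_mm)
    dx, dy, dz = _world_coords(dwi_shape, spec.dwi_voxel_size_mm)
    # DWI voxel at world p shows the anatomy at T(p) in the CT frame,
    # where T = misalignment maps DWI world -> CT world.
    grid = np.stack(np.broadcast_arrays(dx, dy, dz), axis=-1).reshape(-1, 3)
    warped = spec.misalignment.apply(grid)
    wx = warped[:, 0].reshape(dwi_shape)
    wy = warped[:, 1].reshape(dwi_shape)
    wz = warped[:, 2].reshape(dwi_shape)

    dwi_clean = anat.dwi_clean(wx, wy, wz)
    dwi_noisy = dwi_clean
    if spec.dwi_noise_sd > 0:
        dwi_noisy = dwi_clean + rng.normal(0.0, spec.dwi_noise_sd, size=dwi_shape)
    dwi = VolumeImage(dwi_noisy, dwi_affine, "DWI")
    dwi_noise_free = VolumeImage(dwi_clean, dwi_affine, "DWI")

    lesion_dwi = SegmentationMask(
        _inside_ellipsoid(wx, wy, wz, anat.lesion_center, anat.lesion_axes).astype(np.uint8),
        dwi_affine,
        "lesion",
    )

    return PhantomBundle(
        ct=ct,
        dwi=dwi,
        truth_lesion_mask_dwi=lesion_dwi,
        truth_lesion_mask_ct=lesion_ct,
        truth_contralateral_mask_ct=contra_ct,
        truth_brain_mask_ct=brain_ct,
        truth_transform=spec.misalignment,
        truth_nwu_pct=spec.lesion_nwu_pct,
        ct_noise_free=ct_noise_free,
        dwi_noise_free=dwi_noise_free,
        spec=spec,
    )


def make_template(grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE,
                  voxel_size_mm: float = DEFAULT_VOXEL_MM) -> VolumeImage:
    """Built-in mid-sagittally symmetric head template (lesion-free, noise-free).

    Serves the role an external symmetric atlas would play: it defines the
    mirror plane x = 0 in template world coordinates.
    """
    spec = PhantomSpec(
        grid_shape=grid_shape,
        voxel_size_mm=voxel_size_mm,
        thalamus_sd_hu=0.0,
        lesion_nwu_pct=0.0,
        noise_sd_hu=0.0,
        misalignment=RigidTransform.identity(),
        dwi_noise_sd=0.0,
        dwi_lesion_intensity=110.0,
        dwi_brain_intensity=100.0,
    )
    anat = _Anatomy(spec)
    shape = tuple(int(n) for n in grid_shape)
    spacing = (voxel_size_mm,) * 3
    x, y, z = _world_coords(shape, spacing)
    ct = anat.ct_clean(x, y, z)
    # no lesion: overwrite the (NWU = 0) lesion region is a no-op already,
    # but make symmetry explicit
    ct = _mirror_symmetrize(ct)
    return VolumeImage(ct, _centered_affine(shape, spacing), "CT")


# -- cohort generation ------------------------------------------------------

def generate_cohort(
    specs: list[PhantomSpec],
    onset_hours: list[float],
    out_dir: str | Path,
    case_ids: list[str] | None = None,
) -> Path:
    """Write one phantom bundle per case plus a JSON manifest.

    Returns the manifest path.  The manifest records case id, onset-to-CT
    hours, ground-truth NWU, seed and file layout, and round-trips losslessly.
    """
    from . import io as _io  # deferred: io imports images only

    if len(specs) != len(onset_hours):
        raise ValidationError(
            f"specs ({len(specs)}) and onset_hours ({len(onset_hours)}) differ in length"
        )
    if case_ids is None:
        case_ids = [f"case-{i + 1:03d}" for i in range(len(specs))]
    if len(case_ids) != len(specs):
        raise ValidationError("case_ids must match specs in length")
    if len(set(case_ids)) != len(case_ids):
        dupes = sorted({c for c in case_ids if case_ids.count(c) > 1})
        raise ValidationError(f"duplicate case ids requested: {dupes}")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cases = []
    for cid, spec, hours in zip(case_ids, specs, onset_hours):
        bundle = generate_phantom(spec)
        case_dir = out_dir / cid
        case_dir.mkdir(parents=True, exist_ok=True)
        _io.write_volume(bundle.ct, case_dir / "ct.nii.gz")
        _io.write_volume(bundle.dwi, case_dir / "dwi.nii.gz")
        _io.write_mask(bundle.truth_lesion_mask_dwi, case_dir / "truth_lesion_dwi.nii.gz")
        _io.write_mask(bundle.truth_lesion_mask_ct, case_dir / "truth_lesion_ct.nii.gz")
        _io.write_mask(
            bundle.truth_contralateral_mask_ct, case_dir / "truth_contralateral_ct.nii.gz"
        )
        _io.write_mask(bundle.truth_brain_mask_ct, case_dir / "truth_brain_ct.nii.gz")
        bundle.truth_transform.save(case_dir / "truth_transform.json")
        cases.append(
            {
                "case_id": cid,
                "onset_to_ct_hours": float(hours),
                "truth_nwu_pct": float(bundle.truth_nwu_pct),
                "seed": int(spec.seed),
                "ct": f"{cid}/ct.nii.gz",
                "dwi": f"{cid}/dwi.nii.gz",
                "truth_lesion_dwi": f"{cid}/truth_lesion_dwi.nii.gz",
                "truth_lesion_ct": f"{cid}/truth_lesion_ct.nii.gz",
                "truth_contralateral_ct": f"{cid}/truth_contralateral_ct.nii.gz",
                "truth_brain_ct": f"{cid}/truth_brain_ct.nii.gz",
                "truth_transform": f"{cid}/truth_transform.json",
            }
        )
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps({"cases": cases}, indent=1))
    return manifest_path


def load_manifest(path: str | Path) -> list[dict]:
    return json.loads(Path(path).read_text())["cases"]


def cohort_specs_like_study(
    n_per_window: int = 11,
    nwu_by_window: tuple[float, float, float, float] = (6.4, 7.3, 14.4, 16.6),
    noise_sd_hu: float = 1.0,
    thalamus_sd_hu: float = 2.6,
    seed: int = 0,
    **overrides,
) -> tuple[list[PhantomSpec], list[float]]:
    """Specs and onset hours for a study-like cohort.

    One block of ``n_per_window`` cases per onset time window, with
    ground-truth NWU set to the window's cohort mean and onset times at the
    window mid-points.  Seeds are derived deterministically from ``seed``.
    """
    mid_hours = (3.0, 9.0, 18.0, 30.0)
    specs: list[PhantomSpec] = []
    hours: list[float] = []
    base = PhantomSpec()
    k = 0
    for nwu, h in zip(nwu_by_window, mid_hours):
        for _ in range(n_per_window):
            specs.append(
                replace(
                    base,
                    lesion_nwu_pct=nwu,
                    noise_sd_hu=noise_sd_hu,
                    thalamus_sd_hu=thalamus_sd_hu,
                    seed=(seed * 100003 + k) % (2**31 - 1),
                    lesion_side="left" if k % 3 else "right",
                    **overrides,
                )
            )
            hours.append(h)
            k += 1
    return specs, hours
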