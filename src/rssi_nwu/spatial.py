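"""Spatial workflow: brain extraction, lesion segmentation, co-registration,
template normalization and contralateral mirroring.

The workflow mirrors a DWI-defined infarct onto the co-registered CT: the
lesion is segmented on DWI, shrunk to exclude partial-volume boundary voxels,
carried into CT space by a rigid multimodal registration, and reflected about
the mid-sagittal plane of a built-in symmetric head template to sample the
homologous contralateral tissue.

Conventions
-----------
* Transforms map *source* world mm to *target* world mm (a DWI->CT transform
  maps DWI coordinates onto CT coordinates).
* Masks are resampled with nearest-neighbour interpolation, images with
  linear interpolation.
* Registration uses SimpleITK with fixed sampling seeds, so results are
  reproducible run to run.
"""

from __future__ import annotations

import functools
import math

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .errors import ConvergenceError, EmptySelectionError, ValidationError
from .images import SegmentationMask, VolumeImage, dice
from .phantom import make_template
from .transforms import AffineTransform, AnyTransform, RigidTransform, as_matrix

__all__ = [
    "extract_brain",
    "segment_lesion_dwi",
    "shrink_mask",
    "register_rigid",
    "resample_mask",
    "normalize_to_template",
    "mirror_mask_across_midline",
    "default_template",
    "dice",
]


# -- SimpleITK bridge -------------------------------------------------------

def _to_sitk(img: VolumeImage) -> sitk.Image:
    # our arrays are indexed (i, j, k) = (x, y, z); SimpleITK expects z-fastest
    arr = np.ascontiguousarray(np.transpose(img.data.astype(np.float32), (2, 1, 0)))
    out = sitk.GetImageFromArray(arr)
    out.SetSpacing(tuple(float(s) for s in img.spacing))
    out.SetOrigin(tuple(float(o) for o in img.origin))
    out.SetDirection(tuple(img.direction.flatten()))
    return out


def _euler_to_matrix(tx: sitk.Euler3DTransform) -> np.ndarray:
    m = np.eye(4)
    r = np.asarray(tx.GetMatrix()).reshape(3, 3)
    c = np.asarray(tx.GetCenter())
    t = np.asarray(tx.GetTranslation())
    m[:3, :3] = r
    m[:3, 3] = c + t - r @ c
    return m


def _affine_to_matrix(tx: sitk.AffineTransform) -> np.ndarray:
    m = np.eye(4)
    a = np.asarray(tx.GetMatrix()).reshape(3, 3)
    c = np.asarray(tx.GetCenter())
    t = np.asarray(tx.GetTranslation())
    m[:3, :3] = a
    m[:3, 3] = c + t - a @ c
    return m


def _check_converged(reg: sitk.ImageRegistrationMethod, budget: int) -> None:
    desc = reg.GetOptimizerStopConditionDescription()
    if "Maximum number of iterations" in desc and reg.GetOptimizerIteration() >= budget:
        raise ConvergenceError(
            f"registration did not converge within {budget} iterations "
            f"(final metric {reg.GetMetricValue():.6f}): {desc}",
            final_metric=float(reg.GetMetricValue()),
        )


def _best_of(reg: sitk.ImageRegistrationMethod, fixed: sitk.Image, moving: sitk.Image,
             candidates: list[sitk.Transform]) -> sitk.Transform:
    """Pick the candidate with the lowest metric value (ITK metrics: lower is better).

    Guards the step-walking optimizer against leaving an already-optimal
    initialization (its first move is always a full step away from the start).
    """
    scored = []
    for tx in candidates:
        reg.SetInitialTransform(tx, inPlace=False)
        scored.append((float(reg.MetricEvaluate(fixed, moving)), tx))
    return min(scored, key=lambda p: p[0])[1]


# -- segmentation -----------------------------------------------------------

def extract_brain(
    img: VolumeImage,
    hu_low: float = 0.0,
    hu_high: float = 100.0,
) -> SegmentationMask:
    """Threshold-based brain extraction.

    Selects voxels with intensity in ``[hu_low, hu_high]`` (for CT the default
    0-100 HU captures parenchyma while excluding skull and air), keeps the
    largest connected component and fills interior holes.
    """
    if not hu_low < hu_high:
        raise ValidationError(f"hu_low ({hu_low}) must be < hu_high ({hu_high})")
    sel = (img.data >= hu_low) & (img.data <= hu_high)
    if not sel.any():
        raise EmptySelectionError(
            f"no voxel in intensity range [{hu_low}, {hu_high}]"
        )
    labels, n = ndimage.label(sel)
    if n > 1:
        sizes = ndimage.sum_labels(sel, labels, index=np.arange(1, n + 1))
        sel = labels == (int(np.argmax(sizes)) + 1)
    sel = ndimage.binary_fill_holes(sel)
    return SegmentationMask(sel.astype(np.uint8), img.affine, "brain")


def segment_lesion_dwi(
    dwi: VolumeImage,
    brain: SegmentationMask,
    k_sd: float = 3.0,
) -> SegmentationMask:
    """Segment the hyperintense DWI lesion.

    Voxels brighter than ``brain mean + k_sd x brain SD`` (within the brain
    mask) are selected, restricted to the largest connected component, eroded
    by one pass and hole-filled.
    """
    brain.check_aligned(dwi)
    vals = dwi.data[brain.boolean()]
    thr = float(vals.mean() + k_sd * vals.std())
    sel = (dwi.data > thr) & brain.boolean()
    if not sel.any():
        raise EmptySelectionError(
            f"no voxel above brain mean + {k_sd} x SD (threshold {thr:.2f})"
        )
    labels, n = ndimage.label(sel)
    if n > 1:
        sizes = ndimage.sum_labels(sel, labels, index=np.arange(1, n + 1))
        sel = labels == (int(np.argmax(sizes)) + 1)
    sel = ndimage.binary_erosion(sel, iterations=1)
    if not sel.any():
        raise EmptySelectionError("lesion vanished after binary erosion (too small)")
    sel = ndimage.binary_fill_holes(sel)
    return SegmentationMask(sel.astype(np.uint8), dwi.affine, "lesion")


def shrink_mask(mask: SegmentationMask, target_fraction: float = 0.9) -> SegmentationMask:
    """Shrink a mask to approximately ``target_fraction`` of its volume.

    Boundary voxels are peeled by raising a Euclidean distance-transform
    threshold (in mm, anisotropy-aware) until the volume first drops to at
    most the target; the result is a subset of the input and never empty.
    """
    if not 0.0 < target_fraction <= 1.0:
        raise ValidationError(f"target_fraction must be in (0, 1], got {target_fraction}")
    n0 = mask.count
    if n0 == 0:
        raise ValidationError("cannot shrink an empty mask")
    if target_fraction == 1.0:
        return mask.with_data(mask.data.copy())
    n_keep = int(math.floor(target_fraction * n0))
    if n_keep < 1:
        raise ValidationError(
            f"shrinking to {target_fraction:.2f} of volume would empty the mask "
            f"({n0} voxels); use a larger target_fraction"
        )
    dt = ndimage.distance_transform_edt(mask.boolean(), sampling=mask.spacing)
    idx = np.argwhere(mask.boolean())
    depth = dt[tuple(idx.T)]
    # deepest voxels survive; ties within the cut distance class are broken by
    # voxel index order (stable sort), so the result is deterministic
    order = np.argsort(-depth, kind="stable")
    keep_idx = idx[order[:n_keep]]
    out = np.zeros_like(mask.data)
    out[tuple(keep_idx.T)] = 1
    return mask.with_data(out)


# -- registration -----------------------------------------------------------

def register_rigid(
    fixed: VolumeImage,
    moving: VolumeImage,
    max_iterations: int = 300,
    sampling_fraction: float = 0.2,
    seed: int = 13,
) -> RigidTransform:
    """Rigid (6-DOF) multimodal registration of ``moving`` onto ``fixed``.

    Maximizes Mattes mutual information over a 3-level multi-resolution
    pyramid, with geometry-centred initialization and a fixed sampling seed
    for reproducibility.  Returns the transform mapping *moving* world
    coordinates onto *fixed* world coordinates (e.g. DWI -> CT).
    """
    f = _to_sitk(fixed)
    m = _to_sitk(moving)
    init = sitk.CenteredTransformInitializer(
        f, m, sitk.Euler3DTransform(), sitk.CenteredTransformInitializerFilter.GEOMETRY
    )
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=50)
    reg.SetMetricSamplingStrategy(reg.RANDOM)
    reg.SetMetricSamplingPercentage(sampling_fraction, seed)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=2.0,
        minStep=5e-4,
        numberOfIterations=max_iterations,
        gradientMagnitudeTolerance=1e-8,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    optimized = sitk.Euler3DTransform(init)
    reg.SetInitialTransform(optimized, inPlace=True)
    reg.Execute(f, m)
    _check_converged(reg, max_iterations)
    best = _best_of(reg, f, m, [optimized, sitk.Euler3DTransform(init)])
    euler = sitk.Euler3DTransform(best)
    fixed_to_moving = _euler_to_matrix(euler)
    # SimpleITK's resampling transform maps fixed -> moving points; the
    # anatomical moving -> fixed mapping is its inverse.
    return RigidTransform.from_matrix(
        np.linalg.inv(fixed_to_moving), center_mm=tuple(euler.GetCenter())
    )


def normalize_to_template(
    img: VolumeImage,
    template: VolumeImage | None = None,
    max_iterations: int = 300,
    sampling_fraction: float = 0.2,
    seed: int = 17,
) -> AffineTransform:
    """Affine (12-DOF) normalization of a CT to the symmetric head template.

    Returns the transform mapping subject world coordinates onto template
    world coordinates; its only downstream use is to define the mirror
    (mid-sagittal) plane, which the template fixes at x = 0.
    """
    if template is None:
        template = default_template()
    f = _to_sitk(template)
    m = _to_sitk(img)

    def _configure(reg: sitk.ImageRegistrationMethod) -> None:
        reg.SetMetricAsCorrelation()
        reg.SetMetricSamplingStrategy(reg.RANDOM)
        reg.SetMetricSamplingPercentage(sampling_fraction, seed)
        reg.SetInterpolator(sitk.sitkLinear)
        reg.SetOptimizerAsRegularStepGradientDescent(
            learningRate=2.0,
            minStep=1e-3,
            numberOfIterations=max_iterations,
            gradientMagnitudeTolerance=1e-8,
        )
        reg.SetOptimizerScalesFromPhysicalShift()
        reg.SetShrinkFactorsPerLevel([4, 2, 1])
        reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
        reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()

    # stage 1: rigid alignment (pose carries the rotational signal of the
    # near-ellipsoidal head far more strongly than the full 12-DOF problem)
    rigid0 = sitk.CenteredTransformInitializer(
        f, m, sitk.Euler3DTransform(), sitk.CenteredTransformInitializerFilter.GEOMETRY
    )
    reg = sitk.ImageRegistrationMethod()
    _configure(reg)
    rigid = sitk.Euler3DTransform(rigid0)
    reg.SetInitialTransform(rigid, inPlace=True)
    reg.Execute(f, m)
    _check_converged(reg, max_iterations)
    rigid = sitk.Euler3DTransform(
        _best_of(reg, f, m, [rigid, sitk.Euler3DTransform(rigid0)])
    )

    # stage 2: affine refinement initialized at the rigid pose
    affine0 = sitk.AffineTransform(3)
    affine0.SetCenter(rigid.GetCenter())
    affine0.SetMatrix(rigid.GetMatrix())
    affine0.SetTranslation(rigid.GetTranslation())
    reg = sitk.ImageRegistrationMethod()
    _configure(reg)
    optimized = sitk.AffineTransform(affine0)
    reg.SetInitialTransform(optimized, inPlace=True)
    reg.Execute(f, m)
    _check_converged(reg, max_iterations)
    best = _best_of(reg, f, m, [optimized, sitk.AffineTransform(affine0)])
    template_to_subject = _affine_to_matrix(sitk.AffineTransform(best))
    return AffineTransform(np.linalg.inv(template_to_subject))


@functools.lru_cache(maxsize=1)
def default_template() -> VolumeImage:
    """The built-in mid-sagittally symmetric head template (mirror plane x = 0)."""
    return make_template()


TEMPLATE_MID_X_MM = 0.0


# -- resampling and mirroring ----------------------------------------------

def resample_mask(
    mask: SegmentationMask,
    transform: AnyTransform | np.ndarray,
    target: VolumeImage | SegmentationMask,
    allow_empty: bool = False,
) -> SegmentationMask:
    """Resample a mask onto ``target``'s grid through a world-space transform.

    ``transform`` maps the mask's world coordinates onto the target's world
    coordinates.  Nearest-neighbour interpolation; with an identity transform
    on an identical grid the output is bit-identical to the input.
    """
    matrix = as_matrix(transform)
    # target voxel -> target world -> (inverse transform) mask world -> mask voxel
    full = np.linalg.inv(mask.affine) @ np.linalg.inv(matrix) @ target.affine
    shape = target.shape
    ii, jj, kk = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]),
        indexing="ij", sparse=True,
    )
    ci = full[0, 0] * ii + full[0, 1] * jj + full[0, 2] * kk + full[0, 3]
    cj = full[1, 0] * ii + full[1, 1] * jj + full[1, 2] * kk + full[1, 3]
    ck = full[2, 0] * ii + full[2, 1] * jj + full[2, 2] * kk + full[2, 3]
    out = ndimage.map_coordinates(
        mask.data,
        [np.broadcast_to(c, shape) for c in (ci, cj, ck)],
        order=0,
        mode="constant",
        cval=0,
    )
    if not allow_empty and not out.any():
        raise EmptySelectionError(
            f"resampled {mask.role} mask is empty on the target grid"
        )
    return SegmentationMask(out.astype(np.uint8), target.affine, mask.role,
                            allow_empty=allow_empty)


def mirror_mask_across_midline(
    mask: SegmentationMask,
    to_template: AffineTransform,
    template_mid_x_mm: float = TEMPLATE_MID_X_MM,
) -> SegmentationMask:
    """Reflect a lesion mask about the template mid-sagittal plane.

    The mask is carried to template space by ``to_template``, reflected about
    the plane x = ``template_mid_x_mm`` and carried back, yielding the
    homologous contralateral region in native space.  The composite native
    mapping ``A^-1 o F o A`` is a single affine, so only one nearest-neighbour
    resampling occurs.
    """
    reflect = AffineTransform.reflection_x(template_mid_x_mm)
    native_mirror = to_template.inverse().compose(reflect).compose(to_template)
    out = resample_mask(
        mask,
        native_mirror,
        SegmentationMask(mask.data, mask.affine, mask.role),
        allow_empty=True,
    )
    if out.count == 0:
        raise EmptySelectionError("mirrored mask is empty")
    return out.with_data(out.data, role="contralateral", allow_empty=False)
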