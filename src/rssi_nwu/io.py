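"""NIfTI, CSV and JSON input/output plus provenance sidecars.

Volumes are exchanged as NIfTI-1 (optionally gzipped) with the voxel-to-world
affine in the header (RAS mm).  Masks are unsigned 8-bit NIfTI with values
{0, 1}; a {0, 255}-valued mask is normalized on read with a warning.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np

from . import __version__
from .errors import FormatError
from .images import SegmentationMask, VolumeImage


def read_volume(path: str | Path, modality: str = "CT") -> VolumeImage:
    """Read a 3-D NIfTI volume.

    Raises :class:`FormatError` for unreadable files or non-3-D images.
    """
    path = Path(path)
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises several types for bad headers
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got {data.ndim}-D data")
    affine = img.affine
    if affine is None or not np.all(np.isfinite(affine)):
        raise FormatError(f"{path}: missing or non-finite affine header")
    return VolumeImage(np.asarray(data, dtype=np.float64), affine, modality)


def write_volume(img: VolumeImage, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(img.data, dtype=np.float32), img.affine), path)
    return path


def read_mask(path: str | Path, role: str = "lesion", allow_empty: bool = False) -> SegmentationMask:
    """Read a binary mask; tolerates the common {0, 255} dialect."""
    path = Path(path)
    try:
        img = nib.load(path)
    except Exception as exc:
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asarray(np.asanyarray(img.dataobj))
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D mask, got {data.ndim}-D data")
    vals = np.unique(data)
    if not np.all(np.isin(vals, (0, 1))):
        if np.all(np.isin(vals, (0, 255))):
            warnings.warn(
                f"{path}: mask uses values {{0, 255}}; normalizing to {{0, 1}}",
                stacklevel=2,
            )
            data = (data > 0).astype(np.uint8)
        else:
            raise FormatError(
                f"{path}: mask values must be binary, found {vals[:5].tolist()}"
            )
    return SegmentationMask(data.astype(np.uint8), img.affine, role, allow_empty=allow_empty)


def write_mask(mask: SegmentationMask, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine), path)
    return path


def write_sidecar(path: str | Path, *, seed: int | None = None, **params) -> Path:
    """Write a JSON provenance sidecar next to an output file."""
    path = Path(path)
    sidecar = path.with_name(path.name.split(".")[0] + ".params.json")
    payload = {"package": "rssi-nwu", "version": __version__, "seed": seed, **params}
    sidecar.write_text(json.dumps(payload, indent=1, default=_jsonify))
    return sidecar


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if hasattr(obj, "to_dict"):
        return obj.to_dict()
    if hasattr(obj, "__dict__"):
        return {k: v for k, v in vars(obj).items() if not k.startswith("_")}
    return str(obj)


def write_json(path: str | Path, payload: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=1, default=_jsonify))
    return path
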