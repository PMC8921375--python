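"""NIfTI / MetaImage volume I/O.

Volumes are normalized to RAS+ orientation on load; arrays are stored
``(z, y, x)`` (reversed NIfTI axis order) so the physical coordinate of a
voxel is ``origin + index * spacing`` per axis.  HU values are clamped to
[-1024, 3071]; out-of-range voxels are counted and reported with a warning.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import HU_MAX, HU_MIN, FormatError, Volume3D

log = logging.getLogger(__name__)


def _affine_from(vol: Volume3D) -> np.ndarray:
    aff = np.eye(4)
    # array axes (z, y, x) -> world axes (x, y, z)
    aff[0, 0] = vol.spacing[2]
    aff[1, 1] = vol.spacing[1]
    aff[2, 2] = vol.spacing[0]
    aff[:3, 3] = (vol.origin[2], vol.origin[1], vol.origin[0])
    return aff


def read_volume(path, phase: str = "inspiratory") -> Volume3D:
    """Load a NIfTI (or SimpleITK-convertible MetaImage) volume as HU.

    Raises :class:`bprm.core.FormatError` for unreadable or non-3-D inputs.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as err:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read {path} as an image: {err}") from err
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    aff = img.affine
    spacing_xyz = np.sqrt((aff[:3, :3] ** 2).sum(axis=0))
    origin_xyz = aff[:3, 3]
    out_of_range = int(np.count_nonzero((data < HU_MIN) | (data > HU_MAX)))
    if out_of_range:
        warnings.warn(
            f"{path.name}: clamped {out_of_range} voxels outside "
            f"[{HU_MIN:.0f}, {HU_MAX:.0f}] HU",
            stacklevel=2,
        )
        data = np.clip(data, HU_MIN, HU_MAX)
    return Volume3D(
        values=np.ascontiguousarray(data.T),  # (x,y,z) -> (z,y,x)
        spacing=tuple(float(s) for s in spacing_xyz[::-1]),
        origin=tuple(float(o) for o in origin_xyz[::-1]),
        phase=phase,
    )


def write_volume(vol: Volume3D, path, dtype=np.float32) -> None:
    data = np.asarray(vol.values, dtype=dtype).T  # (z,y,x) -> (x,y,z)
    img = nib.Nifti1Image(data, _affine_from(vol))
    nib.save(img, str(path))


def write_labels(labels: np.ndarray, geometry: Volume3D, path,
                 label_dict: dict | None = None) -> None:
    """Write an unsigned-integer label map with a JSON label dictionary sidecar."""
    data = np.asarray(labels).astype(np.uint8).T
    img = nib.Nifti1Image(data, _affine_from(geometry))
    nib.save(img, str(path))
    if label_dict is not None:
        side = Path(str(path)).with_suffix("").with_suffix("")  # strip .nii.gz
        with open(str(side) + ".labels.json", "w") as fh:
            json.dump(label_dict, fh, indent=2, sort_keys=True)


def read_labels(path) -> tuple[np.ndarray, Volume3D]:
    vol = read_volume(path)
    return vol.values.astype(np.uint8), vol
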