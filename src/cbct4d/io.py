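"""Readers and writers for volumes (MHA / NIfTI), projections (HDF5) and
run manifests.

Volumes store the voxel spacing and the physical position of the first
voxel center in the container header, so write -> read round-trips the
grid exactly.  Projection stacks live in HDF5 with datasets ``/frames``
(angle-major, float32), ``/angles`` and ``/timestamps``, and the scan
geometry as root attributes.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np

from .geometry import ScanGeometry
from .projector import ProjectionSet
from .volume import VolumeImage

__all__ = [
    "read_volume",
    "write_volume",
    "read_projections",
    "write_projections",
    "sha256_of",
]

_GEO_ATTRS = (
    "sad",
    "sdd",
    "detector_rows",
    "detector_cols",
    "pitch_u",
    "pitch_v",
    "lateral_offset",
)


def write_volume(path: str | Path, volume: VolumeImage) -> Path:
    """Write a volume as MetaImage (.mha/.mhd) or NIfTI (.nii/.nii.gz)."""
    path = Path(path)
    suffix = "".join(path.suffixes)
    first_center = np.asarray(volume.origin) + 0.5 * np.asarray(volume.voxel_size)
    if suffix in (".mha", ".mhd"):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(volume.values.T))
        img.SetSpacing(tuple(volume.voxel_size))
        img.SetOrigin(tuple(first_center))
        sitk.WriteImage(img, str(path))
    elif suffix in (".nii", ".nii.gz"):
        import nibabel as nib

        affine = np.diag(list(volume.voxel_size) + [1.0])
        affine[:3, 3] = first_center
        nib.save(nib.Nifti1Image(volume.values, affine), str(path))
    else:
        raise ValueError(f"unsupported volume format {suffix!r}")
    return path


def read_volume(path: str | Path) -> VolumeImage:
    path = Path(path)
    suffix = "".join(path.suffixes)
    if suffix in (".mha", ".mhd"):
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        values = sitk.GetArrayFromImage(img).T
        spacing = np.asarray(img.GetSpacing())
        first_center = np.asarray(img.GetOrigin())
    elif suffix in (".nii", ".nii.gz"):
        import nibabel as nib

        img = nib.load(str(path))
        values = np.asarray(img.dataobj, dtype=float)
        affine = img.affine
        spacing = np.abs(np.diag(affine)[:3])
        first_center = affine[:3, 3]
    else:
        raise ValueError(f"unsupported volume format {suffix!r}")
    origin = tuple(first_center - 0.5 * spacing)
    return VolumeImage(np.ascontiguousarray(values, dtype=float), tuple(spacing), origin)


def write_projections(
    path: str | Path, projections: ProjectionSet, geometry: ScanGeometry | None = None
) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=projections.frames.astype(np.float32))
        f.create_dataset("angles", data=projections.angles)
        f.create_dataset("timestamps", data=projections.timestamps)
        f.attrs["n0"] = projections.n0
        if geometry is not None:
            for name in _GEO_ATTRS:
                f.attrs[name] = getattr(geometry, name)
    return path


def read_projections(path: str | Path) -> tuple[ProjectionSet, ScanGeometry | None]:
    path = Path(path)
    with h5py.File(path, "r") as f:
        for ds in ("frames", "angles", "timestamps"):
            if ds not in f:
                raise ValueError(f"projection file {path} is missing /{ds}")
        frames = np.asarray(f["frames"], dtype=np.float64)
        angles = np.asarray(f["angles"])
        timestamps = np.asarray(f["timestamps"])
        n0 = float(f.attrs.get("n0", 1e5))
        geometry = None
        if all(name in f.attrs for name in _GEO_ATTRS):
            geometry = ScanGeometry(
                sad=float(f.attrs["sad"]),
                sdd=float(f.attrs["sdd"]),
                detector_rows=int(f.attrs["detector_rows"]),
                detector_cols=int(f.attrs["detector_cols"]),
                pitch_u=float(f.attrs["pitch_u"]),
                pitch_v=float(f.attrs["pitch_v"]),
                lateral_offset=float(f.attrs["lateral_offset"]),
                angles=angles,
                timestamps=timestamps,
            )
    return ProjectionSet(frames, angles, timestamps, n0=n0), geometry


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, payload: dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path
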