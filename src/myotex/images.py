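"""Lightweight image containers and NIfTI / DICOM-series I/O.

The pipeline exchanges three kinds of objects: a 3D tracer-uptake volume
(:class:`VolumeImage`), a single short-axis slice (:class:`SliceImage`) and a
binary left-ventricle region of interest (:class:`ROIMask`).  They are thin
wrappers over numpy arrays carrying physical voxel spacing; every numeric
routine in the package accepts either the wrapper or a bare array.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class VolumeImage:
    """A 3D scalar intensity grid with voxel spacing in mm.

    Axial (short-axis) slices are indexed along the last axis.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.voxels.shape}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite values")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape


@dataclass
class SliceImage:
    """A 2D scalar intensity grid with pixel spacing in mm."""

    pixels: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"slice must be 2D, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("slice contains non-finite values")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape


@dataclass
class ROIMask:
    """Binary mask aligned to a parent volume or slice."""

    voxels: np.ndarray
    spacing: tuple = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("mask values must be 0/1")
        self.voxels = arr.astype(bool)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape

    def count(self) -> int:
        return int(self.voxels.sum())


def as_array(obj) -> np.ndarray:
    """Return the underlying numpy array of a container or a bare array."""
    if isinstance(obj, VolumeImage):
        return obj.voxels
    if isinstance(obj, SliceImage):
        return obj.pixels
    if isinstance(obj, ROIMask):
        return obj.voxels
    return np.asarray(obj)


def as_bool_mask(obj, shape=None) -> np.ndarray:
    arr = as_array(obj).astype(bool)
    if shape is not None and arr.shape != tuple(shape):
        raise ValueError(f"mask shape {arr.shape} does not match image {tuple(shape)}")
    return arr


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_volume(path) -> VolumeImage:
    """Read a 3D volume from a NIfTI file or a DICOM series directory."""
    import os

    if os.path.isdir(str(path)):
        return _read_dicom_series(path)
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    zooms = img.header.get_zooms()[:3]
    return VolumeImage(data, spacing=tuple(float(z) for z in zooms))


def _read_dicom_series(dirpath) -> VolumeImage:
    import os

    import pydicom

    files = sorted(
        os.path.join(dirpath, f) for f in os.listdir(dirpath) if not f.startswith(".")
    )
    slices = [pydicom.dcmread(f) for f in files]
    slices.sort(key=lambda d: float(getattr(d, "InstanceNumber", 0)))
    vol = np.stack([s.pixel_array.astype(float) for s in slices], axis=-1)
    ps = getattr(slices[0], "PixelSpacing", [1.0, 1.0])
    dz = float(getattr(slices[0], "SliceThickness", 1.0))
    return VolumeImage(vol, spacing=(float(ps[0]), float(ps[1]), dz))


def write_volume(vol: VolumeImage, path) -> None:
    import nibabel as nib

    affine = np.diag(list(vol.spacing) + [1.0])
    nib.save(nib.Nifti1Image(vol.voxels.astype(np.float32), affine), str(path))


def read_mask(path) -> ROIMask:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    return ROIMask(data > 0)


def write_mask(mask: ROIMask, path, spacing=(1.0, 1.0, 1.0)) -> None:
    import nibabel as nib

    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(as_array(mask).astype(np.uint8), affine), str(path))
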