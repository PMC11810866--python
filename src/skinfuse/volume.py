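"""Volumetric image container, file I/O and grid preprocessing.

A :class:`VolumetricImage` is a 3D scalar grid (CT Hounsfield units or
arbitrary MR intensity) together with the geometric metadata needed to map
voxel indices to world millimetres::

    world = origin + axes @ (index * spacing)

with 0-based indices, strictly positive per-axis ``spacing`` in mm and an
orthonormal direction matrix ``axes`` with determinant +1.  Slices are
stacked along ``slice_axis`` (default: the third array axis).

Two preprocessing steps feed the skin segmentation:

* :func:`pad_volume` adds an in-plane border of background (global minimum
  intensity) around every slice, so that region growing can always start
  from the slice corners and flow around objects touching the field of
  view (e.g. the scanner bed).
* :func:`subsample_volume` decimates the grid (keep every ``factor``-th
  voxel) to trade surface resolution for speed.  No anti-alias filtering is
  applied: the point is to test/exploit robustness to the raw
  lower-resolution image.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "VolumetricImage",
    "SegmentationConfig",
    "VolumeFormatError",
    "read_volume",
    "write_volume",
    "pad_volume",
    "subsample_volume",
]

_ORTHO_TOL = 1e-4


class VolumeFormatError(ValueError):
    """A volume file could not be interpreted; the message names the field."""


@dataclass
class VolumetricImage:
    """3D scalar image with voxel-to-world geometry.

    Parameters
    ----------
    data:
        3D array of intensities, indexed ``data[i, j, k]``.
    spacing:
        Per-axis voxel size in mm, strictly positive.
    origin:
        World position (mm) of voxel ``(0, 0, 0)``.
    axes:
        3x3 orthonormal direction matrix (columns are the world directions
        of the three index axes); determinant must be +1.
    slice_axis:
        Index of the array axis along which 2D slices are stacked.
    """

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axes: np.ndarray = field(default_factory=lambda: np.eye(3))
    slice_axis: int = 2

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got ndim={self.data.ndim}")
        if any(n < 2 for n in self.data.shape):
            raise ValueError(f"each axis needs >= 2 voxels, got shape {self.data.shape}")
        if not np.all(self.spacing > 0):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        _check_direction(self.axes)
        if self.slice_axis not in (0, 1, 2):
            raise ValueError(f"slice_axis must be 0, 1 or 2, got {self.slice_axis}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def world_coords(self, indices: np.ndarray) -> np.ndarray:
        """Map (N, 3) voxel indices to (N, 3) world coordinates in mm."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return self.origin + (self.axes @ (idx * self.spacing).T).T

    @property
    def inplane_axes(self) -> tuple[int, int]:
        """The two array axes lying within a slice."""
        return tuple(a for a in (0, 1, 2) if a != self.slice_axis)  # type: ignore[return-value]


@dataclass
class SegmentationConfig:
    """Parameters of the skin segmentation.

    ``iso_value`` is the skin iso-value: the intensity threshold separating
    air (below) from body tissue (at or above).  For CT this is a Hounsfield
    value; for MR an arbitrary scanner-dependent level.  ``pad_width`` voxels
    of background border are added around each slice before region growing;
    ``subsample_factor`` optionally decimates the volume first.
    """

    iso_value: float
    pad_width: int = 1
    subsample_factor: int = 1
    slice_axis: int | None = None  # override the volume's slice axis

    def __post_init__(self) -> None:
        if self.pad_width < 0:
            raise ValueError("pad_width must be >= 0")
        if self.subsample_factor < 1:
            raise ValueError("subsample_factor must be >= 1")


def _check_direction(axes: np.ndarray) -> None:
    if not np.allclose(axes.T @ axes, np.eye(3), atol=_ORTHO_TOL):
        raise VolumeFormatError(
            "direction matrix is not orthonormal (axes^T axes != I)"
        )
    if not np.isclose(np.linalg.det(axes), 1.0, atol=_ORTHO_TOL):
        raise VolumeFormatError(
            f"direction matrix must have determinant +1, got {np.linalg.det(axes):.6f}"
        )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_META_SUFFIXES = (".mha", ".mhd")


def _infer_format(path: str | os.PathLike) -> str:
    name = str(path).lower()
    if name.endswith(_NIFTI_SUFFIXES):
        return "nifti"
    if name.endswith(_META_SUFFIXES):
        return "metaimage"
    raise VolumeFormatError(f"cannot infer volume format from path {path!r}")


def read_volume(path: str | os.PathLike, format: str | None = None) -> VolumetricImage:
    """Read a NIfTI-1 (``.nii``/``.nii.gz``) or MetaImage (``.mha``/``.mhd``) volume.

    The voxel grid is returned untouched (no intensity rescaling); geometry
    comes from the header.  A header whose direction matrix is not a proper
    rotation raises :class:`VolumeFormatError`.
    """
    fmt = format or _infer_format(path)
    if fmt == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        affine = img.affine
        if affine is None:
            raise VolumeFormatError("NIfTI header carries no affine")
        M = affine[:3, :3]
        spacing = np.linalg.norm(M, axis=0)
        if np.any(spacing <= 0):
            raise VolumeFormatError(f"non-positive voxel spacing in affine: {spacing}")
        axes = M / spacing
        _check_direction(axes)
        data = np.asanyarray(img.dataobj)
        return VolumetricImage(data=data, spacing=spacing, origin=affine[:3, 3], axes=axes)
    if fmt == "metaimage":
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        if img.GetDimension() != 3:
            raise VolumeFormatError(f"expected 3D image, got {img.GetDimension()}D")
        axes = np.asarray(img.GetDirection(), dtype=float).reshape(3, 3)
        _check_direction(axes)
        # SimpleITK arrays are indexed [k, j, i]; ours are [i, j, k]
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        return VolumetricImage(
            data=data,
            spacing=np.asarray(img.GetSpacing()),
            origin=np.asarray(img.GetOrigin()),
            axes=axes,
        )
    raise VolumeFormatError(f"unsupported volume format {fmt!r}")


def write_volume(vol: VolumetricImage, path: str | os.PathLike, format: str | None = None) -> None:
    """Write a volume as NIfTI-1 or MetaImage, preserving geometry."""
    fmt = format or _infer_format(path)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    if fmt == "nifti":
        import nibabel as nib

        affine = np.eye(4)
        affine[:3, :3] = vol.axes * vol.spacing
        affine[:3, 3] = vol.origin
        nib.save(nib.Nifti1Image(np.asarray(vol.data), affine), str(path))
        return
    if fmt == "metaimage":
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.transpose(2, 1, 0)))
        img.SetSpacing(tuple(float(s) for s in vol.spacing))
        img.SetOrigin(tuple(float(o) for o in vol.origin))
        img.SetDirection(tuple(vol.axes.ravel()))
        sitk.WriteImage(img, str(path))
        return
    raise VolumeFormatError(f"unsupported volume format {fmt!r}")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def pad_volume(vol: VolumetricImage, cfg: SegmentationConfig | int) -> VolumetricImage:
    """Add an in-plane background border around every slice.

    The border is ``pad_width`` voxels wide and filled with the global
    minimum intensity of the original volume, guaranteeing that the slice
    corners are background so region growing can start there and flow
    around any object touching the original field of view.  Padding is
    in-plane only (slice count unchanged) and the origin is shifted so that
    original voxels keep their world coordinates.
    """
    pad = cfg.pad_width if isinstance(cfg, SegmentationConfig) else int(cfg)
    if pad == 0:
        return vol
    fill = float(np.min(vol.data))
    widths = [(0, 0)] * 3
    offset = np.zeros(3)
    for a in vol.inplane_axes:
        widths[a] = (pad, pad)
        offset[a] = pad
    data = np.pad(vol.data, widths, mode="constant", constant_values=fill)
    origin = vol.origin - vol.axes @ (offset * vol.spacing)
    return VolumetricImage(
        data=data, spacing=vol.spacing, origin=origin, axes=vol.axes, slice_axis=vol.slice_axis
    )


def subsample_volume(
    vol: VolumetricImage, factor: int | Sequence[int]
) -> VolumetricImage:
    """Decimate the grid, keeping every ``factor``-th voxel from index 0.

    ``factor`` may be a scalar or per-axis triple.  Spacing is multiplied by
    the factor; the origin is unchanged (voxel 0 stays put).  Pure
    decimation — no smoothing.
    """
    f = np.broadcast_to(np.asarray(factor, dtype=int), (3,)).copy()
    if np.any(f < 1):
        raise ValueError(f"subsample factor must be >= 1, got {f}")
    if np.any(f >= np.asarray(vol.shape)):
        raise ValueError(
            f"subsample factor {tuple(f)} too large for volume of shape {vol.shape}"
        )
    data = vol.data[:: f[0], :: f[1], :: f[2]]
    return VolumetricImage(
        data=data,
        spacing=vol.spacing * f,
        origin=vol.origin,
        axes=vol.axes,
        slice_axis=vol.slice_axis,
    )
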