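"""Volumes, NIfTI I/O and patch extraction/recombination.

A :class:`Volume` is a dense 2D or 3D scalar lattice with voxel spacing (mm)
and a physical origin. Axis order is (x, y, z), matching the on-disk array
layout; voxel indices are 0-based and ranges are half-open.

Large volumes are processed patch-wise: patches are extracted by sliding a
fixed-size window over the lattice, the last window per axis clamped so it
ends exactly at the boundary, and recombined by count-normalized averaging
of overlapping footprints.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "read_volume",
    "write_volume",
    "patch_offsets",
    "extract_patches",
    "recombine_patches",
]


@dataclass
class Volume:
    """A scalar image lattice with geometry.

    Parameters
    ----------
    data : ndarray
        2D or 3D array of finite intensities.
    spacing : tuple of float
        Physical size of a voxel along each axis, mm. Strictly positive.
    origin : tuple of float
        Physical coordinate of voxel (0, ..., 0).
    """

    data: np.ndarray
    spacing: tuple = ()
    origin: tuple = ()

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim not in (2, 3):
            raise ValueError(f"expected a 2D or 3D lattice, got ndim={self.data.ndim}")
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"all lattice dimensions must be >= 1, got {self.data.shape}")
        if not self.spacing:
            self.spacing = (1.0,) * self.data.ndim
        if not self.origin:
            self.origin = (0.0,) * self.data.ndim
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != self.data.ndim or len(self.origin) != self.data.ndim:
            raise ValueError("spacing/origin length must match lattice dimensionality")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite (no NaN/Inf)")

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def like(self, data: np.ndarray) -> "Volume":
        """New Volume with this volume's geometry and different data."""
        return Volume(np.asarray(data), self.spacing, self.origin)


def _affine(spacing, origin):
    aff = np.eye(4)
    for i, s in enumerate(spacing[:3]):
        aff[i, i] = s
    for i, o in enumerate(origin[:3]):
        aff[i, 3] = o
    return aff


def read_volume(path) -> Volume:
    """Read a NIfTI (.nii/.nii.gz) scalar volume.

    Geometry (spacing, origin) is taken from the header; intensities are
    returned unchanged as float64.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    # trailing singleton dimensions are how 2D images live in NIfTI files
    while data.ndim > 2 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim not in (2, 3):
        raise ValueError(f"{path}: expected a scalar 2D/3D volume, got shape {data.shape}")
    if not np.issubdtype(data.dtype, np.number):
        raise ValueError(f"{path}: non-scalar voxel type {data.dtype}")
    zooms = img.header.get_zooms()[: data.ndim]
    origin = tuple(float(x) for x in img.affine[: data.ndim, 3])
    return Volume(data.astype(np.float64), tuple(float(z) for z in zooms), origin)


def write_volume(v: Volume, path) -> None:
    """Write a Volume as NIfTI-1 (float64, axis-aligned affine)."""
    data = v.data
    if data.ndim == 2:
        data = data[:, :, None]
    spacing = v.spacing + (1.0,) * (3 - len(v.spacing))
    origin = v.origin + (0.0,) * (3 - len(v.origin))
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), _affine(spacing, origin))
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def patch_offsets(size: int, patch: int, stride: int) -> list:
    """Covering start offsets along one axis; the last offset is clamped so
    the final patch ends at the boundary."""
    if patch > size:
        raise ValueError(f"patch ({patch}) larger than axis ({size})")
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    if stride > patch:
        raise ValueError(f"stride ({stride}) > patch ({patch}) would leave uncovered voxels")
    offs = list(range(0, size - patch + 1, stride))
    if offs[-1] + patch < size:
        offs.append(size - patch)
    return offs


def extract_patches(v: Volume, patch_shape, stride):
    """Extract covering patches by sliding a window over the volume.

    Returns a list of ``(offset, Volume)`` pairs in lexicographic offset
    order. The union of patch footprints covers every voxel.
    """
    patch_shape = _per_axis(patch_shape, v.ndim)
    stride = _per_axis(stride, v.ndim)
    axes_offsets = [patch_offsets(v.shape[a], patch_shape[a], stride[a]) for a in range(v.ndim)]
    out = []
    for off in itertools.product(*axes_offsets):
        sl = tuple(slice(o, o + p) for o, p in zip(off, patch_shape))
        origin = tuple(v.origin[a] + off[a] * v.spacing[a] for a in range(v.ndim))
        out.append((off, Volume(v.data[sl].copy(), v.spacing, origin)))
    return out


def recombine_patches(patches, out_shape, spacing=None, origin=None) -> Volume:
    """Reassemble patches into a full volume.

    Overlapping regions are averaged with uniform weights (count-normalized
    accumulation). Voxels whose overlapping contributions all agree keep
    that exact value, so a round trip over unmodified patches is bit-exact
    for any covering stride. Raises if any voxel of ``out_shape`` is
    uncovered.
    """
    out_shape = tuple(out_shape)
    acc = np.zeros(out_shape, dtype=np.float64)
    cnt = np.zeros(out_shape, dtype=np.int64)
    first = np.zeros(out_shape, dtype=np.float64)
    agree = np.ones(out_shape, dtype=bool)
    for off, p in patches:
        data = p.data if isinstance(p, Volume) else np.asarray(p, dtype=np.float64)
        sl = tuple(slice(o, o + s) for o, s in zip(off, data.shape))
        if any(o < 0 or o + s > n for o, s, n in zip(off, data.shape, out_shape)):
            raise ValueError(f"patch at {off} with shape {data.shape} exceeds output {out_shape}")
        seen = cnt[sl] > 0
        agree[sl] &= np.where(seen, first[sl] == data, True)
        first[sl] = np.where(seen, first[sl], data)
        acc[sl] += data
        cnt[sl] += 1
    if np.any(cnt == 0):
        raise ValueError("patches do not cover the output volume")
    data = np.where(agree, first, acc / cnt)
    first_patch = patches[0][1]
    if spacing is None and isinstance(first_patch, Volume):
        spacing = first_patch.spacing
    if origin is None and isinstance(first_patch, Volume):
        # patch origins are absolute; volume origin corresponds to offset 0
        origin = tuple(
            first_patch.origin[a] - patches[0][0][a] * first_patch.spacing[a] for a in range(len(out_shape))
        )
    return Volume(data, spacing or (), origin or ())


def _per_axis(value, ndim):
    if np.isscalar(value):
        return (int(value),) * ndim
    value = tuple(int(x) for x in value)
    if len(value) != ndim:
        raise ValueError(f"expected {ndim} per-axis values, got {value}")
    return value
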