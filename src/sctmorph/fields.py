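"""Displacement-field algebra for deformable registration.

A displacement field D stores one vector per voxel, in voxel units on the
fixed-image grid; the associated deformation is Delta = Id + D. Warping uses
the pull-back convention: the warped image is sampled at x + D(x) with
linear interpolation and nearest-boundary extension.

Composition of two fields follows the accumulation rule

    D1 (+) D2 = (Delta1 o Delta2) - Id,  i.e.  (D1 (+) D2)(x) = D2(x) + D1(x + D2(x)),

which remains diffeomorphic when both inputs are (diagnosed, not enforced,
via the Jacobian determinant of Id + D).

Regularization is certainty-weighted normalized convolution: each component
is smoothed as G_sigma*(c . d) / G_sigma*(c), so locations with high
certainty dominate their neighbourhood and structureless regions inherit
the field of nearby reliable ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import Volume, read_volume, write_volume

__all__ = [
    "DisplacementField",
    "warp",
    "compose",
    "regularize",
    "jacobian_determinant",
    "read_field",
    "write_field",
]


@dataclass
class DisplacementField:
    """Per-voxel displacement vectors, shape (dim, *lattice), voxel units.

    The zero field is the identity deformation.
    """

    vectors: np.ndarray

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim < 2 or self.vectors.shape[0] != self.vectors.ndim - 1:
            raise ValueError(
                f"expected (dim, *lattice) with matching dim, got {self.vectors.shape}"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement components must be finite")

    @classmethod
    def zero(cls, shape) -> "DisplacementField":
        shape = tuple(shape)
        return cls(np.zeros((len(shape),) + shape))

    @property
    def dim(self) -> int:
        return self.vectors.shape[0]

    @property
    def shape(self):
        return self.vectors.shape[1:]

    def magnitude(self) -> np.ndarray:
        return np.sqrt(np.sum(self.vectors**2, axis=0))


def _identity_coords(shape):
    return np.stack(np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape], indexing="ij"))


def _sample(data: np.ndarray, coords: np.ndarray, order: int = 1) -> np.ndarray:
    # nearest-boundary extension; order 1 = linear (monotone), 3 = cubic spline
    return ndimage.map_coordinates(data, coords, order=order, mode="nearest")


def warp(v, d: DisplacementField, order: int = 1):
    """Warp an image: output(x) = v(x + d(x)) (pull-back).

    Linear interpolation by default (cheap and monotone, so impulse noise
    cannot ring); the registration driver warps with cubic splines
    internally, where interpolation blur would bias the phase differences.
    """
    data = v.data if isinstance(v, Volume) else np.asarray(v, dtype=np.float64)
    if data.shape != d.shape:
        raise ValueError(f"shape mismatch: image {data.shape} vs field {d.shape}")
    coords = _identity_coords(data.shape) + d.vectors
    out = _sample(data, coords, order)
    return v.like(out) if isinstance(v, Volume) else out


def compose(d1: DisplacementField, d2: DisplacementField) -> DisplacementField:
    """Displacement of the composed deformation Delta1 o Delta2.

    result(x) = d2(x) + d1(x + d2(x)); d1 is resampled linearly. Applying
    the composed field in one warp matches warping by d1 then by d2.
    """
    if d1.shape != d2.shape:
        raise ValueError(f"shape mismatch: {d1.shape} vs {d2.shape}")
    coords = _identity_coords(d2.shape) + d2.vectors
    moved = np.stack([_sample(comp, coords) for comp in d1.vectors])
    return DisplacementField(d2.vectors + moved)


def regularize(d: DisplacementField, certainty: np.ndarray, sigma: float) -> DisplacementField:
    """Certainty-weighted normalized convolution with a Gaussian kernel.

    Per component: G_sigma*(c . d) / G_sigma*(c) where the denominator
    exceeds eps = 1e-8 * max(c); elsewhere the output is zero. Uniform
    certainty reduces to plain Gaussian smoothing.
    """
    certainty = np.asarray(certainty, dtype=np.float64)
    if certainty.shape != d.shape:
        raise ValueError(f"certainty shape {certainty.shape} != field shape {d.shape}")
    if np.any(certainty < 0):
        raise ValueError("certainty must be non-negative")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    cmax = certainty.max()
    if cmax == 0:
        return DisplacementField(np.zeros_like(d.vectors))
    denom = ndimage.gaussian_filter(certainty, sigma)
    eps = 1e-8 * cmax
    safe = denom > eps
    out = np.zeros_like(d.vectors)
    for a in range(d.dim):
        num = ndimage.gaussian_filter(certainty * d.vectors[a], sigma)
        out[a][safe] = num[safe] / denom[safe]
    return DisplacementField(out)


def jacobian_determinant(d: DisplacementField) -> np.ndarray:
    """det(I + grad d) per voxel.

    Gradients use central differences in the interior and one-sided
    differences at the boundary (numpy.gradient). Values > 0 everywhere
    diagnose a locally invertible (diffeomorphism-compatible) field.
    """
    if any(s < 3 for s in d.shape):
        raise ValueError(f"field too small for Jacobian, shape {d.shape}")
    dim = d.dim
    jac = np.empty(d.shape + (dim, dim))
    for i in range(dim):
        grads = np.gradient(d.vectors[i])
        if dim == 1:
            grads = [grads]
        for j in range(dim):
            jac[..., i, j] = grads[j] + (1.0 if i == j else 0.0)
    return np.linalg.det(jac)


def write_field(d: DisplacementField, path) -> None:
    """Save as a multi-component NIfTI, components stacked on the last axis."""
    arr = np.moveaxis(d.vectors, 0, -1)
    import nibabel as nib

    if arr.ndim == 3:  # 2D field -> (x, y, 1, comp)
        arr = arr[:, :, None, :]
    nib.save(nib.Nifti1Image(arr.astype(np.float64), np.eye(4)), str(path))


def read_field(path) -> DisplacementField:
    import nibabel as nib

    arr = np.asarray(nib.load(str(path)).dataobj).astype(np.float64)
    arr = np.squeeze(arr) if arr.shape[-1] != arr.ndim - 1 else arr
    vecs = np.moveaxis(arr, -1, 0)
    return DisplacementField(vecs)
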