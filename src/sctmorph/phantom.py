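"""Seeded head-like phantoms: paired multi-contrast MR + CT with ground truth.

Each phantom is built from one tissue label map with exactly three classes —
air (0), soft tissue (1) and bone (2) — arranged as an ellipsoidal head: a
bone shell enclosing soft tissue with embedded air cavities, surrounded by
air. The four modalities (fat, water, R2 MR contrasts and CT) share this
geometry but assign deliberately different class contrasts (bone bright on
CT, dark on every MR contrast; soft tissue bright on "fat", dimmer on
"water", dim on "R2"), emulating the contrast inversions that defeat
intensity-based multimodal registration. Per-class Gaussian intensity noise
and a smooth multiplicative bias field are added.

The corrupted MR is the clean MR warped by a known smooth diffeomorphic
displacement field and then hit with salt-and-pepper impulse noise — a
stand-in for acquisition-time deformation and contamination. All randomness
derives from a single integer seed via numpy SeedSequence spawning (one
sub-stream per consumer), so a case is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .fields import DisplacementField, jacobian_determinant, warp
from .volume import Volume

__all__ = [
    "AIR",
    "SOFT",
    "BONE",
    "PhantomSpec",
    "PhantomCase",
    "generate_phantom",
    "random_smooth_field",
    "salt_and_pepper",
    "head_mask",
]

AIR, SOFT, BONE = 0, 1, 2

MODALITIES = ("fat", "water", "r2", "ct")

# class mean intensity per modality (arbitrary units), indexed [air, soft, bone]
DEFAULT_TISSUE_MODEL = {
    "ct": (0.0, 0.5, 1.0),
    "fat": (0.05, 0.9, 0.1),
    "water": (0.05, 0.5, 0.15),
    "r2": (0.1, 0.3, 0.05),
}
DEFAULT_TISSUE_SIGMA = 0.02


@dataclass
class PhantomSpec:
    """Study conditions for one synthetic case."""

    shape: tuple = (64, 64)
    seed: int = 0
    tissue_model: dict = dc_field(default_factory=lambda: dict(DEFAULT_TISSUE_MODEL))
    tissue_sigma: float = DEFAULT_TISSUE_SIGMA
    bias_amplitude: float = 0.1
    deform_amplitude: float = 3.0
    deform_smoothness: float = 8.0
    sp_noise_fraction: float = 0.02

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if any(s < 32 for s in self.shape):
            raise ValueError(f"phantom axes must be >= 32 voxels, got {self.shape}")
        if not (0.0 <= self.sp_noise_fraction < 1.0):
            raise ValueError("sp_noise_fraction must be in [0, 1)")
        if self.deform_amplitude < 0:
            raise ValueError("deform_amplitude must be >= 0")


@dataclass
class PhantomCase:
    """One generated case: geometry, clean/corrupted MR, CT, true field."""

    labels: np.ndarray
    mr: dict  # contrast name -> Volume (clean)
    mr_corrupted: dict  # contrast name -> Volume (deformed + salt-and-pepper)
    ct: Volume
    true_field: DisplacementField
    spec: PhantomSpec
    noise_seeds: dict = None  # contrast name -> salt-and-pepper sub-seed


def _ellipse_mask(shape, center, radii):
    grids = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape], indexing="ij")
    r2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return r2 <= 1.0


def _label_map(shape, rng) -> np.ndarray:
    labels = np.full(shape, AIR, dtype=np.int64)
    center = [s / 2.0 for s in shape]
    outer = [0.42 * s for s in shape]
    inner = [r - max(2.5, 0.05 * min(shape)) for r in outer]
    labels[_ellipse_mask(shape, center, outer)] = BONE
    labels[_ellipse_mask(shape, center, inner)] = SOFT
    # 2-3 air cavities at jittered but seeded positions inside the soft region
    n_cav = int(rng.integers(2, 4))
    for _ in range(n_cav):
        offs = rng.uniform(-0.18, 0.18, size=len(shape))
        cav_center = [c + o * s for c, o, s in zip(center, offs, shape)]
        cav_radii = [max(2.0, rng.uniform(0.05, 0.1) * s) for s in shape]
        cav = _ellipse_mask(shape, cav_center, cav_radii)
        labels[cav & (labels == SOFT)] = AIR
    return labels


def _bias_field(shape, amplitude, rng) -> np.ndarray:
    raw = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(raw, sigma=[0.25 * s for s in shape])
    span = smooth.max() - smooth.min()
    if span == 0:
        return np.ones(shape)
    return 1.0 + amplitude * (2.0 * (smooth - smooth.min()) / span - 1.0)


def _render(labels, means, sigma, bias, rng) -> np.ndarray:
    img = np.zeros(labels.shape, dtype=np.float64)
    noise = rng.standard_normal(labels.shape) * sigma
    for cls, mean in enumerate(means):
        img[labels == cls] = mean
    return (img + noise) * bias


def random_smooth_field(shape, amplitude: float, smoothness: float, seed) -> DisplacementField:
    """Gaussian-smoothed random vectors scaled to a max magnitude.

    The amplitude is halved until the minimum Jacobian determinant of
    Id + D exceeds 0.1, guaranteeing a comfortably invertible field.
    """
    shape = tuple(int(s) for s in shape)
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    if amplitude == 0:
        return DisplacementField.zero(shape)
    raw = rng.standard_normal((len(shape),) + shape)
    smooth = np.stack([ndimage.gaussian_filter(c, smoothness) for c in raw])
    mag = np.sqrt(np.sum(smooth**2, axis=0)).max()
    if mag == 0:
        return DisplacementField.zero(shape)
    amp = float(amplitude)
    while True:
        d = DisplacementField(smooth * (amp / mag))
        if jacobian_determinant(d).min() > 0.1 or amp < 1e-6:
            return d
        amp /= 2.0


def salt_and_pepper(v: Volume, fraction: float, seed) -> Volume:
    """Set an exact seeded fraction of voxels to the volume min (pepper) or
    max (salt), each with probability 1/2; other voxels unchanged."""
    if not (0.0 <= fraction < 1.0):
        raise ValueError("fraction must be in [0, 1)")
    data = v.data.copy()
    n = data.size
    k = int(round(fraction * n))
    if k:
        rng = np.random.default_rng(seed)
        idx = rng.choice(n, size=k, replace=False)
        salt = rng.random(k) < 0.5
        flat = data.ravel()
        flat[idx[salt]] = data.max()
        flat[idx[~salt]] = data.min()
    return v.like(data)


def head_mask(labels: np.ndarray) -> np.ndarray:
    """Voxels inside the head (bone shell and everything it encloses)."""
    return ndimage.binary_fill_holes(labels != AIR)


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Generate one paired multi-contrast MR + CT case with ground truth.

    Randomness is split into independent sub-streams (geometry, bias, per-
    modality noise, deformation, corruption) derived from ``spec.seed``, so
    identical specs give bit-identical cases.
    """
    ss = np.random.SeedSequence(spec.seed)
    keys = ["geometry", "bias", "fat", "water", "r2", "ct", "deform", "noise"]
    streams = dict(zip(keys, ss.spawn(len(keys))))

    labels = _label_map(spec.shape, np.random.default_rng(streams["geometry"]))
    bias = _bias_field(spec.shape, spec.bias_amplitude, np.random.default_rng(streams["bias"]))

    volumes = {}
    for mod in MODALITIES:
        rng = np.random.default_rng(streams[mod])
        volumes[mod] = Volume(_render(labels, spec.tissue_model[mod], spec.tissue_sigma, bias, rng))
    ct = volumes.pop("ct")
    mr = volumes

    deform_seed = streams["deform"].generate_state(1)[0] % (2**31)
    true_field = random_smooth_field(spec.shape, spec.deform_amplitude, spec.deform_smoothness, deform_seed)

    noise_state = streams["noise"].generate_state(len(mr)) % (2**31)
    noise_seeds = {}
    mr_corrupted = {}
    for (name, vol), nseed in zip(sorted(mr.items()), noise_state):
        deformed = warp(vol, true_field)
        noise_seeds[name] = int(nseed)
        mr_corrupted[name] = salt_and_pepper(deformed, spec.sp_noise_fraction, int(nseed))

    return PhantomCase(labels=labels, mr=mr, mr_corrupted=mr_corrupted, ct=ct,
                       true_field=true_field, spec=spec, noise_seeds=noise_seeds)
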